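"""Curated glycosaminoglycan (GAG) reaction–gene knowledge base.

The knowledge base (KB) is the backbone of the pipeline: it enumerates the
enzymatic reactions of GAG biosynthesis — linker/backbone assembly, heparan
sulfate (HS) sulfation, chondroitin/dermatan sulfate (CS/DS) sulfation,
keratan sulfate (KS) synthesis and hyaluronan (HA) synthesis/catabolism —
and, for each reaction, the genes whose products can carry it out, together
with the aggregation semantics used to score the reaction from expression
data:

* ``ALTERNATIVES`` — isozymes; any single gene product suffices, so the
  reaction is scored by the *maximum* TPM over members.
* ``COMPLEX`` — obligate subunits of one enzyme complex (the EXT1/EXT2 HS
  polymerase); the reaction is scored by the *minimum* TPM over members.

The packaged ``paper-v1`` KB ships as a JSON data file so that membership can
be corrected without code changes. Its inventory is fixed by validation:
29 reactions in 5 categories and 66 distinct genes (reaction genes plus
auxiliary transporter / PAPS-synthesis / nucleotide-catabolism / regulator
sets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "GeneGroup",
    "ReactionStep",
    "AuxiliaryGeneSet",
    "KnowledgeBase",
    "ValidationReport",
    "load_kb",
    "validate_kb",
    "genes_for_reaction",
    "CATEGORIES",
    "SEMANTICS",
    "AUX_ROLES",
]

CATEGORIES = ("BACKBONE", "HS_SULFATION", "CSDS_SULFATION", "KS", "HA")
SEMANTICS = ("ALTERNATIVES", "COMPLEX")
AUX_ROLES = ("TRANSPORTER", "PAPS_SYNTHESIS", "NUCLEOTIDE_CATABOLISM", "REGULATOR")

#: inventory the packaged paper-v1 KB must satisfy
EXPECTED_GENES = 66
EXPECTED_REACTIONS = 29
EXPECTED_CATEGORIES = 5


class KBError(ValueError):
    """Malformed KB file or failed lookup."""


@dataclass(frozen=True)
class GeneGroup:
    """Genes able to perform one reaction, with aggregation semantics."""

    members: tuple[str, ...]
    semantics: str  # ALTERNATIVES | COMPLEX

    def __post_init__(self) -> None:
        if not self.members:
            raise KBError("gene group has no members")
        if self.semantics not in SEMANTICS:
            raise KBError(f"unknown semantics {self.semantics!r}")
        if len(set(self.members)) != len(self.members):
            raise KBError(f"duplicate members in gene group {self.members}")


@dataclass(frozen=True)
class ReactionStep:
    reaction_id: str
    display_number: int
    category: str
    gene_group: GeneGroup
    substrate_label: str
    product_label: str
    successor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise KBError(
                f"reaction {self.reaction_id!r}: unknown category {self.category!r}"
            )


@dataclass(frozen=True)
class AuxiliaryGeneSet:
    """Genes supporting GAG synthesis without a mapped reaction step.

    Nucleotide-sugar/PAPS transporters, PAPS synthases, nucleotide
    catabolism enzymes and transcriptional/Golgi regulators.
    """

    role: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in AUX_ROLES:
            raise KBError(f"unknown auxiliary role {self.role!r}")


@dataclass(frozen=True)
class KnowledgeBase:
    reactions: tuple[ReactionStep, ...]
    auxiliary: tuple[AuxiliaryGeneSet, ...]
    aliases: dict[str, str] = field(default_factory=dict)
    version: str = "unversioned"

    # -- inventory ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    @property
    def categories(self) -> list[str]:
        seen: list[str] = []
        for r in self.reactions:
            if r.category not in seen:
                seen.append(r.category)
        return seen

    def reactions_in(self, category: str) -> list[ReactionStep]:
        return [r for r in self.reactions if r.category == category]

    @property
    def reaction_genes(self) -> list[str]:
        """Distinct gene symbols appearing in reaction gene groups (KB order)."""
        out: list[str] = []
        for r in self.reactions:
            for g in r.gene_group.members:
                if g not in out:
                    out.append(g)
        return out

    @property
    def auxiliary_genes(self) -> list[str]:
        out: list[str] = []
        for a in self.auxiliary:
            for g in a.members:
                if g not in out:
                    out.append(g)
        return out

    @property
    def genes(self) -> list[str]:
        """All distinct gene symbols, reaction genes first (stable KB order)."""
        out = self.reaction_genes
        return out + [g for g in self.auxiliary_genes if g not in out]

    def reaction(self, reaction_id: str) -> ReactionStep:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        raise KBError(f"unknown reaction_id {reaction_id!r}")

    def resolve_alias(self, symbol: str) -> str:
        """Map an input symbol (case-insensitive) to its canonical KB symbol."""
        s = symbol.upper()
        return self.aliases.get(s, s)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "reactions": [
                {
                    "reaction_id": r.reaction_id,
                    "display_number": r.display_number,
                    "category": r.category,
                    "gene_group": {
                        "semantics": r.gene_group.semantics,
                        "members": list(r.gene_group.members),
                    },
                    "substrate_label": r.substrate_label,
                    "product_label": r.product_label,
                    "successor_ids": list(r.successor_ids),
                }
                for r in self.reactions
            ],
            "auxiliary": [
                {"role": a.role, "members": list(a.members)} for a in self.auxiliary
            ],
            "aliases": dict(self.aliases),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def to_tsv(self) -> str:
        """Flat one-gene-per-row export for diffing KB versions."""
        lines = ["reaction_id\tdisplay_number\tcategory\tsemantics\tgene_symbol"]
        for r in self.reactions:
            for g in r.gene_group.members:
                lines.append(
                    f"{r.reaction_id}\t{r.display_number}\t{r.category}"
                    f"\t{r.gene_group.semantics}\t{g}"
                )
        return "\n".join(lines) + "\n"


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    @property
    def valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "valid" if self.valid else "\n".join(self.violations)


def _parse_reaction(rec: dict) -> ReactionStep:
    try:
        gg = rec["gene_group"]
        return ReactionStep(
            reaction_id=rec["reaction_id"],
            display_number=int(rec["display_number"]),
            category=rec["category"],
            gene_group=GeneGroup(tuple(gg["members"]), gg["semantics"]),
            substrate_label=rec.get("substrate_label", ""),
            product_label=rec.get("product_label", ""),
            successor_ids=tuple(rec.get("successor_ids", ())),
        )
    except (KeyError, TypeError) as exc:
        raise KBError(
            f"malformed reaction record {rec.get('reaction_id', rec)!r}: {exc}"
        ) from exc


def load_kb(path: str | Path | None = None) -> KnowledgeBase:
    """Load a KB JSON file; with no path, load the packaged ``paper-v1`` KB.

    The returned KB has passed :func:`validate_kb`; a KB failing validation
    raises :class:`KBError` listing the violations.
    """
    if path is None:
        text = (
            resources.files("gagmap").joinpath("data/gag_kb_v1.json").read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise KBError(f"KB file is not valid JSON: {exc}") from exc

    reactions = tuple(_parse_reaction(r) for r in raw.get("reactions", ()))
    try:
        auxiliary = tuple(
            AuxiliaryGeneSet(a["role"], tuple(a["members"]))
            for a in raw.get("auxiliary", ())
        )
    except (KeyError, TypeError) as exc:
        raise KBError(f"malformed auxiliary record: {exc}") from exc
    kb = KnowledgeBase(
        reactions=reactions,
        auxiliary=auxiliary,
        aliases={k.upper(): v.upper() for k, v in raw.get("aliases", {}).items()},
        version=raw.get("version", "unversioned"),
    )
    report = validate_kb(kb, enforce_inventory=kb.version == "paper-v1")
    if not report.valid:
        raise KBError("KB failed validation:\n" + str(report))
    return kb


def validate_kb(kb: KnowledgeBase, enforce_inventory: bool = True) -> ValidationReport:
    """Check structural invariants; violations are reported, not raised.

    With ``enforce_inventory`` the fixed counts of the packaged KB
    (66 genes / 29 reactions / 5 categories, 12 backbone and 5 CS/DS
    sulfation steps) are also enforced.
    """
    rep = ValidationReport()

    ids = kb.reaction_ids
    for rid in sorted({i for i in ids if ids.count(i) > 1}):
        rep.add(f"duplicate reaction_id {rid!r}")

    id_set = set(ids)
    for r in kb.reactions:
        for s in r.successor_ids:
            if s not in id_set:
                rep.add(f"reaction {r.reaction_id!r}: unknown successor {s!r}")

    # per-category pathway graphs must be acyclic
    for cat in kb.categories:
        g = nx.DiGraph()
        cat_rx = kb.reactions_in(cat)
        cat_ids = {r.reaction_id for r in cat_rx}
        g.add_nodes_from(cat_ids)
        for r in cat_rx:
            for s in r.successor_ids:
                if s in cat_ids:
                    g.add_edge(r.reaction_id, s)
        if not nx.is_directed_acyclic_graph(g):
            rep.add(f"category {cat}: pathway graph contains a cycle")

    # a gene maps to exactly one gene group; one group may serve several
    # steps (the EXT1/EXT2 polymerase performs two numbered transfers)
    gene_to_group: dict[str, GeneGroup] = {}
    for r in kb.reactions:
        for g_sym in r.gene_group.members:
            prev = gene_to_group.setdefault(g_sym, r.gene_group)
            if prev != r.gene_group:
                rep.add(
                    f"gene {g_sym!r} appears in distinct gene groups "
                    f"({prev.members} vs {r.gene_group.members})"
                )

    aux_syms = kb.auxiliary_genes
    for g_sym in aux_syms:
        if g_sym in gene_to_group:
            rep.add(f"gene {g_sym!r} is both a reaction gene and auxiliary")
    if len(aux_syms) != sum(len(a.members) for a in kb.auxiliary):
        rep.add("duplicate gene symbol across auxiliary sets")

    for alias, target in kb.aliases.items():
        if target not in set(kb.genes):
            rep.add(f"alias {alias!r} resolves to unknown symbol {target!r}")
        if alias in set(kb.genes):
            rep.add(f"alias {alias!r} shadows a canonical symbol")

    if enforce_inventory:
        n_genes = len(set(kb.genes))
        if n_genes != EXPECTED_GENES:
            rep.add(f"gene count {n_genes} != {EXPECTED_GENES}")
        if len(kb.reactions) != EXPECTED_REACTIONS:
            rep.add(f"reaction count {len(kb.reactions)} != {EXPECTED_REACTIONS}")
        if len(kb.categories) != EXPECTED_CATEGORIES:
            rep.add(
                f"category count {len(kb.categories)} != {EXPECTED_CATEGORIES}"
            )
        expected_steps = {"BACKBONE": 12, "CSDS_SULFATION": 5}
        for cat, n in expected_steps.items():
            steps = sorted(r.display_number for r in kb.reactions_in(cat))
            if steps != list(range(1, n + 1)):
                rep.add(f"category {cat}: display numbers {steps} != 1..{n}")
    return rep


def genes_for_reaction(kb: KnowledgeBase, reaction_id: str) -> GeneGroup:
    """Gene group (members + semantics) responsible for one reaction step."""
    return kb.reaction(reaction_id).gene_group
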