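"""Reading and transforming gene-by-sample TPM expression tables.

Two table dialects are supported: consensus-tissue tables (gene rows, tissue
columns, each tissue its own group) and cohort tables (gene rows or columns,
plus a sample→group manifest, e.g. tumor/normal). Values are plain TPM
(transcripts per million); columns are never renormalized.

UCSC Xena distributes TCGA/GTEx expression as ``log2(TPM + 0.001)``;
:func:`xena_log_to_tpm` undoes that encoding. Boxplot-style displays use
``log2(TPM + 1)`` (:func:`log2_tpm_plus1`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .knowledge_base import KnowledgeBase

__all__ = [
    "ExpressionMatrix",
    "IngestReport",
    "read_tpm_table",
    "xena_log_to_tpm",
    "log2_tpm_plus1",
    "harmonize_symbols",
]


@dataclass
class ExpressionMatrix:
    """Gene × sample TPM matrix with a group label per sample.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample-id
    columns; ``sample_groups`` maps every sample id to a group label (tissue
    name, or ``tumor``/``normal``).
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values are not allowed")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> pd.Series:
        return pd.Series(
            [self.sample_groups[s] for s in self.sample_ids],
            index=self.values.columns,
            name="group",
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes], dict(self.sample_groups))

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class IngestReport:
    """Outcome of harmonizing a matrix against the knowledge base."""

    n_genes_matched: int
    unmatched_kb_genes: list[str]
    alias_resolutions: list[tuple[str, str]] = field(default_factory=list)
    collapsed_duplicates: list[str] = field(default_factory=list)


def read_tpm_table(
    path: str | Path,
    orientation: str,
    manifest: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table.

    ``orientation`` must be stated explicitly — ``"rows"`` for genes in rows
    (samples in columns) or ``"cols"`` for genes in columns. Silent
    auto-transposition is refused by design. Without a manifest, each column
    is treated as its own group (consensus-tissue dialect); a manifest TSV
    (``sample_id<TAB>group``, optional header) assigns cohort groups.
    """
    if orientation not in ("rows", "cols"):
        raise ValueError("orientation must be 'rows' or 'cols' (stated explicitly)")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "cols":
        df = df.T
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric cells in columns: {non_numeric}")
    if df.isna().to_numpy().any():
        raise ValueError("missing values in expression table")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative TPM in expression table")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if manifest is None:
        groups = {s: s for s in df.columns}
    else:
        man = pd.read_csv(manifest, sep="\t", header=None, dtype=str)
        if man.shape[1] < 2:
            raise ValueError("manifest must have two columns: sample_id, group")
        if list(man.iloc[0, :2]) == ["sample_id", "group"]:
            man = man.iloc[1:]
        groups = dict(zip(man.iloc[:, 0], man.iloc[:, 1]))
        absent = [s for s in df.columns if s not in groups]
        if absent:
            raise ValueError(f"manifest missing samples: {absent}")
        groups = {s: groups[s] for s in df.columns}
    return ExpressionMatrix(df, groups)


def xena_log_to_tpm(x):
    """Invert the UCSC Xena encoding: ``TPM = 2**x - 0.001``.

    Values that fall below zero only through the fixed 0.001 offset (the
    Xena zero-TPM encoding is ``log2(0.001)``) are clamped at 0.
    """
    tpm = np.power(2.0, np.asarray(x, dtype=float)) - 0.001
    tpm = np.clip(tpm, 0.0, None)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(tpm, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(tpm, index=x.index, name=x.name)
    if np.isscalar(x):
        return float(tpm)
    return tpm


def log2_tpm_plus1(tpm):
    """``log2(TPM + 1)`` display transform; 0 maps to 0, monotone."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative TPM")
    out = np.log2(arr + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    if isinstance(tpm, pd.Series):
        return pd.Series(out, index=tpm.index, name=tpm.name)
    if np.isscalar(tpm):
        return float(out)
    return out


def harmonize_symbols(
    m: ExpressionMatrix, kb: KnowledgeBase
) -> tuple[ExpressionMatrix, IngestReport]:
    """Upper-case symbols, resolve KB aliases, collapse duplicates by max.

    Duplicate rows mapping to one canonical symbol are collapsed by the
    per-sample maximum, consistent with the isozyme (ALTERNATIVES)
    aggregation rule. Idempotent. The report lists KB genes absent from the
    harmonized matrix.
    """
    df = m.values.copy()
    originals = [str(g) for g in df.index]
    canonical = [kb.resolve_alias(g) for g in originals]
    aliases = [
        (orig, canon)
        for orig, canon in zip(originals, canonical)
        if orig.upper() != canon
    ]
    df.index = pd.Index(canonical, name=df.index.name)

    collapsed: list[str] = []
    if df.index.has_duplicates:
        collapsed = sorted(set(df.index[df.index.duplicated()]))
        df = df.groupby(level=0, sort=False).max()

    kb_genes = kb.genes
    present = set(df.index)
    unmatched = [g for g in kb_genes if g not in present]
    report = IngestReport(
        n_genes_matched=len(kb_genes) - len(unmatched),
        unmatched_kb_genes=unmatched,
        alias_resolutions=aliases,
        collapsed_duplicates=collapsed,
    )
    return ExpressionMatrix(df, dict(m.sample_groups)), report
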