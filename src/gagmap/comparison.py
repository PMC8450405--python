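"""Tumor-vs-normal differential analysis of genes and pathway reactions.

Fold changes follow the median-with-pseudocount convention:

    fc = (median(tumor TPM) + 1) / (median(normal TPM) + 1)

A target is called UP when fc > 1.5 and DOWN when fc < 1/1.5 (displayed as
0.667), strictly; otherwise UNCHANGED. The raw median ratio (no pseudocount)
is reported alongside — it is the unbiased estimator of a multiplicative
expression shift, whereas the pseudocounted ratio, which is the
classification statistic, shrinks toward 1 for low-expressed genes.

Significance uses the two-sided Wilcoxon rank-sum (Mann–Whitney) test by
default: the cohorts compared here are unpaired and of unequal size, so the
matched-pairs signed-rank variant, while exposed for genuinely paired
designs, cannot be the default. Exact p-values are computed for small
tie-free samples (≤ 25 per arm) and the tie-corrected normal approximation
otherwise.

Reaction-level records aggregate per-sample gene TPM into per-sample
reaction activities first and take medians second (aggregate-then-median);
the reverse order is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, harmonize_symbols
from .knowledge_base import KnowledgeBase
from .reaction_mapping import reaction_activity

__all__ = [
    "UP",
    "DOWN",
    "UNCHANGED",
    "FoldChangeRecord",
    "ComparisonResult",
    "median_fold_change",
    "classify_direction",
    "rank_test",
    "compare_cohorts",
]

UP, DOWN, UNCHANGED = "UP", "DOWN", "UNCHANGED"

#: classification thresholds on (median+1) ratios; the lower bound is the
#: exact reciprocal of the upper (displayed as 0.667)
UP_THRESHOLD = 1.5
DOWN_THRESHOLD = 1.0 / UP_THRESHOLD
ALPHA_DISPLAY = 1e-4  # significance level highlighted in reports

EXACT_MAX_N = 25  # per-arm size up to which the exact rank-sum null is used


@dataclass
class FoldChangeRecord:
    target_id: str
    level: str  # "gene" | "reaction"
    median_tumor: float
    median_normal: float
    fc: float  # (median_tumor + pseudocount) / (median_normal + pseudocount)
    fc_raw: float  # median_tumor / median_normal (nan when median_normal == 0)
    direction: str
    p_value: float
    n_tumor: int
    n_normal: int
    in_kb: bool = True
    q_value: float | None = None


@dataclass
class ComparisonResult:
    records: list[FoldChangeRecord]
    up_threshold: float = UP_THRESHOLD
    down_threshold: float = DOWN_THRESHOLD
    alpha_display: float = ALPHA_DISPLAY

    def record(self, target_id: str, level: str | None = None) -> FoldChangeRecord:
        for r in self.records:
            if r.target_id == target_id and (level is None or r.level == level):
                return r
        raise KeyError(f"no record for {target_id!r}")

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "target_id", "level", "median_tumor", "median_normal", "fc",
            "fc_raw", "direction", "p_value", "q_value", "n_tumor",
            "n_normal", "in_kb",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records])


def median_fold_change(
    tumor_values, normal_values, pseudocount: float = 1.0
) -> tuple[float, float, float, float]:
    """Return (median_tumor, median_normal, fc, fc_raw).

    fc is the pseudocounted ratio used for classification; fc_raw the plain
    median ratio (nan when the normal median is 0).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("empty sample list")
    mt, mn = float(np.median(t)), float(np.median(n))
    fc = (mt + pseudocount) / (mn + pseudocount)
    fc_raw = mt / mn if mn > 0 else float("nan")
    return mt, mn, fc, fc_raw


def classify_direction(
    fc: float, up: float = UP_THRESHOLD, down: float = DOWN_THRESHOLD
) -> str:
    """UP iff fc > up, DOWN iff fc < down (both strict), else UNCHANGED."""
    if not fc > 0:
        raise ValueError("fold change must be positive")
    if fc > up:
        return UP
    if fc < down:
        return DOWN
    return UNCHANGED


def rank_test(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided rank test between two samples.

    Unpaired (default): Wilcoxon rank-sum / Mann–Whitney U; the exact null
    distribution is enumerated when both arms have ≤ 25 tie-free
    observations, otherwise the tie-corrected normal approximation is used.
    ``paired=True`` runs the Wilcoxon matched-pairs signed-rank test on
    equal-length samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        if a.size < 3:
            raise ValueError("paired test requires n >= 3 pairs")
        if np.array_equal(a, b):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if a.size < 3 or b.size < 3:
        raise ValueError("rank-sum test requires >= 3 observations per arm")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact"
        if (not has_ties and a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _bh(pvals: list[float]) -> list[float]:
    return list(stats.false_discovery_control(np.asarray(pvals), method="bh"))


def compare_cohorts(
    kb: KnowledgeBase,
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    pseudocount: float = 1.0,
    up: float = UP_THRESHOLD,
    down: float | None = None,
    missing_policy: str = "permissive",
    reaction_order: str = "aggregate_then_median",
    bh: bool = False,
    compute_p: bool = True,
) -> ComparisonResult:
    """Differential gene- and reaction-level records between two cohorts.

    Both matrices are harmonized against the KB. Gene-level records cover
    every gene present in both cohorts (KB membership flagged, so
    proteoglycan core genes pass through); reaction-level records cover
    every KB reaction, scored per sample and summarized by medians
    (``reaction_order='median_then_aggregate'`` reverses that order for
    sensitivity analysis; p-values always come from per-sample activities).
    """
    if down is None:
        down = 1.0 / up
    if reaction_order not in ("aggregate_then_median", "median_then_aggregate"):
        raise ValueError(f"unknown reaction_order {reaction_order!r}")
    tum, _ = harmonize_symbols(tumor, kb)
    nor, _ = harmonize_symbols(normal, kb)
    shared = [g for g in tum.values.index if g in set(nor.values.index)]
    if not shared:
        raise ValueError("tumor and normal matrices share no gene symbols")
    kb_genes = set(kb.genes)
    n_t, n_n = len(tum.sample_ids), len(nor.sample_ids)

    records: list[FoldChangeRecord] = []
    for g in shared:
        tv = tum.values.loc[g].to_numpy(dtype=float)
        nv = nor.values.loc[g].to_numpy(dtype=float)
        mt, mn, fc, fc_raw = median_fold_change(tv, nv, pseudocount)
        p = rank_test(tv, nv)[1] if compute_p else float("nan")
        records.append(
            FoldChangeRecord(
                target_id=g, level="gene", median_tumor=mt, median_normal=mn,
                fc=fc, fc_raw=fc_raw, direction=classify_direction(fc, up, down),
                p_value=p, n_tumor=n_t, n_normal=n_n, in_kb=g in kb_genes,
            )
        )

    act_t = reaction_activity(kb, tum, missing_policy)
    act_n = reaction_activity(kb, nor, missing_policy)
    for rx in kb.reactions:
        tv = act_t.values.loc[rx.reaction_id].to_numpy(dtype=float)
        nv = act_n.values.loc[rx.reaction_id].to_numpy(dtype=float)
        if reaction_order == "aggregate_then_median":
            mt, mn, fc, fc_raw = median_fold_change(tv, nv, pseudocount)
        else:
            # aggregate the per-cohort gene medians instead
            med_t = tum.values.median(axis=1)
            med_n = nor.values.median(axis=1)
            members = [g for g in rx.gene_group.members if g in med_t.index]
            if rx.gene_group.semantics == "COMPLEX" and (
                len(members) < len(rx.gene_group.members)
            ):
                mt = mn = 0.0
            elif members:
                agg = min if rx.gene_group.semantics == "COMPLEX" else max
                mt = float(agg(med_t[g] for g in members))
                mn = float(agg(med_n[g] for g in members))
            else:
                mt = mn = 0.0
            fc = (mt + pseudocount) / (mn + pseudocount)
            fc_raw = mt / mn if mn > 0 else float("nan")
        p = rank_test(tv, nv)[1] if compute_p else float("nan")
        records.append(
            FoldChangeRecord(
                target_id=rx.reaction_id, level="reaction", median_tumor=mt,
                median_normal=mn, fc=fc, fc_raw=fc_raw,
                direction=classify_direction(fc, up, down), p_value=p,
                n_tumor=n_t, n_normal=n_n,
            )
        )

    if bh and compute_p:
        qs = _bh([r.p_value for r in records])
        for r, q in zip(records, qs):
            r.q_value = float(q)
    return ComparisonResult(records, up_threshold=up, down_threshold=down)
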