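"""Expression-side statistics: seven-group FPKM categories, two-fold DEG
flags, the tissue-specificity index tau, and mark-vs-expression association.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionTable  # noqa: F401  (re-export)

#: upper log2(FPKM) bounds of groups 1..6 (group 0 = no reads)
GROUP_EDGES = (-3.0, 0.0, 3.0, 6.0, 9.0)
DEG_EPSILON = 0.01


@dataclass(frozen=True)
class TauResult:
    gene_id: str
    tau: float | None  # None when max expression is 0 (undefined)
    n_tissues: int


def expression_group(fpkm: float, has_reads: bool = True) -> int:
    """Seven-group expression category from log2(FPKM).

    Group 0: no reads.  Groups 1..6 partition the log2 scale at
    -3, 0, 3, 6, 9 with group 6 requiring x > 9 strictly.
    """
    if fpkm < 0:
        raise ValueError("FPKM must be >= 0")
    if not has_reads:
        return 0
    x = np.log2(fpkm) if fpkm > 0 else -np.inf
    if x > 9.0:
        return 6
    for grp, hi in zip((1, 2, 3, 4, 5), GROUP_EDGES):
        if x < hi:
            return grp
    return 5  # x == 9.0 exactly: group 6 needs x > 9 strictly


def expression_groups(
    table: ExpressionTable, sample: str, min_fpkm_for_reads: float = 0.01
) -> pd.Series:
    """Group labels for every gene of one sample column.

    Without an explicit read-presence indicator, FPKM < ``min_fpkm_for_reads``
    is the group-0 proxy.
    """
    vals = table.fpkm[sample]
    return vals.apply(lambda v: expression_group(v, has_reads=v >= min_fpkm_for_reads))


def deg_flag(fpkm_a: float, fpkm_b: float, epsilon: float = DEG_EPSILON) -> tuple[bool, str | None]:
    """Two-fold differential-expression flag between two samples.

    Flags |log2((a+eps)/(b+eps))| >= 1.0 (inclusive); the Cuffdiff-style
    confidence criterion is not recomputed here and may be supplied as an
    external significance column downstream.  Returns (flag, direction) with
    direction 'up_in_A' or 'up_in_B' when flagged.
    """
    ratio = float(np.log2((fpkm_a + epsilon) / (fpkm_b + epsilon)))
    if abs(ratio) >= 1.0:
        return True, ("up_in_A" if ratio > 0 else "up_in_B")
    return False, None


def tau(values: Sequence[float], gene_id: str = "") -> TauResult:
    """Tissue-specificity index tau = sum(1 - x_i/x_max) / (n - 1).

    0 for perfectly uniform (housekeeping) expression, 1 for strictly
    one-tissue expression; undefined (None) when all values are 0.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("tau needs expression in >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression")
    m = x.max()
    if m == 0:
        return TauResult(gene_id, None, x.size)
    t = float((1.0 - x / m).sum() / (x.size - 1))
    return TauResult(gene_id, t, x.size)


def tau_table(table: ExpressionTable, tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Tau for every gene over the given tissue columns (all columns by default)."""
    cols = list(tissues) if tissues else table.columns()
    sub = table.fpkm[cols]
    rows = [(g, tau(sub.loc[g].values, g).tau) for g in sub.index]
    return pd.DataFrame(rows, columns=["gene_id", "tau"]).set_index("gene_id")


def group_distribution_test(
    marked_counts: Mapping[int, int] | Sequence[int],
    total_counts: Mapping[int, int] | Sequence[int],
) -> tuple[float, float]:
    """Pearson chi-squared of a gene subset's seven-group distribution against
    expected proportions from all genes.

    Returns (statistic, p).  Degrees of freedom = non-empty expected bins - 1.
    """
    if isinstance(marked_counts, Mapping):
        keys = sorted(set(marked_counts) | set(total_counts))
        obs = np.array([marked_counts.get(k, 0) for k in keys], dtype=float)
        tot = np.array([total_counts.get(k, 0) for k in keys], dtype=float)
    else:
        obs = np.asarray(list(marked_counts), dtype=float)
        tot = np.asarray(list(total_counts), dtype=float)
    if tot.sum() == 0 or obs.sum() == 0:
        raise ValueError("empty distribution")
    keep = tot > 0
    if obs[~keep].sum() > 0:
        raise ValueError("subset genes in a bin that is empty in the total")
    obs, tot = obs[keep], tot[keep]
    exp = tot / tot.sum() * obs.sum()
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = int(keep.sum()) - 1
    if df == 0:
        return 0.0, 1.0
    return statistic, float(stats.chi2.sf(statistic, df))


def mark_expression_concordance(
    k27_direction: Mapping[str, str],
    deg_results: Mapping[str, tuple[bool, str | None]],
) -> pd.DataFrame:
    """Per-gene class of H3K27me3 change vs expression change.

    ``k27_direction`` maps gene -> 'up_in_A'/'up_in_B' for genes with a
    differential H3K27me3 call; ``deg_results`` maps gene -> deg_flag output.
    negative: the sample with more H3K27me3 has lower expression;
    positive: same direction; uncoupled: H3K27me3 differs but expression is
    not differentially expressed.
    """
    rows = []
    for g, kdir in k27_direction.items():
        flag, edir = deg_results.get(g, (False, None))
        if not flag:
            cls = "uncoupled"
        elif edir == kdir:
            cls = "positive"
        else:
            cls = "negative"
        rows.append((g, kdir, edir, cls))
    return pd.DataFrame(
        rows, columns=["gene_id", "k27_direction", "expr_direction", "concordance"]
    ).set_index("gene_id")


def concordance_summary(classes: pd.DataFrame) -> dict[str, float]:
    """Percentages of each concordance class among H3K27me3-different genes.

    ``pct_deg`` is the share of genes that are differentially expressed at
    all (positive + negative), the headline fraction of the association table.
    """
    n = len(classes)
    if n == 0:
        raise ValueError("no H3K27me3-different genes")
    counts = classes["concordance"].value_counts()
    pct = {f"pct_{k}": 100.0 * counts.get(k, 0) / n for k in ("negative", "positive", "uncoupled")}
    pct["pct_deg"] = 100.0 * (counts.get("negative", 0) + counts.get("positive", 0)) / n
    pct["n"] = n
    return pct


def class_value_test(values_a: Iterable[float], values_b: Iterable[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a quantity (e.g. tau or
    log2 FPKM) between two gene classes.  Returns (statistic, p)."""
    a = [v for v in values_a if v is not None and np.isfinite(v)]
    b = [v for v in values_b if v is not None and np.isfinite(v)]
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
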