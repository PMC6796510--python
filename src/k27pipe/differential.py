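"""Differential H3K27me3 between two samples.

Region read counts (gene +/- 200 bp) are compared after signal extraction
scaling (SES) normalization of each ChIP library against its input.  Gene-
level significance uses a two-sided Fisher exact test on scaled library
totals, Benjamini-Hochberg q-values, and the joint gate
|log2 ratio| > 2.0, q < 0.05, with the higher-signal sample required to
carry a marking call.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import BinnedCoverage, RegionCountMatrix  # noqa: F401  (re-export)
from .marking import MarkingCallSet

SES_FACTOR_BOUNDS = (1e-6, 1e6)


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    log2_ratio: float
    p_value: float
    q_value: float
    significant: bool
    direction: str  # {up_in_A, up_in_B}


def ses_scale_factor(chip: BinnedCoverage, input_: BinnedCoverage) -> float:
    """SES scale factor mapping the ChIP library onto its input background.

    Bins are sorted by ascending ChIP count; with cumulative count fractions
    P_k (ChIP) and Q_k (input), the separation point k* maximizes Q_k - P_k
    (ties -> smallest k) and the factor is the input/ChIP cumulative count
    ratio at k*, clipped to [1e-6, 1e6].
    """
    if chip.bin_size != input_.bin_size:
        raise ValueError("ChIP and input must share the bin grid")
    c = chip.flat().astype(np.float64)
    i = input_.flat().astype(np.float64)
    if len(c) != len(i):
        raise ValueError("ChIP and input must share the bin grid")
    nonempty = int(((c > 0) | (i > 0)).sum())
    if nonempty < 100:
        raise ValueError(f"need >= 100 non-empty bins for SES, got {nonempty}")
    order = np.argsort(c, kind="stable")
    cum_c = np.cumsum(c[order])
    cum_i = np.cumsum(i[order])
    p = cum_c / cum_c[-1]
    q = cum_i / cum_i[-1]
    k = int(np.argmax(q - p))  # first index on ties
    if cum_c[k] == 0:
        raise ValueError("background not estimable: all-zero ChIP cumulative at k*")
    factor = cum_i[k] / cum_c[k]
    return float(np.clip(factor, *SES_FACTOR_BOUNDS))


def differential_test(
    a: int,
    b: int,
    library_total_a: int,
    library_total_b: int,
    scale_a: float = 1.0,
    scale_b: float = 1.0,
) -> tuple[float, float]:
    """Fisher exact comparison of one region's counts between samples A and B.

    Effective totals are the SES-scaled library totals rounded to integers;
    the 2x2 table is [[a, T_a - a], [b, T_b - b]] with a two-sided (minimum-
    likelihood) Fisher exact P.  The log2 ratio of region rates uses a +1
    pseudocount so it stays finite at zero counts; the test table does not.
    """
    t_a = int(round(scale_a * library_total_a))
    t_b = int(round(scale_b * library_total_b))
    if t_a - a < 0 or t_b - b < 0:
        raise ValueError("scaled effective total smaller than region count")
    _, p = stats.fisher_exact([[a, t_a - a], [b, t_b - b]], alternative="two-sided")
    log2_ratio = float(np.log2(((a + 1) / (t_a + 1)) / ((b + 1) / (t_b + 1))))
    return log2_ratio, float(p)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserving, monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_differential(
    results: pd.DataFrame,
    marking_a: MarkingCallSet | set[str],
    marking_b: MarkingCallSet | set[str],
    log2_cut: float = 2.0,
    q_cut: float = 0.05,
) -> list[DifferentialResult]:
    """Apply the significance gate to per-gene test results.

    ``results`` needs columns gene_id, log2_ratio, p_value, q_value.  A gene
    is significant iff |log2_ratio| > log2_cut (strict), q < q_cut, and the
    sample on the higher side carries a marking call for that gene.
    """
    marked_a = marking_a.marked_genes if isinstance(marking_a, MarkingCallSet) else marking_a
    marked_b = marking_b.marked_genes if isinstance(marking_b, MarkingCallSet) else marking_b
    out: list[DifferentialResult] = []
    for row in results.itertuples(index=False):
        direction = "up_in_A" if row.log2_ratio >= 0 else "up_in_B"
        high_marked = row.gene_id in (marked_a if row.log2_ratio >= 0 else marked_b)
        sig = (
            abs(row.log2_ratio) > log2_cut
            and row.q_value < q_cut
            and high_marked
        )
        out.append(
            DifferentialResult(
                row.gene_id,
                float(row.log2_ratio),
                float(row.p_value),
                float(row.q_value),
                bool(sig),
                direction,
            )
        )
    return out


def differential_analysis(
    rcm: RegionCountMatrix,
    sample_a: str,
    sample_b: str,
    scale_a: float = 1.0,
    scale_b: float = 1.0,
    marking_a: MarkingCallSet | set[str] = frozenset(),
    marking_b: MarkingCallSet | set[str] = frozenset(),
    log2_cut: float = 2.0,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Run the full per-gene differential comparison between two samples."""
    genes = list(rcm.counts.index)
    rows = []
    for g in genes:
        l2, p = differential_test(
            int(rcm.counts.at[g, sample_a]),
            int(rcm.counts.at[g, sample_b]),
            rcm.library_totals[sample_a],
            rcm.library_totals[sample_b],
            scale_a,
            scale_b,
        )
        rows.append((g, l2, p))
    df = pd.DataFrame(rows, columns=["gene_id", "log2_ratio", "p_value"])
    df["q_value"] = bh_qvalues(df["p_value"])
    calls = classify_differential(df, marking_a, marking_b, log2_cut, q_cut)
    df["significant"] = [c.significant for c in calls]
    df["direction"] = [c.direction for c in calls]
    return df
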