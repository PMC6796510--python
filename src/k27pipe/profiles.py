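"""Coverage profiling: metagene plots, read segment composition, sample
correlation, and vernalization nucleation/spreading quantification.

The vernalization model follows Polycomb dynamics at FLC-like loci: during
cold, H3K27me3 accumulates in a nucleation region spanning the first exon
and the proximal first intron; after return to warmth it spreads 5' to 3'
across the gene body.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import (
    BinnedCoverage,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    PeakSet,
    RegionCountMatrix,
)

SEGMENTS = ("upstream_2kb", "exon", "intron", "downstream_2kb", "irr", "intergenic")


@dataclass
class MetageneProfile:
    """Mean coverage profile over genes: fixed flank bins + scaled body bins.

    ``values`` holds, 5'->3', ``n_flank_bins`` upstream bins, ``body_bins``
    scaled gene-body bins, and ``n_flank_bins`` downstream bins, each the
    cross-gene mean read density in RPM per bp (reads per bp per million
    mapped reads, scaled by 1e6).
    """

    sample_id: str
    values: np.ndarray
    n_flank_bins: int
    body_bins: int
    flank_bin_bp: int

    @property
    def upstream(self) -> np.ndarray:
        return self.values[: self.n_flank_bins]

    @property
    def body(self) -> np.ndarray:
        return self.values[self.n_flank_bins : self.n_flank_bins + self.body_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.values[self.n_flank_bins + self.body_bins :]


def _window_count(arr: np.ndarray, bin_size: int, s: float, e: float) -> float:
    """Reads in [s, e) from a bin array with fractional boundary attribution."""
    lo, hi = s / bin_size, e / bin_size
    i0, i1 = max(int(np.floor(lo)), 0), min(int(np.ceil(hi)), len(arr))
    total = 0.0
    for i in range(i0, i1):
        total += arr[i] * (min(hi, i + 1) - max(lo, i))
    return total


def metagene_profile(
    coverage: BinnedCoverage,
    genes: Iterable[Gene],
    flank_bp: int = 1000,
    flank_bin_bp: int = 50,
    body_bins: int = 40,
) -> MetageneProfile:
    """Average strand-oriented coverage profile over a gene selection.

    Each gene body is rescaled to ``body_bins`` equal windows; flanks use
    fixed ``flank_bin_bp`` windows.  Per-window read density is converted to
    RPM per bp and averaged across genes; minus-strand genes are reversed so
    the axis runs 5'->3'.  Windows falling off the chromosome contribute NaN
    and are ignored in the mean.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene selection")
    n_flank = flank_bp // flank_bin_bp
    total = coverage.total_reads or 1
    rows = []
    for g in genes:
        if g.length < body_bins:
            continue
        arr = coverage.counts.get(g.locus.chrom)
        if arr is None:
            continue
        chrom_end = len(arr) * coverage.bin_size
        windows: list[tuple[float, float]] = []
        s0, e0 = g.locus.start, g.locus.end
        for j in range(n_flank):
            windows.append((s0 - flank_bp + j * flank_bin_bp, s0 - flank_bp + (j + 1) * flank_bin_bp))
        step = g.length / body_bins
        for j in range(body_bins):
            windows.append((s0 + j * step, s0 + (j + 1) * step))
        for j in range(n_flank):
            windows.append((e0 + j * flank_bin_bp, e0 + (j + 1) * flank_bin_bp))
        vals = np.empty(len(windows))
        for k, (ws, we) in enumerate(windows):
            cs, ce = max(ws, 0.0), min(we, float(chrom_end))
            if ce <= cs:
                vals[k] = np.nan
                continue
            vals[k] = _window_count(arr, coverage.bin_size, cs, ce) / (ce - cs)
        if g.strand == "-":
            vals = vals[::-1]
        rows.append(vals * 1e6 / total)
    if not rows:
        raise ValueError("no usable genes for the metagene profile")
    values = np.nanmean(np.vstack(rows), axis=0)
    return MetageneProfile(coverage.sample_id, values, n_flank, body_bins, flank_bin_bp)


def segment_composition(
    positions: Mapping[str, np.ndarray],
    annotation: GenomeAnnotation,
    irr: PeakSet | Sequence[GenomicInterval] = (),
    weights: Mapping[str, np.ndarray] | None = None,
    flank_bp: int = 2000,
) -> dict[str, float]:
    """Proportion of reads per genomic segment class.

    ``positions`` maps chromosome -> array of read positions (bp); optional
    ``weights`` give per-position read multiplicities.  Each read is assigned
    exactly one segment with precedence exon > intron > 2 kb upstream > 2 kb
    downstream > IRR > intergenic; proportions sum to 1.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}

    def add(kind: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            trees.setdefault(chrom, {k: IntervalTree() for k in SEGMENTS[:5]})[kind].addi(s, e)

    for g in annotation:
        c = g.locus.chrom
        for ex in g.exons:
            add("exon", c, ex.start, ex.end)
        add("intron", c, g.locus.start, g.locus.end)
        if g.strand == "-":
            add("upstream_2kb", c, g.locus.end, g.locus.end + flank_bp)
            add("downstream_2kb", c, max(0, g.locus.start - flank_bp), g.locus.start)
        else:
            add("upstream_2kb", c, max(0, g.locus.start - flank_bp), g.locus.start)
            add("downstream_2kb", c, g.locus.end, g.locus.end + flank_bp)
    irr_ivs = irr.peaks if isinstance(irr, PeakSet) else irr
    for item in irr_ivs:
        iv = item.interval if hasattr(item, "interval") else item
        add("irr", iv.chrom, iv.start, iv.end)

    totals = dict.fromkeys(SEGMENTS, 0.0)
    grand = 0.0
    for chrom, pos in positions.items():
        w = weights[chrom] if weights is not None else np.ones(len(pos))
        ctrees = trees.get(chrom)
        for p, wt in zip(pos, w):
            grand += wt
            if ctrees is None:
                totals["intergenic"] += wt
                continue
            for kind in SEGMENTS[:5]:
                if ctrees[kind].overlaps_point(p):
                    totals[kind] += wt
                    break
            else:
                totals["intergenic"] += wt
    if grand == 0:
        raise ValueError("no reads")
    return {k: v / grand for k, v in totals.items()}


def positions_from_coverage(cov: BinnedCoverage) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Bin midpoints and counts, usable as weighted read positions."""
    pos = {c: (np.arange(len(a)) + 0.5) * cov.bin_size for c, a in cov.counts.items()}
    wts = {c: a.astype(float) for c, a in cov.counts.items()}
    return pos, wts


def sample_correlation(rcm: RegionCountMatrix, a: str, b: str) -> float:
    """Pearson correlation of per-gene RPM-normalized region counts."""
    rpm = rcm.rpm()
    r, _ = stats.pearsonr(rpm[a], rpm[b])
    return float(r)


def nucleation_region(gene: Gene, intron_extent_bp: int = 500) -> GenomicInterval:
    """The nucleation region: first exon plus the proximal part of intron 1.

    The intron extension is clipped to the intron's length; single-exon genes
    fall back to the 5' half of the gene body.  Strand-aware: for minus-strand
    genes the region sits at the genomic 3' end.
    """
    exons = gene.exons_5to3()
    c = gene.locus.chrom
    if len(exons) == 1:
        half = gene.length // 2 or 1
        if gene.strand == "-":
            return GenomicInterval(c, gene.locus.end - half, gene.locus.end, gene.strand)
        return GenomicInterval(c, gene.locus.start, gene.locus.start + half, gene.strand)
    e1, e2 = exons[0], exons[1]
    if gene.strand == "-":
        intron_len = e1.start - e2.end
        ext = min(intron_extent_bp, intron_len)
        return GenomicInterval(c, e1.start - ext, e1.end, gene.strand)
    intron_len = e2.start - e1.end
    ext = min(intron_extent_bp, intron_len)
    return GenomicInterval(c, e1.start, e1.end + ext, gene.strand)


@dataclass
class SpreadingReport:
    gene_id: str
    nucleation_enrichment: float
    body_breadth: float
    thirds_profile: tuple[float, float, float]  # 5', middle, 3' (background-normalized)
    spreading_call: str  # {none, nucleation_only, spread}


def background_rate(cov: BinnedCoverage) -> float:
    """Genome-wide background read density (reads per bp): median bin count
    over the genome, falling back to the mean when the median is zero."""
    flat = cov.flat()
    med = float(np.median(flat))
    if med == 0:
        med = float(flat.mean())
    if med == 0:
        raise ValueError("coverage is empty; background not estimable")
    return med / cov.bin_size


def spreading_report(
    cov: BinnedCoverage,
    gene: Gene,
    intron_extent_bp: int = 500,
    e_min: float = 2.0,
    b_spread: float = 0.5,
    breadth_fold: float = 2.0,
) -> SpreadingReport:
    """Quantify nucleation vs spreading of coverage over one gene.

    nucleation_enrichment: mean read density over the nucleation region
    divided by genome background.  body_breadth: fraction of gene-body bins
    with counts above ``breadth_fold`` x the background bin level.  Calls:
    spread when breadth >= ``b_spread``; nucleation_only when the nucleation
    region is > ``e_min``-fold enriched but the body is still narrow; none
    otherwise.
    """
    arr = cov.counts.get(gene.locus.chrom)
    if arr is None:
        raise ValueError(f"no coverage for chromosome {gene.locus.chrom}")
    bg = background_rate(cov)
    nuc = nucleation_region(gene, intron_extent_bp)
    nuc_rate = _window_count(arr, cov.bin_size, nuc.start, nuc.end) / nuc.length
    nuc_enr = nuc_rate / bg

    i0 = int(np.ceil(gene.locus.start / cov.bin_size))
    i1 = int(np.floor(gene.locus.end / cov.bin_size))
    body_bins = arr[i0:i1] if i1 > i0 else arr[i0 : i0 + 1]
    thr = breadth_fold * bg * cov.bin_size
    breadth = float((body_bins > thr).mean())

    L = gene.length
    thirds = []
    for j in range(3):
        s = gene.locus.start + j * L / 3
        e = gene.locus.start + (j + 1) * L / 3
        thirds.append((_window_count(arr, cov.bin_size, s, e) / (e - s)) / bg)
    if gene.strand == "-":
        thirds = thirds[::-1]

    if breadth >= b_spread:
        call = "spread"
    elif nuc_enr > e_min:
        call = "nucleation_only"
    else:
        call = "none"
    return SpreadingReport(gene.gene_id, float(nuc_enr), breadth, tuple(thirds), call)


def spreading_call(
    coverages: Sequence[tuple[str, BinnedCoverage]],
    gene: Gene,
    intron_extent_bp: int = 500,
    e_min: float = 2.0,
    b_spread: float = 0.5,
    breadth_fold: float = 2.0,
) -> tuple[list[tuple[str, SpreadingReport]], list[str]]:
    """Spreading reports across an ordered timepoint series plus transitions.

    Returns ([(timepoint, report), ...], ["none->nucleation_only", ...]).
    """
    reports = [
        (label, spreading_report(cov, gene, intron_extent_bp, e_min, b_spread, breadth_fold))
        for label, cov in coverages
    ]
    transitions = [
        f"{a.spreading_call}->{b.spreading_call}"
        for (_, a), (_, b) in zip(reports, reports[1:])
    ]
    return reports, transitions
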