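"""Gene-level H3K27me3 marking calls from peak/annotation overlap.

A gene is H3K27me3-marked when a single peak intersects its genic region
(gene body extended by 200 bp on both sides) over more than 200 bp.  From
per-sample calls the module derives stable (marked in all four line x tissue
samples), tissue-specific, and Venn overlap sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import Gene, GenomeAnnotation, GenomicInterval, PeakSet

RULES = ("overlap", "contained", "peak_length")


@dataclass(frozen=True)
class MarkingCall:
    gene_id: str
    sample_id: str
    marked: bool
    supporting_peak_overlap_bp: int


@dataclass
class MarkingCallSet:
    """Marking calls of one sample; ``marked_genes`` is the derived gene set."""

    sample_id: str
    calls: dict[str, MarkingCall]

    @property
    def marked_genes(self) -> set[str]:
        return {g for g, c in self.calls.items() if c.marked}

    def __len__(self) -> int:
        return len(self.calls)


def extended_region(gene: Gene, flank_bp: int = 200, chrom_length: int | None = None) -> GenomicInterval:
    """Gene locus extended by ``flank_bp`` on both sides (strand-independent),
    clipped at 0 and at the chromosome end when known."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    start = max(0, gene.locus.start - flank_bp)
    end = gene.locus.end + flank_bp
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.locus.chrom, start, end, gene.strand)


def call_marked_genes(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    min_peak_len: int = 200,
    flank_bp: int = 200,
    rule: str = "overlap",
) -> MarkingCallSet:
    """Call per-gene marking for one sample.

    rule='overlap' (default): marked iff some single peak's intersection with
    the extended region exceeds ``min_peak_len`` (overlaps are never summed
    across peaks).  rule='contained': the peak must lie fully inside the
    region and be longer than ``min_peak_len``.  rule='peak_length': any
    overlap qualifies provided the peak's own length exceeds ``min_peak_len``.
    """
    if rule not in RULES:
        raise ValueError(f"unknown marking rule {rule!r}")
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    trees: dict[str, IntervalTree] = {}
    for p in peaks.peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )
    calls: dict[str, MarkingCall] = {}
    for gene in annotation:
        region = extended_region(
            gene, flank_bp, annotation.chrom_lengths.get(gene.locus.chrom)
        )
        best = 0
        marked = False
        tree = trees.get(region.chrom)
        if tree is not None:
            for hit in tree.overlap(region.start, region.end):
                peak_iv: GenomicInterval = hit.data.interval
                ov = region.overlap_length(peak_iv)
                best = max(best, ov)
                if rule == "overlap":
                    ok = ov > min_peak_len
                elif rule == "contained":
                    ok = region.contains(peak_iv) and peak_iv.length > min_peak_len
                else:  # peak_length
                    ok = ov > 0 and peak_iv.length > min_peak_len
                marked = marked or ok
        calls[gene.gene_id] = MarkingCall(gene.gene_id, peaks.sample_id, marked, best)
    return MarkingCallSet(peaks.sample_id, calls)


def venn_counts(callsets: Sequence[MarkingCallSet]) -> dict[tuple[bool, ...], int]:
    """Counts of every membership cell over the union of marked genes.

    Keys are membership tuples aligned with ``callsets`` order; the all-False
    cell is absent (counts partition the union, not the genome).
    """
    sets = [cs.marked_genes for cs in callsets]
    union = set().union(*sets) if sets else set()
    cells: dict[tuple[bool, ...], int] = {
        pattern: 0 for pattern in product([True, False], repeat=len(sets))
        if any(pattern)
    }
    for g in union:
        pattern = tuple(g in s for s in sets)
        cells[pattern] += 1
    return cells


def stable_and_specific(
    calls: Mapping[tuple[str, str], set[str] | MarkingCallSet],
    lines: Sequence[str] = ("T23", "T24"),
    tissues: Sequence[str] = ("2dC", "14dL"),
) -> tuple[set[str], dict[str, set[str]]]:
    """Derive stably marked and tissue-specific marked gene sets.

    ``calls`` maps (line, tissue) to that sample's marked set.  Stable genes
    are marked in all four samples.  A gene is tissue-specific for tissue t
    when it is marked in both lines' t samples and unmarked in both lines'
    samples of every other tissue.
    """
    sets: dict[tuple[str, str], set[str]] = {}
    for key, val in calls.items():
        sets[key] = val.marked_genes if isinstance(val, MarkingCallSet) else set(val)
    missing = [k for k in product(lines, tissues) if k not in sets]
    if missing:
        raise ValueError(f"missing samples {missing}")
    stable = set.intersection(*(sets[(l, t)] for l in lines for t in tissues))
    specific: dict[str, set[str]] = {}
    for t in tissues:
        in_t = set.intersection(*(sets[(l, t)] for l in lines))
        others = set().union(
            *(sets[(l, u)] for l in lines for u in tissues if u != t)
        )
        specific[t] = in_t - others
    return stable, specific
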