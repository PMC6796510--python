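"""Domain containers and readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; conversions to the 1-based
closed conventions of GFF3 and VCF happen only at the I/O boundary.
Chromosome names are matched by exact string equality.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint or on another chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Gene:
    """A gene locus with exon structure and triplicated-genome metadata.

    ``exons`` are stored in ascending genome coordinates; use
    :meth:`exons_5to3` for transcription order.  ``subgenome`` is one of the
    Brassica whole-genome-triplication subgenomes (LF, MF1, MF2) or "NA".
    """

    gene_id: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    subgenome: str = "NA"
    paralog_set_id: str | None = None
    ortholog_id: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if not self.locus.contains(e):
                raise ValueError(f"exon outside gene {self.gene_id}: {e}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.locus.strand

    def exons_5to3(self) -> list[GenomicInterval]:
        """Exons in transcription order (genome-descending for the minus strand)."""
        return self.exons if self.strand != "-" else list(reversed(self.exons))

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons_5to3()[0]

    @property
    def length(self) -> int:
        return self.locus.length


@dataclass(frozen=True)
class Peak:
    """A scored interval from a peak caller; significance was decided upstream."""

    interval: GenomicInterval
    score: float = 0.0
    pvalue_exponent: float = 0.0  # -log10 P from the caller

    def __post_init__(self) -> None:
        if self.pvalue_exponent < 0:
            raise ValueError("pvalue_exponent must be >= 0")


@dataclass
class PeakSet:
    """Peaks of one sample, kept sorted by (chrom, start)."""

    sample_id: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.interval.chrom, p.interval.start))

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(p)
        return out

    @property
    def total_length(self) -> int:
        return sum(p.interval.length for p in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class VariantRecord:
    """A homozygous SNP call with its supporting read depth (pos is 1-based)."""

    chrom: str
    pos: int
    depth: int
    genotype_class: str  # {hom, het}

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype_class not in {"hom", "het"}:
            raise ValueError(f"bad genotype_class {self.genotype_class!r}")


@dataclass
class GenomeAnnotation:
    """Genes keyed by gene_id plus chromosome lengths."""

    genes: dict[str, Gene]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            out.setdefault(g.locus.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.locus.start)
        return out

    def paralog_sets(self) -> dict[str, list[str]]:
        """Map paralog_set_id -> member gene_ids (sets of size >= 2 only)."""
        sets: dict[str, list[str]] = {}
        for g in self.genes.values():
            if g.paralog_set_id:
                sets.setdefault(g.paralog_set_id, []).append(g.gene_id)
        return {k: sorted(v) for k, v in sets.items() if len(v) >= 2}


@dataclass
class BinnedCoverage:
    """Genome-wide read counts on a fixed bin grid, one array per chromosome."""

    sample_id: str
    bin_size: int
    counts: dict[str, np.ndarray]  # chrom -> int array
    total_reads: int | None = None

    def __post_init__(self) -> None:
        for chrom, arr in self.counts.items():
            a = np.asarray(arr)
            if (a < 0).any():
                raise ValueError(f"negative bin count on {chrom}")
            self.counts[chrom] = a
        if self.total_reads is None:
            self.total_reads = int(sum(int(a.sum()) for a in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return sum(len(a) for a in self.counts.values())

    def flat(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])

    def rebin(self, new_bin_size: int) -> "BinnedCoverage":
        """Aggregate to a coarser grid; ``new_bin_size`` must be a multiple of ``bin_size``."""
        if new_bin_size % self.bin_size:
            raise ValueError("new bin size must be a multiple of the current bin size")
        k = new_bin_size // self.bin_size
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self.counts.items():
            pad = (-len(arr)) % k
            a = np.pad(arr, (0, pad))
            out[chrom] = a.reshape(-1, k).sum(axis=1)
        return BinnedCoverage(self.sample_id, new_bin_size, out, self.total_reads)

    def region_count(self, region: GenomicInterval) -> float:
        """Reads overlapping a region, with fractional attribution of boundary bins."""
        arr = self.counts.get(region.chrom)
        if arr is None:
            return 0.0
        bs = self.bin_size
        lo, hi = region.start / bs, region.end / bs
        i0, i1 = int(np.floor(lo)), min(int(np.ceil(hi)), len(arr))
        total = 0.0
        for i in range(max(i0, 0), i1):
            frac = min(hi, i + 1) - max(lo, i)
            total += arr[i] * min(1.0, frac)
        return total


@dataclass
class RegionCountMatrix:
    """Per-gene-region read counts per sample plus library totals.

    ``counts`` is a genes x samples integer DataFrame of reads falling in the
    gene +/- 200 bp target region; ``library_totals`` maps sample_id to the
    total mapped reads of that library.
    """

    counts: pd.DataFrame
    library_totals: dict[str, int]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative region counts")
        for s in self.counts.columns:
            if s not in self.library_totals:
                raise ValueError(f"missing library total for sample {s}")
            if int(self.counts[s].max()) > self.library_totals[s]:
                raise ValueError(f"region count exceeds library total for {s}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def rpm(self) -> pd.DataFrame:
        """Counts scaled to reads per million mapped reads, per sample."""
        return self.counts / pd.Series(self.library_totals) * 1e6


@dataclass
class ExpressionTable:
    """FPKM per gene across samples/tissues (genes x columns DataFrame)."""

    fpkm: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ValueError("negative FPKM")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    def columns(self) -> list[str]:
        return list(self.fpkm.columns)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> GenomeAnnotation:
    """Read a GFF3 annotation into a :class:`GenomeAnnotation`.

    GFF 1-based closed coordinates become 0-based half-open.  ``subgenome``,
    ``paralog_set_id`` and ``ortholog_id`` attributes on gene features are
    parsed when present.  Duplicate gene IDs and exons lying outside their
    parent gene are hard errors.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: dict[str, Gene] = {}
    chrom_lengths: dict[str, int] = {}
    for region in db.features_of_type("region"):
        chrom_lengths[region.seqid] = region.end
    for f in db.features_of_type("gene"):
        gid = f.id
        if gid in genes:
            raise ValueError(f"duplicate gene_id {gid}")
        locus = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand or ".")
        exons = []
        for e in db.children(f, featuretype="exon"):
            iv = GenomicInterval(e.seqid, e.start - 1, e.end, e.strand or ".")
            if not locus.contains(iv):
                raise ValueError(f"exon outside parent gene {gid}: {iv}")
            exons.append(iv)
        attr = lambda k: f.attributes[k][0] if k in f.attributes else None
        genes[gid] = Gene(
            gene_id=gid,
            locus=locus,
            exons=exons,
            subgenome=attr("subgenome") or "NA",
            paralog_set_id=attr("paralog_set_id"),
            ortholog_id=attr("ortholog_id"),
        )
    if not genes:
        raise ValueError(f"no gene features in {path}")
    return GenomeAnnotation(genes, chrom_lengths)


def write_gff(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a GenomeAnnotation back to GFF3 (inverse of :func:`read_gff`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_lengths):
            L = annotation.chrom_lengths[chrom]
            fh.write(f"{chrom}\tk27pipe\tregion\t1\t{L}\t.\t.\t.\tID=region-{chrom}\n")
        for g in sorted(annotation, key=lambda g: (g.locus.chrom, g.locus.start)):
            attrs = [f"ID={g.gene_id}"]
            if g.subgenome != "NA":
                attrs.append(f"subgenome={g.subgenome}")
            if g.paralog_set_id:
                attrs.append(f"paralog_set_id={g.paralog_set_id}")
            if g.ortholog_id:
                attrs.append(f"ortholog_id={g.ortholog_id}")
            fh.write(
                f"{g.locus.chrom}\tk27pipe\tgene\t{g.locus.start + 1}\t{g.locus.end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{e.chrom}\tk27pipe\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_peaks(path: str | Path, dialect: str = "narrowPeak", sample_id: str | None = None) -> PeakSet:
    """Read BED (>=3 columns) or ENCODE narrowPeak (10 columns) into a PeakSet.

    Intervals are 0-based half-open as in BED; malformed lines with
    end <= start are dropped with a logged count.
    """
    if dialect not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if dialect == "narrowPeak" and df.shape[1] < 10:
        raise ValueError(f"narrowPeak requires 10 columns, got {df.shape[1]}")
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    bad = df[2] <= df[1]
    if bad.any():
        logger.warning("dropped %d peak lines with end <= start in %s", int(bad.sum()), path)
        df = df[~bad]
    peaks = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row[0]), int(row[1]), int(row[2]))
        score = float(row[4]) if df.shape[1] > 4 else 0.0
        pexp = float(row[7]) if dialect == "narrowPeak" else 0.0
        peaks.append(Peak(iv, score=score, pvalue_exponent=max(pexp, 0.0)))
    return PeakSet(sample_id or Path(path).stem, peaks)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read an FPKM TSV (first column gene_id, remaining columns samples/tissues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"expression table {path} has no data columns")
    if (df.values < 0).any():
        raise ValueError(f"negative FPKM in {path}")
    return ExpressionTable(df)


def read_counts(path: str | Path) -> RegionCountMatrix:
    """Read a long-format region-count TSV.

    Required columns: gene_id, sample_id, reads_in_region, library_total.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "sample_id", "reads_in_region", "library_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s) {sorted(missing)} in {path}")
    wide = df.pivot(index="gene_id", columns="sample_id", values="reads_in_region")
    totals = df.groupby("sample_id")["library_total"].first().astype(int).to_dict()
    return RegionCountMatrix(wide.fillna(0).astype(int), totals)


def write_counts(rcm: RegionCountMatrix, path: str | Path) -> None:
    rows = rcm.counts.stack().rename("reads_in_region").reset_index()
    rows.columns = ["gene_id", "sample_id", "reads_in_region"]
    rows["library_total"] = rows["sample_id"].map(rcm.library_totals)
    rows.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read SNPs from a VCF, keeping only homozygous records with a DP field.

    Mirrors an upstream ``bcftools view -v snps -g hom`` extraction followed
    by the read-depth filter applied later in :func:`~k27pipe.comparative.snp_density`.
    """
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        dp = v.INFO.get("DP")
        if dp is None:
            continue
        het = bool(v.num_het)
        if het:
            continue
        out.append(VariantRecord(v.CHROM, v.POS, int(dp), "hom"))
    return out


def read_bedgraph(
    path: str | Path,
    bin_size: int,
    chrom_lengths: Mapping[str, int],
    sample_id: str | None = None,
    total_reads: int | None = None,
) -> BinnedCoverage:
    """Read a bedGraph whose intervals are aligned to a fixed bin grid."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "count"], dtype={"chrom": str})
    counts = {
        c: np.zeros(-(-chrom_lengths[c] // bin_size), dtype=np.int64) for c in chrom_lengths
    }
    for row in df.itertuples(index=False):
        if row.chrom not in counts:
            raise ValueError(f"bedGraph chromosome {row.chrom} absent from annotation")
        if row.start % bin_size or (row.end - row.start) != bin_size:
            raise ValueError("bedGraph intervals must lie on the bin grid")
        counts[row.chrom][row.start // bin_size] = int(row.count)
    return BinnedCoverage(sample_id or Path(path).stem, bin_size, counts, total_reads)


def write_bedgraph(cov: BinnedCoverage, path: str | Path, skip_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cov.counts):
            arr = cov.counts[chrom]
            idx = np.nonzero(arr)[0] if skip_zero else np.arange(len(arr))
            for i in idx:
                s = int(i) * cov.bin_size
                fh.write(f"{chrom}\t{s}\t{s + cov.bin_size}\t{int(arr[i])}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write any tabular result as TSV with a header row."""
    df.to_csv(path, sep="\t", index=index)
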