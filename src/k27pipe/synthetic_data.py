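"""Synthetic miniature triplicated genome with planted ground truth.

Emulates the study design the pipeline targets: three subgenomes (LF, MF1,
MF2) carrying 2- and 3-copy syntenic paralog sets, per-gene H3K27me3 marking
states across two inbred lines x two tissues with Poisson ChIP enrichment
over input, tissue-structured FPKM, homozygous SNPs, and a four-timepoint
vernalization coverage series with nucleation-then-spreading dynamics at
FLC-like loci.  Everything downstream of read alignment and peak calling is
generated directly from the planted truth, so every pipeline stage can be
tested against a known answer without external data.

All generators are deterministic under a fixed config seed; each stage uses
an independent seed stream so stages may be re-run in any order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    BinnedCoverage,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    RegionCountMatrix,
    VariantRecord,
    write_bedgraph,
    write_gff,
)
from .marking import extended_region

SUBGENOMES = ("LF", "MF1", "MF2")
CHROMS = {"A01": "LF", "A02": "MF1", "A03": "MF2"}
_ALIGN = 50  # gene coordinates snap to the coverage bin grid


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Depths are mean reads per kb; ``frac_marked`` is the per-tissue
    probability that a paralog set (or singleton) carries the mark;
    ``frac_copy_specific`` the probability that a marked multi-copy set is
    marked in only one copy.  ``line_discordance`` perturbs marking between
    the two inbred lines and defaults to 0 (the lines are near-identical).
    """

    seed: int = 0
    n_paralog_sets_3copy: int = 100
    n_paralog_sets_2copy: int = 200
    n_singletons: int = 100
    gene_length_bp: tuple[int, int] = (1000, 3000)
    frac_marked: float = 0.3
    frac_copy_specific: float = 0.3
    enrichment_fold: float = 8.0
    depth_chip: float = 100.0
    depth_input: float = 100.0
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "flower", "silique", "callus")
    tau_high_fraction: float = 0.2
    vernalization_timepoints: tuple[str, ...] = ("NV_early", "NV_late", "V1", "V2")
    lines: tuple[str, ...] = ("T23", "T24")
    study_tissues: tuple[str, ...] = ("2dC", "14dL")
    line_discordance: float = 0.0
    coverage_bin_bp: int = 50
    flank_bp: int = 200
    overdispersion: float = 0.0  # gamma-mixed Poisson shape^-1; 0 = pure Poisson
    n_noise_peaks: int = 5
    n_flc_like: int = 4
    vernalization_fold: float = 6.0
    nucleation_intron_bp: int = 500
    expression_suppression: float = 0.25
    marked_tau_weight: float = 2.0
    snp_rate: float = 0.005  # SNPs per bp in unmarked genes
    snp_rate_ratio_marked: float = 0.5
    snp_frac_low_depth: float = 0.3
    snp_het_fraction: float = 0.2
    intergenic_spacing_bp: int = 4000
    max_chrom_length_bp: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "frac_marked",
            "frac_copy_specific",
            "line_discordance",
            "tau_high_fraction",
            "snp_frac_low_depth",
            "snp_het_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_fold < 1 or self.vernalization_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.gene_length_bp[0] < 8 * _ALIGN:
            raise ValueError("minimum gene length too small")

    @property
    def samples(self) -> list[str]:
        return [f"{l}_{t}" for l in self.lines for t in self.study_tissues]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stage])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("gene_length_bp", "tissues", "vernalization_timepoints",
                    "lines", "study_tissues"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted per-gene states every downstream module is graded against."""

    marking: pd.DataFrame  # genes x samples, bool
    set_class: dict[str, str] = field(default_factory=dict)  # set -> conserved/copy_specific/none
    tau_class: dict[str, str] = field(default_factory=dict)
    home_tissue: dict[str, str] = field(default_factory=dict)
    flc_genes: list[str] = field(default_factory=list)
    vern_schedule: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def marked_genes(self, sample: str) -> set[str]:
        return set(self.marking.index[self.marking[sample]])


def _gene_structure(rng: np.random.Generator, length: int) -> list[tuple[int, int]]:
    """Exon (start, end) offsets within a gene of the given aligned length."""
    e1 = min(300, (length // 4 // _ALIGN) * _ALIGN)
    e1 = max(e1, 2 * _ALIGN)
    i1 = min(600, (length // 4 // _ALIGN) * _ALIGN)
    i1 = max(i1, 2 * _ALIGN)
    rest = length - e1 - i1
    if length >= 2200 and rest >= 8 * _ALIGN:
        # three exons: split the remainder around a short second intron
        i2 = 200
        e2 = ((rest - i2) // 2 // _ALIGN) * _ALIGN
        e3 = rest - i2 - e2
        return [(0, e1), (e1 + i1, e1 + i1 + e2), (length - e3, length)]
    return [(0, e1), (e1 + i1, length)]


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build the annotation and plant per-sample marking states.

    3-copy sets place one copy per subgenome; 2-copy sets occupy two distinct
    subgenomes; genes never overlap and keep >= 4 kb intergenic spacing so
    2 kb flanks cannot collide.  Every gene has >= 2 exons.
    """
    rng = config.rng(1)
    chroms = list(CHROMS)
    lo, hi = config.gene_length_bp

    members: list[tuple[str, str, list[str]]] = []  # (set_id, kind, chrom list)
    for i in range(config.n_paralog_sets_3copy):
        members.append((f"P3-{i:04d}", "3copy", chroms.copy()))
    for i in range(config.n_paralog_sets_2copy):
        pick = sorted(rng.choice(len(chroms), size=2, replace=False))
        members.append((f"P2-{i:04d}", "2copy", [chroms[j] for j in pick]))
    for i in range(config.n_singletons):
        members.append((f"S-{i:04d}", "single", [chroms[int(rng.integers(len(chroms)))]]))

    cursors = dict.fromkeys(chroms, config.intergenic_spacing_bp)
    genes: dict[str, Gene] = {}
    set_members: dict[str, list[str]] = {}
    for set_id, kind, placement in members:
        length = int(rng.integers(lo // _ALIGN, hi // _ALIGN + 1)) * _ALIGN
        strand = "+" if rng.random() < 0.5 else "-"
        exon_offsets = _gene_structure(rng, length)
        if strand == "-":
            # mirror so the transcriptional first exon (and its short proximal
            # intron) sits at the genomic 3' end
            exon_offsets = [(length - e, length - s) for s, e in reversed(exon_offsets)]
        ids = []
        for chrom in placement:
            start = cursors[chrom]
            cursors[chrom] = start + length + config.intergenic_spacing_bp
            gid = f"{set_id}-{CHROMS[chrom]}"
            locus = GenomicInterval(chrom, start, start + length, strand)
            exons = [
                GenomicInterval(chrom, start + s, start + e, strand)
                for s, e in exon_offsets
            ]
            genes[gid] = Gene(
                gid,
                locus,
                exons,
                subgenome=CHROMS[chrom],
                paralog_set_id=set_id if kind != "single" else None,
                ortholog_id=f"AT-{set_id}",
            )
            ids.append(gid)
        set_members[set_id] = ids
    chrom_lengths = {c: cursors[c] + 1000 for c in chroms}
    if config.max_chrom_length_bp is not None:
        over = {c: L for c, L in chrom_lengths.items() if L > config.max_chrom_length_bp}
        if over:
            raise ValueError(
                f"chromosome capacity exceeded ({over}); reduce the number of genes"
            )
    annotation = GenomeAnnotation(genes, chrom_lengths)

    # plant marking: per-set, per-tissue Bernoulli; copy-specific sets mark one copy
    samples = config.samples
    marking = pd.DataFrame(False, index=sorted(genes), columns=samples)
    set_class: dict[str, str] = {}
    ref_tissue = config.study_tissues[-1]  # 14-day leaves drive conservation classes
    for set_id, ids in set_members.items():
        copy_specific = rng.random() < config.frac_copy_specific and len(ids) > 1
        chosen = ids[int(rng.integers(len(ids)))]
        for tissue in config.study_tissues:
            if rng.random() >= config.frac_marked:
                marked_ids: list[str] = []
            elif copy_specific:
                marked_ids = [chosen]
            else:
                marked_ids = ids
            for line in config.lines:
                for gid in marked_ids:
                    marking.at[gid, f"{line}_{tissue}"] = True
            if tissue == ref_tissue and len(ids) > 1:
                if not marked_ids:
                    set_class[set_id] = "none"
                else:
                    set_class[set_id] = "copy_specific" if copy_specific else "conserved"
    if config.line_discordance > 0:
        for gid in marking.index:
            for tissue in config.study_tissues:
                if rng.random() < config.line_discordance:
                    line = config.lines[int(rng.integers(len(config.lines)))]
                    col = f"{line}_{tissue}"
                    marking.at[gid, col] = not marking.at[gid, col]

    truth = GroundTruth(marking=marking, set_class=set_class)

    # FLC-like vernalization genes: long singletons with a real first intron
    singles = [g for g in sorted(genes) if genes[g].paralog_set_id is None]
    candidates = [g for g in singles if genes[g].length >= 2000 and len(genes[g].exons) >= 2]
    n_flc = min(config.n_flc_like, len(candidates))
    truth.flc_genes = [candidates[i] for i in rng.choice(len(candidates), n_flc, replace=False)] if n_flc else []
    schedule = tuple(
        "none" if t.startswith("NV") else ("nucleation_only" if t == "V1" else "spread")
        for t in config.vernalization_timepoints
    )
    truth.vern_schedule = {g: schedule for g in truth.flc_genes}
    return annotation, truth


def _coverage_arrays(config: SimulationConfig, annotation: GenomeAnnotation,
                     rng: np.random.Generator, depth_per_kb: float) -> dict[str, np.ndarray]:
    lam = depth_per_kb * config.coverage_bin_bp / 1000.0
    return {
        c: rng.poisson(lam, -(-L // config.coverage_bin_bp)).astype(np.int64)
        for c, L in annotation.chrom_lengths.items()
    }


def _add_enrichment(arr: np.ndarray, config: SimulationConfig, rng: np.random.Generator,
                    start: int, end: int, fold: float, base_lam: float) -> None:
    bs = config.coverage_bin_bp
    i0, i1 = start // bs, -(-end // bs)
    extra = base_lam * (fold - 1.0)
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        extra *= rng.gamma(shape, 1.0 / shape)
    arr[i0:i1] += rng.poisson(extra, i1 - i0)


def simulate_chip(
    truth: GroundTruth, annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[dict[str, PeakSet], RegionCountMatrix, dict[str, dict[str, BinnedCoverage]]]:
    """Emit per-sample peaks, region counts and binned ChIP/input coverage.

    Marked genes receive ``enrichment_fold`` x background Poisson ChIP reads
    over the gene body plus one peak covering >= 60% of it; unmarked genes and
    the input libraries are background everywhere.  Region counts (gene
    +/- 200 bp) are sums of the coverage bins, so counts, coverage and peaks
    are mutually consistent by construction.
    """
    base_lam = config.depth_chip * config.coverage_bin_bp / 1000.0
    rng = config.rng(2)
    peaks: dict[str, PeakSet] = {}
    coverage: dict[str, dict[str, BinnedCoverage]] = {}
    region_counts: dict[str, dict[str, int]] = {}
    genes_sorted = sorted(annotation.genes)
    for sample in config.samples:
        chip = _coverage_arrays(config, annotation, rng, config.depth_chip)
        inp = _coverage_arrays(config, annotation, rng, config.depth_input)
        marked = truth.marked_genes(sample)
        sample_peaks: list[Peak] = []
        for gid in genes_sorted:
            g = annotation[gid]
            if gid in marked and config.enrichment_fold > 1:
                _add_enrichment(
                    chip[g.locus.chrom], config, rng,
                    g.locus.start, g.locus.end, config.enrichment_fold, base_lam,
                )
            if gid in marked:
                frac = rng.uniform(0.65, 0.9)
                plen = max(int(frac * g.length // _ALIGN) * _ALIGN, 6 * _ALIGN)
                pstart = g.locus.start + ((g.length - plen) // 2 // _ALIGN) * _ALIGN
                sample_peaks.append(
                    Peak(
                        GenomicInterval(g.locus.chrom, pstart, pstart + plen),
                        score=float(config.enrichment_fold),
                        pvalue_exponent=float(rng.uniform(5, 30)),
                    )
                )
        # intergenic noise peaks, too short / far to mark any gene
        by_chrom = annotation.genes_by_chrom()
        for _ in range(config.n_noise_peaks):
            chrom = list(CHROMS)[int(rng.integers(len(CHROMS)))]
            glist = by_chrom[chrom]
            if len(glist) < 2:
                continue
            j = int(rng.integers(len(glist) - 1))
            gap_mid = (glist[j].locus.end + glist[j + 1].locus.start) // 2
            sample_peaks.append(
                Peak(GenomicInterval(chrom, gap_mid - 75, gap_mid + 75),
                     score=1.0, pvalue_exponent=float(rng.uniform(5, 10)))
            )
        peaks[sample] = PeakSet(sample, sample_peaks)
        chip_cov = BinnedCoverage(sample, config.coverage_bin_bp, chip)
        inp_cov = BinnedCoverage(f"{sample}_input", config.coverage_bin_bp, inp)
        coverage[sample] = {"chip": chip_cov, "input": inp_cov}
        region_counts[sample] = {
            gid: int(round(chip_cov.region_count(
                extended_region(annotation[gid], config.flank_bp,
                                annotation.chrom_lengths.get(annotation[gid].locus.chrom))
            )))
            for gid in genes_sorted
        }
    counts = pd.DataFrame(region_counts).loc[genes_sorted, config.samples]
    totals = {s: int(coverage[s]["chip"].total_reads) for s in config.samples}
    return peaks, RegionCountMatrix(counts, totals), coverage


def simulate_expression(
    truth: GroundTruth, annotation: GenomeAnnotation, config: SimulationConfig
) -> pd.DataFrame:
    """FPKM table over the tissue panel plus the four study samples.

    A ``tau_high_fraction`` of genes (marked genes over-sampled by
    ``marked_tau_weight``) is strictly one-tissue-specific (target tau >= 0.9,
    log2 FPKM ~ N(7, 1) in the home tissue); the rest are housekeeping-like
    (target tau <= 0.2).  In the study sample columns, expression of a gene
    is multiplied by ``expression_suppression`` wherever it is marked.
    """
    rng = config.rng(3)
    genes = list(truth.marking.index)
    marked_any = truth.marking.any(axis=1)
    w = np.where(marked_any.values, config.marked_tau_weight, 1.0)
    p = np.minimum(config.tau_high_fraction * w * len(w) / w.sum(), 0.95)
    specific = rng.random(len(genes)) < p

    fpkm = pd.DataFrame(0.0, index=genes, columns=list(config.tissues) + config.samples)
    for i, gid in enumerate(genes):
        if specific[i]:
            home = config.tissues[int(rng.integers(len(config.tissues)))]
            truth.tau_class[gid] = "specific"
            truth.home_tissue[gid] = home
            for t in config.tissues:
                if t == home:
                    fpkm.at[gid, t] = 2.0 ** rng.normal(7.0, 1.0)
                else:
                    fpkm.at[gid, t] = 2.0 ** rng.normal(-4.0, 1.0)
        else:
            truth.tau_class[gid] = "housekeeping"
            base = 2.0 ** rng.normal(4.0, 1.0)
            for t in config.tissues:
                fpkm.at[gid, t] = base * 2.0 ** rng.normal(0.0, 0.15)
        base_s = 2.0 ** rng.normal(4.0, 1.5)
        for s in config.samples:
            v = base_s * 2.0 ** rng.normal(0.0, 0.3)
            if truth.marking.at[gid, s]:
                v *= config.expression_suppression
            fpkm.at[gid, s] = v
    return fpkm


def simulate_vernalization(
    annotation: GenomeAnnotation, config: SimulationConfig, truth: GroundTruth
) -> dict[str, BinnedCoverage]:
    """Four-timepoint coverage series with nucleation-then-spreading dynamics.

    FLC-like genes are background at both non-vernalized timepoints, enriched
    only over the nucleation region (first exon + proximal first intron) at
    V1, and across the whole gene body at V2.  All other genes are unchanged.
    """
    from .profiles import nucleation_region

    rng = config.rng(4)
    base_lam = config.depth_chip * config.coverage_bin_bp / 1000.0
    out: dict[str, BinnedCoverage] = {}
    for tp in config.vernalization_timepoints:
        arrs = _coverage_arrays(config, annotation, rng, config.depth_chip)
        for gid in truth.flc_genes:
            g = annotation[gid]
            if tp == "V1":
                nuc = nucleation_region(g, config.nucleation_intron_bp)
                _add_enrichment(arrs[g.locus.chrom], config, rng, nuc.start, nuc.end,
                                config.vernalization_fold, base_lam)
            elif tp == "V2":
                _add_enrichment(arrs[g.locus.chrom], config, rng,
                                g.locus.start, g.locus.end,
                                config.vernalization_fold, base_lam)
        out[tp] = BinnedCoverage(tp, config.coverage_bin_bp, arrs)
    return out


def simulate_variants(
    annotation: GenomeAnnotation, config: SimulationConfig, truth: GroundTruth
) -> list[VariantRecord]:
    """Per-gene Poisson SNPs; marked genes get a reduced rate.

    A gene counts as marked when it carries the mark in the reference tissue
    (14-day leaves) of either line.  A ``snp_frac_low_depth`` fraction of
    records receives depth <= 10 (failing the strict >10-read filter) and a
    ``snp_het_fraction`` is heterozygous (dropped at VCF read time).
    """
    rng = config.rng(5)
    ref = config.study_tissues[-1]
    marked = set()
    for line in config.lines:
        marked |= truth.marked_genes(f"{line}_{ref}")
    records: list[VariantRecord] = []
    for gid in sorted(annotation.genes):
        g = annotation[gid]
        rate = config.snp_rate * (config.snp_rate_ratio_marked if gid in marked else 1.0)
        n = int(rng.poisson(rate * g.length))
        if n == 0:
            continue
        offsets = rng.choice(g.length, size=min(n, g.length), replace=False)
        for off in sorted(offsets):
            if rng.random() < config.snp_frac_low_depth:
                depth = int(rng.integers(1, 11))
            else:
                depth = int(rng.integers(11, 61))
            gt = "het" if rng.random() < config.snp_het_fraction else "hom"
            records.append(VariantRecord(g.locus.chrom, g.locus.start + int(off) + 1, depth, gt))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def simulate_terms(
    annotation: GenomeAnnotation, config: SimulationConfig, truth: GroundTruth,
    n_terms: int = 20, base_rate: float = 0.05, biased_rate: float = 0.3,
) -> dict[str, set[str]]:
    """Flat functional term assignments with one term biased toward genes in
    conserved-marked paralog sets, giving the enrichment stage signal."""
    rng = config.rng(6)
    conserved_sets = {s for s, c in truth.set_class.items() if c == "conserved"}
    terms: dict[str, set[str]] = {f"T{i:02d}": set() for i in range(n_terms)}
    for gid in sorted(annotation.genes):
        g = annotation[gid]
        for i, (tid, members) in enumerate(terms.items()):
            rate = base_rate
            if i == 0 and g.paralog_set_id in conserved_sets:
                rate = biased_rate
            if rng.random() < rate:
                members.add(gid)
    return terms


# ---------------------------------------------------------------------------
# Plain-text writers for the formats io_formats reads
# ---------------------------------------------------------------------------

def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{int(p.score * 10)}\t.\t"
                f"{p.score:.3f}\t{p.pvalue_exponent:.3f}\t-1\t{iv.length // 2}\n"
            )


def write_vcf(records: Sequence[VariantRecord], chrom_lengths: Mapping[str, int],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in records:
            gt = "0/1" if r.genotype_class == "het" else "1/1"
            fh.write(f"{r.chrom}\t{r.pos}\t.\tA\tG\t60\tPASS\tDP={r.depth}\tGT\t{gt}\n")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    df = truth.marking.astype(int).copy()
    df["tau_class"] = pd.Series(truth.tau_class).reindex(df.index).fillna("NA")
    df["flc"] = [int(g in truth.flc_genes) for g in df.index]
    df.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces, ready for the pipeline."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: GroundTruth
    peaks: dict[str, PeakSet]
    region_counts: RegionCountMatrix
    coverage: dict[str, dict[str, BinnedCoverage]]
    expression: pd.DataFrame
    vernalization: dict[str, BinnedCoverage]
    variants: list[VariantRecord]
    terms: dict[str, set[str]]


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage under one config."""
    annotation, truth = simulate_genome(config)
    peaks, rcm, coverage = simulate_chip(truth, annotation, config)
    expression = simulate_expression(truth, annotation, config)
    vern = simulate_vernalization(annotation, config, truth)
    variants = simulate_variants(annotation, config, truth)
    terms = simulate_terms(annotation, config, truth)
    return SimulatedDataset(
        config, annotation, truth, peaks, rcm, coverage, expression, vern, variants, terms
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input in the exact formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def record(name: str, p: Path) -> Path:
        paths[name] = p
        return p

    write_gff(ds.annotation, record("annotation.gff3", out / "annotation.gff3"))
    for s, ps in ds.peaks.items():
        write_narrowpeak(ps, record(f"peaks_{s}.narrowPeak", out / f"peaks_{s}.narrowPeak"))
    from .io_formats import write_counts
    write_counts(ds.region_counts, record("region_counts.tsv", out / "region_counts.tsv"))
    for s, covs in ds.coverage.items():
        write_bedgraph(covs["chip"], record(f"chip_{s}.bedGraph", out / f"chip_{s}.bedGraph"))
        write_bedgraph(covs["input"], record(f"input_{s}.bedGraph", out / f"input_{s}.bedGraph"))
    ds.expression.to_csv(record("fpkm.tsv", out / "fpkm.tsv"), sep="\t", index_label="gene_id")
    for tp, cov in ds.vernalization.items():
        write_bedgraph(cov, record(f"vern_{tp}.bedGraph", out / f"vern_{tp}.bedGraph"))
    write_vcf(ds.variants, ds.annotation.chrom_lengths, record("variants.vcf", out / "variants.vcf"))
    pd.DataFrame(
        [(t, g) for t, ms in ds.terms.items() for g in sorted(ms)],
        columns=["term_id", "gene_id"],
    ).to_csv(record("terms.tsv", out / "terms.tsv"), sep="\t", index=False)
    write_truth(ds.truth, record("truth.tsv", out / "truth.tsv"))
    return paths
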