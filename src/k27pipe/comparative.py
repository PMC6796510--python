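"""Conservation of H3K27me3 across the triplicated genome and across species,
plus per-gene SNP density.

Paralog sets (2 or 3 syntenic copies retained across the LF/MF1/MF2
subgenomes) are classified by how many copies carry the mark; 1:1 orthologs
against an external species are classified by presence of the mark in two
external reference sets; SNP density is homozygous SNPs passing a strict
read-depth filter per bp of gene locus.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, VariantRecord

logger = logging.getLogger(__name__)

THREE_COPY_CLASSES = ("all_three", "exactly_two", "exactly_one", "none")
TWO_COPY_CLASSES = ("both", "one", "none")


@dataclass
class ParalogClassification:
    """Counts of marking classes per paralog family type.

    Conserved = mark retained in >= 2 copies (all_three + exactly_two + both);
    copy-specific = mark in exactly one copy (exactly_one + one).
    """

    three_copy: dict[str, int]
    two_copy: dict[str, int]
    per_set: pd.DataFrame  # set_id, n_copies, n_marked, class
    n_excluded: int = 0

    @property
    def paralogous_conserved(self) -> int:
        return (
            self.three_copy["all_three"]
            + self.three_copy["exactly_two"]
            + self.two_copy["both"]
        )

    @property
    def copy_specific(self) -> int:
        return self.three_copy["exactly_one"] + self.two_copy["one"]

    @property
    def n_three_copy(self) -> int:
        return sum(self.three_copy.values())

    @property
    def n_two_copy(self) -> int:
        return sum(self.two_copy.values())


@dataclass
class OrthologConservation:
    """Partition of 1:1 orthologs by cross-species mark conservation."""

    species_conserved: int
    partially_conserved: int
    species_specific: int
    unmarked_focal: int
    n_one_to_one: int

    def percentages(self) -> dict[str, float]:
        n = self.n_one_to_one
        if n == 0:
            raise ValueError("empty 1:1 ortholog table")
        return {
            "species_conserved": 100.0 * self.species_conserved / n,
            "partially_conserved": 100.0 * self.partially_conserved / n,
            "species_specific": 100.0 * self.species_specific / n,
            "unmarked_focal": 100.0 * self.unmarked_focal / n,
        }


def classify_paralogs(
    marked: set[str] | Mapping[str, bool],
    paralog_sets: Mapping[str, Sequence[str]],
) -> ParalogClassification:
    """Classify every 2- and 3-copy paralog set by its number of marked copies.

    Classes are mutually exclusive ("exactly_two" means 2 of 3 copies marked)
    so class counts per family type sum to the family-type total.  Sets with
    fewer than 2 resolvable members are excluded with a logged count.
    """
    marked_set = (
        {g for g, m in marked.items() if m} if isinstance(marked, Mapping) else set(marked)
    )
    three = dict.fromkeys(THREE_COPY_CLASSES, 0)
    two = dict.fromkeys(TWO_COPY_CLASSES, 0)
    rows = []
    excluded = 0
    for set_id, members in paralog_sets.items():
        members = list(members)
        if len(members) < 2:
            excluded += 1
            continue
        if len(members) > 3:
            raise ValueError(f"paralog set {set_id} has {len(members)} members")
        k = sum(g in marked_set for g in members)
        if len(members) == 3:
            cls = THREE_COPY_CLASSES[3 - k]
            three[cls] += 1
        else:
            cls = TWO_COPY_CLASSES[2 - k]
            two[cls] += 1
        rows.append((set_id, len(members), k, cls))
    if excluded:
        logger.warning("excluded %d paralog sets with < 2 resolvable members", excluded)
    per_set = pd.DataFrame(rows, columns=["set_id", "n_copies", "n_marked", "class"])
    return ParalogClassification(three, two, per_set, excluded)


def ortholog_collapse(pairs: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Reduce a many-to-one homology table to strict 1:1 pairs.

    Every external gene hit by two or more focal genes is dropped together
    with all of its mappings; focal genes mapping to several external genes
    are likewise dropped.
    """
    pairs = list(pairs)
    ext_degree: dict[str, int] = {}
    focal_degree: dict[str, int] = {}
    for br, at in pairs:
        ext_degree[at] = ext_degree.get(at, 0) + 1
        focal_degree[br] = focal_degree.get(br, 0) + 1
    return [
        (br, at) for br, at in pairs if ext_degree[at] == 1 and focal_degree[br] == 1
    ]


def homology_fraction(marked_genes: set[str], pairs: Iterable[tuple[str, str]]) -> float:
    """Fraction of a marked gene set with >= 1 putative ortholog in the table."""
    if not marked_genes:
        raise ValueError("empty marked set")
    with_hit = {br for br, _ in pairs}
    return len(marked_genes & with_hit) / len(marked_genes)


def classify_orthologs(
    marked_focal: set[str],
    external_set_1: set[str],
    external_set_2: set[str],
    table_1to1: Sequence[tuple[str, str]],
) -> OrthologConservation:
    """Classify focal marked genes by cross-species conservation of the mark.

    species_conserved: marked in the focal genome and present in both external
    marked sets; partially_conserved: in exactly one; species_specific: in
    neither.  Percentages use the full 1:1 denominator.
    """
    conserved = partial = specific = unmarked = 0
    for br, at in table_1to1:
        if br not in marked_focal:
            unmarked += 1
            continue
        k = (at in external_set_1) + (at in external_set_2)
        if k == 2:
            conserved += 1
        elif k == 1:
            partial += 1
        else:
            specific += 1
    return OrthologConservation(conserved, partial, specific, unmarked, len(table_1to1))


@dataclass(frozen=True)
class SnpDensity:
    gene_id: str
    n_snps: int
    density: float  # SNPs per bp of locus


def snp_density(
    variants: Sequence[VariantRecord],
    annotation: GenomeAnnotation,
    min_depth: int = 10,
) -> pd.DataFrame:
    """SNPs per bp of gene locus, counting homozygous SNPs with depth strictly
    above ``min_depth`` whose position falls inside the locus (introns included)."""
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        if v.genotype_class == "hom" and v.depth > min_depth:
            by_chrom.setdefault(v.chrom, []).append(v.pos)
    pos_arrays = {c: np.sort(np.array(p)) for c, p in by_chrom.items()}
    rows = []
    for g in annotation:
        arr = pos_arrays.get(g.locus.chrom)
        if arr is None:
            n = 0
        else:
            # VCF pos is 1-based: inside [start+1, end]
            n = int(
                np.searchsorted(arr, g.locus.end, side="right")
                - np.searchsorted(arr, g.locus.start + 1, side="left")
            )
        rows.append((g.gene_id, n, n / g.length))
    return pd.DataFrame(rows, columns=["gene_id", "n_snps", "density"]).set_index("gene_id")
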