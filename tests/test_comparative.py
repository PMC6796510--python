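"""Paralog/ortholog conservation classes and SNP density."""
import numpy as np
import pytest

from k27pipe.comparative import (
    classify_orthologs,
    classify_paralogs,
    homology_fraction,
    ortholog_collapse,
    snp_density,
)
from k27pipe.io_formats import GenomeAnnotation, VariantRecord

from conftest import make_gene


class TestParalogs:
    def test_single_set_classes(self):
        sets = {"s1": ["a", "b", "c"], "s2": ["d", "e"]}
        out = classify_paralogs({"a", "b", "d"}, sets)
        assert out.three_copy["exactly_two"] == 1
        assert out.two_copy["one"] == 1

    def test_class_counts_partition_the_families(self):
        rng = np.random.default_rng(13)
        sets = {}
        marked = set()
        for i in range(40):
            n = 3 if i % 2 else 2
            members = [f"s{i}m{j}" for j in range(n)]
            sets[f"s{i}"] = members
            for m in members:
                if rng.random() < 0.4:
                    marked.add(m)
        out = classify_paralogs(marked, sets)
        assert out.n_three_copy + out.n_two_copy == 40
        assert sum(out.three_copy.values()) == out.n_three_copy
        assert sum(out.two_copy.values()) == out.n_two_copy
        # brute-force check of every set's class
        for row in out.per_set.itertuples(index=False):
            k = sum(m in marked for m in sets[row.set_id])
            assert row.n_marked == k

    def test_sets_smaller_than_two_excluded(self):
        out = classify_paralogs({"a"}, {"s1": ["a"], "s2": ["b", "c"]})
        assert out.n_excluded == 1
        assert out.n_two_copy == 1

    def test_recovery_of_planted_copy_specific_fraction(self, default_dataset):
        """The recovered per-set classes equal the planted ones, and the
        copy-specific share among marked sets matches the configured rate."""
        from k27pipe.marking import call_marked_genes

        ds = default_dataset
        marked = set.intersection(
            *(call_marked_genes(ds.peaks[f"{l}_14dL"], ds.annotation).marked_genes
              for l in ds.config.lines)
        )
        out = classify_paralogs(marked, ds.annotation.paralog_sets())
        planted = ds.truth.set_class
        to_planted = {
            "all_three": "conserved", "exactly_two": "conserved",
            "both": "conserved", "exactly_one": "copy_specific",
            "one": "copy_specific", "none": "none",
        }
        for set_id, cls in zip(out.per_set["set_id"], out.per_set["class"]):
            assert to_planted[cls] == planted[set_id]
        # the copy-specific share among marked sets matches the planted rate
        n_marked_sets = out.paralogous_conserved + out.copy_specific
        share = out.copy_specific / n_marked_sets
        assert share == pytest.approx(ds.config.frac_copy_specific, abs=0.1)


class TestOrthologs:
    def test_collapse_drops_shared_external_gene(self):
        pairs = [("br1", "at1"), ("br2", "at1"), ("br3", "at2")]
        assert ortholog_collapse(pairs) == [("br3", "at2")]

    def test_collapse_identity_when_unique(self):
        pairs = [("br1", "at1"), ("br2", "at2")]
        assert ortholog_collapse(pairs) == pairs

    def test_collapse_matches_degree_oracle(self):
        rng = np.random.default_rng(31)
        pairs = list(
            {(f"br{int(rng.integers(15))}", f"at{int(rng.integers(10))}")
             for _ in range(30)}
        )
        got = set(ortholog_collapse(pairs))
        ext = {}
        foc = {}
        for br, at in pairs:
            ext.setdefault(at, set()).add(br)
            foc.setdefault(br, set()).add(at)
        want = {
            (br, at) for br, at in pairs
            if len(ext[at]) == 1 and len(foc[br]) == 1
        }
        assert got == want

    def test_partial_conservation(self):
        out = classify_orthologs(
            {"br1"}, {"at1"}, set(), [("br1", "at1")]
        )
        assert out.partially_conserved == 1

    def test_classes_partition(self):
        rng = np.random.default_rng(37)
        pairs = [(f"br{i}", f"at{i}") for i in range(50)]
        marked = {f"br{i}" for i in range(50) if rng.random() < 0.6}
        e1 = {f"at{i}" for i in range(50) if rng.random() < 0.4}
        e2 = {f"at{i}" for i in range(50) if rng.random() < 0.4}
        out = classify_orthologs(marked, e1, e2, pairs)
        assert (
            out.species_conserved + out.partially_conserved
            + out.species_specific + out.unmarked_focal
        ) == 50
        pct = out.percentages()
        assert sum(pct.values()) == pytest.approx(100.0)


class TestSnpDensity:
    def _ann(self):
        return GenomeAnnotation({"g1": make_gene("g1", start=1000, end=3000,
                                                 exons=[(1000, 1500), (2000, 3000)])})

    def test_density_arithmetic(self):
        variants = [VariantRecord("A01", p, 20, "hom") for p in (1100, 1500, 2500, 2999)]
        out = snp_density(variants, self._ann())
        assert out.at["g1", "n_snps"] == 4
        assert out.at["g1", "density"] == pytest.approx(0.002)

    def test_depth_boundary_strictly_greater(self):
        variants = [
            VariantRecord("A01", 1100, 10, "hom"),  # excluded: depth not > 10
            VariantRecord("A01", 1200, 11, "hom"),
        ]
        out = snp_density(variants, self._ann())
        assert out.at["g1", "n_snps"] == 1

    def test_position_membership_matches_brute_force(self):
        rng = np.random.default_rng(41)
        genes = {
            f"g{i}": make_gene(f"g{i}", start=5000 * i + 1000, end=5000 * i + 3000,
                               exons=[(5000 * i + 1000, 5000 * i + 1500),
                                      (5000 * i + 2000, 5000 * i + 3000)])
            for i in range(5)
        }
        ann = GenomeAnnotation(genes)
        variants = [
            VariantRecord("A01", int(p), int(d), "hom")
            for p, d in zip(rng.integers(1, 30000, 200), rng.integers(1, 40, 200))
        ]
        out = snp_density(variants, ann)
        for gid, g in genes.items():
            brute = sum(
                1 for v in variants
                if v.depth > 10 and g.locus.start + 1 <= v.pos <= g.locus.end
            )
            assert out.at[gid, "n_snps"] == brute

    def test_planted_rate_ratio_recovered(self, default_dataset):
        """Marked genes carry the configured fraction of the unmarked SNP rate."""
        ds = default_dataset
        out = snp_density(
            [v for v in ds.variants if v.genotype_class == "hom"], ds.annotation
        )
        ref = ds.config.study_tissues[-1]
        marked = set()
        for line in ds.config.lines:
            marked |= ds.truth.marked_genes(f"{line}_{ref}")
        dm = out.loc[out.index.isin(marked), "density"].mean()
        du = out.loc[~out.index.isin(marked), "density"].mean()
        assert dm / du == pytest.approx(ds.config.snp_rate_ratio_marked, rel=0.25)


def test_homology_fraction():
    marked = {f"g{i}" for i in range(100)}
    pairs = [(f"g{i}", f"at{i}") for i in range(60)] + [("x1", "at999")]
    assert homology_fraction(marked, pairs) == pytest.approx(0.6)
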