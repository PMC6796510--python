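"""Metagene profiles, segment composition, nucleation and spreading."""
import numpy as np
import pytest

from k27pipe.io_formats import BinnedCoverage, GenomeAnnotation, GenomicInterval
from k27pipe.profiles import (
    metagene_profile,
    nucleation_region,
    positions_from_coverage,
    sample_correlation,
    segment_composition,
    spreading_call,
    spreading_report,
)

from conftest import make_gene


def flat_cov(value, n_bins=400, bin_size=50, sample="s"):
    return BinnedCoverage(sample, bin_size, {"A01": np.full(n_bins, value)})


class TestMetagene:
    def test_uniform_coverage_is_flat(self):
        cov = flat_cov(5)
        g = make_gene(start=5000, end=9000,
                      exons=[(5000, 5500), (6000, 9000)])
        prof = metagene_profile(cov, [g])
        expect = (5 / 50) * 1e6 / cov.total_reads
        assert np.allclose(prof.values, expect)
        assert len(prof.values) == 20 + 40 + 20

    def test_body_elevated_over_flanks(self):
        arr = np.full(400, 2)
        arr[100:180] = 20  # gene body [5000, 9000)
        cov = BinnedCoverage("s", 50, {"A01": arr})
        g = make_gene(start=5000, end=9000, exons=[(5000, 5500), (6000, 9000)])
        prof = metagene_profile(cov, [g])
        assert prof.body.mean() > 5 * prof.upstream.mean()
        # closed form: body bins at 20 reads / 50 bp
        assert prof.body == pytest.approx(
            np.full(40, (20 / 50) * 1e6 / cov.total_reads)
        )

    def test_minus_strand_reversed(self):
        arr = np.full(400, 2)
        arr[100:110] = 50  # 5' end in genome coords [5000, 5500)
        cov = BinnedCoverage("s", 50, {"A01": arr})
        gp = make_gene("gp", start=5000, end=9000, strand="+",
                       exons=[(5000, 5500), (6000, 9000)])
        gm = make_gene("gm", start=5000, end=9000, strand="-",
                       exons=[(5000, 5500), (6000, 9000)])
        pp = metagene_profile(cov, [gp])
        pm = metagene_profile(cov, [gm])
        assert np.argmax(pp.body) < 5          # left for + strand
        assert np.argmax(pm.body) > 34         # right (3' of the profile axis) for -
        assert pm.values == pytest.approx(pp.values[::-1])

    def test_rpm_invariant_to_depth_scaling(self):
        g = make_gene(start=5000, end=9000, exons=[(5000, 5500), (6000, 9000)])
        p1 = metagene_profile(flat_cov(5), [g])
        p2 = metagene_profile(flat_cov(50), [g])
        assert p1.values == pytest.approx(p2.values)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile(flat_cov(5), [])


class TestSegmentComposition:
    def _ann(self):
        return GenomeAnnotation({
            "g1": make_gene("g1", start=10000, end=14000,
                            exons=[(10000, 10500), (11000, 14000)])
        })

    def test_all_reads_in_exons(self):
        pos = {"A01": np.array([10100.0, 10400.0, 12000.0])}
        out = segment_composition(pos, self._ann())
        assert out["exon"] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        pos = {"A01": rng.uniform(0, 30000, 500)}
        out = segment_composition(pos, self._ann())
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_read_oracle(self):
        rng = np.random.default_rng(9)
        ann = self._ann()
        g = ann["g1"]
        irr = [GenomicInterval("A01", 20000, 21000)]
        pos = {"A01": rng.uniform(0, 30000, 300)}
        out = segment_composition(pos, ann, irr)

        def classify(p):
            if any(e.start <= p < e.end for e in g.exons):
                return "exon"
            if g.locus.start <= p < g.locus.end:
                return "intron"
            if g.locus.start - 2000 <= p < g.locus.start:  # + strand upstream
                return "upstream_2kb"
            if g.locus.end <= p < g.locus.end + 2000:
                return "downstream_2kb"
            if 20000 <= p < 21000:
                return "irr"
            return "intergenic"

        n = len(pos["A01"])
        for seg in out:
            brute = sum(1 for p in pos["A01"] if classify(p) == seg) / n
            assert out[seg] == pytest.approx(brute)

    def test_from_coverage_weights(self):
        cov = flat_cov(3, n_bins=100)
        pos, wts = positions_from_coverage(cov)
        out = segment_composition(pos, self._ann(), weights=wts)
        assert sum(out.values()) == pytest.approx(1.0)


class TestCorrelation:
    def test_identical_vectors(self, default_dataset):
        rcm = default_dataset.region_counts
        s = rcm.samples[0]
        assert sample_correlation(rcm, s, s) == pytest.approx(1.0)

    def test_hand_computed(self):
        import pandas as pd
        from k27pipe.io_formats import RegionCountMatrix

        rcm = RegionCountMatrix(
            pd.DataFrame({"a": [1, 2, 3], "b": [2, 4, 7]}, index=["g1", "g2", "g3"]),
            {"a": 100, "b": 100},
        )
        x, y = np.array([1, 2, 3.0]), np.array([2, 4, 7.0])
        r = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert sample_correlation(rcm, "a", "b") == pytest.approx(r)


class TestNucleation:
    def test_first_exon_plus_intron_extent(self):
        g = make_gene(start=0, end=2000, exons=[(0, 300), (1200, 2000)])
        r = nucleation_region(g)
        assert (r.start, r.end) == (0, 800)

    def test_short_intron_clipped(self):
        g = make_gene(start=0, end=2000, exons=[(0, 300), (500, 2000)])
        r = nucleation_region(g)
        assert (r.start, r.end) == (0, 500)

    def test_minus_strand_at_genomic_3prime(self):
        g = make_gene(start=0, end=2000, strand="-",
                      exons=[(0, 800), (1700, 2000)])
        r = nucleation_region(g)
        # first exon is [1700, 2000); intron extends 500 bp leftwards
        assert (r.start, r.end) == (1200, 2000)

    def test_single_exon_first_half(self):
        g = make_gene(start=1000, end=3000, exons=[(1000, 3000)])
        r = nucleation_region(g)
        assert (r.start, r.end) == (1000, 2000)


class TestSpreading:
    def test_background_gene_is_none(self):
        cov = flat_cov(5)
        g = make_gene(start=5000, end=9000, exons=[(5000, 5300), (6000, 9000)])
        rep = spreading_report(cov, g)
        assert rep.spreading_call == "none"
        assert rep.nucleation_enrichment == pytest.approx(1.0, abs=0.5)

    def test_planted_schedule_recovered(self, default_dataset):
        """Every FLC-like gene follows none -> none -> nucleation_only -> spread."""
        ds = default_dataset
        tps = ds.config.vernalization_timepoints
        for gid in ds.truth.flc_genes:
            reports, transitions = spreading_call(
                [(tp, ds.vernalization[tp]) for tp in tps], ds.annotation[gid]
            )
            calls = tuple(r.spreading_call for _, r in reports)
            assert calls == ds.truth.vern_schedule[gid]
            assert transitions[-1] == "nucleation_only->spread"
            # V1: nucleation hot, distal third at background
            v1 = dict(reports)["V1"]
            assert v1.nucleation_enrichment > 2.0
            assert v1.thirds_profile[2] == pytest.approx(1.0, abs=0.35)
            v2 = dict(reports)["V2"]
            assert v2.body_breadth >= 0.9

    def test_non_flc_genes_unchanged(self, default_dataset):
        ds = default_dataset
        others = [g for g in ds.annotation.genes if g not in ds.truth.flc_genes][:10]
        for gid in others:
            for tp in ds.config.vernalization_timepoints:
                rep = spreading_report(ds.vernalization[tp], ds.annotation[gid])
                assert rep.spreading_call == "none"
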