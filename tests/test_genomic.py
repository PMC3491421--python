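"""Category assignment, distribution statistics and feature overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydroxyscan.annotation import Gene, GenomeAnnotation
from hydroxyscan.genomic import (
    CATEGORIES, CategoryScheme, assign_category, category_counts,
    categorize_probes, cgi_classes, coverage_normalized_distribution,
    distribution_chi2, feature_overlap, region_level_compare,
)
from hydroxyscan.peaks import PeakParams, call_peaks

from conftest import make_track


@pytest.fixture(scope="module")
def two_gene_ann():
    """One plus-strand and one minus-strand gene with known coordinates."""
    plus = Gene("plus", "chr1", "+", 50_000, 60_000,
                exons=((50_000, 51_000), (55_000, 56_000)))
    minus = Gene("minus", "chr1", "-", 200_000, 210_000,
                 exons=((200_000, 210_000),))
    return GenomeAnnotation(chromosomes={"chr1": 400_000},
                            genes=[plus, minus])


class TestAssignCategory:
    @pytest.mark.parametrize("pos,expected,gene", [
        (50_100, "promoter", "plus"),     # TSS+100 within -1kb..+250
        (49_500, "promoter", "plus"),     # TSS-500
        (50_500, "exon", "plus"),         # beyond +250, inside exon 1
        (52_000, "intron", "plus"),       # between exons
        (55_500, "exon", "plus"),         # exon 2
        (60_500, "downstream", "plus"),   # txEnd..+1kb
        (45_000, "upstream", "plus"),     # -7.25kb..-1kb
        (150_000, "intergenic", None),    # far from both genes
    ])
    def test_plus_strand_windows(self, two_gene_ann, pos, expected, gene):
        cat, gid = assign_category(("chr1", pos - 5, pos + 5), two_gene_ann)
        assert cat == expected
        assert gid == gene

    @pytest.mark.parametrize("pos,expected", [
        (209_900, "promoter"),    # TSS at 209_999; offset +99
        (210_500, "promoter"),    # 501 bp 5' of TSS in genome coords
        (209_000, "exon"),        # offset ~1000, inside the single exon
        (199_500, "downstream"),  # past txEnd on the transcribed strand
        (213_000, "upstream"),
    ])
    def test_minus_strand_windows_hand_computed(self, two_gene_ann, pos, expected):
        cat, gid = assign_category(("chr1", pos - 5, pos + 5), two_gene_ann)
        assert cat == expected
        assert gid == "minus"

    def test_promoter_precedence_over_gene_body(self):
        # overlapping windows: promoter of B sits in the body of A
        a = Gene("a", "chr1", "+", 10_000, 30_000, exons=((10_000, 30_000),))
        b = Gene("b", "chr1", "+", 30_500, 40_000, exons=((30_500, 40_000),))
        ann = GenomeAnnotation(chromosomes={"chr1": 100_000}, genes=[a, b])
        cat, gid = assign_category(("chr1", 29_700, 29_800), ann)
        assert (cat, gid) == ("promoter", "b")

    def test_unknown_chromosome_raises(self, two_gene_ann):
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_category(("chrX", 0, 10), two_gene_ann)

    def test_total_function_and_conservation(self, small_ann):
        rng = np.random.default_rng(8)
        n = 500
        pos = rng.integers(0, 1_400_000, size=n)
        cats = [assign_category(("chr1", p, p + 50), small_ann)[0]
                for p in pos]
        assert all(c in CATEGORIES for c in cats)
        counts = category_counts(pd.Series(cats))
        assert counts.sum() == n

    def test_strand_mirror_invariance(self, two_gene_ann):
        """Mirroring every coordinate (and flipping strands) must not
        change any category assignment."""
        length = two_gene_ann.chromosomes["chr1"]
        mirrored_genes = []
        for g in two_gene_ann.genes:
            exons = tuple(sorted((length - e, length - s) for s, e in g.exons))
            mirrored_genes.append(Gene(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                length - g.end, length - g.start, exons=exons))
        mirrored = GenomeAnnotation(chromosomes={"chr1": length},
                                    genes=mirrored_genes)
        rng = np.random.default_rng(9)
        for p in rng.integers(100, length - 100, size=300):
            p = int(p)
            # odd interval length: the midpoint mirrors exactly
            cat, _ = assign_category(("chr1", p, p + 11), two_gene_ann)
            mcat, _ = assign_category(("chr1", length - p - 11, length - p),
                                      mirrored)
            assert cat == mcat


class TestDistributions:
    def test_equal_proportions_give_zero(self):
        obs = pd.Series({c: 10 for c in CATEGORIES})
        bg = pd.Series({c: 1000 for c in CATEGORIES})
        stat, p = distribution_chi2(obs, bg)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_cell_example(self, caplog):
        # (90, 10) observed vs (50, 50) expected: 40^2/50 * 2 = 64
        obs = pd.Series({"promoter": 90, "exon": 10})
        bg = pd.Series({"promoter": 500, "exon": 500})
        with caplog.at_level("WARNING"):
            stat, p = distribution_chi2(obs, bg)
        assert stat == pytest.approx(64.0)
        assert "collapsing" in caplog.text  # four empty categories pooled out

    def test_planted_gene_body_peaks_significant(self, small_ann):
        from hydroxyscan.simulate import simulate_probe_signals

        hmc, _, _ = simulate_probe_signals(
            small_ann, seed=21, noise_sd=0.3, body_peak_fraction=0.5,
            body_peak_effect=3.0, intensity_trend=0.0)
        scores = hmc.scores[hmc.group_samples("control")].mean(axis=1)
        ps = call_peaks(hmc, scores, PeakParams())
        probe_cats = categorize_probes(hmc, small_ann)
        obs = category_counts(probe_cats.loc[sorted(ps.probe_ids)])
        bg = category_counts(probe_cats)
        _, p = distribution_chi2(obs, bg)
        assert p < 0.001

    def test_coverage_normalized_uniform(self):
        pk = pd.Series({c: 5 for c in CATEGORIES})
        pr = pd.Series({c: 50 for c in CATEGORIES})
        out = coverage_normalized_distribution(pk, pr)
        assert np.allclose(out.to_numpy(), 1 / 6)

    def test_coverage_normalized_single_category(self):
        pk = pd.Series({"intron": 7})
        pr = pd.Series({c: 50 for c in CATEGORIES})
        out = coverage_normalized_distribution(pk, pr)
        assert out["intron"] == 1.0
        assert out.drop("intron").sum() == 0.0

    def test_random_placement_proportional_to_coverage(self):
        rng = np.random.default_rng(10)
        pr = pd.Series({c: int(v) for c, v in
                        zip(CATEGORIES, [5000, 2000, 8000, 1000, 3000, 6000])})
        draws = rng.multinomial(20_000, pr / pr.sum())
        pk = pd.Series(dict(zip(CATEGORIES, draws)))
        out = coverage_normalized_distribution(pk, pr)
        assert np.abs(out.to_numpy() - 1 / 6).max() < 0.02


class TestFeatureOverlap:
    def test_all_feature_probes_in_peaks(self):
        track = make_track(np.zeros(10))
        ps = call_peaks(track, np.full(10, 2.0), PeakParams(), threshold=1.0)
        features = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                 "end": [400]})
        n_f, n_in, frac = feature_overlap(ps, features, track)
        assert frac == 1.0 and n_f == n_in > 0

    def test_features_covering_no_probes_is_error(self):
        track = make_track(np.zeros(10))
        ps = call_peaks(track, np.zeros(10), PeakParams(), threshold=1.0)
        features = pd.DataFrame({"chrom": ["chr1"], "start": [100_000],
                                 "end": [101_000]})
        with pytest.raises(ValueError, match="cover no probes"):
            feature_overlap(ps, features, track)

    def test_empty_feature_set_is_error(self):
        track = make_track(np.zeros(10))
        ps = call_peaks(track, np.zeros(10), PeakParams(), threshold=1.0)
        with pytest.raises(ValueError, match="empty feature"):
            feature_overlap(ps, pd.DataFrame(columns=["chrom", "start", "end"]),
                            track)

    def test_enhancer_5hmc_exceeds_5mc(self, small_ann):
        """A track with 5hmC planted over enhancers overlaps them more
        than the matching 5mC track does."""
        from hydroxyscan.genomic import enhancer_windows
        from hydroxyscan.simulate import simulate_probe_signals

        hmc, mc, _ = simulate_probe_signals(
            small_ann, seed=31, noise_sd=0.3, body_peak_genes={},
            mc_body_level=0.0, intensity_trend=0.0)
        enh = enhancer_windows(small_ann)
        boost = np.zeros(len(hmc.probes))
        mid = hmc.midpoints
        for row in enh.itertuples():
            m = (hmc.probes["chrom"].to_numpy() == row.chrom) & \
                (mid >= row.start) & (mid < row.end)
            boost[m] = 2.5
        h_scores = hmc.scores[hmc.group_samples("control")].mean(axis=1) + boost
        m_scores = mc.scores[mc.group_samples("control")].mean(axis=1)
        ps_h = call_peaks(hmc, h_scores, PeakParams())
        ps_m = call_peaks(mc, m_scores, PeakParams())
        _, _, frac_h = feature_overlap(ps_h, enh, hmc)
        try:
            _, _, frac_m = feature_overlap(ps_m, enh, mc)
        except ValueError:
            frac_m = 0.0
        assert frac_h > frac_m


class TestRegionCompare:
    def test_identical_sets_not_significant(self):
        rng = np.random.default_rng(11)
        track = make_track(rng.normal(size=2000))
        scores = track.scores["s0"].to_numpy()
        regions = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(20) * 10_000,
            "end": np.arange(20) * 10_000 + 1000})
        res = region_level_compare(track, scores, regions, regions)
        assert res["p_value"] > 0.99

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 0.3, size=20_000)
        track = make_track(scores)
        half = 10_000 * 100
        starts_a = np.arange(100) * 10_000
        starts_b = half + np.arange(100) * 10_000
        mid = track.midpoints
        scores = scores.copy()
        scores[mid >= half] += 1.0
        a = pd.DataFrame({"chrom": "chr1", "start": starts_a,
                          "end": starts_a + 1000})
        b = pd.DataFrame({"chrom": "chr1", "start": starts_b,
                          "end": starts_b + 1000})
        res = region_level_compare(track, scores, a, b)
        assert res["p_value"] < 0.001
        assert res["means_b"].mean() - res["means_a"].mean() == \
            pytest.approx(1.0, abs=0.15)

    def test_single_region_set_raises(self):
        track = make_track(np.zeros(100))
        one = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        many = pd.DataFrame({"chrom": "chr1", "start": [0, 2000],
                             "end": [1000, 3000]})
        with pytest.raises(ValueError, match=">= 2"):
            region_level_compare(track, np.zeros(100), one, many)


class TestCgiClasses:
    def test_promoter_and_intergenic_cgis(self, two_gene_ann):
        two_gene_ann.cgis = [
            ("chr1", 49_900, 50_300),   # spans the plus-strand TSS
            ("chr1", 150_000, 150_500),  # far from genes
            ("chr1", 52_000, 52_400),   # inside the plus gene body
        ]
        classes = cgi_classes(two_gene_ann)
        assert list(classes) == ["promoter", "intergenic", "intragenic"]
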