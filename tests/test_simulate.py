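"""Generator contracts: geometry, determinism, recoverable planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydroxyscan.annotation import offset_window_to_genomic
from hydroxyscan.chipseq import count_in_regions, dedup, normalize_counts
from hydroxyscan.simulate import (
    simulate_annotation, simulate_epimark_cq, simulate_expression,
    simulate_fragments, simulate_probe_signals, simulate_promoter_sequences,
    TruthLedger,
)


class TestAnnotation:
    def test_minimal_single_gene(self):
        ann = simulate_annotation(1, 60_000, seed=1, n_chroms=1,
                                  n_enhancers=0, n_intergenic_tiles=0)
        assert len(ann.genes) == 1
        g = ann.genes[0]
        assert any(c == g.chrom and s <= g.tss < e
                   for c, s, e in ann.tiled_regions)

    def test_nonoverlapping_mixed_strands(self):
        ann = simulate_annotation(100, 5_000_000, seed=7)
        by_chrom = ann.genes_by_chrom()
        for genes in by_chrom.values():
            for a, b in zip(genes, genes[1:]):  # brute-force disjointness
                assert a.end <= b.start
        assert {g.strand for g in ann.genes} == {"+", "-"}
        assert sum(len(v) for v in by_chrom.values()) == 100

    def test_exons_inside_gene(self):
        ann = simulate_annotation(40, 2_000_000, seed=3, n_chroms=1)
        for g in ann.genes:
            assert 1 <= len(g.exons) <= 8
            for s, e in g.exons:
                assert g.start <= s < e <= g.end

    def test_determinism(self, tmp_path):
        a = simulate_annotation(25, 1_500_000, seed=42)
        b = simulate_annotation(25, 1_500_000, seed=42)
        a.to_gff3(tmp_path / "a.gff3")
        b.to_gff3(tmp_path / "b.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == \
            (tmp_path / "b.gff3").read_bytes()
        assert a.tiled_regions == b.tiled_regions
        assert a.enhancers == b.enhancers

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_annotation(100, 100_000, seed=1, n_chroms=1)


class TestProbeSignals:
    @pytest.fixture(scope="class")
    def null_tracks(self, small_ann):
        return simulate_probe_signals(
            small_ann, seed=2, noise_sd=0.5, body_peak_genes={},
            mc_body_level=0.0, intensity_trend=0.0)

    def test_probe_geometry(self, null_tracks):
        hmc, _, _ = null_tracks
        lengths = hmc.probes["end"] - hmc.probes["start"]
        assert lengths.between(50, 70).all()
        for _, sub in hmc.probes.groupby("tiled_region_id"):
            gaps = np.diff(np.sort(sub["start"].to_numpy()))
            assert (gaps == 100).all()

    def test_null_track_group_means_bounded(self, null_tracks):
        hmc, mc, _ = null_tracks
        for track in (hmc, mc):
            for group in ("control", "treated"):
                cols = track.group_samples(group)
                m = track.scores[cols].mean(axis=1)
                sd = np.sqrt(0.5**2 / len(cols) + 0.1**2)
                assert np.abs(m).max() < 5 * sd

    def test_planted_peak_recomputed_from_table(self, small_ann):
        gid = small_ann.gene_ids[0]
        hmc, _, ledger = simulate_probe_signals(
            small_ann, seed=9, noise_sd=0.1,
            body_peak_genes={gid: (600, 1400)}, body_peak_effect=3.0,
            tiers={g: "medium" for g in small_ann.gene_ids},
            mc_body_level=0.0, intensity_trend=0.0)
        chrom, s, e = ledger.planted_peaks["5hmC"][0]
        mid = hmc.midpoints
        inside = (hmc.probes["chrom"].to_numpy() == chrom) & \
            (mid >= s) & (mid < e)
        all_means = hmc.scores.mean(axis=1).to_numpy()
        diff = all_means[inside].mean() - all_means[~inside].mean()
        assert diff == pytest.approx(3.0, abs=0.1)

    def test_induced_reciprocal_ppr_signs(self, small_ann):
        gid = small_ann.gene_ids[3]
        hmc, mc, ledger = simulate_probe_signals(
            small_ann, seed=12, noise_sd=0.2, body_peak_genes={},
            induced={gid: 2.0}, flank_effect=1.0, intensity_trend=0.0)
        g = small_ann.gene(gid)
        s, e = offset_window_to_genomic(g.tss, g.strand, -1000, 1000)
        for track, sign in ((hmc, 1), (mc, -1)):
            mid = track.midpoints
            m = (track.probes["chrom"].to_numpy() == g.chrom) & \
                (mid >= s) & (mid < e)
            ctrl = track.scores[track.group_samples("control")].to_numpy()
            trt = track.scores[track.group_samples("treated")].to_numpy()
            delta = trt[m].mean() - ctrl[m].mean()
            assert np.sign(delta) == sign
        assert gid in ledger.tss_core_loss

    def test_planting_outside_tiled_regions_raises(self, small_ann):
        gid = small_ann.gene_ids[0]
        with pytest.raises(ValueError, match="outside tiled"):
            simulate_probe_signals(
                small_ann, seed=1,
                body_peak_genes={gid: (2900, 25_000)})

    def test_determinism(self, small_ann):
        a = simulate_probe_signals(small_ann, seed=33)
        b = simulate_probe_signals(small_ann, seed=33)
        pd.testing.assert_frame_equal(a[0].scores, b[0].scores)
        pd.testing.assert_frame_equal(a[1].scores, b[1].scores)

    def test_precondition_errors(self, small_ann):
        with pytest.raises(ValueError):
            simulate_probe_signals(small_ann, seed=1, noise_sd=0.0)
        with pytest.raises(ValueError):
            simulate_probe_signals(small_ann, seed=1, n_control=1)


class TestFragments:
    def test_uniform_counts_proportional_to_length(self, small_ann):
        ip, _ = simulate_fragments(small_ann, "H3K36me3", [], 30_000, seed=4)
        regions = pd.DataFrame(
            [(g.chrom, g.start, g.end, g.gene_id) for g in small_ann.genes],
            columns=["chrom", "start", "end", "region_id"])
        counts = count_in_regions(dedup(ip), regions).to_numpy()
        lengths = (regions["end"] - regions["start"]).to_numpy()
        expected = counts.sum() * lengths / lengths.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 1e-3

    def test_enriched_region_scores_highest(self, small_ann):
        target = small_ann.genes[5]
        enr = [(target.chrom, target.start, target.end, 10.0)]
        ip, bg = simulate_fragments(small_ann, "H3K36me3", enr, 20_000, seed=8)
        regions = pd.DataFrame(
            [(g.chrom, g.start, g.end, g.gene_id) for g in small_ann.genes],
            columns=["chrom", "start", "end", "region_id"])
        ipc = count_in_regions(dedup(ip), regions)
        lengths = (regions["end"] - regions["start"])
        lengths.index = regions["region_id"]
        rate = ipc / lengths
        assert rate.idxmax() == target.gene_id

    def test_empty_library(self, small_ann):
        ip, bg = simulate_fragments(small_ann, "H3K4me2", [], 0, seed=1)
        regions = pd.DataFrame([("chr1", 0, 1000, "r0")],
                               columns=["chrom", "start", "end", "region_id"])
        assert len(ip) == 0
        assert count_in_regions(ip, regions).sum() == 0

    def test_zero_length_region_raises(self, small_ann):
        with pytest.raises(ValueError, match="zero-length"):
            simulate_fragments(small_ann, "H3K4me2",
                               [("chr1", 100, 100, 2.0)], 100, seed=1)

    def test_duplicate_injection_rate(self, small_ann):
        ip, _ = simulate_fragments(small_ann, "H3K27me3", [], 10_000, seed=6,
                                   duplicate_rate=0.1)
        assert len(ip) == 11_000


class TestExpression:
    def test_lfc_recovery(self, small_ann):
        gid = small_ann.gene_ids[2]
        expr, _ = simulate_expression(small_ann, {gid: 2.0}, seed=3,
                                      noise_sd=0.2)
        ctrl = expr.loc[[s for s in expr.index if s.startswith("control")]]
        trt = expr.loc[[s for s in expr.index if s.startswith("treated")]]
        est = trt[gid].mean() - ctrl[gid].mean()
        assert est == pytest.approx(2.0, abs=0.3)

    def test_no_induced_genes_all_small(self, small_ann):
        expr, _ = simulate_expression(small_ann, {}, seed=3, noise_sd=0.1)
        ctrl = expr.loc[[s for s in expr.index if s.startswith("control")]]
        trt = expr.loc[[s for s in expr.index if s.startswith("treated")]]
        lfc = (trt.mean() - ctrl.mean()).abs()
        assert lfc.max() < 0.5

    def test_designed_tissue_genes(self, small_ann):
        ledger = TruthLedger()
        _, panel = simulate_expression(small_ann, {}, seed=3, tissue_count=5,
                                       ledger=ledger)
        for gid, t in ledger.single_tissue_genes.items():
            row = panel.loc[gid]
            assert (row > 0).sum() == 1
            assert row.iloc[t] > 0
        for gid in ledger.uniform_tissue_genes:
            assert panel.loc[gid].nunique() == 1

    def test_unknown_induced_gene_raises(self, small_ann):
        with pytest.raises(KeyError):
            simulate_expression(small_ann, {"nope": 2.0}, seed=1)


class TestEpimarkCq:
    def test_fully_unmodified_hits_ceiling(self):
        cq = simulate_epimark_cq({"L": (0.0, 0.0, 1.0)}, seed=1)
        msp = cq[(cq["digest"] == "MspI")]
        assert (msp["cq"] == 40.0).all()

    def test_determinism(self):
        a = simulate_epimark_cq({"L": (0.1, 0.4, 0.5)}, seed=7, noise_sd=0.2)
        b = simulate_epimark_cq({"L": (0.1, 0.4, 0.5)}, seed=7, noise_sd=0.2)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            simulate_epimark_cq({"L": (0.6, 0.6, 0.2)}, seed=1)


class TestLedger:
    def test_json_round_trip(self, small_study, tmp_path):
        ledger = small_study.ledger
        path = tmp_path / "ledger.json"
        ledger.to_json(path)
        back = TruthLedger.from_json(path)
        assert back.induced_genes == ledger.induced_genes
        assert back.planted_peaks == ledger.planted_peaks
        assert back.tiers == ledger.tiers
        assert back.unique_fragment_counts == ledger.unique_fragment_counts

    def test_invalid_ledger_rejected(self):
        with pytest.raises(ValueError, match="fold change"):
            TruthLedger(induced_genes={"g": -1.0})
        with pytest.raises(ValueError, match="fractions"):
            TruthLedger(true_fractions={"L": (0.7, 0.7, 0.2)})


class TestPromoterSequences:
    def test_cgi_promoters_are_dense(self, small_ann):
        seqs = simulate_promoter_sequences(small_ann, seed=2)
        cgi_genes = set()
        for g in small_ann.genes:
            s, e = offset_window_to_genomic(g.tss, g.strand, -1000, 250)
            if any(c == g.chrom and cs < e and s < ce
                   for c, cs, ce in small_ann.cgis):
                cgi_genes.add(g.gene_id)
        assert cgi_genes, "fixture should contain CGI promoters"
        for gid, seq in seqs.items():
            density = seq.upper().count("CG") * 100 / len(seq)
            if gid in cgi_genes:
                assert density > 5
            else:
                assert density < 1.5
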