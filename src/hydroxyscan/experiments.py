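"""Seeded recovery and calibration experiments.

These drive whole-pipeline questions on synthetic studies: does the peak
caller recover planted 5hmC domains probe-for-probe, does the default
differential scenario reproduce the expected sign pattern of the five
change-vs-expression correlations, and is the family region analysis
calibrated under the null?  Used by the test suite and the acceptance
script alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .chipseq import region_scores
from .differential import (
    DNA_REGIONS, HISTONE_REGIONS, combine_mark_deltas,
    family_region_analysis, gene_region_windows, study_change_correlations,
    track_region_deltas,
)
from .norm import delta_track, group_mean
from .peaks import PeakParams, call_peaks
from .simulate import simulate_annotation, simulate_fragments, \
    simulate_probe_signals, simulate_study

EXPECTED_SIGNS = {"5hmC": 1, "5mC": -1, "H3K4me2": 1,
                  "H3K36me3": 1, "H3K27me3": -1}


def peak_recovery_experiment(seed: int, *, n_genes: int = 150,
                             chrom_length: int = 4_000_000,
                             effect: float = 2.0,
                             noise_sd: float = 0.5) -> dict:
    """Plant 5hmC gene-body domains and score probe-level recovery.

    Peaks are called on the control group-mean track at default
    parameters; truth probes are those whose midpoint falls in a planted
    interval.  Returns per-probe sensitivity and the false discovery
    proportion.
    """
    ann = simulate_annotation(n_genes, chrom_length, seed)
    hmc, _, ledger = simulate_probe_signals(
        ann, seed=seed + 1, noise_sd=noise_sd, body_peak_effect=effect,
        tiers={g: "medium" for g in ann.gene_ids}, mc_body_level=0.0)
    scores = group_mean(hmc, "control")
    peakset = call_peaks(hmc, scores, PeakParams())

    mid = hmc.midpoints
    chrom_arr = hmc.probes["chrom"].to_numpy()
    truth = np.zeros(len(hmc.probes), dtype=bool)
    for chrom, s, e in ledger.planted_peaks["5hmC"]:
        truth |= (chrom_arr == chrom) & (mid >= s) & (mid < e)
    truth_ids = set(hmc.probes.loc[truth, "probe_id"])
    called = peakset.probe_ids
    tp = len(called & truth_ids)
    sensitivity = tp / len(truth_ids) if truth_ids else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return {"sensitivity": sensitivity, "fdp": fdp,
            "n_truth_probes": len(truth_ids), "n_called_probes": len(called),
            "n_peaks": len(peakset), "threshold": peakset.threshold}


def sign_recovery_experiment(seed: int, n_replicates: int = 100,
                             **study_kwargs) -> dict:
    """Fraction of studies reproducing the expected correlation signs.

    Each replicate generates a fresh default study and recomputes the
    five change-vs-expression correlations over its detected induced
    genes; a replicate succeeds when every mark's sign matches the
    expected (+, -, +, +, -) pattern.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    successes = 0
    correlations = []
    for s in sub_seeds:
        study = simulate_study(int(s), **study_kwargs)
        corr = study_change_correlations(study)
        correlations.append({m: corr[m][0] for m in corr})
        ok = all(np.sign(corr[m][0]) == EXPECTED_SIGNS[m]
                 for m in EXPECTED_SIGNS)
        successes += ok
    return {"rate": successes / n_replicates, "n_replicates": n_replicates,
            "correlations": correlations}


def null_family_calibration(seed: int, n_replicates: int = 200, *,
                            n_genes: int = 40, chrom_length: int = 1_500_000,
                            n_fragments: int = 5_000,
                            alpha: float = 0.005) -> dict:
    """Type-I behaviour of the family analysis under a null generator.

    No effects are planted; per replicate a random 10-gene "family" is
    tested against 30 unaffected genes over every region x mark cell.
    Returns the fraction of cells flagged at p < alpha.
    """
    ann = simulate_annotation(n_genes, chrom_length, seed, n_chroms=1)
    rng = np.random.default_rng(seed + 1)
    flags = 0
    cells = 0
    histone_regions = {
        kind: _regions_frame(ann, kind) for kind in HISTONE_REGIONS}
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        hmc, mc, _ = simulate_probe_signals(
            ann, seed=rep_seed, body_peak_genes={}, mc_body_level=0.0,
            intensity_trend=0.0)
        per_mark = {}
        for mark, track in (("5hmC", hmc), ("5mC", mc)):
            delta = delta_track(group_mean(track, "control"),
                                group_mean(track, "treated"))
            per_mark[mark] = track_region_deltas(track, delta, ann,
                                                 regions=DNA_REGIONS)
        for mi, mark in enumerate(("H3K4me2", "H3K27me3", "H3K36me3")):
            pairs = []
            for li, group in enumerate(("control", "treated")):
                for r in range(2):
                    pairs.append(simulate_fragments(
                        ann, mark, [], n_fragments,
                        rep_seed + 7 * mi + 2 * li + r,
                        sample_id=f"{group}_{r + 1}"))
            frames = {}
            for kind in HISTONE_REGIONS:
                scores = region_scores(pairs, histone_regions[kind])
                ctrl = [c for c in scores.columns if c.startswith("control")]
                trt = [c for c in scores.columns if c.startswith("treated")]
                frames[kind] = scores[trt].mean(axis=1) - \
                    scores[ctrl].mean(axis=1)
            per_mark[mark] = pd.DataFrame(frames)
        deltas = combine_mark_deltas(per_mark)
        ids = list(deltas.index)
        picked = rng.permutation(len(ids))
        family = [ids[i] for i in picked[:10]]
        unaffected = [ids[i] for i in picked[10:40]]
        result = family_region_analysis(deltas, family, unaffected,
                                        alpha=alpha)
        flags += int(result["significant"].sum())
        cells += len(result)
    return {"flag_rate": flags / cells, "n_cells": cells,
            "n_replicates": n_replicates}


def _regions_frame(ann: GenomeAnnotation, kind: str) -> pd.DataFrame:
    rows = []
    for g in ann.genes:
        chrom, s, e = gene_region_windows(g)[kind]
        rows.append((chrom, s, e, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
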