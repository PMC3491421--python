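"""End-to-end orchestration: simulate (or load), normalize, call peaks,
annotate, profile, score ChIP-seq regions, run the differential analysis
and write a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .annotation import GenomeAnnotation
from .chipseq import region_scores
from .config import PipelineConfig, validate_config
from .cpg import tss_5hmc_enriched
from .differential import (
    build_change_table, change_correlation, change_profile,
    combine_mark_deltas, expression_change, family_region_analysis,
    gene_region_windows, select_induced, select_unaffected,
    track_region_deltas, DNA_REGIONS, HISTONE_REGIONS,
)
from .genomic import (
    CategoryScheme, categorize_peaks, categorize_probes, category_counts,
    cgi_shores, coverage_normalized_distribution, distribution_chi2,
    enhancer_windows, feature_overlap,
)
from .norm import delta_track, group_mean, normalize_track
from .peaks import PeakParams, PeakSet, call_peaks, peak_probe_fraction
from .profiles import (
    expression_tiers, gene_body_profile, ppr_heatmap, ppr_means,
    tiered_meta_profiles,
)
from .simulate import StudyData, simulate_study
from .track import ProbeTrack

log = logging.getLogger(__name__)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the result bundle and writes ``outdir``."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle: dict = {"config": cfg}

    # ----------------------------------------------------------- inputs
    if cfg.simulate:
        study = simulate_study(
            cfg.seed, n_genes=cfg.n_genes, chrom_length=cfg.chrom_length,
            n_chroms=cfg.n_chroms, n_control=cfg.n_control,
            n_treated=cfg.n_treated, n_induced=cfg.n_induced,
            noise_sd=cfg.noise_sd, n_fragments=cfg.n_fragments,
            simulate_chip=cfg.simulate_chip)
        ann, hmc, mc, expr = study.ann, study.hmc, study.mc, study.expression
        bundle["study"] = study
    else:
        ann = GenomeAnnotation.from_gff3(cfg.gff)
        hmc = ProbeTrack.from_tsv(cfg.hmc_tsv, mark="5hmC")
        mc = ProbeTrack.from_tsv(cfg.mc_tsv, mark="5mC")
        expr = pd.read_csv(cfg.expr_tsv, sep="\t", index_col=0)
        study = None
    log.info("inputs ready in %.1fs", time.time() - t0)

    scheme = CategoryScheme(promoter=cfg.promoter_window,
                            upstream=cfg.upstream_window,
                            downstream_extent=cfg.downstream_extent)
    control = [s for s, g in hmc.groups.items() if g == "control"]
    treated = [s for s, g in hmc.groups.items() if g == "treated"]

    # ---------------------------------------------------- normalization
    tracks = {}
    for mark, track in (("5hmC", hmc), ("5mC", mc)):
        if track.intensity is None:
            order = tuple(s for s in cfg.norm_order if s != "loess")
        else:
            order = cfg.norm_order
        tracks[mark] = normalize_track(track, order=order,
                                       span=cfg.loess_span)
    means = {m: {g: group_mean(t, g) for g in ("control", "treated")}
             for m, t in tracks.items()}
    deltas = {m: delta_track(means[m]["control"], means[m]["treated"])
              for m in tracks}
    bundle.update(tracks=tracks, means=means, deltas=deltas)
    log.info("normalization done at %.1fs", time.time() - t0)

    # ----------------------------------------------------- peak calling
    params = PeakParams(q=cfg.peak_q, min_above=cfg.peak_min_above,
                        window_probes=cfg.peak_window_probes,
                        max_gap=cfg.peak_max_gap)
    peaksets: dict[str, PeakSet] = {}
    peak_stats = {}
    for mark in tracks:
        ps = call_peaks(tracks[mark], means[mark]["control"], params)
        peaksets[mark] = ps
        n_in, frac, pct = peak_probe_fraction(ps, tracks[mark])
        peak_stats[mark] = {"n_peaks": len(ps), "probes_in_peaks": n_in,
                            "percent_of_probes": pct}
        ps.to_bed(outdir / f"peaks_{mark}.bed")
    bundle.update(peaks=peaksets, peak_stats=peak_stats)
    log.info("peak calling done at %.1fs", time.time() - t0)

    # ------------------------------------------------------- annotation
    probe_cats = categorize_probes(tracks["5hmC"], ann, scheme)
    bg_counts = category_counts(probe_cats)
    annot = {}
    for mark, ps in peaksets.items():
        members = pd.Index(sorted(ps.probe_ids))
        obs = category_counts(probe_cats.loc[members])
        chi2, p = distribution_chi2(obs, bg_counts)
        annot[mark] = {
            "peak_categories": categorize_peaks(ps, ann, scheme),
            "probe_category_counts": obs,
            "chi2": chi2, "chi2_p": p,
            "coverage_normalized":
                coverage_normalized_distribution(obs, bg_counts),
        }
        enh = enhancer_windows(ann)
        if len(enh):
            n_f, n_fp, frac = feature_overlap(ps, enh, tracks[mark])
            annot[mark]["enhancer_overlap"] = {
                "feature_probes": n_f, "in_peaks": n_fp, "fraction": frac}
        shores = cgi_shores(ann)
        if len(shores):
            try:
                n_f, n_fp, frac = feature_overlap(ps, shores, tracks[mark])
                annot[mark]["shore_overlap"] = {
                    "feature_probes": n_f, "in_peaks": n_fp, "fraction": frac}
            except ValueError:
                pass
    bundle["annotation"] = {"background_counts": bg_counts, "marks": annot}
    log.info("annotation done at %.1fs", time.time() - t0)

    # --------------------------------------------------------- profiles
    mean_expr = expr.loc[control].mean(axis=0)
    tiers = expression_tiers(mean_expr)
    profiles = tiered_meta_profiles(
        tracks["5hmC"], means["5hmC"]["control"], ann.genes, tiers,
        span=cfg.profile_span, window=cfg.profile_window,
        step=cfg.profile_step)
    short_genes = [g for g in ann.genes if 2000 <= g.length < 3000]
    body_profiles = {}
    if short_genes:
        body_profiles = gene_body_profile(
            tracks["5hmC"], means["5hmC"]["control"], short_genes, tiers)
    ppr = ppr_means(tracks["5hmC"], ann.genes)
    heat, row_order, _ = ppr_heatmap(ppr, clip=cfg.heatmap_clip)
    tss_enriched = tss_5hmc_enriched(ann.genes, peaksets["5hmC"],
                                     cfg.tss_enrich_halfwidth)
    bundle.update(tiers=tiers, tss_profiles=profiles,
                  body_profiles=body_profiles, ppr_matrix=ppr,
                  heatmap=heat, heatmap_order=row_order,
                  tss_5hmc_enriched=tss_enriched)
    log.info("profiles done at %.1fs", time.time() - t0)

    # ----------------------------------------------------- ChIP-seq scores
    chip_changes: dict[str, pd.Series] = {}
    chip_deltas_by_region: dict[str, pd.DataFrame] = {}
    if study is not None and study.libraries:
        for mark, libs in study.libraries.items():
            region_kind = "promoter_k4" if mark == "H3K4me2" else "gene_body"
            per_region = {}
            for kind in HISTONE_REGIONS:
                regions = _gene_regions_frame(ann, kind, scheme)
                scores = region_scores(libs, regions,
                                       pseudocount=cfg.chip_pseudocount)
                ctrl_cols = [c for c in scores.columns if c.startswith("control")]
                trt_cols = [c for c in scores.columns if c.startswith("treated")]
                per_region[kind] = (scores[trt_cols].mean(axis=1)
                                    - scores[ctrl_cols].mean(axis=1))
            chip_deltas_by_region[mark] = pd.DataFrame(per_region)
            headline = _gene_regions_frame(ann, region_kind, scheme)
            scores = region_scores(libs, headline,
                                   pseudocount=cfg.chip_pseudocount)
            ctrl_cols = [c for c in scores.columns if c.startswith("control")]
            trt_cols = [c for c in scores.columns if c.startswith("treated")]
            chip_changes[mark] = (scores[trt_cols].mean(axis=1)
                                  - scores[ctrl_cols].mean(axis=1))
        bundle["chip_region_deltas"] = chip_deltas_by_region
    log.info("chip-seq scoring done at %.1fs", time.time() - t0)

    # ------------------------------------------------------ differential
    expr_records = expression_change(expr, control, treated)
    d_ppr = {m: ppr_means(tracks[m], ann.genes,
                          scores=deltas[m]).iloc[:, 0] for m in tracks}
    change_table = build_change_table(
        expr_records, d_ppr["5hmC"], d_ppr["5mC"], chip_changes,
        threshold=cfg.induction_threshold)
    induced = select_induced(change_table, cfg.induction_threshold)
    unaffected = select_unaffected(change_table, n=max(len(induced), 3))
    correlations = {}
    mark_cols = ["d5hmC_ppr", "d5mC_ppr"] + \
        [f"d{m}" for m in chip_changes]
    if len(induced) >= 3:
        for col in mark_cols:
            correlations[col] = change_correlation(change_table, induced, col)
        genes_by_id = {g.gene_id: g for g in ann.genes}
        profiles_delta = {
            m: change_profile(tracks[m], deltas[m],
                              [genes_by_id[g] for g in induced])
            for m in tracks}
        bundle["change_profiles"] = profiles_delta

    dna_deltas = {m: track_region_deltas(tracks[m], deltas[m], ann,
                                         regions=DNA_REGIONS, scheme=scheme)
                  for m in tracks}
    all_deltas = combine_mark_deltas({**dna_deltas, **chip_deltas_by_region})
    family = None
    if len(induced) >= 3 and len(unaffected) >= 3:
        family = family_region_analysis(all_deltas, induced, unaffected,
                                        alpha=cfg.family_alpha)
    bundle.update(expression=expr_records, change_table=change_table,
                  induced=induced, unaffected=unaffected,
                  correlations=correlations, region_deltas=all_deltas,
                  family_analysis=family)
    log.info("differential analysis done at %.1fs", time.time() - t0)

    _write_outputs(bundle, outdir)
    _write_manifest(bundle, outdir, cfg)
    return bundle


def _gene_regions_frame(ann: GenomeAnnotation, kind: str,
                        scheme: CategoryScheme) -> pd.DataFrame:
    rows = []
    for g in ann.genes:
        chrom, s, e = gene_region_windows(g, scheme)[kind]
        rows.append((chrom, s, e, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])


def _write_outputs(bundle: dict, outdir: Path) -> None:
    bundle["change_table"].to_csv(outdir / "gene_changes.tsv", sep="\t")
    for tier, prof in bundle["tss_profiles"].items():
        prof.to_frame().to_csv(outdir / f"tss_profile_{tier}.tsv",
                               sep="\t", index=False)
    for tier, frame in bundle.get("body_profiles", {}).items():
        frame.to_csv(outdir / f"body_profile_{tier}.tsv", sep="\t",
                     index=False)
    bundle["heatmap"].to_csv(outdir / "ppr_heatmap.tsv", sep="\t")
    if bundle.get("family_analysis") is not None:
        bundle["family_analysis"].to_csv(outdir / "family_regions.tsv",
                                         sep="\t", index=False)
    counts = pd.DataFrame({
        "all_probes": bundle["annotation"]["background_counts"],
        **{f"{m}_peak_probes": a["probe_category_counts"]
           for m, a in bundle["annotation"]["marks"].items()},
    })
    counts.to_csv(outdir / "category_counts.tsv", sep="\t")


def _write_manifest(bundle: dict, outdir: Path, cfg: PipelineConfig) -> None:
    digests = {}
    for name in ("hmc_tsv", "mc_tsv", "expr_tsv", "gff"):
        path = getattr(cfg, name)
        if path and Path(path).exists():
            digests[name] = hashlib.sha256(
                Path(path).read_bytes()).hexdigest()
    manifest = {
        "hydroxyscan_version": __version__,
        "numpy": np.__version__, "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "config": cfg.to_dict(),
        "input_digests": digests,
        "peak_stats": bundle["peak_stats"],
        "n_induced": len(bundle["induced"]),
        "correlations": {k: {"r": v[0], "p": v[1]}
                         for k, v in bundle["correlations"].items()},
        "metadata": {
            "peak_exceedance": "strict >",
            "quantile_convention": "linear interpolation",
            "probe_window_membership": "midpoint",
            "unaffected_rule": "|lfc| < 0.1 and p > 0.5, smallest |lfc| first",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
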