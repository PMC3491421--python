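"""Treatment-induced changes per gene and region.

Expression changes (Welch t), selection of induced genes (> log2 1.5
fold), correlation of per-gene mark changes with expression change over
the induced set, TSS-centred change profiles, and the gene-family region
analysis with two-sided Wilcoxon rank-sum tests against unaffected genes
at p < 0.005.  Sign conventions throughout: change = treated - control,
positive = gain upon treatment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Gene, GenomeAnnotation, offset_window_to_genomic
from .genomic import CategoryScheme
from .profiles import MetaProfile, meta_profile, tss_anchors
from .track import ProbeTrack

log = logging.getLogger(__name__)

INDUCTION_THRESHOLD = 1.5  # log2; selection is strict >
DNA_REGIONS = ("upstream", "promoter", "exon", "intron", "downstream")
HISTONE_REGIONS = ("upstream", "promoter", "gene_body", "downstream")


def expression_change(expr: pd.DataFrame, control: list[str],
                      treated: list[str]) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch two-sample t p-value.

    ``expr`` is a samples x genes matrix of log2 expression values; lfc
    is mean(treated) - mean(control).
    """
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need >= 2 samples per group")
    c = expr.loc[control].to_numpy(dtype=float)
    t = expr.loc[treated].to_numpy(dtype=float)
    lfc = t.mean(axis=0) - c.mean(axis=0)
    _, p = stats.ttest_ind(t, c, axis=0, equal_var=False)
    return pd.DataFrame({"lfc": lfc, "p_value": p}, index=expr.columns)


def select_induced(records: pd.DataFrame,
                   threshold: float = INDUCTION_THRESHOLD) -> list[str]:
    """Genes with expression lfc strictly above ``threshold`` (stable order)."""
    return list(records.index[records["lfc"] > threshold])


def select_unaffected(records: pd.DataFrame, n: int, band: float = 0.1,
                      p_min: float = 0.5) -> list[str]:
    """The n genes most clearly unaffected by treatment.

    Candidates have |lfc| < band and p > p_min; among them the n smallest
    |lfc| are taken (stable order), so the set is deterministic.
    """
    cand = records[(records["lfc"].abs() < band) & (records["p_value"] > p_min)]
    if len(cand) < n:
        log.warning("only %d unaffected candidates for requested %d",
                    len(cand), n)
    order = cand["lfc"].abs().sort_values(kind="stable")
    return list(order.index[:n])


def change_correlation(records: pd.DataFrame, subset: list[str],
                       mark_column: str) -> tuple[float, float]:
    """Pearson correlation of a mark's change with expression lfc."""
    if len(subset) < 3:
        raise ValueError("need >= 3 genes for a correlation")
    sub = records.loc[subset]
    ok = sub[[mark_column, "lfc"]].dropna()
    r, p = stats.pearsonr(ok[mark_column], ok["lfc"])
    return float(r), float(p)


def change_profile(track: ProbeTrack, delta: pd.Series, genes: list[Gene],
                   span: int = 3000, window: int = 200,
                   step: int = 50) -> MetaProfile:
    """TSS-centred sliding-window profile of a per-probe change vector."""
    if not genes:
        raise ValueError("empty gene subset")
    return meta_profile(track, delta, tss_anchors(genes), span=span,
                        window=window, step=step)


# --------------------------------------------------------------------------
# per-gene region changes
# --------------------------------------------------------------------------

def gene_region_windows(gene: Gene, scheme: CategoryScheme = CategoryScheme()
                        ) -> dict[str, tuple[str, int, int]]:
    """Genomic windows of the per-gene analysis regions (strand-aware)."""
    tss, strand = gene.tss, gene.strand
    length = gene.length
    wins = {
        "upstream": offset_window_to_genomic(tss, strand, *scheme.upstream),
        "promoter": offset_window_to_genomic(tss, strand, *scheme.promoter),
        "gene_body": (gene.start, gene.end),
        "downstream": offset_window_to_genomic(
            tss, strand, length, length + scheme.downstream_extent),
        "promoter_k4": offset_window_to_genomic(tss, strand, -1000, 2000),
        "ppr": offset_window_to_genomic(tss, strand, -1000, 1000),
    }
    return {k: (gene.chrom, max(0, s), e) for k, (s, e) in wins.items()}


def track_region_deltas(track: ProbeTrack, delta: pd.Series | np.ndarray,
                        ann: GenomeAnnotation,
                        regions: tuple[str, ...] = DNA_REGIONS,
                        scheme: CategoryScheme = CategoryScheme()) -> pd.DataFrame:
    """Mean per-probe change per gene and region for a probe track.

    Probe membership is by midpoint; the exon/intron regions split the
    gene body by the probe midpoint falling in an exon interval.
    """
    delta_arr = np.asarray(delta, dtype=float)
    mid = track.midpoints
    chrom_arr = track.probes["chrom"].to_numpy()
    out = {}
    for g in ann.genes:
        wins = gene_region_windows(g, scheme)
        on_chrom = chrom_arr == g.chrom
        row = {}
        for region in regions:
            if region in ("exon", "intron"):
                m = on_chrom & (mid >= g.start) & (mid < g.end)
                in_exon = np.zeros(len(mid), dtype=bool)
                for s, e in g.exons:
                    in_exon |= on_chrom & (mid >= s) & (mid < e)
                m = m & in_exon if region == "exon" else m & ~in_exon
            else:
                _, s, e = wins[region]
                m = on_chrom & (mid >= s) & (mid < e)
            vals = delta_arr[m]
            vals = vals[np.isfinite(vals)]
            row[region] = float(vals.mean()) if vals.size else np.nan
        out[g.gene_id] = row
    return pd.DataFrame.from_dict(out, orient="index")[list(regions)]


def combine_mark_deltas(per_mark: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-mark region-delta frames into MultiIndex (mark, region)."""
    frames = {mark: df for mark, df in per_mark.items()}
    return pd.concat(frames, axis=1)


def family_region_analysis(deltas: pd.DataFrame, family: list[str],
                           unaffected: list[str],
                           alpha: float = 0.005) -> pd.DataFrame:
    """Average change per region and mark for a gene family.

    ``deltas`` has genes as rows and MultiIndex (mark, region) columns of
    treated-minus-control changes.  For every cell: the family mean and
    standard error, a two-sided Wilcoxon rank-sum test against the
    unaffected genes' changes, a significance flag at p < ``alpha`` and
    the fold enrichment |family mean| / |unaffected mean| (NaN-guarded).
    Raw p-values are reported; no multiplicity correction is applied.
    """
    if len(family) < 3 or len(unaffected) < 3:
        raise ValueError("need >= 3 genes in both sets")
    rows = []
    for mark, region in deltas.columns:
        fam = deltas.loc[family, (mark, region)].dropna().to_numpy()
        ref = deltas.loc[unaffected, (mark, region)].dropna().to_numpy()
        if fam.size < 3 or ref.size < 3:
            continue
        stat, p = stats.ranksums(fam, ref)
        ref_abs = np.abs(ref).mean()
        rows.append({
            "mark": mark, "region": region,
            "mean_change": float(fam.mean()),
            "se": float(fam.std(ddof=1) / np.sqrt(fam.size)),
            "p_value": float(p),
            "significant": bool(p < alpha),
            "fold_enrichment": float(np.abs(fam.mean()) / ref_abs)
            if ref_abs > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def study_change_correlations(study, pseudocount: float = 1.0) -> dict:
    """Per-mark (Pearson r, p) of change vs expression lfc at induced genes.

    Runs the analysis path on one study: between-array scale
    normalization, group-mean deltas, PPR deltas for the DNA marks,
    region-score changes for the histone marks (H3K4me2 over TSS -1/+2
    kb, the others over the gene body), induced-gene selection from the
    expression matrix, then the five correlations.  Within-array loess is
    deliberately omitted here: the planted intensity trend is shared by
    both groups and cancels in treated - control.
    """
    from .chipseq import region_scores
    from .norm import delta_track, group_mean, scale_normalize
    from .profiles import ppr_means

    control = [s for s, g in study.hmc.groups.items() if g == "control"]
    treated = [s for s, g in study.hmc.groups.items() if g == "treated"]
    records = expression_change(study.expression, control, treated)
    induced = select_induced(records)
    if len(induced) < 3:
        raise ValueError("fewer than 3 induced genes detected")
    genes = [g for g in study.ann.genes if g.gene_id in set(induced)]

    out: dict[str, tuple[float, float]] = {}
    for mark, track in (("5hmC", study.hmc), ("5mC", study.mc)):
        norm = scale_normalize(track)
        delta = delta_track(group_mean(norm, "control"),
                            group_mean(norm, "treated"))
        d_ppr = ppr_means(norm, genes, scores=delta).iloc[:, 0]
        table = records.loc[induced].copy()
        table["d"] = d_ppr
        out[mark] = change_correlation(table, induced, "d")

    for mark, libs in study.libraries.items():
        rows = []
        for g in genes:
            key = "promoter_k4" if mark == "H3K4me2" else "gene_body"
            chrom, s, e = gene_region_windows(g)[key]
            rows.append((chrom, s, e, g.gene_id))
        regions = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                              "region_id"])
        scores = region_scores(libs, regions, pseudocount=pseudocount)
        ctrl = [c for c in scores.columns if c.startswith("control")]
        trt = [c for c in scores.columns if c.startswith("treated")]
        change = scores[trt].mean(axis=1) - scores[ctrl].mean(axis=1)
        table = records.loc[induced].copy()
        table["d"] = change
        out[mark] = change_correlation(table, induced, "d")
    return out


def build_change_table(
    expr_records: pd.DataFrame,
    d_hmc_ppr: pd.Series,
    d_mc_ppr: pd.Series,
    chip_changes: dict[str, pd.Series] | None = None,
    threshold: float = INDUCTION_THRESHOLD,
) -> pd.DataFrame:
    """Assemble the per-gene change record table.

    Columns: expression lfc and p, d5hmC/d5mC over the PPR, per-histone
    changes (H3K4me2 over TSS -1/+2 kb, H3K27me3 and H3K36me3 over the
    gene body), and a status of induced / unaffected / other.
    """
    table = expr_records.copy()
    table["d5hmC_ppr"] = d_hmc_ppr
    table["d5mC_ppr"] = d_mc_ppr
    for mark, series in (chip_changes or {}).items():
        table[f"d{mark}"] = series
    induced = set(select_induced(table, threshold))
    unaffected = set(select_unaffected(table, n=len(induced) or 30))
    table["status"] = [
        "induced" if g in induced else
        "unaffected" if g in unaffected else "other"
        for g in table.index]
    return table
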