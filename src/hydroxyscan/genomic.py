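"""Genic category assignment and distribution statistics for peaks.

Probes and peaks are assigned uniquely (by interval midpoint) to one of
six non-overlapping genic categories relative to the nearest TSS:
promoter (-1 kb..+250 bp, strand-aware), exon, intron, downstream
(1 kb past the gene end), upstream (-7.25 kb..-1 kb) and intergenic.
Distributions are compared to the all-probe background by Pearson
chi-square and can be coverage-normalized; peak overlap with CpG
islands, shores and enhancers is probe-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Gene, GenomeAnnotation, genomic_to_offset
from .peaks import PeakSet
from .track import ProbeTrack

log = logging.getLogger(__name__)

CATEGORIES = ("promoter", "exon", "intron", "downstream", "upstream", "intergenic")


@dataclass(frozen=True)
class CategoryScheme:
    """Strand-aware offset windows for the six genic categories.

    Precedence for unique assignment: promoter > exon > intron >
    downstream > upstream > intergenic (the catch-all).
    """

    promoter: tuple[int, int] = (-1000, 250)
    upstream: tuple[int, int] = (-7250, -1000)
    downstream_extent: int = 1000


def _gene_category(gene: Gene, pos: int, scheme: CategoryScheme) -> str | None:
    """Category of genomic position ``pos`` relative to one gene, or None."""
    off = genomic_to_offset(gene.tss, gene.strand, pos)
    if scheme.promoter[0] <= off < scheme.promoter[1]:
        return "promoter"
    if 0 <= off < gene.length:
        in_exon = any(s <= pos < e for s, e in gene.exons)
        return "exon" if in_exon else "intron"
    if gene.length <= off < gene.length + scheme.downstream_extent:
        return "downstream"
    if scheme.upstream[0] <= off < scheme.upstream[1]:
        return "upstream"
    return None


_PRECEDENCE = {c: i for i, c in enumerate(
    ("promoter", "exon", "intron", "downstream", "upstream"))}


def assign_category(interval: tuple[str, int, int], ann: GenomeAnnotation,
                    scheme: CategoryScheme = CategoryScheme(),
                    _by_chrom: dict | None = None) -> tuple[str, str | None]:
    """Assign an interval to one category by its midpoint.

    Returns ``(category, gene_id)``; the gene context is the gene with
    the nearest TSS among those whose windows contain the midpoint.
    Positions claimed by no gene are intergenic.
    """
    chrom, start, end = interval
    if chrom not in ann.chromosomes:
        raise ValueError(f"unknown chromosome {chrom}")
    mid = (start + end) // 2
    genes = (_by_chrom or ann.genes_by_chrom()).get(chrom, [])
    best: tuple[int, int, str, str] | None = None
    for g in genes:
        # windows reach at most 7.25 kb upstream / length+1 kb downstream
        if mid < g.start - 10_000 or mid > g.end + 10_000:
            continue
        cat = _gene_category(g, mid, scheme)
        if cat is None:
            continue
        key = (_PRECEDENCE[cat], abs(mid - g.tss))
        if best is None or key < (best[0], best[1]):
            best = (*key, cat, g.gene_id)
    if best is None:
        return "intergenic", None
    return best[2], best[3]


def categorize_probes(track: ProbeTrack, ann: GenomeAnnotation,
                      scheme: CategoryScheme = CategoryScheme()) -> pd.Series:
    """Category per probe, midpoint-based, indexed by probe_id."""
    by_chrom = ann.genes_by_chrom()
    cats = [
        assign_category((row.chrom, row.start, row.end), ann, scheme,
                        _by_chrom=by_chrom)[0]
        for row in track.probes.itertuples()
    ]
    return pd.Series(cats, index=track.probes["probe_id"], name="category")


def categorize_peaks(peakset: PeakSet, ann: GenomeAnnotation,
                     scheme: CategoryScheme = CategoryScheme()) -> pd.DataFrame:
    by_chrom = ann.genes_by_chrom()
    rows = []
    for row in peakset.peaks.itertuples():
        cat, gid = assign_category((row.chrom, row.start, row.end), ann,
                                   scheme, _by_chrom=by_chrom)
        rows.append((row.peak_id, cat, gid))
    return pd.DataFrame(rows, columns=["peak_id", "category", "gene_id"])


def category_counts(categories: pd.Series) -> pd.Series:
    """Counts per category over all six labels (zero-filled)."""
    return categories.value_counts().reindex(CATEGORIES, fill_value=0)


def distribution_chi2(observed: pd.Series, background: pd.Series) -> tuple[float, float]:
    """Pearson chi-square of peak-probe category counts vs the all-probe
    distribution (expected proportions from ``background``), df = cells-1.

    Categories with a zero expected count are collapsed into their
    neighbours (pooled into a rest cell) with a logged warning.
    """
    obs = observed.reindex(CATEGORIES, fill_value=0).astype(float)
    bg = background.reindex(CATEGORIES, fill_value=0).astype(float)
    keep = bg > 0
    if not keep.all():
        dropped = list(bg.index[~keep])
        log.warning("collapsing zero-expected categories: %s", dropped)
        obs = obs[keep]
        bg = bg[keep]
    expected = bg / bg.sum() * obs.sum()
    stat, p = stats.chisquare(obs.to_numpy(), expected.to_numpy())
    return float(stat), float(p)


def coverage_normalized_distribution(peak_counts: pd.Series,
                                     probe_counts: pd.Series) -> pd.Series:
    """Peak distribution divided by probe coverage, rescaled to sum to 1."""
    pk = peak_counts.reindex(CATEGORIES, fill_value=0).astype(float)
    pr = probe_counts.reindex(CATEGORIES, fill_value=0).astype(float)
    reported = pr > 0
    if (pk[~reported] > 0).any():
        raise ValueError("peaks in a category with zero probe coverage")
    ratio = pk[reported] / pr[reported]
    total = ratio.sum()
    if total == 0:
        return ratio
    return ratio / total


def feature_overlap(peakset: PeakSet, features: pd.DataFrame,
                    track: ProbeTrack) -> tuple[int, int, float]:
    """Overlap of a feature set with peaks, counted in probes.

    A probe is a feature probe if its interval intersects any feature.
    Returns (feature probes, feature probes inside peaks, fraction).
    """
    if len(features) == 0:
        raise ValueError("empty feature set")
    probes = track.probes
    in_feature = np.zeros(len(probes), dtype=bool)
    for chrom, sub in features.groupby("chrom"):
        sel = probes["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        ps = probes.loc[sel, "start"].to_numpy()
        pe = probes.loc[sel, "end"].to_numpy()
        fs = np.sort(sub["start"].to_numpy())
        fe = np.sort(sub["end"].to_numpy())
        n_start_before = np.searchsorted(fs, pe, side="left")
        n_end_before = np.searchsorted(fe, ps, side="right")
        in_feature[sel] = (n_start_before - n_end_before) > 0
    n_feature = int(in_feature.sum())
    if n_feature == 0:
        raise ValueError("features cover no probes")
    feature_ids = set(probes.loc[in_feature, "probe_id"])
    n_in_peaks = len(feature_ids & peakset.probe_ids)
    return n_feature, n_in_peaks, n_in_peaks / n_feature


def cgi_shores(ann: GenomeAnnotation, width: int = 1000) -> pd.DataFrame:
    """Regions 1 kb upstream (lower-coordinate side) of annotated CGIs."""
    rows = [(c, max(0, s - width), s) for c, s, e in ann.cgis if s > 0]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def enhancer_windows(ann: GenomeAnnotation, width: int = 1000) -> pd.DataFrame:
    """Enhancer midpoints expanded to fixed 1 kb stretches."""
    rows = []
    for c, s, e in ann.enhancers:
        mid = (s + e) // 2
        rows.append((c, max(0, mid - width // 2), mid + width // 2))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def region_level_compare(track: ProbeTrack, scores: np.ndarray | pd.Series,
                         regions_a: pd.DataFrame,
                         regions_b: pd.DataFrame) -> dict:
    """Mean probe score per region for two region sets + rank-sum p.

    Regions are 1 kb-scale intervals (chrom/start/end); probe membership
    is by midpoint.  Returns means per set and the two-sided Wilcoxon
    rank-sum p-value between the two sets of region means.
    """
    means_a = region_means(track, scores, regions_a)
    means_b = region_means(track, scores, regions_b)
    if len(means_a) < 2 or len(means_b) < 2:
        raise ValueError("need >= 2 scored regions per set")
    stat, p = stats.ranksums(means_a, means_b)
    return {"means_a": means_a, "means_b": means_b,
            "statistic": float(stat), "p_value": float(p)}


def region_means(track: ProbeTrack, scores: np.ndarray | pd.Series,
                 regions: pd.DataFrame) -> np.ndarray:
    """Mean probe score (midpoint membership) per region; NaN-free result."""
    score_arr = np.asarray(scores, dtype=float)
    mid = track.midpoints
    chrom_arr = track.probes["chrom"].to_numpy()
    out = []
    for row in regions.itertuples():
        m = (chrom_arr == row.chrom) & (mid >= row.start) & (mid < row.end)
        vals = score_arr[m]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out.append(float(vals.mean()))
    return np.asarray(out)


def cgi_classes(ann: GenomeAnnotation,
                scheme: CategoryScheme = CategoryScheme()) -> pd.Series:
    """Classify CGIs as promoter-associated, intra-genic or inter-genic."""
    from .annotation import offset_window_to_genomic

    labels = []
    by_chrom = ann.genes_by_chrom()
    for chrom, s, e in ann.cgis:
        promoter = False
        for g in by_chrom.get(chrom, []):
            ps, pe = offset_window_to_genomic(g.tss, g.strand, *scheme.promoter)
            if ps < e and s < pe:
                promoter = True
                break
        if promoter:
            labels.append("promoter")
            continue
        mid = (s + e) // 2
        intra = any(g.start <= mid < g.end for g in by_chrom.get(chrom, []))
        labels.append("intragenic" if intra else "intergenic")
    return pd.Series(labels, name="cgi_class")
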