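"""Sliding-window meta-profiles, expression tiers and PPR heat maps.

Profiles average probe scores in 200 bp windows stepped every 50 bp in
TSS-relative, strand-aware coordinates; probes belong to a window by
their midpoint.  Expression tiers follow the quartile rule (low = bottom
25%, high = top 25%, medium = the rest).  PPR heat maps are per-animal
mean scores over TSS +/-1 kb, clipped to +/-2.5, row-ordered by
agglomerative clustering with Euclidean distance and Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .annotation import Gene, genomic_to_offset, offset_window_to_genomic
from .track import ProbeTrack

log = logging.getLogger(__name__)


def expression_tiers(expr: pd.Series) -> pd.Series:
    """Quartile expression tiers: low / medium / high.

    Bottom quartile is low, top quartile high, the rest medium; ties are
    broken by stable gene order so the tier sizes are always n//4,
    n - 2*(n//4), n//4.
    """
    if len(expr) < 4:
        raise ValueError("need >= 4 genes to form tiers")
    order = np.argsort(expr.to_numpy(), kind="stable")
    q = len(expr) // 4
    tiers = np.full(len(expr), "medium", dtype=object)
    tiers[order[:q]] = "low"
    tiers[order[len(expr) - q:]] = "high"
    return pd.Series(tiers, index=expr.index, name="tier")


@dataclass
class MetaProfile:
    """Mean score per TSS-relative offset, with contributing-gene counts."""

    offsets: np.ndarray
    mean: np.ndarray
    n: np.ndarray
    window: int
    step: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "n": self.n})


def profile_offsets(span: int, window: int, step: int) -> np.ndarray:
    """Window-centre offsets for windows fully inside +/-span.

    Count is (2*span - window) / step + 1.
    """
    if span % step:
        raise ValueError("span must be a multiple of step")
    first = -(span - window // 2)
    n = (2 * span - window) // step + 1
    return first + step * np.arange(n)


def meta_profile(track: ProbeTrack, scores: np.ndarray | pd.Series,
                 anchors: list[tuple[str, int, str]],
                 span: int = 1500, window: int = 200,
                 step: int = 50) -> MetaProfile:
    """Average profile around TSS anchors ``(chrom, tss, strand)``.

    Per anchor and offset, the mean of probe scores whose midpoint lies
    in [offset - window/2, offset + window/2) in strand-flipped
    TSS-relative coordinates; offsets are then averaged across anchors
    (each contributing anchor with equal weight).
    """
    offs = profile_offsets(span, window, step)
    score_arr = np.asarray(scores, dtype=float)
    mid = track.midpoints
    chrom_arr = track.probes["chrom"].to_numpy()
    half = window // 2

    total = np.zeros(len(offs))
    count = np.zeros(len(offs), dtype=int)
    any_probes = False
    for chrom, tss, strand in anchors:
        m = (chrom_arr == chrom) & (mid >= tss - span - window) & \
            (mid <= tss + span + window)
        if not m.any():
            continue
        rel = genomic_to_offset(tss, strand, mid[m]).astype(float)
        vals = score_arr[m]
        ok = np.isfinite(vals)
        rel, vals = rel[ok], vals[ok]
        if rel.size == 0:
            continue
        any_probes = True
        inside = (rel[None, :] >= offs[:, None] - half) & \
                 (rel[None, :] < offs[:, None] + half)
        with np.errstate(invalid="ignore"):
            sums = inside @ vals
            ns = inside.sum(axis=1)
        has = ns > 0
        total[has] += sums[has] / ns[has]
        count[has] += 1
    if not any_probes:
        raise ValueError("no probes near any anchor")
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetaProfile(offsets=offs, mean=mean, n=count,
                       window=window, step=step)


def tss_anchors(genes: list[Gene]) -> list[tuple[str, int, str]]:
    return [(g.chrom, g.tss, g.strand) for g in genes]


def tiered_meta_profiles(track: ProbeTrack, scores, genes: list[Gene],
                         tiers: pd.Series, span: int = 1500,
                         window: int = 200, step: int = 50) -> dict[str, MetaProfile]:
    """One TSS meta-profile per expression tier."""
    out = {}
    for tier in ("low", "medium", "high"):
        sub = [g for g in genes if tiers.get(g.gene_id) == tier]
        if not sub:
            log.info("tier %s empty, omitted", tier)
            continue
        out[tier] = meta_profile(track, scores, tss_anchors(sub),
                                 span=span, window=window, step=step)
    return out


def gene_body_profile(track: ProbeTrack, scores, genes: list[Gene],
                      tiers: pd.Series, flank: int = 500,
                      window: int = 200, step: int = 50) -> dict[str, pd.DataFrame]:
    """Per-tier profile over gene bodies in absolute bp from the TSS.

    Designed for short (2-3 kb) genes fully covered by the array; offsets
    run from -flank to the longest gene's end + flank with no length
    scaling.  Empty tiers are omitted with a log notice.
    """
    if not genes:
        raise ValueError("no genes given")
    score_arr = np.asarray(scores, dtype=float)
    mid = track.midpoints
    chrom_arr = track.probes["chrom"].to_numpy()
    half = window // 2
    max_len = max(g.length for g in genes)
    offs = np.arange(-flank + half, max_len + flank - half + 1, step)

    out: dict[str, pd.DataFrame] = {}
    for tier in ("low", "medium", "high"):
        sub = [g for g in genes if tiers.get(g.gene_id) == tier]
        if not sub:
            log.info("gene_body_profile: tier %s empty, omitted", tier)
            continue
        total = np.zeros(len(offs))
        count = np.zeros(len(offs), dtype=int)
        for g in sub:
            m = (chrom_arr == g.chrom)
            rel = genomic_to_offset(g.tss, g.strand, mid[m]).astype(float)
            vals = score_arr[m]
            ok = np.isfinite(vals) & (rel >= -flank - window) & \
                (rel <= g.length + flank + window)
            rel, vals = rel[ok], vals[ok]
            if rel.size == 0:
                continue
            valid_offs = offs <= g.length + flank - half
            inside = (rel[None, :] >= offs[:, None] - half) & \
                     (rel[None, :] < offs[:, None] + half)
            sums = inside @ vals
            ns = inside.sum(axis=1)
            has = (ns > 0) & valid_offs
            total[has] += sums[has] / ns[has]
            count[has] += 1
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        out[tier] = pd.DataFrame({"offset": offs, "mean": mean, "n": count})
    return out


# --------------------------------------------------------------------------
# PPR scoring and heat map
# --------------------------------------------------------------------------

def ppr_means(track: ProbeTrack, genes: list[Gene], half_width: int = 1000,
              scores: pd.DataFrame | pd.Series | None = None) -> pd.DataFrame:
    """Mean probe score over each gene's PPR (TSS +/-1 kb), per sample.

    ``scores`` defaults to the track's full score matrix; a Series gives
    a single-column result.  Probe membership is by midpoint.  Genes with
    no probes in their PPR get NaN.
    """
    if scores is None:
        scores = track.scores
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    mat = scores.to_numpy(dtype=float)
    mid = track.midpoints
    chrom_arr = track.probes["chrom"].to_numpy()
    rows = []
    for g in genes:
        s, e = offset_window_to_genomic(g.tss, g.strand, -half_width,
                                        half_width)
        m = (chrom_arr == g.chrom) & (mid >= s) & (mid < e)
        if m.any():
            with np.errstate(invalid="ignore"):
                rows.append(np.nanmean(mat[m], axis=0))
        else:
            rows.append(np.full(mat.shape[1], np.nan))
    return pd.DataFrame(rows, index=[g.gene_id for g in genes],
                        columns=list(scores.columns))


def deterministic_leaf_order(z: np.ndarray, n: int) -> list[int]:
    """Leaf order for a linkage matrix with a fixed tie-break.

    At every merge the two children are laid out ordered by
    (cluster size, smallest original member index), which makes the row
    order reproducible across runs and platforms.
    """
    order: dict[int, list[int]] = {i: [i] for i in range(n)}
    for j, row in enumerate(z):
        a, b = int(row[0]), int(row[1])
        ka = (len(order[a]), min(order[a]))
        kb = (len(order[b]), min(order[b]))
        first, second = (a, b) if ka <= kb else (b, a)
        order[n + j] = order[first] + order[second]
        del order[a], order[b]
    return order[n + len(z) - 1]


def ppr_heatmap(matrix: pd.DataFrame, clip: float = 2.5
                ) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Clip a PPR x animal matrix to +/-clip and Ward-cluster the rows.

    Returns (reordered clipped matrix, row order, linkage matrix).  Rows
    with any missing value are dropped before clustering.
    """
    mat = matrix.dropna(axis=0, how="any").clip(-clip, clip)
    if len(mat) < 2:
        raise ValueError("need >= 2 PPRs to cluster")
    z = linkage(mat.to_numpy(), method="ward", metric="euclidean")
    leaves = deterministic_leaf_order(z, len(mat))
    ordered = mat.iloc[leaves]
    return ordered, list(ordered.index), z
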