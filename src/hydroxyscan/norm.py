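"""Within- and between-array normalization of probe log2(IP/input) scores.

Within-array saturation effects are removed by loess of score on mean
log-intensity (tricube weights, locally linear, robustness iterations);
between-array spread is equalized by scale normalization, dividing each
sample by its median absolute deviation and restoring the geometric mean
of all samples' MADs.  The 5hmC and 5mC tracks are always normalized
separately.  Missing values propagate; they are never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .track import ProbeTrack

log = logging.getLogger(__name__)


def loess_normalize(track: ProbeTrack, span: float = 0.3,
                    iterations: int = 3) -> ProbeTrack:
    """Subtract a loess fit of score on intensity, per sample.

    ``span`` is the loess smoothing fraction in (0, 1].  Requires an
    intensity matrix and at least 50 probes.  A constant intensity column
    falls back to subtracting the column median (logged).
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(track.probes) < 50:
        raise ValueError("loess normalization needs >= 50 probes")
    if track.intensity is None:
        raise ValueError("track has no intensity matrix")
    out = track.scores.copy()
    for sample in track.samples:
        y = track.scores[sample].to_numpy(dtype=float)
        x = track.intensity[sample].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(x)
        if np.ptp(x[ok]) == 0:
            log.warning("constant intensity for %s: subtracting median", sample)
            out[sample] = y - np.nanmedian(y[ok])
            continue
        fit = lowess(y[ok], x[ok], frac=span, it=iterations,
                     delta=0.01 * np.ptp(x[ok]), return_sorted=False)
        resid = y.copy()
        resid[ok] = y[ok] - fit
        out[sample] = resid
    new = track.copy_with_scores(out)
    new.meta["loess_span"] = span
    return new


def _mad(values: np.ndarray) -> float:
    v = values[np.isfinite(values)]
    return float(np.median(np.abs(v - np.median(v))))


def scale_normalize(track: ProbeTrack) -> ProbeTrack:
    """Equalize per-sample MADs to their geometric mean.

    After scaling every sample column has the same median absolute
    deviation, so between-array spread differences are removed while
    within-array ranking is untouched.  Idempotent to rounding error.
    """
    if len(track.samples) < 2:
        raise ValueError("scale normalization needs >= 2 samples")
    mads = {}
    for sample in track.samples:
        m = _mad(track.scores[sample].to_numpy(dtype=float))
        if m == 0:
            raise ValueError(f"zero MAD in sample {sample!r}")
        mads[sample] = m
    target = float(np.exp(np.mean(np.log(list(mads.values())))))
    out = track.scores.copy()
    for sample in track.samples:
        out[sample] = track.scores[sample] * (target / mads[sample])
    new = track.copy_with_scores(out)
    new.meta["scale_target_mad"] = target
    return new


def group_mean(track: ProbeTrack, group: str) -> pd.Series:
    """Arithmetic per-probe mean over one group's samples (NaN-excluded)."""
    samples = track.group_samples(group)
    sub = track.scores[samples]
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        log.info("group_mean %s: %d missing values excluded pairwise",
                 group, n_missing)
    mean = sub.mean(axis=1, skipna=True)
    mean.name = f"mean_{group}"
    return mean


def delta_track(control_mean: pd.Series, treated_mean: pd.Series) -> pd.Series:
    """Per-probe change, treated - control (positive = gain on treatment)."""
    if not control_mean.index.equals(treated_mean.index):
        bad = control_mean.index.symmetric_difference(treated_mean.index)
        raise ValueError(f"probe sets differ: {list(bad[:10])}")
    delta = treated_mean - control_mean
    delta.name = "delta"
    return delta


def normalize_track(track: ProbeTrack, order: tuple[str, ...] = ("loess", "scale"),
                    span: float = 0.3) -> ProbeTrack:
    """Apply the configured normalization steps, within-array first."""
    for step in order:
        if step == "loess":
            track = loess_normalize(track, span=span)
        elif step == "scale":
            track = scale_normalize(track)
        else:
            raise ValueError(f"unknown normalization step {step!r}")
    track.meta["normalization_order"] = list(order)
    return track
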