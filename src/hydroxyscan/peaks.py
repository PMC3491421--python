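"""Probe-window percentile peak calling.

A peak is a merged run of five-probe windows in which at least four
probes strictly exceed the 90th-percentile score of the whole track.
Windows never span tiled-region boundaries or start-to-start gaps larger
than ``max_gap``; overlapping or adjacent qualifying windows merge into a
single peak spanning the first probe start to the last probe end, and the
peak's member probes are all probes inside that span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .track import ProbeTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakParams:
    q: float = 90.0          # percentile of the whole score vector
    min_above: int = 4       # probes above threshold required per window
    window_probes: int = 5   # probes per sliding window
    max_gap: int = 500       # bp, start-to-start, within a window run

    def __post_init__(self) -> None:
        if not 0 < self.q < 100:
            raise ValueError("q must be in (0, 100)")
        if self.min_above > self.window_probes:
            raise ValueError("min_above exceeds window")
        if self.window_probes < 1 or self.min_above < 1:
            raise ValueError("window_probes and min_above must be >= 1")


@dataclass
class PeakSet:
    """Merged peaks with member probes, threshold and calling parameters."""

    peaks: pd.DataFrame  # chrom, start, end, peak_id, n_probes, max/mean score
    member_probes: list[list[str]]
    threshold: float
    params: PeakParams
    meta: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> set[str]:
        return {p for members in self.member_probes for p in members}

    def __len__(self) -> int:
        return len(self.peaks)

    def to_bed(self, path: str | Path) -> None:
        out = self.peaks[["chrom", "start", "end", "peak_id"]].copy()
        out["score"] = self.peaks["mean_score"].round(4)
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)


def percentile_threshold(scores: np.ndarray | pd.Series, q: float = 90.0) -> float:
    """Empirical quantile (linear interpolation), missing values excluded."""
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite scores to take a percentile of")
    return float(np.percentile(arr, q))


def call_peaks(track: ProbeTrack, scores: np.ndarray | pd.Series,
               params: PeakParams = PeakParams(),
               threshold: float | None = None) -> PeakSet:
    """Call peaks on a per-probe score vector aligned with ``track``.

    ``scores`` is typically a group-mean vector; the threshold defaults to
    the ``params.q`` percentile of that vector.  Exceedance is strict
    (ties at the threshold do not count).  Missing scores never exceed.
    """
    score_arr = np.asarray(scores, dtype=float)
    if len(score_arr) != len(track.probes):
        raise ValueError("score vector length does not match track")
    if threshold is None:
        threshold = percentile_threshold(score_arr, params.q)
    above = np.where(np.isfinite(score_arr), score_arr > threshold, False)

    probes = track.probes
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    pids = probes["probe_id"].to_numpy()

    w, k = params.window_probes, params.min_above
    peak_rows = []
    members: list[list[str]] = []
    skipped = 0
    for run in _window_runs(probes, params.max_gap):
        if len(run) < w:
            skipped += 1
            continue
        run_above = above[run]
        # count of above-threshold probes per w-window via cumulative sum
        cs = np.concatenate([[0], np.cumsum(run_above)])
        counts = cs[w:] - cs[:-w]
        qual = np.flatnonzero(counts >= k)
        if qual.size == 0:
            continue
        # merge overlapping/adjacent qualifying windows: window j covers
        # run indices [j, j+w); windows merge when spans touch or overlap
        merge_start = qual[0]
        prev = qual[0]
        spans = []
        for j in qual[1:]:
            if j <= prev + w:  # overlap or adjacency in probe index space
                prev = j
            else:
                spans.append((merge_start, prev + w))
                merge_start = prev = j
        spans.append((merge_start, prev + w))
        for a, b in spans:
            idx = run[a:b]
            peak_scores = score_arr[idx]
            finite = peak_scores[np.isfinite(peak_scores)]
            peak_rows.append((
                probes["chrom"].iloc[idx[0]], int(starts[idx[0]]),
                int(ends[idx[-1]]), len(idx),
                float(np.max(finite)) if finite.size else np.nan,
                float(np.mean(finite)) if finite.size else np.nan,
            ))
            members.append(list(pids[idx]))
    if skipped:
        log.info("call_peaks: skipped %d runs shorter than the window", skipped)

    order = sorted(range(len(peak_rows)), key=lambda i: (peak_rows[i][0],
                                                         peak_rows[i][1]))
    peaks = pd.DataFrame(
        [peak_rows[i] for i in order],
        columns=["chrom", "start", "end", "n_probes", "max_score", "mean_score"])
    peaks.insert(3, "peak_id", [f"peak_{i + 1}" for i in range(len(peaks))])
    return PeakSet(peaks=peaks, member_probes=[members[i] for i in order],
                   threshold=float(threshold), params=params,
                   meta={"exceedance": "strict >",
                         "quantile": "linear interpolation"})


def _window_runs(probes: pd.DataFrame, max_gap: int) -> list[np.ndarray]:
    """Maximal runs of consecutive probes within one tiled region.

    Probes must be sorted by (chrom, start); raises if not.  A run breaks
    at tiled-region boundaries and at start-to-start gaps > max_gap.
    """
    starts = probes["start"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    regions = probes["tiled_region_id"].to_numpy()
    n = len(probes)
    if n == 0:
        return []
    same_chrom = chroms[1:] == chroms[:-1]
    if np.any(same_chrom & (np.diff(starts) < 0)):
        raise ValueError("probes are not sorted by (chrom, start)")
    breaks = (~same_chrom) | (regions[1:] != regions[:-1]) | \
             (np.diff(starts) > max_gap)
    bounds = np.concatenate([[0], np.flatnonzero(breaks) + 1, [n]])
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def fraction_as_percent(n_subset: int, n_total: int, decimals: int = 1) -> float:
    """Fraction expressed as a percentage rounded to ``decimals``."""
    if n_total <= 0:
        raise ValueError("total count must be > 0")
    return round(100.0 * n_subset / n_total, decimals)


def peak_probe_fraction(peakset: PeakSet, track: ProbeTrack,
                        decimals: int = 1) -> tuple[int, float, float]:
    """(probes in peaks, fraction, percent) over the track's probe universe."""
    n_total = len(track.probes)
    if n_total == 0:
        raise ValueError("empty track")
    n_in = len(peakset.probe_ids)
    return n_in, n_in / n_total, fraction_as_percent(n_in, n_total, decimals)
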