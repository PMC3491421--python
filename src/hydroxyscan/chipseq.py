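"""ChIP-seq fragment libraries and normalized per-region log2 scores.

Mapped fragment locations (we never touch reads) are deduplicated,
counted over predefined regions with an any-overlap rule, scaled to the
mean library size and expressed as log2((IP + c) / (background + c))
against the matched background library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


@dataclass
class FragmentLibrary:
    """A library of mapped genomic fragments for one sample and mark."""

    fragments: pd.DataFrame  # chrom, start, end
    mark: str
    sample_id: str
    background: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.fragments
        missing = [c for c in FRAGMENT_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        if len(f) and not (f["start"] < f["end"]).all():
            raise ValueError("fragments must satisfy start < end")

    def __len__(self) -> int:
        return len(self.fragments)

    def to_bed(self, path: str | Path) -> None:
        out = self.fragments.copy()
        out["name"] = [f"{self.mark}_{i}" for i in range(len(out))]
        out["score"] = 0
        out["strand"] = "."
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, mark: str, sample_id: str,
                 background: bool = False) -> "FragmentLibrary":
        df = pd.read_csv(path, sep="\t", header=None)
        df = df.iloc[:, :3]
        df.columns = FRAGMENT_COLUMNS
        return cls(fragments=df, mark=mark, sample_id=sample_id,
                   background=background)


def dedup(lib: FragmentLibrary) -> FragmentLibrary:
    """Collapse exact (chrom, start, end) duplicate locations to one."""
    unique = lib.fragments.drop_duplicates(
        subset=FRAGMENT_COLUMNS).reset_index(drop=True)
    removed = len(lib.fragments) - len(unique)
    if removed:
        log.info("dedup %s/%s: removed %d duplicate locations",
                 lib.mark, lib.sample_id, removed)
    out = FragmentLibrary(fragments=unique, mark=lib.mark,
                          sample_id=lib.sample_id, background=lib.background,
                          meta=dict(lib.meta))
    out.meta["duplicates_removed"] = removed
    return out


def count_in_regions(lib: FragmentLibrary, regions: pd.DataFrame) -> pd.Series:
    """Count fragments overlapping each region (any overlap >= 1 bp).

    ``regions`` needs columns chrom/start/end and a ``region_id`` column
    (or a unique index).  A fragment is counted once per region it
    intersects, so a fragment spanning two regions counts in both.
    """
    if "region_id" in regions.columns:
        ids = regions["region_id"].to_numpy()
    else:
        ids = regions.index.to_numpy()
    counts = np.zeros(len(regions), dtype=int)
    frags = lib.fragments
    for chrom, sub in frags.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        sel = regions["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        rs = regions.loc[sel, "start"].to_numpy()
        re_ = regions.loc[sel, "end"].to_numpy()
        # overlap iff fragment.start < region.end and fragment.end > region.start
        n_start_before_end = np.searchsorted(starts, re_, side="left")
        n_end_before_start = np.searchsorted(ends, rs, side="right")
        counts[sel] = n_start_before_end - n_end_before_start
    return pd.Series(counts, index=ids, name=f"{lib.mark}:{lib.sample_id}")


def normalize_counts(counts: pd.DataFrame,
                     library_sizes: dict[str, int]) -> pd.DataFrame:
    """Scale per-sample counts by total fragments to the mean library size."""
    sizes = pd.Series(library_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    mean_size = sizes.mean()
    scaled = counts.astype(float).copy()
    for col in counts.columns:
        scaled[col] = counts[col] * (mean_size / sizes[col])
    return scaled


def log2_vs_background(ip: pd.DataFrame | pd.Series,
                       bg: pd.DataFrame | pd.Series,
                       pseudocount: float = 1.0):
    """log2((IP + c) / (background + c)) on scaled counts."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((ip + pseudocount) / (bg + pseudocount))


def region_scores(
    pairs: list[tuple[FragmentLibrary, FragmentLibrary]],
    regions: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-region log2 IP/background scores for a list of (IP, bg) pairs.

    Each pair is deduplicated, counted, library-size scaled across all
    IP+background libraries jointly, and converted to a log2 score column
    named after the IP sample id.
    """
    deduped = [(dedup(ip), dedup(bg)) for ip, bg in pairs]
    all_counts = {}
    sizes = {}
    for ip, bg in deduped:
        for lib, tag in ((ip, "ip"), (bg, "bg")):
            key = f"{tag}:{lib.sample_id}"
            all_counts[key] = count_in_regions(lib, regions)
            sizes[key] = max(len(lib), 1)
    counts = pd.DataFrame(all_counts)
    scaled = normalize_counts(counts, sizes)
    out = {}
    for ip, bg in deduped:
        out[ip.sample_id] = log2_vs_background(
            scaled[f"ip:{ip.sample_id}"], scaled[f"bg:{bg.sample_id}"],
            pseudocount)
    return pd.DataFrame(out)
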