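"""Probe-level log2(IP/input) track container and TSV/bedGraph I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "tiled_region_id"]


@dataclass
class ProbeTrack:
    """Ordered array probes with per-sample log2(IP/input) scores.

    ``probes`` holds chrom/start/end/probe_id/tiled_region_id, sorted by
    (chrom, start).  ``scores`` and ``intensity`` are probe x sample
    matrices aligned row-for-row with ``probes``; ``intensity`` carries the
    mean log-intensity (A-value) used for within-array loess correction.
    ``groups`` maps sample id to 'control' or 'treated'.
    """

    probes: pd.DataFrame
    scores: pd.DataFrame
    groups: dict[str, str]
    intensity: pd.DataFrame | None = None
    mark: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns {missing}")
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id")
        order = self.probes.sort_values(["chrom", "start"], kind="stable").index
        if not order.equals(self.probes.index):
            raise ValueError("probes must be sorted by (chrom, start)")
        if len(self.scores) != len(self.probes):
            raise ValueError("scores/probes length mismatch")
        if self.intensity is not None and self.intensity.shape != self.scores.shape:
            raise ValueError("intensity/scores shape mismatch")
        unknown = set(self.scores.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group labels: {sorted(unknown)}")

    # ----------------------------------------------------------- accessors

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def group_samples(self, group: str) -> list[str]:
        samples = [s for s in self.samples if self.groups[s] == group]
        if not samples:
            raise ValueError(f"unknown or empty group {group!r}")
        return samples

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.probes["start"].to_numpy() + self.probes["end"].to_numpy()) // 2)

    def copy_with_scores(self, scores: pd.DataFrame) -> "ProbeTrack":
        return ProbeTrack(
            probes=self.probes, scores=scores, groups=dict(self.groups),
            intensity=self.intensity, mark=self.mark, meta=dict(self.meta))

    # ----------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path) -> None:
        df = pd.concat(
            [self.probes.reset_index(drop=True),
             self.scores.reset_index(drop=True)], axis=1)
        header = "#groups\t" + "\t".join(
            f"{s}={self.groups[s]}" for s in self.samples) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, mark: str = "") -> "ProbeTrack":
        with open(path) as fh:
            first = fh.readline()
            groups: dict[str, str] = {}
            if first.startswith("#groups"):
                for kv in first.strip().split("\t")[1:]:
                    k, v = kv.split("=")
                    groups[k] = v
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        probes = df[PROBE_COLUMNS]
        sample_cols = [c for c in df.columns if c not in PROBE_COLUMNS]
        groups = groups or {c: "control" for c in sample_cols}
        return cls(probes=probes, scores=df[sample_cols], groups=groups, mark=mark)

    def write_bedgraph(self, outdir: str | Path, prefix: str = "") -> None:
        outdir = Path(outdir)
        for sample in self.samples:
            out = self.probes[["chrom", "start", "end"]].copy()
            out["score"] = self.scores[sample].to_numpy()
            out.to_csv(outdir / f"{prefix}{sample}.bedGraph",
                       sep="\t", header=False, index=False)
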