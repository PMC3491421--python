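"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hydroxyscan.annotation import Gene, GenomeAnnotation
from hydroxyscan.simulate import simulate_annotation, simulate_study
from hydroxyscan.track import ProbeTrack


def make_track(scores: np.ndarray, spacing: int = 100,
               groups: dict[str, str] | None = None,
               sample_names: list[str] | None = None,
               intensity: np.ndarray | None = None,
               chrom: str = "chr1", region_id: int = 0) -> ProbeTrack:
    """A minimal single-region track from a probe x sample score matrix."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    starts = np.arange(n) * spacing
    probes = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + 60,
        "probe_id": [f"p{i:06d}" for i in range(n)],
        "tiled_region_id": region_id,
    })
    names = sample_names or [f"s{j}" for j in range(scores.shape[1])]
    groups = groups or {s: "control" for s in names}
    intensity_df = None
    if intensity is not None:
        intensity = np.asarray(intensity, dtype=float)
        if intensity.ndim == 1:
            intensity = intensity[:, None]
        intensity_df = pd.DataFrame(intensity, columns=names)
    return ProbeTrack(probes=probes, scores=pd.DataFrame(scores, columns=names),
                      groups=groups, intensity=intensity_df)


def make_gene(gene_id="gA", chrom="chr1", strand="+", start=10_000,
              end=18_000, exons=None) -> Gene:
    return Gene(gene_id=gene_id, chrom=chrom, strand=strand, start=start,
                end=end, exons=tuple(exons or [(start, end)]))


@pytest.fixture(scope="session")
def small_ann() -> GenomeAnnotation:
    return simulate_annotation(30, 1_500_000, seed=11, n_chroms=2,
                               n_enhancers=10)


@pytest.fixture(scope="session")
def small_study():
    """A compact but complete study used across modules."""
    return simulate_study(
        5, n_genes=60, chrom_length=2_500_000, n_chroms=1, n_induced=10,
        n_fragments=10_000, tissue_count=6)
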