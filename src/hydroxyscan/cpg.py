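"""CpG density, LCP/ICP/HCP promoter classes, 5hmC-marked TSS detection
and the information-theoretic tissue-specificity score."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import Gene, offset_window_to_genomic
from .peaks import PeakSet

PROMOTER_CLASSES = ("LCP", "ICP", "HCP")


def cpg_density(sequence: str) -> float:
    """CpG dinucleotides per 100 bp (case-insensitive; N never matches)."""
    if not sequence:
        raise ValueError("empty sequence window")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over {A, C, G, T, N}")
    return seq.count("CG") * 100.0 / len(seq)


def classify_promoter(density: float) -> str:
    """LCP (<1), ICP (1-5) or HCP (>5) CpGs per 100 bp."""
    if density < 0:
        raise ValueError("density must be >= 0")
    if density < 1.0:
        return "LCP"
    if density <= 5.0:
        return "ICP"
    return "HCP"


def classify_promoters(sequences: dict[str, str]) -> pd.DataFrame:
    """Density and class per gene id from promoter-window sequences."""
    rows = [(gid, cpg_density(seq), classify_promoter(cpg_density(seq)))
            for gid, seq in sequences.items()]
    return pd.DataFrame(rows, columns=["gene_id", "cpg_per_100bp", "class"])


def tss_5hmc_enriched(genes: list[Gene], peakset: PeakSet,
                      tss_halfwidth: int = 500) -> list[str]:
    """Genes whose TSS window (strand-aware, +/-tss_halfwidth) hits a peak."""
    peaks = peakset.peaks
    out = []
    for g in genes:
        s, e = offset_window_to_genomic(g.tss, g.strand, -tss_halfwidth,
                                        tss_halfwidth)
        sub = peaks[peaks["chrom"] == g.chrom]
        if ((sub["start"] < e) & (s < sub["end"])).any():
            out.append(g.gene_id)
    return out


def specificity_score(expression: np.ndarray | pd.Series) -> float:
    """Tissue-specificity score Si = sum_t p_t * log2(p_t * T).

    This is the Kullback-Leibler divergence of the expression profile
    from the uniform profile: 0 for uniform expression, log2(T) when a
    gene is expressed in exactly one of T tissues.  Zero-expression
    tissues contribute nothing; the score is invariant to rescaling.
    """
    e = np.asarray(expression, dtype=float)
    if e.size < 2:
        raise ValueError("need >= 2 tissues")
    if (e < 0).any():
        raise ValueError("expression must be >= 0")
    total = e.sum()
    if total == 0:
        raise ValueError("expression must not be all zero")
    if np.ptp(e) == 0:
        return 0.0  # uniform profile: exactly zero by definition
    p = e / total
    nz = p > 0
    si = float(np.sum(p[nz] * np.log2(p[nz] * e.size)))
    return 0.0 if abs(si) < 1e-12 else si


def specificity_scores(panel: pd.DataFrame) -> pd.Series:
    """Si per gene for a genes x tissues panel (linear-scale values)."""
    return pd.Series({g: specificity_score(panel.loc[g].to_numpy())
                      for g in panel.index}, name="si")
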