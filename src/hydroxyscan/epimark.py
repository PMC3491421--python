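"""Absolute 5hmC / 5mC / unmodified-CpG fractions from glucosylation-
restriction qPCR (EpiMark-style assay).

Half of the genomic DNA is treated with T4 beta-glucosyltransferase,
which glucosylates 5hmC; both halves are split across MspI, HpaII and
uncut reactions and quantified by qPCR.  MspI cuts CCGG regardless of
CpG methylation but is blocked by glucosyl-5hmC; HpaII is blocked by any
CpG modification.  Under that enzymology the surviving-template
fractions resolve the three cytosine states linearly:

    f_5hmC = f(MspI | glucosylated) - f(MspI | untreated)
    f_5mC  = f(HpaII | untreated)   - f(MspI | glucosylated)
    f_C    = 1 - f(HpaII | untreated)

with the untreated-MspI term acting as the kit's background correction.
qPCR efficiency is taken as exactly 2 per cycle, so a surviving fraction
f shows up ``-log2(f)`` cycles after the uncut reaction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CQ_CEILING = 40.0
REACTIONS = [(True, "MspI"), (False, "MspI"), (True, "HpaII"),
             (False, "HpaII"), (True, "uncut"), (False, "uncut")]


def surviving_fraction(cq_digested: float, cq_uncut: float,
                       ceiling: float = CQ_CEILING) -> float:
    """Template fraction surviving a digest: 2^(Cq_uncut - Cq_digested).

    A digested Cq at the ceiling (complete digestion by qPCR convention)
    maps to 0.  The result is clamped to [0, 1].
    """
    if not (0 < cq_digested <= ceiling and 0 < cq_uncut <= ceiling):
        raise ValueError("Cq values must lie in (0, ceiling]")
    if cq_digested >= ceiling:
        return 0.0
    return float(min(max(2.0 ** (cq_uncut - cq_digested), 0.0), 1.0))


def epimark_fractions(assay: pd.DataFrame, tolerance: float = 0.05
                      ) -> pd.DataFrame:
    """(f_5hmC, f_5mC, f_C) per locus from a six-reaction Cq table.

    ``assay`` needs columns locus / glucosylated / digest / replicate /
    cq.  Replicates are resolved independently and then averaged, with
    the standard error of each fraction across replicates reported when
    there are two or more.  Fractions are clamped to [0, 1]; violations
    beyond ``tolerance`` before clamping are logged as warnings.
    """
    required = {"locus", "glucosylated", "digest", "replicate", "cq"}
    if not required <= set(assay.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    rows = []
    for (locus, rep), sub in assay.groupby(["locus", "replicate"]):
        cq = {(bool(r.glucosylated), r.digest): r.cq for r in sub.itertuples()}
        missing = [key for key in REACTIONS if key not in cq]
        if missing:
            raise ValueError(f"{locus} rep {rep}: missing reactions {missing}")
        f = {key: surviving_fraction(cq[key], cq[(key[0], "uncut")])
             for key in REACTIONS if key[1] != "uncut"}
        raw = {
            "f_5hmC": f[(True, "MspI")] - f[(False, "MspI")],
            "f_5mC": f[(False, "HpaII")] - f[(True, "MspI")],
            "f_C": 1.0 - f[(False, "HpaII")],
        }
        clamped = {}
        for name, value in raw.items():
            if value < -tolerance or value > 1 + tolerance:
                log.warning("%s rep %s: %s = %.3f outside [0, 1] before "
                            "clamping", locus, rep, name, value)
            clamped[name] = min(max(value, 0.0), 1.0)
        clamped["residual"] = 1.0 - sum(clamped.values())
        rows.append({"locus": locus, "replicate": rep, **clamped})
    per_rep = pd.DataFrame(rows)
    agg = per_rep.groupby("locus").agg(
        f_5hmC=("f_5hmC", "mean"), f_5mC=("f_5mC", "mean"),
        f_C=("f_C", "mean"), residual=("residual", "mean"),
        n_replicates=("replicate", "size"),
        se_5hmC=("f_5hmC", "sem"), se_5mC=("f_5mC", "sem"),
        se_C=("f_C", "sem"))
    agg.attrs["per_replicate"] = per_rep
    return agg.reset_index()
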