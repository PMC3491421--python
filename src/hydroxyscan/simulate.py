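"""Synthetic study generator.

Emulates a promoter-centred tiling-array experiment on mouse liver:
50-70 bp probes at fixed start-to-start spacing over tiled regions that
span TSS -7.25 kb .. +3 kb of every gene, two groups of five animals
(control vs drug-treated), intra-genic 5hmC peaks that scale with
expression tier, a broad gene-body 5mC background, and — at drug-induced
genes — a reciprocal promoter-proximal 5hmC gain / 5mC loss with loss of
both marks over the TSS core.  ChIP-seq fragment libraries, an expression
matrix, a tissue panel and glucosylation-qPCR Cq tables are generated with
the same ground truth, recorded in a :class:`TruthLedger`.

Every generator takes an integer seed and is deterministic given it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, merge_intervals, offset_window_to_genomic
from .chipseq import FragmentLibrary
from .track import ProbeTrack

TIER_SCALE = {"low": 0.5, "medium": 1.0, "high": 1.5}

# Tiled-region reach around each TSS, in strand-aware offsets.
TILE_UP = -7250
TILE_DOWN = 3000

CQ_CEILING = 40.0


@dataclass
class TruthLedger:
    """Ground truth of everything the generators planted."""

    planted_peaks: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    induced_genes: dict[str, float] = field(default_factory=dict)
    tss_core_loss: list[str] = field(default_factory=list)
    tss_peak_genes: list[str] = field(default_factory=list)
    tiers: dict[str, str] = field(default_factory=dict)
    baseline_expression: dict[str, float] = field(default_factory=dict)
    true_fractions: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    unique_fragment_counts: dict[str, int] = field(default_factory=dict)
    uniform_tissue_genes: list[str] = field(default_factory=list)
    single_tissue_genes: dict[str, int] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, fr in self.true_fractions.items():
            if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1 + 1e-9:
                raise ValueError(f"invalid modification fractions at {locus}")
        for g, lfc in self.induced_genes.items():
            if lfc <= 0:
                raise ValueError(f"non-positive induced fold change for {g}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        raw = json.loads(Path(path).read_text())
        raw["planted_peaks"] = {
            m: [tuple(iv) for iv in ivs] for m, ivs in raw["planted_peaks"].items()}
        raw["true_fractions"] = {
            k: tuple(v) for k, v in raw["true_fractions"].items()}
        return cls(**raw)


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def simulate_annotation(
    n_genes: int,
    chrom_length: int,
    seed: int,
    *,
    n_chroms: int = 2,
    short_gene_fraction: float = 0.15,
    cgi_fraction: float = 0.5,
    n_enhancers: int = 30,
    n_intergenic_tiles: int = 8,
    min_gap: int = 2500,
) -> GenomeAnnotation:
    """Place non-overlapping gene models on a small synthetic genome.

    Genes get 1-8 exons, mixed strands, a CpG island over a fraction of
    promoters, intergenic enhancers, and tiled regions covering
    TSS-7.25 kb..+3 kb (which fully contains the body of every gene
    shorter than 3 kb).  Raises if the genes cannot be placed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_length = int(chrom_length)
    chromosomes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    chrom_names = sorted(chromosomes)

    per_chrom = np.full(n_chroms, n_genes // n_chroms)
    per_chrom[: n_genes % n_chroms] += 1

    genes: list[Gene] = []
    gid = 0
    for chrom, k in zip(chrom_names, per_chrom):
        if k == 0:
            continue
        n_short = int(round(short_gene_fraction * k))
        lengths = np.concatenate([
            rng.integers(2000, 3000, size=n_short),
            np.exp(rng.uniform(np.log(3200), np.log(15000), size=k - n_short)).astype(int),
        ])
        rng.shuffle(lengths)
        # leave headroom at both chromosome ends for upstream tiling
        margin = -TILE_UP + 500
        needed = int(lengths.sum()) + (k + 1) * min_gap + 2 * margin
        if needed > chrom_length:
            raise ValueError(
                f"cannot place {k} genes in {chrom_length} bp on {chrom}: "
                f"need >= {needed} bp")
        extra = chrom_length - needed
        gaps = min_gap + rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
        pos = margin
        for length, gap in zip(lengths, gaps[:-1]):
            pos += int(gap)
            start, end = pos, pos + int(length)
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 9))
            genes.append(Gene(
                gene_id=f"g{gid:04d}", chrom=chrom, strand=strand,
                start=start, end=end,
                exons=_random_exons(rng, start, end, n_exons)))
            gid += 1

    ann = GenomeAnnotation(chromosomes=chromosomes, genes=genes)

    cgis: list[tuple[str, int, int]] = []
    for g in genes:
        if rng.random() < cgi_fraction:
            s, e = offset_window_to_genomic(g.tss, g.strand, -200, 500)
            cgis.append((g.chrom, max(0, s), min(chrom_length, e)))

    tiled: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for g in genes:
        s, e = offset_window_to_genomic(g.tss, g.strand, TILE_UP, TILE_DOWN)
        tiled[g.chrom].append((max(0, s), min(chrom_length, e)))

    # a little intergenic array content, far from every gene window
    by_chrom_genes = ann.genes_by_chrom()
    placed = 0
    attempts = 0
    while placed < n_intergenic_tiles and attempts < 200 * max(n_intergenic_tiles, 1):
        attempts += 1
        chrom = chrom_names[int(rng.integers(n_chroms))]
        s = int(rng.integers(0, chrom_length - 2000))
        e = s + 2000
        if any(g.start - 11_000 < e and s < g.end + 11_000
               for g in by_chrom_genes.get(chrom, [])):
            continue
        tiled[chrom].append((s, e))
        placed += 1

    tiled_regions = [
        (chrom, s, e)
        for chrom in chrom_names for s, e in merge_intervals(tiled[chrom])]

    enhancers: list[tuple[str, int, int]] = []
    by_chrom = ann.genes_by_chrom()
    attempts = 0
    while len(enhancers) < n_enhancers and attempts < 50 * n_enhancers:
        attempts += 1
        g = genes[int(rng.integers(len(genes)))]
        off = int(rng.integers(-7000, -4600))
        s, e = offset_window_to_genomic(g.tss, g.strand, off, off + 1000)
        if s < 0 or e > chrom_length:
            continue
        if any(gg.start < e and s < gg.end for gg in by_chrom[g.chrom]):
            continue  # keep enhancers intergenic
        if any(c == g.chrom and os < e and s < oe for c, os, oe in enhancers):
            continue
        enhancers.append((g.chrom, s, e))
    if len(enhancers) < n_enhancers:
        raise ValueError("could not place the requested number of enhancers")

    ann.cgis = sorted(cgis)
    ann.enhancers = sorted(enhancers)
    ann.tiled_regions = tiled_regions
    return ann


def _random_exons(rng: np.random.Generator, start: int, end: int,
                  n_exons: int) -> tuple[tuple[int, int], ...]:
    length = end - start
    if n_exons == 1 or length < 4 * n_exons:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2,
                              replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    return tuple((start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
                 for i in range(n_exons))


# --------------------------------------------------------------------------
# probe tracks
# --------------------------------------------------------------------------

def _place_probes(ann: GenomeAnnotation, rng: np.random.Generator,
                  spacing: int = 100) -> pd.DataFrame:
    """Tile probes over the array regions: 50-70 bp long, fixed spacing."""
    rows = []
    pid = 0
    for rid, (chrom, rstart, rend) in enumerate(ann.tiled_regions):
        starts = np.arange(rstart, rend - 70, spacing)
        lengths = rng.integers(50, 71, size=len(starts))
        for s, ln in zip(starts, lengths):
            rows.append((chrom, int(s), int(s + ln), f"p{pid:07d}", rid))
            pid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id",
                                     "tiled_region_id"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_probe_signals(
    ann: GenomeAnnotation,
    *,
    seed: int,
    n_control: int = 5,
    n_treated: int = 5,
    noise_sd: float = 0.5,
    between_animal_sd: float = 0.1,
    tiers: dict[str, str] | None = None,
    body_peak_genes: dict[str, tuple[int, int]] | None = None,
    body_peak_effect: float = 2.0,
    body_peak_fraction: float = 0.5,
    mc_body_level: float = 0.5,
    induced: dict[str, float] | None = None,
    flank_effect: float = 1.0,
    core_loss: float = 0.75,
    tss_peak_genes: list[str] | None = None,
    tss_peak_effect: float = 2.0,
    intensity_trend: float = 0.3,
    spacing: int = 100,
) -> tuple[ProbeTrack, ProbeTrack, TruthLedger]:
    """Generate 5hmC and 5mC probe tracks plus their truth ledger.

    Baseline probe scores are Normal(0, noise_sd) on the log2 scale with a
    per-animal offset of sd ``between_animal_sd``.  5hmC gene-body peaks
    (``body_peak_effect`` log2, scaled by expression tier) are planted in a
    random ``body_peak_fraction`` of genes unless ``body_peak_genes`` gives
    explicit intervals.  For ``induced`` genes (gene id -> true expression
    log2 fold change) treated animals gain ``flank_effect * lfc / 2`` 5hmC
    and lose the same amount of 5mC over the TSS +/-0.25-3 kb flanks, and
    both marks drop by ``core_loss`` over the TSS +/-250 bp core.  A
    per-probe intensity covariate with a saturation-shaped score trend of
    amplitude ``intensity_trend`` is attached for normalization testing.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if n_control < 2 or n_treated < 2:
        raise ValueError("group sizes must be >= 2")
    rng = np.random.default_rng(seed)
    probes = _place_probes(ann, rng, spacing=spacing)
    mid = (probes["start"].to_numpy() + probes["end"].to_numpy()) // 2
    chrom_arr = probes["chrom"].to_numpy()
    n_probes = len(probes)

    samples = [f"control_{i + 1}" for i in range(n_control)] + \
              [f"treated_{i + 1}" for i in range(n_treated)]
    groups = {s: ("control" if s.startswith("control") else "treated")
              for s in samples}
    treated_cols = np.array([groups[s] == "treated" for s in samples])

    tiers = dict(tiers) if tiers is not None else {
        g.gene_id: ["low", "medium", "high"][int(rng.integers(3))]
        for g in ann.genes}
    induced = dict(induced or {})
    for g in induced:
        ann.gene(g)  # raises KeyError on unknown ids

    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in ann.tiled_regions:
        merged_by_chrom.setdefault(chrom, []).append((s, e))

    def _require_tiled(chrom: str, s: int, e: int) -> None:
        if not any(rs <= s and e <= re for rs, re in merged_by_chrom.get(chrom, [])):
            raise ValueError(
                f"planted interval {chrom}:{s}-{e} outside tiled regions")

    def _mask(chrom: str, s: int, e: int) -> np.ndarray:
        return (chrom_arr == chrom) & (mid >= s) & (mid < e)

    ledger = TruthLedger(tiers=tiers, induced_genes=induced,
                         seeds={"probe_signals": int(seed)})
    ledger.planted_peaks = {"5hmC": [], "5mC": []}

    # shared baseline effects (both groups)
    hmc_base = np.zeros(n_probes)
    mc_base = np.zeros(n_probes)

    if body_peak_genes is None:
        body_peak_genes = {}
        for g in ann.genes:
            if rng.random() >= body_peak_fraction:
                continue
            # broad kb-scale intragenic domains, as 5hmC forms over the
            # bodies of expressed genes
            lo = 300
            hi = min(g.length, TILE_DOWN) - 200
            if hi - lo < 2000:
                continue
            a = int(rng.integers(lo, hi - 2000 + 1))
            b = a + int(rng.integers(2000, min(2800, hi - a) + 1))
            body_peak_genes[g.gene_id] = (a, b)

    for gid, (a, b) in body_peak_genes.items():
        g = ann.gene(gid)
        s, e = offset_window_to_genomic(g.tss, g.strand, a, b)
        _require_tiled(g.chrom, s, e)
        hmc_base[_mask(g.chrom, s, e)] += body_peak_effect * TIER_SCALE[tiers[gid]]
        ledger.planted_peaks["5hmC"].append((g.chrom, int(s), int(e)))

    for g in ann.genes:  # broad 5mC background over gene bodies
        s, e = g.start, g.end
        m = _mask(g.chrom, s, e)
        if mc_body_level and m.any():
            mc_base[m] += mc_body_level

    for gid in tss_peak_genes or []:
        g = ann.gene(gid)
        s, e = offset_window_to_genomic(g.tss, g.strand, -250, 250)
        _require_tiled(g.chrom, s, e)
        hmc_base[_mask(g.chrom, s, e)] += tss_peak_effect
        ledger.planted_peaks["5hmC"].append((g.chrom, int(s), int(e)))
    ledger.tss_peak_genes = list(tss_peak_genes or [])

    # treated-only reciprocal changes at induced genes
    hmc_delta = np.zeros(n_probes)
    mc_delta = np.zeros(n_probes)
    for gid, lfc in induced.items():
        g = ann.gene(gid)
        amp = flank_effect * lfc / 2.0
        for a, b in ((-3000, -250), (250, 3000)):
            s, e = offset_window_to_genomic(g.tss, g.strand, a, b)
            _require_tiled(g.chrom, s, e)
            m = _mask(g.chrom, s, e)
            hmc_delta[m] += amp
            mc_delta[m] -= amp
        s, e = offset_window_to_genomic(g.tss, g.strand, -250, 250)
        m = _mask(g.chrom, s, e)
        hmc_delta[m] -= core_loss
        mc_delta[m] -= core_loss
    ledger.tss_core_loss = sorted(induced)

    # intensity covariate with a saturation-shaped trend
    a_base = rng.normal(12.0, 1.5, size=n_probes)

    def _make_track(base: np.ndarray, delta: np.ndarray, mark: str) -> ProbeTrack:
        noise = rng.normal(0.0, noise_sd, size=(n_probes, len(samples)))
        animal = rng.normal(0.0, between_animal_sd, size=len(samples))
        scores = base[:, None] + noise + animal[None, :]
        scores[:, treated_cols] += delta[:, None]
        intensity = a_base[:, None] + rng.normal(0.0, 0.2,
                                                 size=(n_probes, len(samples)))
        scores += intensity_trend * -np.tanh((intensity - 13.5) / 1.5)
        return ProbeTrack(
            probes=probes, mark=mark, groups=dict(groups),
            scores=pd.DataFrame(scores, columns=samples),
            intensity=pd.DataFrame(intensity, columns=samples))

    hmc = _make_track(hmc_base, hmc_delta, "5hmC")
    mc = _make_track(mc_base, mc_delta, "5mC")
    return hmc, mc, ledger


# --------------------------------------------------------------------------
# ChIP-seq fragment libraries
# --------------------------------------------------------------------------

def simulate_fragments(
    ann: GenomeAnnotation,
    mark: str,
    enrichment: list[tuple[str, int, int, float]],
    n_fragments: int,
    seed: int,
    *,
    sample_id: str = "s1",
    duplicate_rate: float = 0.1,
    frag_size: tuple[int, int] = (150, 400),
) -> tuple[FragmentLibrary, FragmentLibrary]:
    """Sample fragment locations with region-proportional rates.

    ``enrichment`` lists intervals with rate multipliers (>= 0); the rest
    of the genome has rate 1.  Exact duplicates are injected at
    ``duplicate_rate`` so that downstream deduplication is exercised.
    Returns the IP library and a matched uniform background library.
    """
    for chrom, s, e, mult in enrichment:
        if e <= s:
            raise ValueError(f"zero-length enrichment region {chrom}:{s}-{e}")
        if mult < 0:
            raise ValueError("enrichment multiplier must be >= 0")
    rng = np.random.default_rng(seed)
    ip = _sample_library(ann, enrichment, n_fragments, rng, mark,
                         sample_id, False, duplicate_rate, frag_size)
    bg = _sample_library(ann, [], n_fragments, rng, mark,
                         sample_id, True, duplicate_rate, frag_size)
    return ip, bg


def _sample_library(ann, enrichment, n_fragments, rng, mark, sample_id,
                    background, duplicate_rate, frag_size) -> FragmentLibrary:
    chroms, starts, ends, mults = [], [], [], []
    by_chrom: dict[str, list[tuple[int, int, float]]] = {
        c: [] for c in sorted(ann.chromosomes)}
    for chrom, s, e, m in enrichment:
        by_chrom[chrom].append((s, e, m))
    for chrom in sorted(ann.chromosomes):
        length = ann.chromosomes[chrom]
        pos = 0
        for s, e, m in sorted(by_chrom[chrom]):
            s = max(s, pos)  # clip overlaps between enrichment windows
            if e <= s:
                continue
            if s > pos:
                chroms.append(chrom); starts.append(pos); ends.append(s)
                mults.append(1.0)
            chroms.append(chrom); starts.append(s); ends.append(e)
            mults.append(float(m))
            pos = e
        if pos < length:
            chroms.append(chrom); starts.append(pos); ends.append(length)
            mults.append(1.0)

    starts_a = np.asarray(starts); ends_a = np.asarray(ends)
    weights = (ends_a - starts_a) * np.asarray(mults)
    if n_fragments > 0:
        probs = weights / weights.sum()
        seg = rng.choice(len(weights), size=n_fragments, p=probs)
        midpts = (starts_a[seg]
                  + rng.random(n_fragments) * (ends_a[seg] - starts_a[seg])).astype(int)
        lengths = rng.integers(frag_size[0], frag_size[1] + 1, size=n_fragments)
        fs = np.maximum(midpts - lengths // 2, 0)
        fe = fs + lengths
        frag_chrom = np.asarray(chroms, dtype=object)[seg]
        n_dup = int(round(duplicate_rate * n_fragments))
        if n_dup:
            dup = rng.integers(0, n_fragments, size=n_dup)
            frag_chrom = np.concatenate([frag_chrom, frag_chrom[dup]])
            fs = np.concatenate([fs, fs[dup]])
            fe = np.concatenate([fe, fe[dup]])
        frags = pd.DataFrame({"chrom": frag_chrom, "start": fs, "end": fe})
        frags = frags.sort_values(["chrom", "start", "end"],
                                  kind="stable").reset_index(drop=True)
    else:
        frags = pd.DataFrame({"chrom": pd.Series(dtype=object),
                              "start": pd.Series(dtype=int),
                              "end": pd.Series(dtype=int)})
    return FragmentLibrary(fragments=frags, mark=mark, sample_id=sample_id,
                           background=background)


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def simulate_expression(
    ann: GenomeAnnotation,
    induced: dict[str, float],
    seed: int,
    *,
    n_control: int = 5,
    n_treated: int = 5,
    noise_sd: float = 0.2,
    baseline: dict[str, float] | None = None,
    tissue_count: int = 0,
    ledger: TruthLedger | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Log2 expression matrix (samples x genes) and optional tissue panel.

    Baselines are Normal(8, 2) on the log2 scale (a log-normal abundance);
    treated samples are shifted by the true log2 fold change for induced
    genes.  The tissue panel (genes x tissues, linear scale) contains
    designed uniformly-expressed and single-tissue genes for specificity
    scoring tests.
    """
    for g, lfc in induced.items():
        ann.gene(g)
        if lfc <= 0:
            raise ValueError(f"true_lfc must be > 0 for induced gene {g}")
    rng = np.random.default_rng(seed)
    gene_ids = ann.gene_ids
    base = baseline or {g: float(rng.normal(8.0, 2.0)) for g in gene_ids}
    samples = [f"control_{i + 1}" for i in range(n_control)] + \
              [f"treated_{i + 1}" for i in range(n_treated)]
    values = np.empty((len(samples), len(gene_ids)))
    for j, gid in enumerate(gene_ids):
        mu = base[gid]
        shift = induced.get(gid, 0.0)
        values[:, j] = mu + rng.normal(0.0, noise_sd, size=len(samples))
        values[n_control:, j] += shift
    expr = pd.DataFrame(values, index=samples, columns=gene_ids)

    panel = None
    if tissue_count >= 2:
        n_designed = max(1, len(gene_ids) // 10)
        uniform_ids = gene_ids[:n_designed]
        single_ids = gene_ids[n_designed:2 * n_designed]
        mat = 2.0 ** rng.normal(6.0, 1.5, size=(len(gene_ids), tissue_count))
        for gid in uniform_ids:
            mat[gene_ids.index(gid)] = 50.0
        single_map = {}
        for gid in single_ids:
            t = int(rng.integers(tissue_count))
            row = np.zeros(tissue_count)
            row[t] = 200.0
            mat[gene_ids.index(gid)] = row
            single_map[gid] = t
        panel = pd.DataFrame(
            mat, index=gene_ids,
            columns=[f"tissue_{t + 1}" for t in range(tissue_count)])
        if ledger is not None:
            ledger.uniform_tissue_genes = list(uniform_ids)
            ledger.single_tissue_genes = single_map
    if ledger is not None:
        ledger.baseline_expression = base
    return expr, panel


# --------------------------------------------------------------------------
# EpiMark qPCR
# --------------------------------------------------------------------------

def simulate_epimark_cq(
    true_fractions: dict[str, tuple[float, float, float]],
    seed: int,
    *,
    cq_uncut: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    ceiling: float = CQ_CEILING,
) -> pd.DataFrame:
    """Forward model of the glucosylation / MspI / HpaII qPCR assay.

    Surviving template fraction f maps to Cq = cq_uncut - log2(f); a Cq at
    the ``ceiling`` (40 cycles by qPCR convention) represents complete
    digestion.  Enzymology: MspI cuts CCGG regardless of CpG methylation
    but is blocked by glucosylated 5hmC; HpaII is blocked by any CpG
    modification; glucosylation only alters 5hmC.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus, (f_hmc, f_mc, f_c) in true_fractions.items():
        if min(f_hmc, f_mc, f_c) < 0 or f_hmc + f_mc + f_c > 1 + 1e-12:
            raise ValueError(f"invalid fractions at {locus}")
        surviving = {
            (True, "MspI"): f_hmc,
            (False, "MspI"): 0.0,
            (True, "HpaII"): f_hmc + f_mc,
            (False, "HpaII"): f_hmc + f_mc,
            (True, "uncut"): 1.0,
            (False, "uncut"): 1.0,
        }
        floor = 2.0 ** (cq_uncut - ceiling)
        for rep in range(n_replicates):
            for (glu, digest), f in surviving.items():
                cq = ceiling if f <= floor else cq_uncut - np.log2(f)
                if noise_sd > 0:
                    cq += rng.normal(0.0, noise_sd)
                rows.append((locus, glu, digest, rep + 1,
                             float(min(cq, ceiling))))
    return pd.DataFrame(rows, columns=["locus", "glucosylated", "digest",
                                       "replicate", "cq"])


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

CHIP_MARKS = ("H3K4me2", "H3K27me3", "H3K36me3")

# control-group enrichment per expression tier
_K4_TIER = {"low": 2.0, "medium": 5.0, "high": 8.0}
_K36_TIER = {"low": 1.5, "medium": 4.0, "high": 7.0}
_K27_TIER = {"low": 6.0, "medium": 3.0, "high": 1.5}


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    ann: GenomeAnnotation
    hmc: ProbeTrack
    mc: ProbeTrack
    expression: pd.DataFrame
    tissue_panel: pd.DataFrame | None
    libraries: dict[str, list[tuple[FragmentLibrary, FragmentLibrary]]]
    cq_table: pd.DataFrame
    ledger: TruthLedger


def simulate_study(
    seed: int,
    *,
    n_genes: int = 200,
    chrom_length: int = 5_000_000,
    n_chroms: int = 2,
    n_control: int = 5,
    n_treated: int = 5,
    n_induced: int = 30,
    lfc_range: tuple[float, float] = (1.6, 4.0),
    noise_sd: float = 0.5,
    expression_noise_sd: float = 0.2,
    n_fragments: int = 50_000,
    chip_replicates: int = 2,
    chip_effect: float = 0.8,
    tissue_count: int = 8,
    n_epimark_loci: int = 6,
    simulate_chip: bool = True,
    **probe_kwargs,
) -> StudyData:
    """Generate a full coherent study: one call, one seed, one ledger."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)

    ann = simulate_annotation(n_genes, chrom_length, int(sub[0]),
                              n_chroms=n_chroms)
    gene_ids = ann.gene_ids

    base = {g: float(rng.normal(8.0, 2.0)) for g in gene_ids}
    order = sorted(gene_ids, key=lambda g: (base[g], g))
    q = len(gene_ids) // 4
    tiers = {g: "low" for g in order[:q]}
    tiers.update({g: "high" for g in order[len(order) - q:]})
    tiers.update({g: "medium" for g in order[q:len(order) - q]
                  if g not in tiers})

    induced_ids = list(rng.choice(gene_ids, size=n_induced, replace=False))
    induced = {g: float(rng.uniform(*lfc_range)) for g in sorted(induced_ids)}

    hmc, mc, ledger = simulate_probe_signals(
        ann, seed=int(sub[1]), n_control=n_control, n_treated=n_treated,
        noise_sd=noise_sd, tiers=tiers, induced=induced, **probe_kwargs)
    ledger.seeds["study"] = int(seed)

    expr, panel = simulate_expression(
        ann, induced, int(sub[2]), n_control=n_control, n_treated=n_treated,
        noise_sd=expression_noise_sd, baseline=base,
        tissue_count=tissue_count, ledger=ledger)

    libraries: dict[str, list[tuple[FragmentLibrary, FragmentLibrary]]] = {}
    if simulate_chip:
        for mi, mark in enumerate(CHIP_MARKS):
            libs = []
            for group in ("control", "treated"):
                for rep in range(chip_replicates):
                    enr = _chip_enrichment(ann, mark, tiers, induced,
                                           group == "treated", chip_effect)
                    ip, bg = simulate_fragments(
                        ann, mark, enr, n_fragments,
                        int(sub[3]) + 97 * mi + 13 * len(libs),
                        sample_id=f"{group}_{rep + 1}")
                    libs.append((ip, bg))
                    ledger.unique_fragment_counts[
                        f"{mark}:{ip.sample_id}"] = int(
                        len(ip.fragments.drop_duplicates()))
            libraries[mark] = libs

    loci = [f"locus_{i + 1}" for i in range(n_epimark_loci)]
    fractions = {}
    for locus in loci:
        f_hmc = float(rng.uniform(0.0, 0.25))
        f_mc = float(rng.uniform(0.2, 0.6))
        fractions[locus] = (f_hmc, f_mc, float(max(0.0, 1 - f_hmc - f_mc)))
    ledger.true_fractions = fractions
    cq = simulate_epimark_cq(fractions, int(sub[4]), noise_sd=0.1,
                             n_replicates=2)

    return StudyData(ann=ann, hmc=hmc, mc=mc, expression=expr,
                     tissue_panel=panel, libraries=libraries,
                     cq_table=cq, ledger=ledger)


def _chip_enrichment(ann, mark, tiers, induced, treated, chip_effect):
    """Per-gene enrichment windows for one histone mark library."""
    enr = []
    for g in ann.genes:
        tier = tiers[g.gene_id]
        lfc = induced.get(g.gene_id, 0.0)
        if mark == "H3K4me2":
            s, e = offset_window_to_genomic(g.tss, g.strand, -1000, 2000)
            mult = _K4_TIER[tier]
            if treated and lfc:
                mult *= 1 + chip_effect * lfc
        elif mark == "H3K36me3":
            s, e = g.start, g.end
            mult = _K36_TIER[tier]
            if treated and lfc:
                mult *= 1 + chip_effect * lfc
        else:  # H3K27me3
            s, e = g.start, g.end
            mult = _K27_TIER[tier]
            if treated and lfc:
                mult /= 1 + chip_effect * lfc
        length = ann.chromosomes[g.chrom]
        enr.append((g.chrom, max(0, s), min(length, e), mult))
    return enr


# --------------------------------------------------------------------------
# promoter sequences (for CpG-density classification tests)
# --------------------------------------------------------------------------

def simulate_promoter_sequences(
    ann: GenomeAnnotation,
    seed: int,
    *,
    window: tuple[int, int] = (-1000, 250),
    cgi_density: float = 8.0,
    noncgi_density: float = 0.5,
) -> dict[str, str]:
    """Promoter-window sequences with controlled CpG density.

    Genes whose promoter intersects an annotated CpG island get
    ``cgi_density`` CpGs per 100 bp, the rest ``noncgi_density``.  The
    backbone is drawn from {A, C, T} so the planted CG dinucleotides are
    the only ones present and the density is exact up to rounding.
    """
    rng = np.random.default_rng(seed)
    length = window[1] - window[0]
    out = {}
    for g in ann.genes:
        s, e = offset_window_to_genomic(g.tss, g.strand, *window)
        has_cgi = any(c == g.chrom and cs < e and s < ce
                      for c, cs, ce in ann.cgis)
        density = cgi_density if has_cgi else noncgi_density
        k = int(round(density * length / 100))
        seq = rng.choice(list("ACT"), size=length)
        slots = np.arange(0, length - 1, 2)
        chosen = rng.choice(slots, size=min(k, len(slots)), replace=False)
        for pos in chosen:
            seq[pos] = "C"
            seq[pos + 1] = "G"
        out[g.gene_id] = "".join(seq)
    return out
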