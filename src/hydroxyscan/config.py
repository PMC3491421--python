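"""Pipeline configuration: every tunable with its default, YAML/JSON I/O
and fail-late validation (all violations reported at once)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs; empty paths mean "simulate"
    simulate: bool = True
    hmc_tsv: str = ""
    mc_tsv: str = ""
    expr_tsv: str = ""
    gff: str = ""
    outdir: str = "hydroxyscan_out"
    seed: int = 1

    # synthetic study scale
    n_genes: int = 200
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_control: int = 5
    n_treated: int = 5
    n_induced: int = 30
    noise_sd: float = 0.5
    n_fragments: int = 50_000
    simulate_chip: bool = True

    # normalization
    norm_order: tuple[str, ...] = ("loess", "scale")
    loess_span: float = 0.3

    # peak calling
    peak_q: float = 90.0
    peak_min_above: int = 4
    peak_window_probes: int = 5
    peak_max_gap: int = 500

    # profiles
    profile_span: int = 1500
    profile_window: int = 200
    profile_step: int = 50
    heatmap_clip: float = 2.5

    # category scheme
    promoter_window: tuple[int, int] = (-1000, 250)
    upstream_window: tuple[int, int] = (-7250, -1000)
    downstream_extent: int = 1000

    # differential
    induction_threshold: float = 1.5
    family_alpha: float = 0.005
    chip_pseudocount: float = 1.0
    tss_enrich_halfwidth: int = 500

    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if not str(path).endswith(".json") \
            else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        for key in ("norm_order", "promoter_window", "upstream_window"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.extras = extras
        return cfg


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Collect every violation; an empty list means the config is valid."""
    errors: list[str] = []
    if cfg.peak_min_above > cfg.peak_window_probes:
        errors.append("min_above exceeds window")
    if not 0 < cfg.peak_q < 100:
        errors.append("peak percentile must be in (0, 100)")
    if cfg.profile_span <= 0:
        errors.append("profile span must be positive")
    if cfg.profile_span % cfg.profile_step:
        errors.append("profile span must be a multiple of the step")
    if not 0 < cfg.loess_span <= 1:
        errors.append("loess span must be in (0, 1]")
    if cfg.n_control < 2 or cfg.n_treated < 2:
        errors.append("group sizes must be >= 2")
    if cfg.noise_sd <= 0:
        errors.append("noise_sd must be > 0")
    if cfg.chip_pseudocount <= 0:
        errors.append("chip pseudocount must be > 0")
    if cfg.promoter_window[0] >= cfg.promoter_window[1]:
        errors.append("promoter window is empty")
    if cfg.upstream_window[0] >= cfg.upstream_window[1]:
        errors.append("upstream window is empty")
    if not cfg.simulate:
        for name in ("hmc_tsv", "mc_tsv", "expr_tsv", "gff"):
            path = getattr(cfg, name)
            if not path:
                errors.append(f"{name} is required when simulate is false")
            elif not Path(path).exists():
                errors.append(f"{name} path does not exist: {path}")
    return errors
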