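"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    length: int = 1024
    gc: float = 0.41
    n_individuals: int = 400
    n_sites: int = 80
    n_causal: int = 10
    h2: float = 0.5
    rare_var_share: float | None = None
    protein_altering_fraction: float = 0.02
    n_geno_pcs: int = 5
    n_expr_pcs: int = 5
    n_pwms: int = 3
    pwm_width: int = 6
    maf_mix: dict = field(default_factory=dict)
    ld_block_size: int = 1


@dataclass
class TrainConfig:
    head_hidden: int = 512
    alpha: float = 0.5
    lr_peak: float = 2e-3
    warmup_frac: float = 0.1
    batch_size: int = 8
    accum_steps: int = 8
    epochs: int = 12
    weight_decay: float = 0.02
    patience: int = 5
    conv_channels: tuple = (16,)
    kernels: tuple = (7,)
    dilations: tuple = (1,)
    readout_channels: int = 32


@dataclass
class PipelineConfig:
    """Paths, window geometry, thresholds, model config and seeds.

    ``simulate`` drives the bundled generator; when it is disabled all
    input paths must exist before any compute starts.
    """

    out_dir: str = "s2f_out"
    seed: int = 0
    window_length: int = 1024
    maf_mask_threshold: float = 0.05
    missingness_threshold: int = 2000
    scan_halfwidth: int = 30
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    reference_fasta: str | None = None
    vcf: str | None = None
    expression_tsv: str | None = None
    consequence_tsv: str | None = None
    chromhmm_bed: str | None = None
    ccre_bed: str | None = None
    pwm_meme: str | None = None

    def __post_init__(self) -> None:
        if self.window_length % 2 != 0 or self.window_length < 512:
            raise ValueError("window length must be even and >= 512")
        if self.simulate:
            self.sim.length = self.window_length

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        train = TrainConfig(**raw.pop("train", {}))
        cfg = cls(sim=sim, train=train, **raw)
        return cfg

    def validate_paths(self) -> None:
        """Fail before any compute if declared inputs are missing."""
        if self.simulate:
            return
        required = {
            "reference_fasta": self.reference_fasta,
            "vcf": self.vcf,
            "expression_tsv": self.expression_tsv,
        }
        for name, p in required.items():
            if p is None:
                raise ValueError(f"config error: {name} is required when simulate=false")
            if not Path(p).exists():
                raise FileNotFoundError(f"config error: {name} path {p} does not exist")

    def to_dict(self) -> dict:
        return asdict(self)
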