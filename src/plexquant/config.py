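"""Pipeline configuration: one flat record of every numeric knob.

Defaults are the acquisition and filtering constants of the protocol
(20 ppm precursor / 0.8 Da fragment tolerance, 1% peptide and protein
FDR, total S/N > 200, isolation specificity > 0.75, p <= 0.05 with
fold-change gates 1.3 / 0.77) plus the simulator's study conditions.
Round-trips through YAML byte-identically.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0

    # synthetic study conditions
    n_proteins: int = 200
    frac_differential: float = 0.1
    fc_low: float = 1.5
    fc_high: float = 3.0
    biological_cv: float = 0.2
    tissues: tuple[str, ...] = ("retina", "vitreous")
    interference_beta_a: float = 2.0
    interference_beta_b: float = 18.0
    noise_baseline: float = 1.0
    noise_sd: float = 2.0
    reporter_yield: float = 50.0
    psm_depth: float = 3.0

    # digestion / search
    max_missed: int = 2
    min_length: int = 6
    precursor_tol_ppm: float = 20.0
    fragment_tol_da: float = 0.8

    # identification filters
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01
    fdr_plus_one: bool = False

    # quantifiability filters
    min_total_sn: float = 200.0
    min_specificity: float = 0.75

    # normalization / aggregation
    plex_scaling: str = "row_mean"

    # differential thresholds
    alpha: float = 0.05
    up_fc: float = 1.3
    down_fc: float = 0.77
    min_n: int = 3
    equal_var: bool = True
    log_scale: bool = True

    def __post_init__(self):
        self.tissues = tuple(self.tissues)
        self.validate()

    def validate(self) -> None:
        positive = (
            "precursor_tol_ppm", "fragment_tol_da", "peptide_fdr", "protein_fdr",
            "min_total_sn", "min_specificity", "alpha", "up_fc", "down_fc",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.down_fc >= self.up_fc:
            raise ValueError(
                f"down_fc ({self.down_fc}) must be below up_fc ({self.up_fc})"
            )
        if self.fc_low <= 0 or self.fc_low > self.fc_high:
            raise ValueError("fc range must be positive with low <= high")
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("frac_differential must be in [0, 1]")

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["tissues"] = list(d["tissues"])
        text = yaml.safe_dump(d, sort_keys=True, default_flow_style=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else str(source)
        d = yaml.safe_load(text)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def fc_range(self) -> tuple[float, float]:
        return (self.fc_low, self.fc_high)

    @property
    def interference(self) -> tuple:
        return ("beta", self.interference_beta_a, self.interference_beta_b)
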