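"""Pipeline configuration: defaults, YAML (de)serialization, config hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Tuple

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable settings of the windowed coalescent analysis.

    ``L0`` is the base window length in bases (80 bp is appropriate for
    human-like polymorphism densities); windows below ``coverage_floor``
    called-site fraction are dropped and windows above it are thinned to
    it. The transform grid spans ``z_span`` in units of 1/pi_hat with
    ``z_count`` log-uniform points. ``rel_err_threshold`` screens
    transform points entering the sigmoid fits; ``retention_sigma`` is
    the asymptote trust band. ``form`` selects the inversion family.
    """

    stat: str = "pairwise"
    L0: int = 80
    coverage_floor: float = 0.8
    min_valid_windows: int = 100
    z_span: Tuple[float, float] = (1e-2, 1e3)
    z_count: int = 32
    rel_err_threshold: float = 0.1
    retention_sigma: float = 3.0
    form: str = "piecewise_exponential"
    penalty_weight: float = 1.0
    allow_point_mass: bool = False
    restarts: int = 50
    seed: int = 0
    outdir: str = "wincoal_out"

    def __post_init__(self):
        if self.L0 < 1:
            raise ValueError("L0 must be >= 1")
        if not (0 < self.coverage_floor <= 1):
            raise ValueError("coverage_floor must be in (0, 1]")
        if self.z_count < 4:
            raise ValueError("z_count must be >= 4")
        if self.z_span[0] <= 0 or self.z_span[1] <= self.z_span[0]:
            raise ValueError("z_span must be an increasing positive pair")
        if self.form not in ("piecewise_exponential", "gamma_mixture"):
            raise ValueError(f"unknown inversion form {self.form!r}")
        if self.rel_err_threshold <= 0 or self.retention_sigma <= 0:
            raise ValueError("thresholds must be positive")
        self.z_span = tuple(float(x) for x in self.z_span)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["z_span"] = list(d["z_span"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "z_span" in d:
            d["z_span"] = tuple(d["z_span"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def hash(self) -> str:
        """Short digest identifying the analysis settings; stamped on outputs.

        The output directory does not enter the hash: it has no effect on
        the computed results.
        """
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
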