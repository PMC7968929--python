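"""Run configuration: one serializable object reproduces a whole run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dynamics import ModelParameters
from .synthetic_data import ReadoutParams


@dataclass
class RunConfig:
    """Everything a pipeline run needs, YAML round-trippable."""

    k_L: float = 1.0
    k_C: float = 1.0
    delta: float = 1.0
    K: float = 0.1
    mu: float = 0.0
    tau: float = 0.4
    fold: float = 3.0
    chain_readthrough: bool = False
    # grids as (lo, hi, n); K grid is logarithmic
    grid_K: tuple[float, float, int] = (1e-3, 10.0, 25)
    grid_mu: tuple[float, float, int] = (0.0, 1.0, 21)
    # synthetic readout
    gain: float = 1e4
    background: float = 100.0
    K_R: float = 0.35
    hill_readout: float = 4.0
    cv: float = 0.1
    n_reps: int = 3
    seed: int = 0

    def model_params(self) -> ModelParameters:
        return ModelParameters(
            k_L=self.k_L,
            k_C=self.k_C,
            delta=self.delta,
            K=self.K,
            mu=self.mu,
            tau=self.tau,
            chain_readthrough=self.chain_readthrough,
        )

    def readout_params(self) -> ReadoutParams:
        return ReadoutParams(
            gain=self.gain,
            background=self.background,
            K_R=self.K_R,
            hill=self.hill_readout,
            cv=self.cv,
            seed=self.seed,
        )

    def K_grid(self):
        import numpy as np

        lo, hi, n = self.grid_K
        return np.logspace(np.log10(lo), np.log10(hi), int(n))

    def mu_grid(self):
        import numpy as np

        lo, hi, n = self.grid_mu
        return np.linspace(lo, hi, int(n))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["grid_K"] = list(d["grid_K"])
        d["grid_mu"] = list(d["grid_mu"])
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: not a mapping")
        for key in ("grid_K", "grid_mu"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
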