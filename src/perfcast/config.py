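"""Run configuration: every tunable with its default, YAML-compatible on disk.

The file format is a flat ``key: value`` mapping (dotted keys), e.g.::

    grid.N: 9
    lasso.lambda: 1.0e-5
    weights: [1, 1, 1, 1, 75]

Unknown keys are rejected; the resolved configuration and its hash are
embedded in every artifact a run writes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .joint import DEFAULT_WIDTHS, LassoConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    kde_bandwidth_scale: float = 1.0
    grid_n: int = 21                      # lattice points per axis (odd)
    grid_k: int = 41                      # marginal evaluation points
    widths: tuple[float, ...] = DEFAULT_WIDTHS
    lasso_lambda: float = 1e-5
    lasso_threshold: float = 1e-9
    lasso_target_nnz: int = 400
    lasso_max_outer: int = 50
    weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 75.0)
    fusion_n_components: int = 6
    solver_max_majors: int = 2000
    solver_gap_tol: float = 1e-9
    seed: int = 0

    _KEYMAP = {
        "kde.bandwidth_scale": "kde_bandwidth_scale",
        "grid.N": "grid_n",
        "grid.K": "grid_k",
        "widths": "widths",
        "lasso.lambda": "lasso_lambda",
        "lasso.threshold": "lasso_threshold",
        "lasso.target_nnz": "lasso_target_nnz",
        "lasso.max_outer": "lasso_max_outer",
        "weights": "weights",
        "fusion.N_c": "fusion_n_components",
        "solver.max_majors": "solver_max_majors",
        "solver.gap_tol": "solver_gap_tol",
        "seed": "seed",
    }

    def __post_init__(self) -> None:
        if self.grid_n < 3 or self.grid_n % 2 == 0:
            raise ValueError("grid.N must be an odd integer >= 3")
        if self.grid_k < 2:
            raise ValueError("grid.K must be >= 2")
        if len(self.weights) != 5:
            raise ValueError("weights must list five block weights")
        if self.lasso_lambda <= 0 or self.lasso_threshold <= 0:
            raise ValueError("lasso.lambda and lasso.threshold must be positive")
        object.__setattr__(self, "widths", tuple(float(w) for w in self.widths))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        """Desk-scale profile: N=9 lattice instead of the production N=21."""
        return cls(grid_n=9, **overrides)

    def lasso_config(self) -> LassoConfig:
        return LassoConfig(
            lam=self.lasso_lambda,
            threshold=self.lasso_threshold,
            target_nnz=self.lasso_target_nnz,
            max_outer_iters=self.lasso_max_outer,
            solver_max_majors=self.solver_max_majors,
            solver_gap_tol=self.solver_gap_tol,
        )

    def to_dict(self) -> dict:
        inv = {v: k for k, v in self._KEYMAP.items()}
        out = {}
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            val = getattr(self, f.name)
            out[inv[f.name]] = list(val) if isinstance(val, tuple) else val
        return out

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        for key, value in data.items():
            if key not in cls._KEYMAP:
                raise ValueError(f"unknown configuration key {key!r}")
            name = cls._KEYMAP[key]
            if name in ("widths", "weights"):
                value = tuple(float(v) for v in value)
            kwargs[name] = value
        return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must be a flat key: value mapping")
    return RunConfig.from_dict(data)
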