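"""Latent-scale fusion of heterogeneous stress measures.

Stress is observed through several incommensurable instruments (salivary
cortisol, alpha amylase, heart rate, subjective ratings). Each source i is
modeled as an affine readout of a single latent stress variable s,

    d_{i,j} = a_i s_j + b_i,

with the latent density a mixture of N_c Gaussians,

    p_S(s) = sum_c alpha_c N(s; mu_c, sigma_c^2).

All parameters Theta = {a_i, b_i, alpha_c, mu_c, sigma_c} are estimated by a
single joint maximum-likelihood fit: each observed datum contributes
-log [ (1/|a_i|) p_S((d - b_i)/a_i) ]. The affine family makes the latent
scale identifiable only up to an affine change of variable, so the scale is
anchored by freezing source 1's (a, b) at their initialization (sample sd and
mean), which makes the latent axis a generalized z-score of source 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .marginals import GridPDF, SourceSeries

__all__ = [
    "AffineSourceModel",
    "LatentMixture",
    "FusionModel",
    "init_fusion",
    "source_density",
    "negative_log_likelihood",
    "fit_ml",
    "fused_marginal",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class AffineSourceModel:
    """d = a*s + b readout of the latent scale for one source."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("scale a must be nonzero")


@dataclass(frozen=True)
class LatentMixture:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (w.shape == m.shape == s.shape and w.ndim == 1):
            raise ValueError("weights/means/sds must be equal-length vectors")
        if np.any(w < 0) or np.any(w > 1) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must lie in [0,1] and sum to 1")
        if np.any(s <= 0):
            raise ValueError("all component sds must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @property
    def n_components(self) -> int:
        return int(self.weights.size)

    def logpdf(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        z = (s[:, None] - self.means[None, :]) / self.sds[None, :]
        comp = (np.log(self.weights[None, :]) - np.log(self.sds[None, :])
                - 0.5 * _LOG_2PI - 0.5 * z * z)
        return logsumexp(comp, axis=1)

    def pdf(self, s) -> np.ndarray:
        return np.exp(self.logpdf(s))


@dataclass(frozen=True)
class FusionModel:
    source_models: tuple[AffineSourceModel, ...]
    mixture: LatentMixture

    def to_json(self, path: str | Path, config_hash: str = "") -> None:
        payload = {
            "anchor": "source 1 affine parameters frozen at sample sd/mean",
            "config_hash": config_hash,
            "sources": [{"a": m.a, "b": m.b} for m in self.source_models],
            "mixture": {
                "weights": self.mixture.weights.tolist(),
                "means": self.mixture.means.tolist(),
                "sds": self.mixture.sds.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            tuple(AffineSourceModel(s["a"], s["b"]) for s in d["sources"]),
            LatentMixture(np.array(d["mixture"]["weights"]),
                          np.array(d["mixture"]["means"]),
                          np.array(d["mixture"]["sds"])),
        )


def init_fusion(sources: Sequence[SourceSeries], n_components: int = 6) -> FusionModel:
    """Initialization for the joint ML fit.

    Per-source affine parameters start at the sample sd (a_i) and sample mean
    (b_i), so each source's z-scores are the initial latent mapping. The
    latent mixture starts as n_components Gaussians of identical weight and
    width 1/N_c, with means linearly spaced over [-2, 4]:

        mu_c = -2 + 6 (c - 1) / (N_c - 1),  c = 1..N_c.
    """
    if n_components < 2:
        raise ValueError("need at least 2 mixture components")
    models = []
    for s in sources:
        if s.n < 2:
            raise ValueError(f"source {s.source_id!r} needs n >= 2")
        sd = float(np.std(s.values, ddof=1))
        if sd == 0:
            raise ValueError(f"source {s.source_id!r} has zero variance")
        models.append(AffineSourceModel(a=sd, b=float(np.mean(s.values))))
    nc = n_components
    mixture = LatentMixture(
        weights=np.full(nc, 1.0 / nc),
        means=-2.0 + 6.0 * np.arange(nc) / (nc - 1),
        sds=np.full(nc, 1.0 / nc),
    )
    return FusionModel(tuple(models), mixture)


def source_density(d, theta: AffineSourceModel, mixture: LatentMixture) -> np.ndarray:
    """Observed-data density (1/|a|) p_S((d - b)/a) under one source model."""
    d = np.asarray(d, dtype=float)
    out = mixture.pdf((np.atleast_1d(d) - theta.b) / theta.a) / abs(theta.a)
    return out if d.ndim else float(out[0])


def negative_log_likelihood(model: FusionModel, sources: Sequence[SourceSeries]) -> float:
    """Joint NLL: sum over sources and data of -log p(d | theta_i)."""
    if len(sources) != len(model.source_models):
        raise ValueError("sources do not align with model's source_models")
    total = 0.0
    for s, theta in zip(sources, model.source_models):
        lp = model.mixture.logpdf((s.values - theta.b) / theta.a)
        total -= float(np.sum(lp)) - s.n * np.log(abs(theta.a))
    return total


def _pack(model: FusionModel) -> np.ndarray:
    """Free parameters: sources 2..N (log a, b), weight logits 2..Nc, means, log(sd - floor)."""
    mix = model.mixture
    parts = []
    for m in model.source_models[1:]:
        parts.extend([np.log(abs(m.a)), m.b])
    logits = np.log(np.maximum(mix.weights, 1e-300))
    parts.extend(logits[1:] - logits[0])
    parts.extend(mix.means)
    parts.extend(np.log(np.maximum(mix.sds - SIGMA_FLOOR, 1e-300)))
    return np.array(parts, dtype=float)


def _unpack(x: np.ndarray, anchor: AffineSourceModel, n_sources: int,
            n_components: int) -> FusionModel:
    i = 0
    models = [anchor]
    for _ in range(n_sources - 1):
        models.append(AffineSourceModel(a=float(np.exp(x[i])), b=float(x[i + 1])))
        i += 2
    nc = n_components
    logits = np.concatenate([[0.0], x[i:i + nc - 1]])
    i += nc - 1
    w = np.exp(logits - logsumexp(logits))
    w = w / w.sum()
    means = x[i:i + nc].copy()
    i += nc
    sds = SIGMA_FLOOR + np.exp(x[i:i + nc])
    return FusionModel(tuple(models), LatentMixture(w, means, sds))


def fit_ml(sources: Sequence[SourceSeries], init: FusionModel | None = None,
           maxiter: int = 2000) -> FusionModel:
    """Joint maximum-likelihood fit of all fusion parameters.

    A deterministic bounded quasi-Newton (L-BFGS-B) descent from the standard
    initialization. Source 1's affine parameters stay frozen at their
    initialization to anchor the latent scale; sds are kept above
    ``SIGMA_FLOOR`` by a log reparameterization and weights on the simplex by
    a softmax with the first logit pinned to 0. If the optimizer fails to
    improve on the initialization, the initialization is returned with a
    warning rather than raising.
    """
    if init is None:
        init = init_fusion(sources)
    anchor = init.source_models[0]
    n_sources = len(init.source_models)
    nc = init.mixture.n_components

    def objective(x: np.ndarray) -> float:
        try:
            model = _unpack(x, anchor, n_sources, nc)
        except (ValueError, FloatingPointError):
            return 1e12
        val = negative_log_likelihood(model, sources)
        return val if np.isfinite(val) else 1e12

    x0 = _pack(init)
    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9})
    fitted = _unpack(res.x, anchor, n_sources, nc)
    if negative_log_likelihood(fitted, sources) > negative_log_likelihood(init, sources):
        logger.warning("ML fit failed to improve on initialization; returning init")
        return init
    return fitted


def fused_marginal(model: FusionModel, lo: float | None = None,
                   hi: float | None = None, grid_points: int = 1001) -> GridPDF:
    """Tabulate the latent stress density p_S(s) as a GridPDF."""
    mix = model.mixture
    if lo is None:
        lo = float(np.min(mix.means - 6.0 * mix.sds))
    if hi is None:
        hi = float(np.max(mix.means + 6.0 * mix.sds))
    grid = np.linspace(lo, hi, grid_points)
    density = mix.pdf(grid)
    density = density / np.trapezoid(density, grid)
    return GridPDF(grid, density)
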