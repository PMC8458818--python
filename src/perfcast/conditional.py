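"""Closed-form conditional outcome densities and their summaries.

For a joint density that is a mixture of isotropic Gaussians, conditioning
on the predictor vector x is exact: each component factorizes into a 3-D
Gaussian in x times a univariate Gaussian in y, so

    p(y | x) = sum_i w_i(x) N(y; mu_{y,i}, sigma_i^2),
    w_i(x) proportional to alpha_i N_3(x; mu_{x,i}, sigma_i^2 I),

with the weights renormalized to sum to one. The conditional is tabulated on
the outcome grid and summarized (mean, sd, mode, median, percentiles, skew,
excess kurtosis, central interval), with every location/scale statistic
mapped back to physical units through the stored axis transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .marginals import AxisTransform, GridPDF
from .joint import JointModel

__all__ = ["ConditionalSummary", "condition", "summarize", "batch_predict"]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ConditionalSummary:
    """Summary statistics of one conditional outcome density (physical units)."""

    mean: float
    sd: float
    mode: float
    median: float
    percentiles: dict[float, float]
    skew: float
    excess_kurtosis: float
    interval: tuple[float, float]
    interval_level: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        levels = sorted(self.percentiles)
        vals = [self.percentiles[q] for q in levels]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("percentile map must be monotone in level")


def _clamp_point(x: np.ndarray) -> np.ndarray:
    if np.any(np.abs(x) > 1.0):
        logger.warning("conditioning point %s outside [-1,1]^3; clamping", x)
    return np.clip(x, -1.0, 1.0)


def condition(
    model: JointModel,
    x: Sequence[float],
    grid_points: int = 513,
    physical: bool = False,
) -> tuple[GridPDF, np.ndarray]:
    """Conditional outcome density p(y | x1, x2, x3) and component weights.

    ``x`` is the 3-vector of predictor coordinates, normalized by default or
    in physical units when ``physical`` is set (mapped through the stored
    axis transforms and clamped to [-1, 1] with a warning). Returns the
    tabulated conditional on the normalized outcome grid together with the
    per-component mixture weights.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError("x must be a 3-vector of predictor values")
    if physical:
        mapped = []
        for j, v in enumerate(x, start=1):
            tr = model.axis_transforms[j]
            if tr is None:
                raise ValueError(f"axis {j} has no transform; pass normalized values")
            mapped.append(float(tr.forward(v)))
        x = np.asarray(mapped)
    x = _clamp_point(x)

    mu = model.centers()
    sig = model.sigmas()
    # log of alpha_i * N_3(x; mu_{x,i}, sigma_i^2 I)
    d2 = np.sum((x[None, :] - mu[:, 1:]) ** 2, axis=1)
    logw = (np.log(model.coefficients) - 1.5 * _LOG_2PI - 3.0 * np.log(sig)
            - 0.5 * d2 / sig**2)
    m = float(np.max(logw))
    denom = float(np.exp(m) * np.sum(np.exp(logw - m)))
    if not denom > 1e-300:
        raise ValueError("conditioning point outside model support")
    w = np.exp(logw - m)
    w = w / w.sum()

    grid = np.linspace(-1.0, 1.0, grid_points)
    z = (grid[:, None] - mu[None, :, 0]) / sig[None, :]
    comp = np.exp(-0.5 * z * z) / (sig[None, :] * np.sqrt(2.0 * np.pi))
    density = comp @ w
    density = density / np.trapezoid(density, grid)
    return GridPDF(grid, density, transform=model.axis_transforms[0]), w


def _refine_mode(grid: np.ndarray, density: np.ndarray) -> float:
    """Grid argmax refined by a local quadratic fit; smallest mode on ties."""
    peak = float(np.max(density))
    ties = np.nonzero(np.isclose(density, peak, rtol=1e-12, atol=0.0))[0]
    if ties.size > 1:
        logger.warning("multimodal tie for mode; returning smallest-value mode")
    k = int(ties[0])
    if 0 < k < grid.size - 1:
        y0, y1, y2 = density[k - 1], density[k], density[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            offset = 0.5 * (y0 - y2) / denom
            h = grid[k + 1] - grid[k]
            return float(grid[k] + np.clip(offset, -0.5, 0.5) * h)
    return float(grid[k])


def summarize(
    cond: GridPDF,
    transform: AxisTransform | None = None,
    levels: Sequence[float] = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975),
    interval_level: float = 0.95,
) -> ConditionalSummary:
    """Quadrature summary of a conditional density, in physical units.

    Moments by trapezoidal quadrature on the grid; median/percentiles via the
    interpolated inverse CDF; the interval is the central ``interval_level``
    predictive interval. ``transform`` (defaulting to the one carried by the
    density) maps locations and scale back to physical units; skew and excess
    kurtosis are affine-invariant and reported as-is.
    """
    tr = transform if transform is not None else cond.transform
    g, d = cond.grid, cond.density
    mean = float(np.trapezoid(g * d, g))
    var = float(np.trapezoid((g - mean) ** 2 * d, g))
    sd = float(np.sqrt(max(var, 0.0)))
    if sd > 0:
        skew = float(np.trapezoid((g - mean) ** 3 * d, g) / sd**3)
        kurt = float(np.trapezoid((g - mean) ** 4 * d, g) / sd**4 - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    mode = _refine_mode(g, d)

    want = sorted(set(levels) | {0.5, (1 - interval_level) / 2, (1 + interval_level) / 2})
    qvals = cond.quantile(want)
    qmap = dict(zip(want, (float(v) for v in qvals)))
    median = qmap[0.5]
    lo = qmap[(1 - interval_level) / 2]
    hi = qmap[(1 + interval_level) / 2]

    if tr is not None:
        scale = tr.half_width
        to_phys = lambda v: float(tr.inverse(v))
        mean, mode, median = to_phys(mean), to_phys(mode), to_phys(median)
        lo, hi = to_phys(lo), to_phys(hi)
        sd = sd * scale
        pct = {q: to_phys(qmap[q]) for q in levels}
    else:
        pct = {q: qmap[q] for q in levels}

    return ConditionalSummary(
        mean=mean, sd=sd, mode=mode, median=median, percentiles=pct,
        skew=skew, excess_kurtosis=kurt, interval=(lo, hi),
        interval_level=interval_level,
    )


def batch_predict(
    models: Mapping[str, JointModel],
    x: Sequence[float],
    levels: Sequence[float] = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975),
    interval_level: float = 0.95,
    physical: bool = False,
) -> dict[str, ConditionalSummary]:
    """One ConditionalSummary per outcome model for a single predictor point.

    All models must share predictor axis transforms so that one physical
    input vector means the same thing for every outcome.
    """
    items = list(models.items())
    if not items:
        raise ValueError("need at least one outcome model")
    ref = items[0][1].axis_transforms[1:]
    for name, m in items[1:]:
        for j, (a, b) in enumerate(zip(ref, m.axis_transforms[1:]), start=1):
            same = (a is None and b is None) or (
                a is not None and b is not None
                and np.isclose(a.physical_lo, b.physical_lo)
                and np.isclose(a.physical_hi, b.physical_hi))
            if not same:
                raise ValueError(
                    f"model {name!r} predictor axis {j} transform mismatch")
    out = {}
    for name, m in items:
        cond, _ = condition(m, x, physical=physical)
        out[name] = summarize(cond, levels=levels, interval_level=interval_level)
    return out
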