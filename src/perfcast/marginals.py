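"""Marginal density estimation from pooled multi-source observations.

Each of the six model variables (three predictors: stress, sleep, physical
exertion; three outcomes: reaction time, executive-function error rate,
perceptuo-motor error rate) gets a one-dimensional marginal PDF. Sources
reporting the same variable in a common unit are pooled: the marginal is the
count-weighted mixture of per-source Gaussian kernel density estimates,

    p(v) = sum_k pi_k p(v | F_k),   pi_k = n_k / sum_j n_j,

tabulated on a regular grid. For downstream joint-density construction the
physical axis is mapped affinely onto [-1, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "SourceSeries",
    "AxisTransform",
    "GridPDF",
    "MomentSummary",
    "moving_average_error",
    "pool_weights",
    "estimate_marginal",
    "moments",
    "normalize_axis",
    "convert_units",
    "read_sources_csv",
    "write_sources_csv",
]

VARIABLES = (
    "stress",
    "sleep",
    "exertion",
    "reaction_time",
    "executive_function",
    "perceptuo_motor",
)


@dataclass(frozen=True)
class SourceSeries:
    """Observations of one variable from one data source, in one unit."""

    source_id: str
    variable: str
    unit: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in source {self.source_id!r}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AxisTransform:
    """Affine map between a physical interval and the normalized axis [-1, 1]."""

    physical_lo: float
    physical_hi: float

    def __post_init__(self) -> None:
        if not self.physical_lo < self.physical_hi:
            raise ValueError("physical_lo must be < physical_hi")

    @property
    def half_width(self) -> float:
        return 0.5 * (self.physical_hi - self.physical_lo)

    def forward(self, x):
        """Physical -> normalized [-1, 1]."""
        x = np.asarray(x, dtype=float)
        return (x - self.physical_lo) / self.half_width - 1.0

    def inverse(self, u):
        """Normalized [-1, 1] -> physical."""
        u = np.asarray(u, dtype=float)
        return self.physical_lo + (u + 1.0) * self.half_width

    def to_dict(self) -> dict:
        return {"physical_lo": self.physical_lo, "physical_hi": self.physical_hi}

    @classmethod
    def from_dict(cls, d: dict) -> "AxisTransform":
        return cls(float(d["physical_lo"]), float(d["physical_hi"]))


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")


_INTEGRAL_TOL = 1e-6


@dataclass(frozen=True)
class GridPDF:
    """A 1-D density tabulated on a strictly increasing grid.

    ``transform`` records the affine map used when the grid lives on the
    normalized [-1, 1] axis; ``None`` means the grid is in physical units.
    """

    grid: np.ndarray
    density: np.ndarray
    transform: AxisTransform | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if g.ndim != 1 or g.size < 3:
            raise ValueError("grid must have at least 3 points")
        if d.shape != g.shape:
            raise ValueError("grid and density must have equal length")
        if not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("density must be nonnegative")
        total = np.trapezoid(d, g)
        if abs(total - 1.0) > _INTEGRAL_TOL:
            raise ValueError(f"density integrates to {total:.8f}, not 1")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "density", d)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def interpolate(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.density,
                         left=0.0, right=0.0)

    def cdf(self) -> np.ndarray:
        """Cumulative trapezoidal integral along the grid, clipped to [0, 1]."""
        steps = np.diff(self.grid) * 0.5 * (self.density[:-1] + self.density[1:])
        c = np.concatenate([[0.0], np.cumsum(steps)])
        return np.clip(c / c[-1], 0.0, 1.0)

    def quantile(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        c = self.cdf()
        # make the CDF strictly increasing for interpolation
        c = np.maximum.accumulate(c + np.arange(c.size) * 1e-15)
        return np.interp(q, c / c[-1], self.grid)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"transform": self.transform.to_dict() if self.transform else None}
        with path.open("w", encoding="utf-8") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            fh.write("grid,density\n")
            for g, d in zip(self.grid, self.density):
                fh.write(f"{float(g)!r},{float(d)!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GridPDF":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing JSON metadata header")
            meta = json.loads(header[1:].strip())
            df = pd.read_csv(fh, float_precision="round_trip")
        tr = meta.get("transform")
        transform = AxisTransform.from_dict(tr) if tr else None
        return cls(df["grid"].to_numpy(), df["density"].to_numpy(), transform)


def moving_average_error(trial_outcomes: Sequence[float], window: int = 5) -> np.ndarray:
    """Convert a binary per-trial error sequence into windowed error rates.

    Returns ``len(trial_outcomes) - window + 1`` means of contiguous windows,
    each in [0, 1].
    """
    x = np.asarray(trial_outcomes, dtype=float)
    if window < 1:
        raise ValueError("window must be a positive integer")
    if x.ndim != 1 or x.size < window:
        raise ValueError(f"need at least {window} trials, got {x.size}")
    if np.any((x != 0) & (x != 1)):
        raise ValueError("trial outcomes must be binary (0 = correct, 1 = error)")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(x, kernel, mode="valid")


def _check_common(sources: Sequence[SourceSeries]) -> None:
    if len(sources) == 0:
        raise ValueError("need at least one source")
    variables = {s.variable for s in sources}
    units = {s.unit for s in sources}
    if len(variables) > 1:
        raise ValueError(f"sources mix variables: {sorted(variables)}")
    if len(units) > 1:
        raise ValueError(f"sources mix units: {sorted(units)}; convert first")


def pool_weights(sources: Sequence[SourceSeries]) -> np.ndarray:
    """Pooling weights pi_k = n_k / sum(n), exact on the rationals."""
    _check_common(sources)
    total = sum(s.n for s in sources)
    fracs = [Fraction(s.n, total) for s in sources]
    assert sum(fracs) == 1
    return np.array([float(f) for f in fracs])


def _source_bandwidth(s: SourceSeries, scale: float) -> float:
    """Scott's rule bandwidth for one source, times the global multiplier."""
    sd = float(np.std(s.values, ddof=1)) if s.n > 1 else 0.0
    if sd == 0.0:
        raise ValueError(f"source {s.source_id!r} has no spread; bandwidth undefined")
    return scale * sd * s.n ** (-1.0 / 5.0)


def estimate_marginal(
    sources: Sequence[SourceSeries],
    bandwidth_scale: float = 1.0,
    grid_points: int = 512,
    padding_bandwidths: float = 3.0,
) -> GridPDF:
    """Pooled kernel density estimate of one variable's marginal PDF.

    The density is the pi-weighted sum of per-source Gaussian KDEs (Scott's
    rule per source, scaled by ``bandwidth_scale``), tabulated on
    ``grid_points`` equally spaced points covering the pooled data range
    padded by ``padding_bandwidths`` pooled bandwidths, then renormalized so
    the trapezoidal integral is exactly 1.
    """
    _check_common(sources)
    weights = pool_weights(sources)
    bandwidths = [_source_bandwidth(s, bandwidth_scale) for s in sources]

    lo = min(float(s.values.min()) for s in sources)
    hi = max(float(s.values.max()) for s in sources)
    pad = padding_bandwidths * float(np.dot(weights, bandwidths))
    grid = np.linspace(lo - pad, hi + pad, grid_points)

    density = np.zeros_like(grid)
    for w, s in zip(weights, sources):
        # gaussian_kde kernel sd = factor * sample sd; Scott factor is n^(-1/5)
        kde = gaussian_kde(s.values, bw_method=bandwidth_scale * s.n ** (-0.2))
        density += w * kde(grid)
    density /= np.trapezoid(density, grid)
    return GridPDF(grid, density)


def moments(pdf: GridPDF, integral_tol: float = 1e-3) -> MomentSummary:
    """Mean and standard deviation of a tabulated density by quadrature."""
    total = pdf.integral()
    if abs(total - 1.0) > integral_tol:
        raise ValueError(f"density not normalized (integral {total:.6f})")
    mean = float(np.trapezoid(pdf.grid * pdf.density, pdf.grid))
    var = float(np.trapezoid((pdf.grid - mean) ** 2 * pdf.density, pdf.grid))
    return MomentSummary(mean=mean, sd=float(np.sqrt(max(var, 0.0))))


def normalize_axis(
    pdf: GridPDF,
    lo_q: float = 0.001,
    hi_q: float = 0.999,
    grid_points: int | None = None,
) -> GridPDF:
    """Map a physical-axis density onto the normalized [-1, 1] axis.

    The physical interval [quantile(lo_q), quantile(hi_q)] is mapped affinely
    onto [-1, 1]; density values are interpolated, multiplied by the Jacobian
    (half the physical width), and renormalized (the <=(lo_q + 1 - hi_q))
    clipped tail mass is redistributed proportionally).
    """
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise ValueError("need 0 <= lo_q < hi_q <= 1")
    if pdf.transform is not None:
        raise ValueError("density is already on the normalized axis")
    p_lo, p_hi = (float(v) for v in pdf.quantile([lo_q, hi_q]))
    if not p_hi > p_lo:
        raise ValueError("degenerate support: quantile bounds coincide")
    transform = AxisTransform(p_lo, p_hi)
    n = grid_points if grid_points is not None else pdf.grid.size
    grid = np.linspace(-1.0, 1.0, n)
    density = pdf.interpolate(transform.inverse(grid)) * transform.half_width
    density = density / np.trapezoid(density, grid)
    return GridPDF(grid, density, transform=transform)


def denormalize_axis(pdf: GridPDF, grid_points: int | None = None) -> GridPDF:
    """Inverse of :func:`normalize_axis`: back to the physical axis."""
    if pdf.transform is None:
        raise ValueError("density carries no axis transform")
    tr = pdf.transform
    n = grid_points if grid_points is not None else pdf.grid.size
    grid = np.linspace(tr.physical_lo, tr.physical_hi, n)
    density = np.interp(tr.forward(grid), pdf.grid, pdf.density) / tr.half_width
    density = density / np.trapezoid(density, grid)
    return GridPDF(grid, density, transform=None)


def convert_units(series: SourceSeries, factor: float, offset: float = 0.0,
                  new_unit: str | None = None) -> SourceSeries:
    """Affine unit conversion: values' = factor * values + offset."""
    if factor == 0:
        raise ValueError("conversion factor must be nonzero")
    unit = new_unit if new_unit is not None else f"{series.unit}*{factor}+{offset}"
    return replace(series, values=factor * series.values + offset, unit=unit)


def read_sources_csv(path: str | Path) -> list[SourceSeries]:
    """Read observation rows (``source_id,variable,unit,value``) into series."""
    df = pd.read_csv(path)
    required = {"source_id", "variable", "unit", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (sid, var, unit), group in df.groupby(
            ["source_id", "variable", "unit"], sort=True):
        out.append(SourceSeries(str(sid), str(var), str(unit),
                                group["value"].to_numpy(dtype=float)))
    return out


def write_sources_csv(sources: Sequence[SourceSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "source_id": s.source_id, "variable": s.variable,
            "unit": s.unit, "value": s.values,
        })
        for s in sources
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
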