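"""Literature effect sizes as correlation constraints.

The joint-density construction consumes, for every predictor-outcome pair, a
correlation coefficient r harvested from meta-analyses and primary studies.
Effect sizes reported on other scales (Cohen's d, Hedges' g) are converted to
r through the standard point-biserial relation; multiple studies of the same
pair are pooled by inverse-variance weighting on the Fisher-z scale.

The packaged default matrix holds the nine predictor x outcome coefficients
(stress / sleep / physical exertion against reaction time / executive
function / perceptuo-motor control) with 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectSizeEntry",
    "EffectSizeMatrix",
    "to_correlation",
    "aggregate",
    "default_matrix",
    "PREDICTORS",
    "OUTCOMES",
]

PREDICTORS = ("stress", "sleep", "exertion")
OUTCOMES = ("reaction_time", "executive_function", "perceptuo_motor")


@dataclass(frozen=True)
class EffectSizeEntry:
    predictor: str
    outcome: str
    r: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError("r must lie strictly inside (-1, 1)")
        if not self.ci_lo <= self.r <= self.ci_hi:
            raise ValueError("confidence bounds must bracket r")


class EffectSizeMatrix:
    """Complete predictor x outcome table of correlation coefficients."""

    def __init__(self, entries: Iterable[EffectSizeEntry],
                 predictors: Sequence[str] = PREDICTORS,
                 outcomes: Sequence[str] = OUTCOMES) -> None:
        self.predictors = tuple(predictors)
        self.outcomes = tuple(outcomes)
        self._entries: dict[tuple[str, str], EffectSizeEntry] = {}
        for e in entries:
            key = (e.predictor, e.outcome)
            if key in self._entries:
                raise ValueError(f"duplicate entry for {key}")
            self._entries[key] = e
        missing = [
            (p, o) for p in self.predictors for o in self.outcomes
            if (p, o) not in self._entries
        ]
        if missing:
            raise ValueError(f"incomplete matrix; missing pairs {missing}")

    def __getitem__(self, key: tuple[str, str]) -> EffectSizeEntry:
        return self._entries[key]

    def r(self, predictor: str, outcome: str) -> float:
        return self._entries[(predictor, outcome)].r

    def entries(self) -> list[EffectSizeEntry]:
        return [self._entries[(p, o)] for p in self.predictors for o in self.outcomes]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([
            {"predictor": e.predictor, "outcome": e.outcome,
             "r": repr(e.r), "ci_lo": repr(e.ci_lo), "ci_hi": repr(e.ci_hi)}
            for e in self.entries()
        ]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EffectSizeMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        entries = [
            EffectSizeEntry(str(row.predictor), str(row.outcome),
                            float(row.r), float(row.ci_lo), float(row.ci_hi))
            for row in df.itertuples()
        ]
        preds, outs = [], []
        for e in entries:
            if e.predictor not in preds:
                preds.append(e.predictor)
            if e.outcome not in outs:
                outs.append(e.outcome)
        return cls(entries, predictors=preds, outcomes=outs)


def to_correlation(value: float, measure: str, n1: int | None = None,
                   n2: int | None = None) -> float:
    """Convert an effect size to a correlation coefficient.

    ``measure`` is one of ``"r"`` (passthrough), ``"cohens_d"`` or
    ``"hedges_g"`` (point-biserial relation r = d / sqrt(d^2 + h) with
    h = (n1 + n2)^2 / (n1 * n2); h = 4 under the equal-group assumption when
    group sizes are absent). Hedges' g is treated as d on this scale.
    """
    if measure == "r":
        if not abs(value) < 1:
            raise ValueError("|r| must be < 1")
        return float(value)
    if measure in ("cohens_d", "hedges_g"):
        if (n1 is None) != (n2 is None):
            raise ValueError("provide both group sizes or neither")
        if n1 is None:
            h = 4.0
        else:
            if n1 < 2 or n2 < 2:
                raise ValueError("group sizes must be >= 2")
            h = (n1 + n2) ** 2 / (n1 * n2)
        return float(value / np.sqrt(value**2 + h))
    raise ValueError(f"unknown effect-size measure {measure!r}")


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(r)


def aggregate(entries: Sequence[EffectSizeEntry],
              weights: Sequence[int]) -> EffectSizeEntry:
    """Pool several studies of one predictor-outcome pair.

    Inverse-variance-weighted mean on the Fisher-z scale, with per-study
    variance 1/(n - 3); the pooled 95% CI comes from the pooled z-variance.
    A single entry is returned unchanged.
    """
    if len(entries) == 0:
        raise ValueError("nothing to aggregate")
    pairs = {(e.predictor, e.outcome) for e in entries}
    if len(pairs) > 1:
        raise ValueError(f"entries mix pairs: {sorted(pairs)}")
    if len(entries) == 1:
        return entries[0]
    if len(weights) != len(entries):
        raise ValueError("need one weight (study n) per entry")
    n = np.asarray(weights, dtype=float)
    if np.any(n <= 3):
        raise ValueError("study sizes must exceed 3 for Fisher-z variance")
    z = _fisher_z(np.array([e.r for e in entries]))
    w = n - 3.0
    z_bar = float(np.sum(w * z) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    predictor, outcome = entries[0].predictor, entries[0].outcome
    return EffectSizeEntry(
        predictor, outcome,
        r=float(np.tanh(z_bar)),
        ci_lo=float(np.tanh(z_bar - 1.959963984540054 * se)),
        ci_hi=float(np.tanh(z_bar + 1.959963984540054 * se)),
    )


# Packaged default predictor x outcome correlations with 95% CIs.
_DEFAULT_ROWS: Mapping[tuple[str, str], tuple[float, float, float]] = {
    ("stress", "reaction_time"): (0.220, 0.157, 0.283),
    ("stress", "executive_function"): (0.091, -0.006, 0.188),
    ("stress", "perceptuo_motor"): (0.459, 0.395, 0.523),
    ("sleep", "reaction_time"): (-0.278, -0.363, -0.193),
    ("sleep", "executive_function"): (-0.183, -0.251, -0.115),
    ("sleep", "perceptuo_motor"): (-0.189, -0.334, -0.044),
    ("exertion", "reaction_time"): (-0.053, -0.156, 0.05),
    ("exertion", "executive_function"): (-0.074, -0.154, 0.006),
    ("exertion", "perceptuo_motor"): (0.578, 0.223, 0.933),
}


def default_matrix() -> EffectSizeMatrix:
    """The packaged 3x3 correlation matrix with confidence intervals."""
    return EffectSizeMatrix(
        EffectSizeEntry(p, o, *vals) for (p, o), vals in _DEFAULT_ROWS.items()
    )
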