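"""Sparse 4-D joint density construction by iteratively reweighted adaptive LASSO.

The joint density of one outcome y and the three predictors x = (x1, x2, x3)
is represented, on the normalized box [-1, 1]^4, as a convex combination of
isotropic Gaussian bumps placed on a lattice:

    p(y, x) = sum_i alpha_i f_i(z),
    f_i(z) = (2 pi)^-2 sigma_i^-4 exp(-||z - mu_i||^2 / (2 sigma_i^2)),

with alpha on the probability simplex. The coefficients are chosen so that
(a) the four implied marginals match supplied marginals at K grid points,
(b) the implied predictor-outcome correlations match literature effect
sizes, and (c) alpha is sparse. Marginals and second moments of the mixture
are linear in alpha, so (a) and (b) stack into linear blocks A_k alpha = p_k
and the fit is the convex program

    min_alpha  sum_k w_k ||p_k - A_k alpha||^2 + lambda ||diag(c) alpha||_1
    s.t.       0 <= alpha_i <= 1,  sum_i alpha_i = 1,

solved repeatedly while the penalty weights c are re-derived from the
previous solution (adaptive reweighting) until at most N_z coefficients
survive thresholding.

On the simplex the weighted L1 penalty is the linear form lambda * c .
alpha, so the inner problem is a smooth convex QP over the simplex. It is
solved by fully corrective Frank-Wolfe (simplicial decomposition): the
linear-minimization oracle over the simplex is a coordinate argmin of the
gradient, the growing atom set is re-optimized exactly by an accelerated
projected-gradient (FISTA) solve on its small Gram system, and the
Frank-Wolfe duality gap certifies the distance to the global optimum. The
constraint stack has far fewer rows than columns, so the optimal support is
small and the atom set stays desk-sized even when the basis has ~10^6
coefficients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import EffectSizeMatrix
from .marginals import AxisTransform, GridPDF, MomentSummary

__all__ = [
    "DEFAULT_WIDTHS",
    "AXIS_NAMES",
    "LatticeBasis",
    "ConstraintSystem",
    "LassoConfig",
    "JointModel",
    "build_basis",
    "eval_basis",
    "marginal_design",
    "moment_design",
    "project_simplex",
    "solve_weighted_lasso",
    "adaptive_sparsify",
    "recovered_stats",
    "eval_slice",
]

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = (0.03, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40)
#: Axis order used everywhere: outcome first, then the three predictors.
AXIS_NAMES = ("y", "x1", "x2", "x3")
_INV_2PI_SQ = 1.0 / (2.0 * np.pi) ** 2
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class LatticeBasis:
    """Isotropic Gaussian bumps of M widths on an N^4 lattice over [-1, 1]^4.

    Basis index ``i = m * N^4 + n`` is width-major; the center index ``n``
    ravels the 4-D lattice in C order over axes (y, x1, x2, x3), so the x3
    coordinate varies fastest. This ordering is fixed and documented so that
    serialized coefficient tables are stable.
    """

    def __init__(self, n_per_axis: int, widths: Sequence[float] = DEFAULT_WIDTHS):
        if n_per_axis < 3 or n_per_axis % 2 == 0:
            raise ValueError("n_per_axis must be an odd integer >= 3")
        w = np.asarray(widths, dtype=float)
        if w.size == 0 or np.any(w <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("widths must be strictly increasing and positive")
        self.n_per_axis = int(n_per_axis)
        self.widths = w
        self.axis_coords = np.linspace(-1.0, 1.0, n_per_axis)
        mesh = np.meshgrid(*([self.axis_coords] * 4), indexing="ij")
        self.centers = np.stack([m.ravel() for m in mesh], axis=-1)  # (N^4, 4)
        self.n_centers = self.centers.shape[0]
        self.basis_count = int(w.size) * self.n_centers
        #: per-basis width, length basis_count
        self.sigmas = np.repeat(w, self.n_centers)

    @property
    def n_widths(self) -> int:
        return int(self.widths.size)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Center coordinate on one axis for every basis index."""
        return np.tile(self.centers[:, axis], self.n_widths)

    def split_index(self, i: np.ndarray):
        """Basis index -> (width index m, center index n)."""
        i = np.asarray(i)
        return i // self.n_centers, i % self.n_centers


def build_basis(n_per_axis: int, widths: Sequence[float] = DEFAULT_WIDTHS) -> LatticeBasis:
    return LatticeBasis(n_per_axis, widths)


def eval_basis(basis: LatticeBasis, points: np.ndarray,
               indices: np.ndarray | None = None) -> np.ndarray:
    """Evaluate f_i(z) for each point (rows) and basis function (columns)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 4:
        raise ValueError("points must be 4-dimensional")
    if indices is None:
        centers = np.tile(basis.centers, (basis.n_widths, 1))
        sig = basis.sigmas
    else:
        idx = np.asarray(indices)
        _, n = basis.split_index(idx)
        centers = basis.centers[n]
        sig = basis.sigmas[idx]
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return _INV_2PI_SQ / sig**4 * np.exp(-0.5 * d2 / sig**2)


def _norm_pdf(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x - mu) / sd
    return _INV_SQRT_2PI / sd * np.exp(-0.5 * z * z)


def marginal_design(basis: LatticeBasis, axis: int,
                    eval_points: np.ndarray) -> np.ndarray:
    """Design block mapping alpha to the implied marginal on one axis.

    Entry (k, i) is the univariate Gaussian N(u_k; mu_{axis,i}, sigma_i^2):
    integrating an isotropic 4-D component over the other three axes leaves
    exactly this factor.
    """
    if not 0 <= axis <= 3:
        raise ValueError("axis must be in 0..3")
    u = np.asarray(eval_points, dtype=float)
    mu = basis.axis_centers(axis)
    return _norm_pdf(u[:, None], mu[None, :], basis.sigmas[None, :])


def moment_design(
    basis: LatticeBasis,
    moments: Mapping[int, MomentSummary],
    r_targets: Sequence[tuple[int, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Moment block relating effect sizes to the coefficients.

    ``moments`` maps axis index -> (mean, sd) of the *supplied* normalized
    marginals; ``r_targets`` lists (predictor axis j, target correlation r).
    Row for pair (x_j, y): sum_i alpha_i mu_{x_j,i} mu_{y,i} / (s_j s_y),
    with target r + m_j m_y / (s_j s_y). The product form is exact: isotropic
    components have zero within-component cross-covariance, so
    E[x_j y] = sum_i alpha_i mu_{x_j,i} mu_{y,i}.
    """
    m_y, s_y = moments[0].mean, moments[0].sd
    mu_y = basis.axis_centers(0)
    rows, targets = [], []
    for axis_j, r in r_targets:
        if not 1 <= axis_j <= 3:
            raise ValueError("predictor axis must be 1..3")
        m_j, s_j = moments[axis_j].mean, moments[axis_j].sd
        rows.append(basis.axis_centers(axis_j) * mu_y / (s_j * s_y))
        targets.append(r + m_j * m_y / (s_j * s_y))
    return np.array(rows), np.array(targets)


@dataclass
class ConstraintSystem:
    """Stacked linear blocks tying coefficients to marginals and moments."""

    basis: LatticeBasis
    marginal_blocks: list[np.ndarray]      # A_1..A_4, each (K, N_B)
    marginal_targets: list[np.ndarray]     # p_1..p_4, each (K,)
    moment_block: np.ndarray               # A_5, (n_pairs, N_B)
    moment_target: np.ndarray              # p_5
    block_weights: np.ndarray              # w_1..w_5
    k_points: int

    def __post_init__(self) -> None:
        if len(self.marginal_blocks) != 4 or len(self.marginal_targets) != 4:
            raise ValueError("need four marginal blocks and targets")
        nb = self.basis.basis_count
        for a, p in zip(self.marginal_blocks, self.marginal_targets):
            if a.shape != (self.k_points, nb) or p.shape != (self.k_points,):
                raise ValueError("marginal block/target shape mismatch")
        if self.moment_block.shape[1] != nb:
            raise ValueError("moment block column count mismatch")
        if len(self.block_weights) != 5:
            raise ValueError("need five block weights")
        for arr in (*self.marginal_blocks, *self.marginal_targets,
                    self.moment_block, self.moment_target):
            if not np.all(np.isfinite(arr)):
                raise ValueError("constraint system contains non-finite entries")

    def blocks(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        out = [
            (a, p, float(self.block_weights[k]))
            for k, (a, p) in enumerate(zip(self.marginal_blocks, self.marginal_targets))
        ]
        out.append((self.moment_block, self.moment_target, float(self.block_weights[4])))
        return out

    def stacked(self, columns: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Weighted stack (sqrt(w_k) A_k, sqrt(w_k) p_k), optionally column-sliced."""
        mats, vecs = [], []
        for a, p, w in self.blocks():
            sw = np.sqrt(w)
            mats.append(sw * (a if columns is None else a[:, columns]))
            vecs.append(sw * p)
        return np.ascontiguousarray(np.vstack(mats)), np.concatenate(vecs)

    def residual_terms(self, alpha: np.ndarray) -> float:
        """Penalty-free data term sum_k w_k ||p_k - A_k alpha||^2."""
        return float(sum(w * np.sum((p - a @ alpha) ** 2) for a, p, w in self.blocks()))


@dataclass(frozen=True)
class LassoConfig:
    lam: float = 1e-5
    threshold: float = 1e-9
    target_nnz: int = 400
    max_outer_iters: int = 50
    solver_max_majors: int = 2000      # Frank-Wolfe major iterations
    solver_gap_tol: float = 1e-9       # duality-gap stopping certificate
    solver_sub_iters: int = 4000       # FISTA iterations per corrective solve
    solver_atoms_per_major: int = 8    # new atoms admitted per major iteration

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.threshold <= 0 or self.target_nnz < 1:
            raise ValueError("lam, threshold must be positive; target_nnz >= 1")


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort algorithm)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css - 1.0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _fista_gram(G: np.ndarray, h: np.ndarray, lin: np.ndarray,
                x0: np.ndarray, max_iter: int) -> np.ndarray:
    """min x'Gx - 2h'x + lin'x over the simplex (corrective subproblem).

    FISTA with adaptive restart on the small Gram system of the active atom
    set; deterministic and exact up to the fixed iteration budget.
    """
    L = 2.0 * float(np.linalg.eigvalsh(G)[-1]) + 1e-12

    def fval(x: np.ndarray) -> float:
        return float(x @ G @ x - 2.0 * h @ x + lin @ x)

    x = project_simplex(x0)
    y = x.copy()
    t = 1.0
    fx = fval(x)
    stall = 0
    for _ in range(max_iter):
        grad = 2.0 * (G @ y - h) + lin
        x_new = project_simplex(y - grad / L)
        f_new = fval(x_new)
        if f_new > fx:  # restart: drop momentum, plain projected step
            t = 1.0
            grad = 2.0 * (G @ x - h) + lin
            x_new = project_simplex(x - grad / L)
            f_new = fval(x_new)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_next) * (x_new - x)
        t = t_next
        improvement = fx - f_new
        x, fx = x_new, f_new
        if improvement <= 1e-15 * max(1.0, abs(fx)):
            stall += 1
            if stall >= 30:
                break
        else:
            stall = 0
    return x


def solve_weighted_lasso(system: ConstraintSystem, config: LassoConfig,
                         c: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
    """Solve the simplex-constrained weighted LASSO for fixed penalty weights c.

    Fully corrective Frank-Wolfe: grow an active atom set by admitting the
    coordinates with the most negative gradient, re-optimize exactly over
    the atoms' convex hull, and stop once the Frank-Wolfe duality gap
    ``grad . alpha - min_i grad_i`` (an upper bound on the distance of the
    objective from its global optimum) falls below ``solver_gap_tol``.
    ``x0`` (a feasible warm start) seeds the initial atom set.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (system.basis.basis_count,) or np.any(c <= 0):
        raise ValueError("c must be a strictly positive vector of length basis_count")
    A, p = system.stacked()
    n = A.shape[1]
    lin = config.lam * c

    if x0 is not None:
        start = np.asarray(x0, dtype=float)
        atoms = list(np.nonzero(start > 0)[0])
        beta = start[atoms] / start[atoms].sum()
    else:
        # best single vertex: argmin_i ||A e_i - p||^2 + lin_i
        f_vertex = np.einsum("ij,ij->j", A, A) - 2.0 * (A.T @ p) + lin
        atoms = [int(np.argmin(f_vertex))]
        beta = np.array([1.0])

    sub_iters = config.solver_sub_iters
    gap = np.inf
    for _ in range(config.solver_max_majors):
        idx = np.asarray(atoms)
        AS = A[:, idx]
        G = AS.T @ AS
        h = AS.T @ p
        beta = _fista_gram(G, h, lin[idx], beta, sub_iters)

        resid = AS @ beta - p
        grad = 2.0 * (A.T @ resid) + lin
        order = np.argsort(grad)
        gap = float(grad[idx] @ beta - grad[order[0]])
        if gap <= config.solver_gap_tol:
            break
        new = [int(i) for i in order[: config.solver_atoms_per_major]
               if int(i) not in set(atoms)]
        if not new:
            # worst atoms already active: the corrective solve is the
            # bottleneck; enlarge its budget and re-optimize
            if sub_iters > 16 * config.solver_sub_iters:
                level = logging.INFO if gap <= 1e-4 * max(1.0, abs(gap)) + 1e-4 \
                    else logging.WARNING
                logger.log(level, "Frank-Wolfe stopped at duality gap %.3e", gap)
                break
            sub_iters *= 2
            continue
        keep = beta > 0.0
        atoms = [a for a, k in zip(atoms, keep) if k] + new
        beta = np.concatenate([beta[keep], np.zeros(len(new))])
    else:
        logger.warning("Frank-Wolfe hit solver_max_majors with gap %.3e", gap)

    alpha = np.zeros(n)
    alpha[np.asarray(atoms)] = beta
    uniform = np.full(n, 1.0 / n)
    f_alpha = float(np.sum((A @ alpha - p) ** 2) + lin @ alpha)
    f_uniform = float(np.sum((A @ uniform - p) ** 2) + lin @ uniform)
    if not f_alpha <= f_uniform + 1e-9:
        raise RuntimeError("solver failed to improve on the uniform vector")
    return alpha


@dataclass
class JointModel:
    """Sparse simplex mixture of lattice Gaussians representing p(y, x1, x2, x3)."""

    basis: LatticeBasis
    support: np.ndarray            # basis indices with nonzero coefficients
    coefficients: np.ndarray       # matching positive coefficients, sum 1
    axis_transforms: tuple[AxisTransform | None, ...] = (None, None, None, None)
    converged: bool = True
    outer_iterations: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.coefficients, dtype=float)
        s = np.asarray(self.support, dtype=int)
        if a.shape != s.shape or a.ndim != 1:
            raise ValueError("support and coefficients must be equal-length vectors")
        if np.any(a < 0) or np.any(a > 1) or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError("coefficients must lie on the probability simplex")
        self.support = s
        self.coefficients = a

    @property
    def nnz(self) -> int:
        return int(self.support.size)

    def centers(self) -> np.ndarray:
        _, n = self.basis.split_index(self.support)
        return self.basis.centers[n]

    def sigmas(self) -> np.ndarray:
        return self.basis.sigmas[self.support]

    def box_mass(self) -> float:
        """Closed-form mass of the raw mixture inside [-1, 1]^4.

        The basis functions are untruncated R^4 Gaussians, so a small part
        of each component's mass can fall outside the normalized box;
        ``density`` divides by this factor so the reported density
        integrates to 1 over the box.
        """
        if getattr(self, "_box_mass", None) is None:
            from scipy.stats import norm
            mu = self.centers()
            sig = self.sigmas()[:, None]
            mass = norm.cdf((1.0 - mu) / sig) - norm.cdf((-1.0 - mu) / sig)
            self._box_mass = float(self.coefficients @ np.prod(mass, axis=1))
        return self._box_mass

    def density(self, points: np.ndarray) -> np.ndarray:
        """Joint density on [-1, 1]^4, renormalized for box truncation."""
        f = eval_basis(self.basis, points, indices=self.support)
        return (f @ self.coefficients) / self.box_mass()

    def marginal_density(self, axes: Sequence[int], points: np.ndarray) -> np.ndarray:
        """Density of the marginal over the listed axes at the given points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        mu = self.centers()[:, list(axes)]
        sig = self.sigmas()
        d2 = ((pts[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
        dim = len(axes)
        comp = (2 * np.pi) ** (-dim / 2.0) / sig**dim * np.exp(-0.5 * d2 / sig**2)
        return (comp @ self.coefficients) / self.box_mass()

    def axis_marginal(self, axis: int, grid: np.ndarray | None = None) -> GridPDF:
        if grid is None:
            grid = np.linspace(-1.0, 1.0, 401)
        dens = self.marginal_density([axis], grid[:, None])
        dens = np.maximum(dens, 0.0)
        dens = dens / np.trapezoid(dens, grid)
        return GridPDF(grid, dens, transform=self.axis_transforms[axis])

    def axis_moments(self) -> list[MomentSummary]:
        """Model-implied mean and sd per axis, in closed form over R^4.

        Moment algebra uses the untruncated mixture (consistent with how the
        moment constraints are assembled and with ``sample_joint``).
        """
        out = []
        mu = self.centers()
        var_comp = self.sigmas() ** 2
        for axis in range(4):
            m = float(self.coefficients @ mu[:, axis])
            ex2 = float(self.coefficients @ (mu[:, axis] ** 2 + var_comp))
            out.append(MomentSummary(mean=m, sd=float(np.sqrt(max(ex2 - m * m, 1e-300)))))
        return out

    def correlation(self, axis_j: int) -> float:
        """Model-implied Pearson r between predictor axis_j and the outcome."""
        mom = self.axis_moments()
        mu = self.centers()
        e_xy = float(self.coefficients @ (mu[:, axis_j] * mu[:, 0]))
        return (e_xy - mom[axis_j].mean * mom[0].mean) / (mom[axis_j].sd * mom[0].sd)

    def save(self, json_path: str | Path, meta: dict | None = None) -> None:
        json_path = Path(json_path)
        csv_path = json_path.with_suffix(".coefficients.csv")
        m, n = self.basis.split_index(self.support)
        pd.DataFrame({
            "basis_index": self.support,
            "width_index": m,
            "center_index": n,
            "alpha": [repr(float(v)) for v in self.coefficients],
        }).to_csv(csv_path, index=False)
        header = {
            "n_per_axis": self.basis.n_per_axis,
            "widths": self.basis.widths.tolist(),
            "axis_transforms": [
                t.to_dict() if t else None for t in self.axis_transforms
            ],
            "converged": self.converged,
            "outer_iterations": self.outer_iterations,
            "coefficients_csv": csv_path.name,
        }
        if meta:
            header.update(meta)
        json_path.write_text(json.dumps(header, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, json_path: str | Path) -> "JointModel":
        json_path = Path(json_path)
        header = json.loads(json_path.read_text(encoding="utf-8"))
        df = pd.read_csv(json_path.parent / header["coefficients_csv"],
                         float_precision="round_trip")
        basis = LatticeBasis(header["n_per_axis"], header["widths"])
        transforms = tuple(
            AxisTransform.from_dict(t) if t else None
            for t in header["axis_transforms"]
        )
        return cls(
            basis,
            df["basis_index"].to_numpy(dtype=int),
            df["alpha"].to_numpy(dtype=float),
            axis_transforms=transforms,
            converged=bool(header.get("converged", True)),
            outer_iterations=int(header.get("outer_iterations", 0)),
        )


def adaptive_sparsify(
    system: ConstraintSystem,
    config: LassoConfig,
    axis_transforms: tuple[AxisTransform | None, ...] = (None, None, None, None),
) -> JointModel:
    """Iteratively reweighted adaptive LASSO down to at most N_z coefficients.

    Procedure: start from uniform penalty weights c = 1; solve the weighted
    problem; update c_i = 1/alpha_i where alpha_i > t and c_i = 1/t where
    alpha_i <= t; threshold (alpha_i <= t -> 0); stop once the nonzero count
    is <= N_z, else repeat with the new c. Coefficients at the 1/t penalty
    cap are excluded from later solves (their penalty gradient lambda/t
    dominates any attainable data-term gradient, so they are zero at the
    optimum). The final coefficients are renormalized to sum exactly to 1.
    """
    nb = system.basis.basis_count
    t = config.threshold
    active = np.arange(nb)
    c_active = np.ones(nb)
    warm: np.ndarray | None = None
    alpha_full = np.zeros(nb)
    converged = False
    outer = 0

    for outer in range(1, config.max_outer_iters + 1):
        sub = _column_subsystem(system, active)
        alpha_sub = solve_weighted_lasso(sub, config, c_active, x0=warm)
        alpha_full = np.zeros(nb)
        alpha_full[active] = alpha_sub

        keep = alpha_sub > t          # step 4: threshold
        nnz = int(np.count_nonzero(keep))
        if nnz <= config.target_nnz:
            converged = True
            break
        # step 3: adaptive reweighting; zeroed coefficients leave the active set
        active = active[keep]
        c_active = 1.0 / alpha_sub[keep]
        warm = alpha_sub[keep] / alpha_sub[keep].sum()

    if not converged:
        logger.warning("adaptive LASSO hit max_outer_iters=%d with nnz > %d",
                       config.max_outer_iters, config.target_nnz)

    alpha_full[alpha_full <= t] = 0.0
    support = np.nonzero(alpha_full)[0]
    coeffs = alpha_full[support]
    coeffs = coeffs / coeffs.sum()    # simplex restoration after thresholding
    return JointModel(system.basis, support, coeffs,
                      axis_transforms=axis_transforms,
                      converged=converged, outer_iterations=outer)


def _column_subsystem(system: ConstraintSystem, columns: np.ndarray) -> ConstraintSystem:
    if columns.size == system.basis.basis_count:
        return system
    sub = ConstraintSystem.__new__(ConstraintSystem)
    sub.basis = _SubBasis(system.basis, columns)
    sub.marginal_blocks = [a[:, columns] for a in system.marginal_blocks]
    sub.marginal_targets = system.marginal_targets
    sub.moment_block = system.moment_block[:, columns]
    sub.moment_target = system.moment_target
    sub.block_weights = system.block_weights
    sub.k_points = system.k_points
    return sub


class _SubBasis:
    """Column-sliced stand-in exposing just basis_count for the inner solver."""

    def __init__(self, parent: LatticeBasis, columns: np.ndarray):
        self.basis_count = int(columns.size)


def build_constraint_system(
    basis: LatticeBasis,
    marginals: Mapping[int, GridPDF],
    effect_rows: Sequence[tuple[int, float]],
    k_points: int = 41,
    block_weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 75.0),
) -> ConstraintSystem:
    """Assemble the full constraint system from supplied normalized marginals.

    ``marginals`` maps axis index (0 = outcome) to its normalized GridPDF;
    ``effect_rows`` lists (predictor axis, target r).
    """
    from .marginals import moments as _moments
    eval_points = np.linspace(-1.0, 1.0, k_points)
    blocks, targets = [], []
    for axis in range(4):
        pdf = marginals[axis]
        blocks.append(marginal_design(basis, axis, eval_points))
        targets.append(pdf.interpolate(eval_points))
    mom = {axis: _moments(marginals[axis]) for axis in range(4)}
    a5, p5 = moment_design(basis, mom, effect_rows)
    return ConstraintSystem(
        basis=basis,
        marginal_blocks=blocks,
        marginal_targets=targets,
        moment_block=a5,
        moment_target=p5,
        block_weights=np.asarray(block_weights, dtype=float),
        k_points=k_points,
    )


def recovered_stats(
    model: JointModel,
    supplied_marginals: Mapping[int, GridPDF],
    supplied_r: Sequence[tuple[int, float]],
) -> dict:
    """Supplied-vs-recovered fidelity report for a fitted joint model.

    The recovered correlation uses the effect-size relation exactly as it is
    used to build the constraint: the cross-moment E[x_j y] comes from the
    fitted mixture (sum_i alpha_i mu_{x_j,i} mu_{y,i}) while the means and
    standard deviations are those of the supplied marginals. The purely
    model-implied correlation (all moments from the mixture) is reported
    alongside as ``model_r``.
    """
    from .marginals import moments as _moments
    report: dict = {"marginals": {}, "correlations": {}, "nnz": model.nnz,
                    "converged": model.converged}
    supplied_mom = {axis: _moments(supplied_marginals[axis]) for axis in range(4)}
    max_l1 = 0.0
    for axis in range(4):
        supplied = supplied_marginals[axis]
        grid = supplied.grid
        rec = model.marginal_density([axis], grid[:, None])
        l1 = float(np.trapezoid(np.abs(rec - supplied.density), grid))
        linf = float(np.max(np.abs(rec - supplied.density)))
        report["marginals"][AXIS_NAMES[axis]] = {
            "l1": l1, "max_abs": linf,
            "recovered_integral": float(np.trapezoid(rec, grid)),
        }
        max_l1 = max(max_l1, l1)
    max_dr = 0.0
    mu = model.centers()
    m_y, s_y = supplied_mom[0].mean, supplied_mom[0].sd
    for axis_j, r_sup in supplied_r:
        m_j, s_j = supplied_mom[axis_j].mean, supplied_mom[axis_j].sd
        e_xy = float(model.coefficients @ (mu[:, axis_j] * mu[:, 0]))
        r_rec = (e_xy - m_j * m_y) / (s_j * s_y)
        report["correlations"][AXIS_NAMES[axis_j]] = {
            "supplied": float(r_sup), "recovered": float(r_rec),
            "abs_error": abs(r_rec - r_sup),
            "model_r": float(model.correlation(axis_j)),
        }
        max_dr = max(max_dr, abs(r_rec - r_sup))
    report["max_marginal_l1"] = max_l1
    report["max_r_error"] = max_dr
    return report


def eval_slice(
    model: JointModel,
    fixed_axes: Mapping[int, float],
    free_axes: Mapping[int, np.ndarray],
) -> np.ndarray:
    """Tabulate the joint density on a slice with some axes held fixed.

    Returns an array shaped like the meshgrid of the free-axis grids (in
    ascending axis order).
    """
    axes = sorted(set(fixed_axes) | set(free_axes))
    if axes != [0, 1, 2, 3]:
        raise ValueError("fixed_axes and free_axes must partition axes 0..3")
    for v in fixed_axes.values():
        if not -1.0 <= v <= 1.0:
            raise ValueError("fixed coordinates must lie in [-1, 1]")
    free = sorted(free_axes)
    grids = [np.asarray(free_axes[a], dtype=float) for a in free]
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.empty(mesh[0].shape + (4,))
    for a in fixed_axes:
        pts[..., a] = fixed_axes[a]
    for a, m in zip(free, mesh):
        pts[..., a] = m
    flat = pts.reshape(-1, 4)
    return model.density(flat).reshape(mesh[0].shape)
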