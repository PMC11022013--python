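"""Three-dimensional thin-plate splines.

The 3-D TPS interpolant between control points X and targets Y is

    f(p) = c + A p + sum_i w_i U(|p - x_i|),

with the 3-D fundamental kernel U(r) = -r (the interpolating map is identical
under U(r) = +r with the weights' sign flipped; the negative sign is chosen so
that the bending energy, the quadratic form of the non-affine weights

    J(f) = sum_d w_d' K w_d,   K_ij = U(|x_i - x_j|),

is non-negative on the side-condition subspace). The bending energy is zero
exactly when the map is affine, and is invariant under rigid motions applied
jointly to both point sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.linalg import LinAlgWarning, lu_factor, lu_solve
from scipy.spatial.distance import cdist


class DegenerateConfigurationError(ValueError):
    """Raised when the TPS linear system is singular (coincident or
    rank-deficient control points)."""


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return -cdist(a, b)


@dataclass(frozen=True)
class TPSModel:
    control_points: np.ndarray   # N x 3
    affine: np.ndarray           # 3 x 3 linear part
    translation: np.ndarray      # 3-vector
    nonaffine_weights: np.ndarray  # N x 3
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_apply(self, points)


def _tps_system(control: np.ndarray) -> np.ndarray:
    n = control.shape[0]
    K = _kernel(control, control)
    P = np.hstack([np.ones((n, 1)), control])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    return L


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the 3-D thin-plate spline mapping ``source`` onto ``target``.

    Interpolates exactly at the control points. Requires at least 4
    control points that are not all coplanar.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must be matching N x 3 arrays")
    n = source.shape[0]
    if n < 4:
        raise ValueError("TPS needs at least 4 control points")

    L = _tps_system(source)
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = target
    try:
        with warnings.catch_warnings():
            # singularity is detected and reported as an exception below
            warnings.simplefilter("ignore", LinAlgWarning)
            lu = lu_factor(L)
            with np.errstate(invalid="raise"):
                sol = lu_solve(lu, rhs)
    except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
        raise DegenerateConfigurationError(
            "singular TPS system: coincident or coplanar control points") from exc
    if not np.all(np.isfinite(sol)) or np.linalg.cond(L) > 1e12:
        raise DegenerateConfigurationError(
            "ill-conditioned TPS system: degenerate control configuration")

    w = sol[:n]
    translation = sol[n]
    affine = sol[n + 1:].T  # rows of sol are coefficient vectors per axis
    K = L[:n, :n]
    energy = float(np.trace(w.T @ K @ w))
    energy = max(energy, 0.0)  # clip roundoff; K is CPD on the constraint space
    return TPSModel(control_points=source, affine=affine,
                    translation=translation, nonaffine_weights=w,
                    bending_energy=energy)


def tps_apply(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary points (M x 3)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    U = _kernel(points, model.control_points)
    return (model.translation + points @ model.affine.T
            + U @ model.nonaffine_weights)


def bending_energy_matrix(control: np.ndarray) -> np.ndarray:
    """The N x N bending-energy matrix B of a control configuration.

    For target positions Y (N x 3), the bending energy of the TPS from
    ``control`` to Y is trace(Y' B Y). B is the upper-left block of the
    inverse of the bordered TPS system matrix; it is symmetric positive
    semidefinite with the affine subspace in its null space.
    """
    control = np.asarray(control, dtype=float)
    n = control.shape[0]
    L = _tps_system(control)
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            "singular TPS system for bending-energy matrix") from exc
    B = Linv[:n, :n]
    return (B + B.T) / 2.0


def estimate_missing_landmarks(config, reference: np.ndarray):
    """Fill a specimen's missing landmarks by TPS from a complete reference.

    A TPS is fitted from the reference's shared (non-missing) landmarks to
    the specimen's, and the reference positions of the missing landmarks are
    mapped through it. Non-missing coordinates are untouched. Because TPS
    reproduces affine maps exactly, a specimen that is an affine image of the
    reference is restored exactly.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != config.coords.shape:
        raise ValueError("reference must match the specimen's landmark count")
    if not config.missing.any():
        return config.copy()
    shared = ~config.missing
    if shared.sum() < 4:
        raise ValueError(
            f"{config.specimen_id}: need >= 4 shared landmarks to estimate "
            f"missing ones, have {int(shared.sum())}")
    model = tps_fit(reference[shared], config.coords[shared])
    out = config.copy()
    filled = tps_apply(model, reference[config.missing])
    out.coords[config.missing] = filled
    out.missing[:] = False
    out.meta.setdefault("estimated_landmarks",
                        np.nonzero(config.missing)[0].tolist())
    return out
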