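"""Sliding semilandmarks by bending-energy minimization.

Semilandmarks carry deficient homology: curve points may move along the local
curve tangent, surface points within the local tangent plane. Per iteration
the Procrustes consensus is recomputed as the sliding reference, each
specimen's sliding displacements are solved jointly as the exact minimizer of
the thin-plate-spline bending energy of the reference -> specimen deformation
(a quadratic in the tangent parameters, one linear solve per specimen), and
points may optionally be projected back onto the original curve polylines and
surface.

Tangent directions are estimated from the specimen itself: central
differences of ordered curve neighbours for interior curve points, and two
orthonormal tangents from the surface normal for surface points (analytic
patch normals by default, or nearest-face mesh normals when a mesh is given).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration
from .procrustes import gpa_align, optimal_rotation, _centre_and_scale
from .template import Template, patch_normal
from .tps import bending_energy_matrix


class GeometryError(ValueError):
    """Raised when a tangent direction is undefined (duplicate neighbours)."""


@dataclass
class SlidingResult:
    dataset: list                 # slid LandmarkConfigurations
    energy_trace: np.ndarray      # n_iter x n_specimens bending energies
    iterations: int


def _curve_tangents(coords: np.ndarray, template: Template) -> dict[int, np.ndarray]:
    """Unit tangents for interior curve points: central differences of the
    ordered neighbours along each curve path."""
    tangents: dict[int, np.ndarray] = {}
    for curve in template.curves:
        path = curve.path
        for k, idx in enumerate(path[1:-1], start=1):
            t = coords[path[k + 1]] - coords[path[k - 1]]
            norm = np.linalg.norm(t)
            if norm < 1e-12:
                raise GeometryError(
                    f"undefined tangent at curve point {idx} on "
                    f"'{curve.name}': duplicate neighbours")
            tangents[idx] = t / norm
    return tangents


def _surface_frames(coords: np.ndarray, template: Template,
                    mesh=None) -> dict[int, np.ndarray]:
    """Two orthonormal tangent vectors per surface semilandmark."""
    idx = np.asarray(template.surface_indices, dtype=int)
    if mesh is not None:
        normals = mesh.nearest_face_normals(coords[idx])
    else:
        normals = patch_normal(template.uv[idx])
    frames: dict[int, np.ndarray] = {}
    for i, n in zip(idx, normals):
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise GeometryError(f"undefined surface normal at point {i}")
        n = n / norm
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(n, helper)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        frames[i] = np.stack([t1, t2])
    return frames


def _slide_one(coords: np.ndarray, reference: np.ndarray, B: np.ndarray,
               template: Template, mesh=None) -> np.ndarray:
    """Exactly minimize trace(Y' B Y) over tangent displacements of the
    semilandmarks of one specimen. Fixed landmarks never move."""
    directions: list[np.ndarray] = []   # unit direction per free parameter
    point_of: list[int] = []            # landmark index per free parameter
    for idx, t in _curve_tangents(coords, template).items():
        directions.append(t)
        point_of.append(idx)
    for idx, frame in _surface_frames(coords, template, mesh).items():
        directions.append(frame[0])
        point_of.append(idx)
        directions.append(frame[1])
        point_of.append(idx)
    D = np.asarray(directions)          # m x 3
    pts = np.asarray(point_of, dtype=int)

    # Energy E(theta) = trace((Y0 + S(theta))' B (Y0 + S(theta))) with the
    # displacement S placing theta_j * D_j at row pts_j. Gradient and Hessian:
    #   g_j = 2 D_j . (B Y0)[pts_j],  H_jk = 2 B[pts_j, pts_k] (D_j . D_k)
    BY0 = B @ coords
    g = 2.0 * np.einsum("jd,jd->j", D, BY0[pts])
    H = 2.0 * B[np.ix_(pts, pts)] * (D @ D.T)
    theta, *_ = np.linalg.lstsq(H, -g, rcond=None)

    out = coords.copy()
    np.add.at(out, pts, theta[:, None] * D)
    return out


def _project_to_polyline(point: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Closest point on a piecewise-linear curve."""
    best, best_d = polyline[0], np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = ab @ ab
        t = 0.0 if denom == 0 else np.clip((point - a) @ ab / denom, 0.0, 1.0)
        q = a + t * ab
        d = np.linalg.norm(point - q)
        if d < best_d:
            best, best_d = q, d
    return best


def _reproject(coords: np.ndarray, original: np.ndarray,
               template: Template, mesh=None) -> np.ndarray:
    """Project slid semilandmarks back onto the original curve polylines and,
    when a mesh is given, the original surface."""
    out = coords.copy()
    for curve in template.curves:
        polyline = original[list(curve.path)]
        for idx in curve.interior:
            out[idx] = _project_to_polyline(coords[idx], polyline)
    if mesh is not None:
        sidx = list(template.surface_indices)
        out[sidx] = mesh.closest_points(coords[sidx])
    return out


def _specimen_energy(coords: np.ndarray, B: np.ndarray) -> float:
    return float(np.trace(coords.T @ B @ coords))


def slide_against_reference(config, reference: np.ndarray,
                            template: Template, mesh=None,
                            reproject: bool = False):
    """Slide one specimen's semilandmarks against an explicit reference
    configuration (same frame), returning the slid configuration and the
    (before, after) bending energies."""
    c = (config.copy() if isinstance(config, LandmarkConfiguration)
         else LandmarkConfiguration("specimen", np.asarray(config, float)))
    reference = np.asarray(reference, dtype=float)
    B = bending_energy_matrix(reference)
    before = _specimen_energy(c.coords, B)
    slid = _slide_one(c.coords, reference, B, template, mesh)
    if reproject:
        slid = _reproject(slid, c.coords, template, mesh)
    c.coords[:] = slid
    return c, (before, _specimen_energy(slid, B))


def slide_semilandmarks(dataset, template: Template, iterations: int = 3,
                        reproject: bool = False, meshes=None,
                        update_reference: bool = False) -> SlidingResult:
    """Slide all semilandmarks of a dataset against the Procrustes
    consensus, minimizing TPS bending energy.

    Configurations must be complete (missing landmarks estimated first).
    By default the reference (the consensus, brought into each specimen's
    own frame by similarity superposition once at the start) is held fixed
    for all iterations; successive iterations only re-linearize the tangent
    directions at the slid positions, which guarantees a per-specimen
    non-increasing bending-energy trace (the zero displacement is always
    feasible). With ``update_reference=True`` the consensus is recomputed
    from the slid data each iteration (the recursive scheme); the energy
    trace is then only approximately monotone, since the target of the
    minimization moves between iterations.
    """
    configs = [c.copy() if isinstance(c, LandmarkConfiguration)
               else LandmarkConfiguration(str(i), np.asarray(c, float))
               for i, c in enumerate(dataset)]
    for c in configs:
        if c.missing.any():
            raise ValueError(f"{c.specimen_id}: estimate missing landmarks "
                             "before sliding")
    if meshes is None:
        meshes = [None] * len(configs)

    def local_references():
        """Consensus superimposed into each specimen's frame, with its
        bending-energy matrix."""
        reference = gpa_align(configs).consensus
        refs = []
        for c in configs:
            spec_shape, cs = _centre_and_scale(c.coords)
            R = optimal_rotation(reference, spec_shape)
            ref_local = (reference @ R) * cs + c.coords.mean(axis=0)
            refs.append((ref_local, bending_energy_matrix(ref_local)))
        return refs

    originals = [c.coords.copy() for c in configs]  # digitized geometry
    refs = local_references()
    trace = []
    for _ in range(iterations):
        if update_reference and trace:
            refs = local_references()
        energies = []
        for c, mesh, orig, (ref_local, B_local) in zip(configs, meshes,
                                                       originals, refs):
            slid = _slide_one(c.coords, ref_local, B_local, template, mesh)
            if reproject:
                slid = _reproject(slid, orig, template, mesh)
            c.coords[:] = slid
            energies.append(_specimen_energy(slid, B_local))
        trace.append(energies)

    return SlidingResult(dataset=configs, energy_trace=np.asarray(trace),
                         iterations=iterations)
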