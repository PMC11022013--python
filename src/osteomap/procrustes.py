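"""Generalized Procrustes analysis.

Superposition removes position (centroid at origin), size (unit centroid
size) and orientation (least-squares rotation to the iteratively updated
consensus). Centroid sizes are recorded before scaling so that form-space
analyses can reintroduce log size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration, centroid_size


class AlignmentError(ValueError):
    """Raised for degenerate configurations (e.g. all points coincident)."""


@dataclass
class ProcrustesResult:
    aligned: np.ndarray          # n x K x 3 unit-size aligned shapes
    centroid_sizes: np.ndarray   # n original centroid sizes (mm)
    consensus: np.ndarray        # K x 3 mean shape, unit centroid size
    iterations: int
    specimen_ids: tuple[str, ...] = ()
    species: tuple[str, ...] = ()
    age_groups: tuple[int, ...] = ()


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation R (3x3, det +1) minimizing ||source R - target||.

    Both inputs are assumed centred. Reflections are excluded, as mirrored
    specimens are not admissible superpositions of same-side anatomy.
    """
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _centre_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred ** 2)))
    if cs <= 0 or not np.isfinite(cs):
        raise AlignmentError("degenerate configuration: all landmarks coincide")
    return centred / cs, cs


def gpa_align(dataset, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes analysis of complete landmark configurations.

    Iterates rotation to the running consensus until the consensus changes
    by less than ``tol`` (root-mean-square), renormalizing the consensus to
    unit centroid size each round.
    """
    configs = list(dataset)
    if len(configs) < 2:
        raise AlignmentError("GPA needs at least 2 configurations")
    coords = []
    ids, species, ages = [], [], []
    for i, c in enumerate(configs):
        if isinstance(c, LandmarkConfiguration):
            if c.missing.any():
                raise AlignmentError(
                    f"{c.specimen_id}: missing landmarks must be estimated "
                    "before GPA")
            coords.append(c.coords)
            ids.append(c.specimen_id)
            species.append(c.species)
            ages.append(c.age_group)
        else:
            coords.append(np.asarray(c, dtype=float))
            ids.append(str(i))
            species.append(None)
            ages.append(None)
    shapes = []
    sizes = []
    for x in coords:
        s, cs = _centre_and_scale(x)
        shapes.append(s)
        sizes.append(cs)
    shapes = np.asarray(shapes)

    consensus = shapes[0]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            R = optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ R
        new_consensus, _ = _centre_and_scale(shapes.mean(axis=0))
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break

    return ProcrustesResult(aligned=shapes, centroid_sizes=np.asarray(sizes),
                            consensus=consensus, iterations=iterations,
                            specimen_ids=tuple(ids), species=tuple(species),
                            age_groups=tuple(ages))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations after
    centring, unit-size scaling and optimal rotation."""
    sa, _ = _centre_and_scale(np.asarray(a, dtype=float))
    sb, _ = _centre_and_scale(np.asarray(b, dtype=float))
    R = optimal_rotation(sa, sb)
    return float(np.linalg.norm(sa @ R - sb))


__all__ = ["ProcrustesResult", "AlignmentError", "gpa_align",
           "optimal_rotation", "procrustes_distance", "centroid_size"]
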