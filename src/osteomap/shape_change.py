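"""Age-group mean shapes, TPS mesh warping and signed-distance heatmaps.

Ontogenetic shape change within a species is visualized by warping a surface
mesh to subsequent age-group mean shapes and colouring the younger mean by
the signed distance to the older one: positive where the older surface lies
outside the younger (a forward displacement through growth), negative where
it lies inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .procrustes import ProcrustesResult
from .tps import tps_apply, tps_fit


class EmptyGroupError(KeyError):
    """Requested species/age-group cell contains no specimens."""


@dataclass
class SurfaceMesh:
    """Triangle mesh with an optional per-vertex scalar field."""

    vertices: np.ndarray            # V x 3 (mm)
    faces: np.ndarray               # F x 3 vertex indices
    per_vertex_scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces index nonexistent vertices")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices, dtype=float),
                   faces=np.asarray(tm.faces, dtype=int))

    def vertex_normals(self) -> np.ndarray:
        tm = self.to_trimesh()
        referenced = np.zeros(len(self.vertices), dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            bad = int(np.nonzero(~referenced)[0][0])
            raise ValueError(f"vertex {bad} lies on no face; normal undefined")
        return np.asarray(tm.vertex_normals, dtype=float)

    def closest_points(self, points: np.ndarray) -> np.ndarray:
        from ._meshgeom import closest_points
        return closest_points(np.atleast_2d(points), self.vertices, self.faces)

    def nearest_face_normals(self, points: np.ndarray) -> np.ndarray:
        from ._meshgeom import closest_points
        _, fidx = closest_points(np.atleast_2d(points), self.vertices,
                                 self.faces, return_faces=True)
        tm = self.to_trimesh()
        return np.asarray(tm.face_normals[fidx], dtype=float)

    def mean_edge_length(self) -> float:
        e = self.to_trimesh().edges_unique_length
        return float(np.mean(e))


@dataclass
class HeatmapResult:
    base_mesh: SurfaceMesh          # younger group's mesh, scalar = distances
    distances: np.ndarray           # V signed distances (mm)
    scale: tuple[float, float]      # symmetric rendering scale
    group_pair: tuple[int, int]
    species: str | None = None
    meta: dict = field(default_factory=dict)


def group_mean_shape(aligned: ProcrustesResult, species: str,
                     age_group: int) -> np.ndarray:
    """Arithmetic mean of the aligned shapes in one species x age-group cell."""
    sel = [i for i, (sp, ag) in enumerate(zip(aligned.species,
                                              aligned.age_groups))
           if sp == species and ag == age_group]
    if not sel:
        cells = sorted({(sp, ag) for sp, ag in zip(aligned.species,
                                                   aligned.age_groups)})
        raise EmptyGroupError(
            f"no specimens for ({species}, AG {age_group}); "
            f"available cells: {cells}")
    return aligned.aligned[sel].mean(axis=0)


def warp_mesh_to_shape(mesh: SurfaceMesh, source_landmarks: np.ndarray,
                       target_landmarks: np.ndarray) -> SurfaceMesh:
    """Warp every mesh vertex through the TPS taking the source landmark
    configuration onto the target. Connectivity is unchanged; landmarks
    embedded in the mesh land on their targets."""
    model = tps_fit(np.asarray(source_landmarks, float),
                    np.asarray(target_landmarks, float))
    return SurfaceMesh(vertices=tps_apply(model, mesh.vertices),
                       faces=mesh.faces.copy(),
                       per_vertex_scalar=None if mesh.per_vertex_scalar is None
                       else mesh.per_vertex_scalar.copy())


def _ray_distances(young: SurfaceMesh, old: SurfaceMesh,
                   cutoff: float) -> np.ndarray:
    """Signed distance along each vertex normal of ``young`` to ``old``;
    NaN where no intersection lies within ``cutoff``."""
    from ._meshgeom import ray_mesh_signed_offsets

    normals = young.vertex_normals()
    t = ray_mesh_signed_offsets(young.vertices, normals,
                                old.vertices, old.faces)
    t[np.abs(t) > cutoff] = np.nan
    return t


def signed_distance_heatmap(young: SurfaceMesh, old: SurfaceMesh,
                            pair: tuple[int, int],
                            method: str = "normal",
                            species: str | None = None,
                            cutoff_factor: float = 5.0) -> HeatmapResult:
    """Per-vertex signed distance from the younger mean surface to the older.

    method="normal": distance along the younger mesh's outward vertex
    normals (nearest intersection in either direction within a cutoff of
    ``cutoff_factor`` mean edge lengths), falling back per-vertex to the
    nearest surface point. method="nearest": nearest-point distance only.
    Positive distances mean the older surface lies outside the younger.
    The rendering scale is symmetric about zero and covers the 2nd-98th
    percentile of the distances.
    """
    dist = np.full(len(young.vertices), np.nan)
    if method == "normal":
        cutoff = cutoff_factor * young.mean_edge_length()
        dist = _ray_distances(young, old, cutoff)
    elif method != "nearest":
        raise ValueError(f"unknown heatmap method {method!r}")

    missing = np.isnan(dist)
    if missing.any():
        normals = young.vertex_normals()[missing]
        closest = old.closest_points(young.vertices[missing])
        delta = closest - young.vertices[missing]
        signed = np.linalg.norm(delta, axis=1) * np.sign(
            np.einsum("ij,ij->i", delta, normals))
        dist[missing] = signed

    p2, p98 = np.percentile(dist, [2.0, 98.0])
    lim = float(max(abs(p2), abs(p98)))
    base = SurfaceMesh(vertices=young.vertices.copy(),
                       faces=young.faces.copy(), per_vertex_scalar=dist)
    return HeatmapResult(base_mesh=base, distances=dist, scale=(-lim, lim),
                         group_pair=tuple(pair), species=species,
                         meta={"method": method})


def heatmap_pairs(available_age_groups) -> list[tuple[int, int]]:
    """Standard subsequent-age-group pairs: (1,3) and (3,5), with (2,3)
    substituted when the youngest group is absent from the sample."""
    ags = set(int(a) for a in available_age_groups)
    pairs = []
    if 1 in ags and 3 in ags:
        pairs.append((1, 3))
    elif 2 in ags and 3 in ags:
        pairs.append((2, 3))
    if 3 in ags and 5 in ags:
        pairs.append((3, 5))
    return pairs
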