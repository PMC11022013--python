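"""Landmark template: the fixed-landmark / curve / surface-semilandmark scheme.

The measurement protocol digitizes 249 points on the right maxilla: 9 fixed
anatomical landmarks, 40 curve semilandmarks distributed over 8 sutural and
marginal curves, and 200 surface semilandmarks covering the bone. For testing
and simulation the template is realized on a smooth synthetic surface patch
(an open quadric over a rectangular parameter domain) so that tangents and
normals are everywhere well defined.

Axis convention: x runs anterior -> posterior, z inferior -> superior, and y
is the outward (facial) direction of the patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: fixed anatomical landmarks, in digitization order
FIXED_LABELS = ("sln", "d", "zyo", "ilr", "ans", "ids", "zm", "mro", "mps")

# (u, v) parameter positions of the fixed landmarks on the synthetic patch;
# u: anterior->posterior, v: inferior->superior.
_FIXED_UV = {
    "sln": (0.15, 0.95),  # superolateral nasion
    "d": (0.35, 0.92),    # dacryon
    "zyo": (0.60, 0.88),  # zygoorbitale
    "ilr": (0.10, 0.70),  # inferolateral rhinion
    "ans": (0.05, 0.45),  # anterior nasal spine
    "ids": (0.08, 0.05),  # alveolare (infradentale superius)
    "zm": (0.75, 0.60),   # zygomaxillare
    "mro": (0.90, 0.55),  # malar root origin
    "mps": (0.85, 0.05),  # maxillo-palatine suture
}

# curve name -> (number of interior semilandmarks, start anchor, end anchor)
CURVE_SCHEME = (
    ("fronto-maxillary suture", 2, "sln", "d"),
    ("naso-maxillary suture", 6, "sln", "ilr"),
    ("inferior orbital margin", 6, "d", "zyo"),
    ("nasal aperture outline", 6, "ilr", "ans"),
    ("subnasal outline", 3, "ans", "ids"),
    ("zygomatico-maxillary suture", 5, "zyo", "zm"),
    ("maxillary contour", 4, "zm", "mro"),
    ("alveolar outline", 8, "ids", "mps"),
)

# physical extent of the patch (mm): anterior-posterior, inferior-superior
_PATCH_SIZE = (40.0, 35.0)
_PATCH_HEIGHT = 10.0


def patch_surface(uv: np.ndarray) -> np.ndarray:
    """Map (u, v) in [0,1]^2 to 3-D points on the synthetic maxilla patch.

    The patch is an open elliptic-paraboloid cap: smooth, single-valued and
    bounded, so surface normals exist everywhere.
    """
    uv = np.asarray(uv, dtype=float)
    u, v = uv[..., 0], uv[..., 1]
    x = _PATCH_SIZE[0] * u
    z = _PATCH_SIZE[1] * v
    y = _PATCH_HEIGHT * (1.0 - 0.8 * (2 * u - 1) ** 2 - 0.6 * (2 * v - 1) ** 2)
    return np.stack([x, y, z], axis=-1)


def patch_normal(uv: np.ndarray) -> np.ndarray:
    """Outward unit normal of the synthetic patch at (u, v)."""
    uv = np.asarray(uv, dtype=float)
    u, v = uv[..., 0], uv[..., 1]
    # partial derivatives of patch_surface w.r.t. u and v
    du = np.stack(
        [np.full_like(u, _PATCH_SIZE[0]),
         _PATCH_HEIGHT * (-3.2) * (2 * u - 1),
         np.zeros_like(u)], axis=-1)
    dv = np.stack(
        [np.zeros_like(v),
         _PATCH_HEIGHT * (-2.4) * (2 * v - 1),
         np.full_like(v, _PATCH_SIZE[1])], axis=-1)
    n = np.cross(dv, du)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return n


@dataclass(frozen=True)
class Curve:
    """One semilandmark curve: interior sliding points between two fixed anchors."""

    name: str
    interior: tuple[int, ...]   # template indices of the sliding points, in order
    anchors: tuple[int, int]    # template indices of the fixed end landmarks

    @property
    def path(self) -> tuple[int, ...]:
        """Ordered point indices along the curve, anchors included."""
        return (self.anchors[0], *self.interior, self.anchors[1])


@dataclass(frozen=True)
class Template:
    """The landmark scheme plus its realization on the synthetic patch."""

    fixed_labels: tuple[str, ...]
    curves: tuple[Curve, ...]
    surface_indices: tuple[int, ...]
    coords: np.ndarray = field(repr=False)  # K x 3 template-mean positions (mm)
    uv: np.ndarray = field(repr=False)      # K x 2 parameter positions

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def fixed_indices(self) -> tuple[int, ...]:
        return tuple(range(len(self.fixed_labels)))

    @property
    def curve_indices(self) -> tuple[int, ...]:
        return tuple(i for c in self.curves for i in c.interior)

    @property
    def semilandmark_indices(self) -> tuple[int, ...]:
        return self.curve_indices + tuple(self.surface_indices)

    @property
    def anchor_indices(self) -> tuple[int, ...]:
        return tuple(sorted({i for c in self.curves for i in c.anchors}))

    def curve_by_name(self, name: str) -> Curve:
        for c in self.curves:
            if c.name == name:
                return c
        raise KeyError(name)

    def surface_normals(self) -> np.ndarray:
        """Analytic outward normals at the surface semilandmarks."""
        return patch_normal(self.uv[list(self.surface_indices)])

    def build_mesh(self, resolution: int = 40):
        """Triangulate the parametric patch into a SurfaceMesh.

        Returns a mesh whose vertices sample the same surface the template
        points lie on, suitable for warping and heatmap tests.
        """
        from .shape_change import SurfaceMesh

        u = np.linspace(0.0, 1.0, resolution)
        v = np.linspace(0.0, 1.0, resolution)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        verts = patch_surface(np.stack([uu.ravel(), vv.ravel()], axis=-1))
        faces = []
        for i in range(resolution - 1):
            for j in range(resolution - 1):
                a = i * resolution + j
                b = a + 1
                c = a + resolution
                d = c + 1
                faces.append((a, b, d))
                faces.append((a, d, c))
        return SurfaceMesh(vertices=verts, faces=np.asarray(faces, dtype=int))


def _stratified_uv(n: int, margin: float = 0.04) -> np.ndarray:
    """Deterministic stratified (u, v) sample: cell centres of a near-square
    grid covering the patch interior, row-major, first ``n`` taken."""
    rows = max(1, int(np.floor(np.sqrt(n))))
    cols = int(np.ceil(n / rows))
    lo, hi = margin, 1.0 - margin
    u = lo + (hi - lo) * (np.arange(rows) + 0.5) / rows
    v = lo + (hi - lo) * (np.arange(cols) + 0.5) / cols
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return np.stack([uu.ravel(), vv.ravel()], axis=-1)[:n]


def make_template(n_surface: int = 200) -> Template:
    """Build the standard template: 9 fixed landmarks, 8 curves with
    (2, 6, 6, 6, 3, 5, 4, 8) interior semilandmarks, and ``n_surface``
    surface semilandmarks (default total: 249 points).
    """
    if n_surface < 1:
        raise ValueError("n_surface must be >= 1")

    labels = FIXED_LABELS
    label_index = {lab: i for i, lab in enumerate(labels)}
    uv_list = [np.array(_FIXED_UV[lab]) for lab in labels]

    curves = []
    next_index = len(labels)
    for name, n_interior, a, b in CURVE_SCHEME:
        ua, ub = np.array(_FIXED_UV[a]), np.array(_FIXED_UV[b])
        fracs = (np.arange(1, n_interior + 1)) / (n_interior + 1)
        for f in fracs:
            uv_list.append(ua + f * (ub - ua))
        interior = tuple(range(next_index, next_index + n_interior))
        next_index += n_interior
        curves.append(Curve(name=name, interior=interior,
                            anchors=(label_index[a], label_index[b])))

    surf_uv = _stratified_uv(n_surface)
    uv_list.extend(surf_uv)
    surface_indices = tuple(range(next_index, next_index + n_surface))

    uv = np.asarray(uv_list, dtype=float)
    coords = patch_surface(uv)
    return Template(fixed_labels=labels, curves=tuple(curves),
                    surface_indices=surface_indices, coords=coords, uv=uv)
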