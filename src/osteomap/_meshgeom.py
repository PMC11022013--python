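"""Brute-force triangle-mesh geometry queries (numpy only).

Meshes in this pipeline are small (hundreds to a few thousand faces), so the
closest-point and ray-intersection queries are computed exhaustively against
all faces, vectorized per query point.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def closest_point_on_triangles(point: np.ndarray,
                               tri: np.ndarray) -> tuple[np.ndarray, int]:
    """Closest point to ``point`` over all triangles (F x 3 x 3).

    Returns (closest point, face index). Uses the standard region
    classification of the point against each triangle's barycentric edges.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = point - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = point - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = point - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    F = len(tri)
    out = np.empty((F, 3))
    done = np.zeros(F, dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)                      # vertex C
    vc = d1 * d4 - d3 * d2
    v_ab = np.divide(d1, d1 - d3, out=np.zeros(F), where=np.abs(d1 - d3) > _EPS)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    w_ac = np.divide(d2, d2 - d6, out=np.zeros(F), where=np.abs(d2 - d6) > _EPS)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    va = d3 * d6 - d5 * d4
    num = d4 - d3
    den = num + (d5 - d6)
    w_bc = np.divide(num, den, out=np.zeros(F), where=np.abs(den) > _EPS)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))
    denom = va + vb + vc
    v = np.divide(vb, denom, out=np.zeros(F), where=np.abs(denom) > _EPS)
    w = np.divide(vc, denom, out=np.zeros(F), where=np.abs(denom) > _EPS)
    assign(np.ones(F, dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    d = np.einsum("ij,ij->i", out - point, out - point)
    best = int(np.argmin(d))
    return out[best], best


def closest_points(points: np.ndarray, vertices: np.ndarray,
                   faces: np.ndarray,
                   return_faces: bool = False):
    """Closest surface points (and optionally face indices) for each query."""
    tri = vertices[faces]
    pts = np.atleast_2d(points)
    res = np.empty_like(pts, dtype=float)
    fidx = np.empty(len(pts), dtype=int)
    for i, p in enumerate(pts):
        res[i], fidx[i] = closest_point_on_triangles(p, tri)
    if return_faces:
        return res, fidx
    return res


def ray_mesh_signed_offsets(origins: np.ndarray, directions: np.ndarray,
                            vertices: np.ndarray,
                            faces: np.ndarray) -> np.ndarray:
    """For each (origin, unit direction) ray-line, the signed parameter t of
    the nearest-|t| intersection with the mesh (both directions searched);
    NaN where the line misses. Moller-Trumbore, vectorized over faces."""
    tri = vertices[faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    out = np.full(len(origins), np.nan)
    for i, (o, d) in enumerate(zip(origins, directions)):
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > _EPS
        inv = np.zeros_like(det)
        inv[ok] = 1.0 / det[ok]
        tvec = o - tri[:, 0]
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
        if hit.any():
            th = t[hit]
            out[i] = th[np.argmin(np.abs(th))]
    return out
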