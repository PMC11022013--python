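"""Bone-modelling (BM) resorption maps.

Each specimen's periosteal surface is quantified on a lattice of 2.5 x 2.5 mm
squares, each square carrying the percentage of its bone area showing
osteoclastic resorption (0 = formation/quiescence). Because specimens differ
in size, every raw grid is standardized to a common lattice (8 x 8 by
default) by area-weighted piecewise-constant resampling before averaging or
multivariate analysis.

Grid orientation convention: row 1 = superior, column 1 = anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EmptyMapError(ValueError):
    """Raised when a grid has no valid squares."""


def _validate_values(values: np.ndarray, valid: np.ndarray, who: str) -> None:
    v = values[valid]
    if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 100):
        raise ValueError(f"{who}: percent resorption outside [0, 100]")


@dataclass
class RawBMGrid:
    """Native-resolution resorption grid for one specimen."""

    specimen_id: str
    values: np.ndarray              # n_rows x n_cols, %BR where valid
    valid: np.ndarray = None        # boolean mask; off-bone squares False
    square_size: float = 2.5        # mm
    areas: np.ndarray | None = None  # optional per-square bone area (mm^2)
    species: str | None = None
    age_group: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = ~np.isnan(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match values shape")
        if self.square_size <= 0:
            raise ValueError("square_size must be positive")
        _validate_values(self.values, self.valid, self.specimen_id)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedBMMap:
    """Resorption map resampled onto the common lattice (default 8 x 8)."""

    specimen_id: str
    values: np.ndarray
    valid: np.ndarray
    provenance: tuple[int, int] = (0, 0)   # source grid dims
    species: str | None = None
    age_group: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        _validate_values(self.values, self.valid, self.specimen_id)


@dataclass
class MeanBMMap:
    """Per-square mean map for one species x age-group cell."""

    species: str
    age_group: int
    values: np.ndarray
    valid: np.ndarray
    n_specimens: np.ndarray        # per-square count of contributing maps
    meta: dict = field(default_factory=dict)


def _overlap_weights(n_src: int, n_tgt: int) -> np.ndarray:
    """n_tgt x n_src matrix of interval-overlap lengths when [0, 1] is cut
    into n_src equal source and n_tgt equal target intervals."""
    src_edges = np.linspace(0.0, 1.0, n_src + 1)
    tgt_edges = np.linspace(0.0, 1.0, n_tgt + 1)
    lo = np.maximum(tgt_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(tgt_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def standardize_bm_grid(grid: RawBMGrid,
                        target: tuple[int, int] = (8, 8),
                        coverage_threshold: float = 0.5) -> StandardizedBMMap:
    """Resample a raw grid onto the target lattice.

    The source is treated as piecewise-constant over its valid squares and
    stretched to the target extent; each target square takes the area-weighted
    average of overlapping valid source squares, and is masked when valid
    source coverage falls below ``coverage_threshold`` of its area. On fully
    valid grids the valid-area-weighted mean is conserved exactly (up to
    float roundoff).
    """
    if not grid.valid.any():
        raise EmptyMapError(f"{grid.specimen_id}: all squares masked")
    rows, cols = target
    Wr = _overlap_weights(grid.n_rows, rows)    # rows x n_src_rows
    Wc = _overlap_weights(grid.n_cols, cols)
    vals = np.where(grid.valid, grid.values, 0.0)
    weight = Wr @ grid.valid.astype(float) @ Wc.T
    total = Wr @ np.ones_like(vals) @ Wc.T
    accum = Wr @ vals @ Wc.T
    with np.errstate(invalid="ignore"):
        out = accum / weight
    valid = weight >= coverage_threshold * total - 1e-12
    out[~valid] = np.nan
    out = np.clip(out, 0.0, 100.0)  # guard float roundoff at the bounds
    out[~valid] = np.nan
    return StandardizedBMMap(specimen_id=grid.specimen_id, values=out,
                             valid=valid,
                             provenance=(grid.n_rows, grid.n_cols),
                             species=grid.species, age_group=grid.age_group)


def mean_bm_map(maps: list[StandardizedBMMap], species: str,
                age_group: int,
                coverage_threshold: float = 0.5) -> MeanBMMap:
    """Average standardized maps square-by-square within one cell.

    Each square's mean is taken over the specimens valid there; a square is
    reported valid when at least ``coverage_threshold`` of the cell's
    specimens are valid at it.
    """
    cell = [m for m in maps
            if m.species == species and m.age_group == age_group]
    if not cell:
        cells = sorted({(m.species, m.age_group) for m in maps})
        raise EmptyMapError(
            f"no maps for ({species}, AG {age_group}); available: {cells}")
    stack = np.stack([np.where(m.valid, m.values, 0.0) for m in cell])
    valid = np.stack([m.valid for m in cell])
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = stack.sum(axis=0) / n
    ok = n >= coverage_threshold * len(cell)
    mean[~ok] = np.nan
    return MeanBMMap(species=species, age_group=age_group, values=mean,
                     valid=ok, n_specimens=n)


def total_percent_resorption(grid: RawBMGrid) -> float:
    """Total %BR for one individual: resorbed area over total measured bone
    area, i.e. the bone-area-weighted mean of the valid squares' values."""
    if not grid.valid.any():
        raise EmptyMapError(f"{grid.specimen_id}: no valid squares")
    if grid.areas is not None:
        areas = np.asarray(grid.areas, dtype=float)
    else:
        areas = np.full_like(grid.values, grid.square_size ** 2)
    v = grid.valid
    return float(np.sum(grid.values[v] * areas[v]) / np.sum(areas[v]))


def common_mask(maps: list[StandardizedBMMap],
                threshold: float = 0.5) -> np.ndarray:
    """Squares valid in more than ``threshold`` of all specimens."""
    valid = np.stack([m.valid for m in maps])
    return valid.mean(axis=0) > threshold


def square_ids(mask: np.ndarray) -> pd.DataFrame:
    """Enumerate the common-mask squares row-major from the
    superior-anterior corner (row 1 = superior, column 1 = anterior)."""
    rows, cols = np.nonzero(mask)
    return pd.DataFrame({"square_id": np.arange(1, len(rows) + 1),
                         "row": rows + 1, "col": cols + 1})


def per_square_profile(maps: list[StandardizedBMMap],
                       mask_threshold: float = 0.5) -> pd.DataFrame:
    """Long table of per-square mean %BR by species and age group.

    One row per common-mask square x species x age group, with the mean over
    the specimens valid at that square and their count.
    """
    mask = common_mask(maps, mask_threshold)
    ids = square_ids(mask)
    rows = []
    cells = sorted({(m.species, m.age_group) for m in maps})
    for sp, ag in cells:
        cell = [m for m in maps if m.species == sp and m.age_group == ag]
        stack = np.stack([np.where(m.valid, m.values, 0.0) for m in cell])
        valid = np.stack([m.valid for m in cell])
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = stack.sum(axis=0) / n
        for _, r in ids.iterrows():
            i, j = int(r["row"]) - 1, int(r["col"]) - 1
            rows.append({"square_id": int(r["square_id"]),
                         "row": i + 1, "col": j + 1,
                         "species": sp, "age_group": ag,
                         "mean_pct_br": mean[i, j] if n[i, j] else np.nan,
                         "n": int(n[i, j])})
    return pd.DataFrame(rows)


def bm_matrix(maps: list[StandardizedBMMap],
              mask_threshold: float = 0.5,
              impute: str = "grand_mean") -> tuple[np.ndarray, pd.DataFrame, list]:
    """Specimens x common-squares %BR matrix for PCA / PERMANOVA.

    Missing squares within an individual are imputed label-blind with the
    across-specimen mean at that square (``impute="grand_mean"``, the
    default: group labels play no role, so the rows stay exchangeable under
    a true null and permutation tests keep their nominal size). Imputing
    with the species x age-group cell mean (``impute="cell_mean"``) is
    available but makes same-group rows artificially similar and inflates
    between-group test statistics; ``impute="restrict"`` instead drops
    squares not valid in every specimen. Returns the matrix, per-specimen
    metadata, and the imputation log as (specimen, n-squares) pairs.
    """
    if impute not in ("grand_mean", "cell_mean", "restrict"):
        raise ValueError(f"unknown imputation policy {impute!r}")
    mask = common_mask(maps, mask_threshold)
    if impute == "restrict":
        mask = mask & np.all(np.stack([m.valid for m in maps]), axis=0)
    rr, cc = np.nonzero(mask)
    X = np.stack([m.values[rr, cc] for m in maps])
    V = np.stack([m.valid[rr, cc] for m in maps])
    meta = pd.DataFrame({
        "specimen_id": [m.specimen_id for m in maps],
        "species": [m.species for m in maps],
        "age_group": [m.age_group for m in maps]})
    imputed = []

    def fill(col_means_for):
        for k in range(len(maps)):
            holes = ~V[k]
            if holes.any():
                X[k, holes] = col_means_for(k)[holes]
                imputed.append((maps[k].specimen_id, int(holes.sum())))

    if impute == "grand_mean":
        with np.errstate(invalid="ignore"):
            grand = np.where(V, X, 0.0).sum(axis=0) / V.sum(axis=0)
        grand = np.nan_to_num(grand, nan=0.0)
        fill(lambda k: grand)
    elif impute == "cell_mean":
        cell_means = {}
        for key, idx in meta.groupby(["species", "age_group"]).groups.items():
            idx = np.asarray(idx)
            with np.errstate(invalid="ignore"):
                cm = (np.where(V[idx], X[idx], 0.0).sum(axis=0)
                      / V[idx].sum(axis=0))
            cell_means[key] = np.nan_to_num(
                cm, nan=float(np.nanmean(np.where(V, X, np.nan))))
        lookup = {k: cell_means[(meta["species"][k], meta["age_group"][k])]
                  for k in range(len(maps))}
        fill(lambda k: lookup[k])
    X = np.nan_to_num(X, nan=0.0)
    return X, meta, imputed


def project_map_on_mesh(bm_map: MeanBMMap, mean_mesh, grid_frame,
                        no_data: float = np.nan):
    """Paint a mean BM map onto a surface mesh.

    ``grid_frame`` maps mesh vertices into grid coordinates: a callable
    taking V x 3 vertices and returning V x 2 fractional (row, col) positions
    in [0, n_rows] x [0, n_cols]. Each vertex takes the value of its
    containing square; masked squares and out-of-grid vertices carry the
    no-data marker.
    """
    import logging

    verts = mean_mesh.vertices
    rc = np.asarray(grid_frame(verts), dtype=float)
    rows, cols = bm_map.values.shape
    r = np.floor(rc[:, 0]).astype(int)
    c = np.floor(rc[:, 1]).astype(int)
    inside = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
    scalar = np.full(len(verts), no_data)
    rr, cc = r[inside], c[inside]
    vals = np.where(bm_map.valid[rr, cc], bm_map.values[rr, cc], no_data)
    scalar[inside] = vals
    if inside.mean() < 0.5:
        logging.getLogger(__name__).warning(
            "grid placement covers only %.0f%% of mesh vertices",
            100 * inside.mean())
    out = type(mean_mesh)(vertices=verts.copy(), faces=mean_mesh.faces.copy(),
                          per_vertex_scalar=scalar)
    return out
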