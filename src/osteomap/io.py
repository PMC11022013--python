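"""Readers and writers for the interchange formats.

Landmark tables are tidy delimited text (one row per specimen x landmark,
blank/NA coordinates meaning missing); the classic TPS landmark-file dialect
(LM3= blocks) is also read. Bone-modelling grids are CSV matrices with a
``# key: value`` header block; masked squares are written as NA. Everything
round-trips bit-identically through ``repr``-precision floats.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bm import RawBMGrid, StandardizedBMMap
from .landmarks import LandmarkConfiguration

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- landmarks

def point_labels(template) -> list[str]:
    """Human-readable label per template point."""
    labels = [None] * template.n_landmarks
    for i, lab in enumerate(template.fixed_labels):
        labels[i] = lab
    for curve in template.curves:
        for k, idx in enumerate(curve.interior, start=1):
            labels[idx] = f"{curve.name}:{k}"
    for k, idx in enumerate(template.surface_indices, start=1):
        labels[idx] = f"surface:{k}"
    return labels


def write_landmark_table(configs, path, template=None) -> None:
    """Write landmark configurations to one tidy CSV."""
    if isinstance(configs, LandmarkConfiguration):
        configs = [configs]
    labels = point_labels(template) if template is not None else None
    rows = []
    for c in configs:
        for i in range(c.n_landmarks):
            x, y, z = c.coords[i]
            rows.append({
                "specimen_id": c.specimen_id,
                "species": c.species if c.species is not None else "",
                "age_group": c.age_group if c.age_group is not None else "",
                "side": c.side,
                "landmark": i,
                "label": labels[i] if labels else "",
                "x": "" if c.missing[i] else repr(float(x)),
                "y": "" if c.missing[i] else repr(float(y)),
                "z": "" if c.missing[i] else repr(float(z)),
                "missing": int(c.missing[i])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmark_table(path, expected_landmarks: int | None = None
                        ) -> list[LandmarkConfiguration]:
    """Read a tidy landmark CSV back into configurations.

    Blank or NA coordinates (or a set missing flag) mark missing landmarks.
    When ``expected_landmarks`` is given (e.g. the template size), every
    specimen's point count is validated against it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"specimen_id": str},
                         float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    needed = {"specimen_id", "landmark", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {needed - set(df.columns)}")
    out = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("landmark")
        k = len(sub)
        if expected_landmarks is not None and k != expected_landmarks:
            raise FormatError(
                f"{path}: specimen {sid!r} has {k} landmarks, "
                f"expected {expected_landmarks}")
        coords = np.full((k, 3), np.nan)
        for axis_i, axis in enumerate(("x", "y", "z")):
            col = pd.to_numeric(sub[axis], errors="coerce")
            bad = col.isna() & sub[axis].notna() & (sub[axis].astype(str)
                                                    .str.strip() != "")
            bad &= ~sub[axis].astype(str).str.upper().isin(["NA", "NAN"])
            if bad.any():
                line = int(sub.index[bad.values][0]) + 2  # header + 1-based
                raise FormatError(
                    f"{path}: non-numeric coordinate at line {line}")
            coords[:, axis_i] = col.to_numpy()
        missing = np.any(np.isnan(coords), axis=1)
        if "missing" in sub.columns:
            missing |= sub["missing"].fillna(0).astype(int).to_numpy() > 0
        coords[missing] = np.nan
        species = sub["species"].iloc[0] if "species" in sub.columns else None
        if pd.isna(species) or species == "":
            species = None
        ag = sub["age_group"].iloc[0] if "age_group" in sub.columns else None
        ag = None if (ag is None or pd.isna(ag) or ag == "") else int(ag)
        side = sub["side"].iloc[0] if "side" in sub.columns else "right"
        out.append(LandmarkConfiguration(
            specimen_id=str(sid), coords=coords, missing=missing,
            species=species, age_group=ag,
            side=side if isinstance(side, str) else "right"))
    return out


_TPS_MISSING = -999.0


def read_tps_file(path, expected_landmarks: int | None = None
                  ) -> list[LandmarkConfiguration]:
    """Read the classic TPS landmark dialect (``LM3=`` blocks, ``ID=`` lines;
    ``-999 -999 -999`` rows mean missing)."""
    path = Path(path)
    configs = []
    coords, sid, n_expect = None, None, 0
    counter = 0

    def flush():
        nonlocal coords, sid
        if coords is None:
            return
        if len(coords) != n_expect:
            raise FormatError(
                f"{path}: block {sid or counter!r} declares LM3={n_expect} "
                f"but has {len(coords)} rows")
        arr = np.asarray(coords, dtype=float)
        missing = np.all(arr == _TPS_MISSING, axis=1)
        arr[missing] = np.nan
        if expected_landmarks is not None and len(arr) != expected_landmarks:
            raise FormatError(
                f"{path}: specimen {sid!r} has {len(arr)} landmarks, "
                f"expected {expected_landmarks}")
        configs.append(LandmarkConfiguration(
            specimen_id=sid or f"specimen_{counter}", coords=arr,
            missing=missing))
        coords, sid = None, None

    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            flush()
            counter += 1
            n_expect = int(line.split("=", 1)[1])
            coords = []
        elif upper.startswith("ID="):
            sid = line.split("=", 1)[1].strip()
        elif "=" in line and coords is not None and len(coords) >= n_expect:
            continue  # other TPS metadata (IMAGE=, SCALE=, ...)
        else:
            if coords is None:
                raise FormatError(f"{path}: line {ln}: data before LM3=")
            parts = line.split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {ln}: non-numeric coordinate") from exc
            if len(vals) < 3:
                vals += [0.0] * (3 - len(vals))
            coords.append(vals)
    flush()
    return configs


# -------------------------------------------------------------------- grids

def write_bm_grid(grid, path) -> None:
    """Write one raw grid (or standardized map) as a headered CSV."""
    path = Path(path)
    values = np.where(grid.valid, grid.values, np.nan)
    lines = [f"# specimen_id: {grid.specimen_id}"]
    if grid.species is not None:
        lines.append(f"# species: {grid.species}")
    if grid.age_group is not None:
        lines.append(f"# age_group: {grid.age_group}")
    lines.append(f"# n_rows: {values.shape[0]}")
    lines.append(f"# n_cols: {values.shape[1]}")
    if isinstance(grid, RawBMGrid):
        lines.append(f"# square_size_mm: {repr(float(grid.square_size))}")
    for row in values:
        lines.append(",".join("NA" if np.isnan(v) else repr(float(v))
                              for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_bm_grid(path) -> RawBMGrid:
    """Read a grid CSV. A missing square_size header falls back to the
    2.5 mm protocol default (logged)."""
    path = Path(path)
    header: dict[str, str] = {}
    matrix = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, val = line[1:].split(":", 1)
                header[key.strip()] = val.strip()
            continue
        row = []
        for cell in line.split(","):
            cell = cell.strip()
            if cell.upper() in ("NA", "NAN", ""):
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {ln}: non-numeric value "
                        f"{cell!r}") from exc
        matrix.append(row)
    if not matrix:
        raise FormatError(f"{path}: no matrix block")
    widths = {len(r) for r in matrix}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged matrix rows")
    values = np.asarray(matrix, dtype=float)
    for key, dim in (("n_rows", 0), ("n_cols", 1)):
        if key in header and int(header[key]) != values.shape[dim]:
            raise FormatError(
                f"{path}: header {key}={header[key]} does not match matrix "
                f"shape {values.shape}")
    if "square_size_mm" in header:
        square = float(header["square_size_mm"])
    else:
        square = 2.5
        log.info("%s: no square_size header; using protocol default 2.5 mm",
                 path)
    finite = values[~np.isnan(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise FormatError(f"{path}: percent resorption outside [0, 100]")
    ag = header.get("age_group")
    return RawBMGrid(specimen_id=header.get("specimen_id", path.stem),
                     values=values, valid=~np.isnan(values),
                     square_size=square, species=header.get("species"),
                     age_group=int(ag) if ag is not None else None)


def read_bm_grids(paths) -> list[RawBMGrid]:
    return [read_bm_grid(p) for p in paths]


def write_standardized_map(m: StandardizedBMMap, path) -> None:
    write_bm_grid(m, path)


# ------------------------------------------------------------------- meshes

def write_mesh_ply(mesh, path) -> None:
    """ASCII PLY with an optional per-vertex ``quality`` scalar."""
    path = Path(path)
    v = mesh.vertices
    f = mesh.faces
    scalar = mesh.per_vertex_scalar
    lines = ["ply", "format ascii 1.0", f"element vertex {len(v)}",
             "property float x", "property float y", "property float z"]
    if scalar is not None:
        lines.append("property float quality")
    lines += [f"element face {len(f)}",
              "property list uchar int vertex_indices", "end_header"]
    for i, (x, y, z) in enumerate(v):
        row = f"{x:.8g} {y:.8g} {z:.8g}"
        if scalar is not None:
            s = scalar[i]
            row += f" {(-1e30 if np.isnan(s) else s):.8g}"
        lines.append(row)
    for a, b, c in f:
        lines.append(f"3 {a} {b} {c}")
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path):
    """Read a PLY/OBJ mesh into a SurfaceMesh (via trimesh)."""
    import trimesh

    from .shape_change import SurfaceMesh

    tm = trimesh.load(str(path), process=False, force="mesh")
    return SurfaceMesh.from_trimesh(tm)
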