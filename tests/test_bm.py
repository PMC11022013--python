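import numpy as np
import pandas as pd
import pytest

from osteomap import (MeanBMMap, RawBMGrid, StandardizedBMMap, SurfaceMesh,
                      common_mask, mean_bm_map, per_square_profile,
                      project_map_on_mesh, standardize_bm_grid,
                      total_percent_resorption)
from osteomap.bm import EmptyMapError


def rasterization_oracle(grid, target=(8, 8)):
    """Independent fine-rasterization resampling: paint the source grid onto
    a raster whose pixel boundaries align with both lattices, then average
    per target cell."""
    tr, tc = target
    fr = grid.n_rows * tr          # commensurate fine resolution
    fc = grid.n_cols * tc
    src_r = (np.arange(fr) * grid.n_rows // fr)
    src_c = (np.arange(fc) * grid.n_cols // fc)
    fine_vals = grid.values[np.ix_(src_r, src_c)]
    fine_valid = grid.valid[np.ix_(src_r, src_c)]
    out = np.full(target, np.nan)
    valid = np.zeros(target, dtype=bool)
    pr, pc = fr // tr, fc // tc
    for i in range(tr):
        for j in range(tc):
            v = fine_vals[i * pr:(i + 1) * pr, j * pc:(j + 1) * pc]
            ok = fine_valid[i * pr:(i + 1) * pr, j * pc:(j + 1) * pc]
            cover = ok.mean()
            if cover >= 0.5:
                valid[i, j] = True
                out[i, j] = v[ok].mean()
    return out, valid


def random_grid(rng, rows, cols, mask_frac=0.2):
    values = rng.uniform(0, 100, size=(rows, cols))
    valid = rng.random((rows, cols)) > mask_frac
    valid[rows // 2, cols // 2] = True
    values[~valid] = np.nan
    return RawBMGrid(f"g{rows}x{cols}", values, valid)


class TestStandardization:
    def test_identity_on_full_8x8(self, rng):
        g = RawBMGrid("s", rng.uniform(0, 100, size=(8, 8)))
        out = standardize_bm_grid(g)
        assert np.allclose(out.values, g.values)
        assert out.valid.all()

    def test_half_and_half_4x4(self):
        vals = np.tile([20.0, 20, 40, 40], (4, 1))
        out = standardize_bm_grid(RawBMGrid("s", vals))
        assert np.allclose(out.values[:, :4], 20.0)
        assert np.allclose(out.values[:, 4:], 40.0)

    @pytest.mark.parametrize("rows,cols", [(3, 5), (5, 3), (7, 9), (12, 10)])
    def test_matches_rasterization_oracle(self, rng, rows, cols):
        g = random_grid(rng, rows, cols)
        out = standardize_bm_grid(g)
        o_vals, o_valid = rasterization_oracle(g)
        assert np.array_equal(out.valid, o_valid)
        assert np.nanmax(np.abs(np.where(out.valid, out.values, 0)
                                - np.where(o_valid, o_vals, 0))) < 1e-6

    def test_weighted_mean_conserved_on_fully_valid(self, rng):
        for rows, cols in [(3, 3), (5, 7), (11, 4)]:
            g = RawBMGrid("s", rng.uniform(0, 100, size=(rows, cols)))
            out = standardize_bm_grid(g)
            assert out.values.mean() == pytest.approx(g.values.mean(),
                                                      abs=1e-9)

    def test_all_masked_raises(self):
        g = RawBMGrid("s", np.full((4, 4), np.nan))
        with pytest.raises(EmptyMapError):
            standardize_bm_grid(g)

    def test_low_coverage_cells_masked(self):
        vals = np.full((8, 8), 50.0)
        vals[0, :] = np.nan       # top row off-bone
        out = standardize_bm_grid(RawBMGrid("s", vals))
        assert not out.valid[0].any()
        assert out.valid[1:].all()


def _smap(sid, values, valid=None, species="a", ag=1):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = ~np.isnan(values)
    return StandardizedBMMap(specimen_id=sid, values=values, valid=valid,
                             species=species, age_group=ag)


class TestMeanMap:
    def test_identical_maps(self, rng):
        v = rng.uniform(0, 100, size=(8, 8))
        mm = mean_bm_map([_smap("a", v), _smap("b", v)], "a", 1)
        assert np.allclose(mm.values, v)
        assert mm.valid.all()

    def test_two_values_average(self):
        mm = mean_bm_map([_smap("a", np.full((8, 8), 10.0)),
                          _smap("b", np.full((8, 8), 30.0))], "a", 1)
        assert np.allclose(mm.values, 20.0)

    def test_masked_specimen_excluded_square(self):
        v1 = np.full((8, 8), 10.0)
        v2 = np.full((8, 8), 30.0)
        v3 = np.full((8, 8), 50.0)
        v3[2, 2] = np.nan
        mm = mean_bm_map([_smap("a", v1), _smap("b", v2), _smap("c", v3)],
                         "a", 1)
        assert mm.values[2, 2] == pytest.approx(20.0)   # mean of 10, 30
        assert mm.values[0, 0] == pytest.approx(30.0)
        assert mm.n_specimens[2, 2] == 2

    def test_empty_cell_raises(self):
        with pytest.raises(EmptyMapError, match="available"):
            mean_bm_map([_smap("a", np.zeros((8, 8)))], "b", 1)


class TestTotalResorption:
    def test_all_zero(self):
        assert total_percent_resorption(
            RawBMGrid("s", np.zeros((3, 3)))) == 0.0

    def test_area_weighting_forced_arithmetic(self):
        g = RawBMGrid("s", np.array([[100.0, 0.0]]),
                      areas=np.array([[1.0, 3.0]]))
        assert total_percent_resorption(g) == pytest.approx(25.0)

    def test_matches_accumulation_oracle(self, rng):
        g = random_grid(rng, 6, 6)
        total_w = total_v = 0.0
        for i in range(6):
            for j in range(6):
                if g.valid[i, j]:
                    total_v += g.values[i, j] * g.square_size ** 2
                    total_w += g.square_size ** 2
        assert total_percent_resorption(g) == pytest.approx(
            total_v / total_w, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(10):
            g = random_grid(rng, 5, 5)
            assert 0.0 <= total_percent_resorption(g) <= 100.0


class TestPerSquareProfile:
    def test_all_valid_gives_64_common_squares(self, rng):
        maps = [_smap(f"s{i}", rng.uniform(0, 100, (8, 8)), species="a",
                      ag=1 + i % 2) for i in range(4)]
        prof = per_square_profile(maps)
        assert prof["square_id"].nunique() == 64
        assert set(prof.groupby(["species", "age_group"]).groups) == \
            {("a", 1), ("a", 2)}

    def test_identical_species_have_identical_profiles(self, rng):
        v = rng.uniform(0, 100, (8, 8))
        maps = [_smap("a1", v, species="a"), _smap("b1", v, species="b")]
        prof = per_square_profile(maps)
        pa = prof[prof.species == "a"].set_index("square_id")["mean_pct_br"]
        pb = prof[prof.species == "b"].set_index("square_id")["mean_pct_br"]
        pd.testing.assert_series_equal(pa, pb, check_names=False)

    def test_common_mask_threshold(self):
        v_ok = np.zeros((8, 8))
        v_holed = np.zeros((8, 8))
        v_holed[0, 0] = np.nan
        maps = [_smap("a", v_ok), _smap("b", v_holed), _smap("c", v_holed)]
        mask = common_mask(maps)
        assert not mask[0, 0]       # valid in only 1/3 of specimens
        assert mask.sum() == 63


class TestProjectOnMesh:
    def flat_mesh(self, nx=16, ny=16):
        x, y = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny),
                           indexing="ij")
        verts = np.stack([x.ravel(), y.ravel(), np.zeros(nx * ny)], axis=-1)
        faces = []
        for i in range(nx - 1):
            for j in range(ny - 1):
                a = i * ny + j
                faces.append((a, a + 1, a + ny))
                faces.append((a + 1, a + ny + 1, a + ny))
        return SurfaceMesh(verts, np.asarray(faces))

    def frame(self, verts):
        # vertices' (x, y) in [0,1] -> fractional (row, col) on an 8x8 grid
        return np.stack([verts[:, 0] * 8 * 0.999,
                         verts[:, 1] * 8 * 0.999], axis=-1)

    def test_uniform_map(self):
        mm = MeanBMMap("a", 1, np.full((8, 8), 33.0),
                       np.ones((8, 8), bool), np.ones((8, 8), int))
        out = project_map_on_mesh(mm, self.flat_mesh(), self.frame)
        assert np.allclose(out.per_vertex_scalar, 33.0)

    def test_checkerboard_map(self):
        vals = np.indices((8, 8)).sum(axis=0) % 2 * 100.0
        mm = MeanBMMap("a", 1, vals, np.ones((8, 8), bool),
                       np.ones((8, 8), int))
        mesh = self.flat_mesh()
        out = project_map_on_mesh(mm, mesh, self.frame)
        rc = np.floor(self.frame(mesh.vertices)).astype(int)
        expect = vals[rc[:, 0], rc[:, 1]]
        assert np.array_equal(out.per_vertex_scalar, expect)

    def test_masked_cell_carries_no_data(self):
        vals = np.full((8, 8), 10.0)
        valid = np.ones((8, 8), bool)
        valid[0, 0] = False
        mm = MeanBMMap("a", 1, vals, valid, np.ones((8, 8), int))
        mesh = self.flat_mesh()
        out = project_map_on_mesh(mm, mesh, self.frame)
        rc = np.floor(self.frame(mesh.vertices)).astype(int)
        in_masked = (rc[:, 0] == 0) & (rc[:, 1] == 0)
        assert np.isnan(out.per_vertex_scalar[in_masked]).all()
        assert not np.isnan(out.per_vertex_scalar[~in_masked]).any()
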