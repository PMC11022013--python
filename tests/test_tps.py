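import numpy as np
import pytest

from osteomap import (LandmarkConfiguration, SimulationConfig,
                      estimate_missing_landmarks, simulate_dataset, tps_apply,
                      tps_fit)
from osteomap.tps import DegenerateConfigurationError, bending_energy_matrix


def tps_oracle(source, target):
    """Independent direct solve of the full bordered TPS system; returns
    (weights, energy). Kept deliberately separate from the implementation."""
    n = len(source)
    r = np.sqrt(((source[:, None, :] - source[None, :, :]) ** 2).sum(-1))
    K = -r
    P = np.concatenate([np.ones((n, 1)), source], axis=1)
    L = np.block([[K, P], [P.T, np.zeros((4, 4))]])
    sol = np.linalg.solve(L, np.concatenate([target, np.zeros((4, 3))]))
    w = sol[:n]
    return w, float(sum(w[:, d] @ K @ w[:, d] for d in range(3)))


def random_system(rng, n):
    src = rng.normal(scale=10.0, size=(n, 3))
    tgt = src + rng.normal(scale=2.0, size=(n, 3))
    return src, tgt


def test_identity_map_has_zero_energy(rng):
    src = rng.normal(size=(10, 3))
    m = tps_fit(src, src)
    assert np.allclose(m.affine, np.eye(3), atol=1e-8)
    assert np.allclose(m.nonaffine_weights, 0.0, atol=1e-8)
    assert m.bending_energy == pytest.approx(0.0, abs=1e-10)


def test_pure_translation_is_affine(rng):
    src = rng.normal(size=(7, 3))
    m = tps_fit(src, src + np.array([1.0, 2.0, 3.0]))
    assert m.bending_energy == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(m.translation, [1, 2, 3], atol=1e-8)
    # affinity preserves midpoints
    mid = (src[0] + src[1]) / 2
    img = tps_apply(m, mid[None])[0]
    assert np.allclose(img, mid + [1, 2, 3], atol=1e-8)


def test_general_affine_target_has_zero_energy(rng):
    src = rng.normal(size=(9, 3))
    A = np.array([[1.2, 0.3, 0.0], [-0.1, 0.9, 0.2], [0.0, 0.1, 1.5]])
    m = tps_fit(src, src @ A.T + [0.5, -1.0, 2.0])
    assert m.bending_energy == pytest.approx(0.0, abs=1e-9)


def test_interpolation_exact_on_random_systems(rng):
    for _ in range(20):
        n = int(rng.integers(6, 31))
        src, tgt = random_system(rng, n)
        m = tps_fit(src, tgt)
        assert np.abs(tps_apply(m, src) - tgt).max() < 1e-8


def test_energy_matches_independent_linear_system_oracle(rng):
    src, tgt = random_system(rng, 6)
    m = tps_fit(src, tgt)
    _, e_oracle = tps_oracle(src, tgt)
    assert m.bending_energy == pytest.approx(e_oracle, rel=1e-9)


def test_energy_invariant_under_rigid_motion(rng):
    src, tgt = random_system(rng, 12)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    shift = np.array([5.0, -3.0, 2.0])
    e0 = tps_fit(src, tgt).bending_energy
    e1 = tps_fit(src @ R.T + shift, tgt @ R.T + shift).bending_energy
    assert e1 == pytest.approx(e0, rel=1e-9)


def test_bending_energy_matrix_agrees_with_fit(rng):
    src, tgt = random_system(rng, 10)
    B = bending_energy_matrix(src)
    e_quadratic = float(np.trace(tgt.T @ B @ tgt))
    assert e_quadratic == pytest.approx(tps_fit(src, tgt).bending_energy,
                                        rel=1e-9)


def test_degenerate_control_points_raise(rng):
    coincident = np.zeros((5, 3))
    with pytest.raises(DegenerateConfigurationError):
        tps_fit(coincident, coincident + 1)
    collinear = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateConfigurationError):
        tps_fit(collinear, collinear)


class TestMissingLandmarkEstimation:
    def test_identity_reference_restores_deleted_point(self, rng):
        ref = rng.normal(size=(12, 3))
        coords = ref.copy()
        coords[5] = np.nan
        cfg = LandmarkConfiguration("s", coords)
        out = estimate_missing_landmarks(cfg, ref)
        assert not out.missing.any()
        assert np.allclose(out.coords[5], ref[5], atol=1e-8)

    def test_affine_image_restored_exactly(self, rng):
        ref = rng.normal(size=(15, 3))
        A = np.array([[1.1, 0.2, 0], [0, 0.9, 0.1], [0.1, 0, 1.3]])
        true = ref @ A.T + [1, 2, 3]
        coords = true.copy()
        coords[[3, 11]] = np.nan
        out = estimate_missing_landmarks(LandmarkConfiguration("s", coords), ref)
        assert np.allclose(out.coords, true, atol=1e-8)

    def test_zero_noise_synthetic_restoration_against_truth(self):
        cfg = SimulationConfig(n_per_cell=1, seed=5, landmark_noise_sd=0.0,
                               missing_landmark_rate=0.05)
        ds = simulate_dataset(cfg)
        spacing = 2.5  # approximate semilandmark spacing on the patch (mm)
        for lm, _ in ds.specimens[:10]:
            if not lm.missing.any():
                continue
            truth = ds.truth.cell_mean_landmarks(lm.species, lm.age_group)
            out = estimate_missing_landmarks(lm, ds.truth.template.coords)
            err = np.linalg.norm(out.coords[lm.missing]
                                 - truth[lm.missing], axis=1)
            assert err.mean() < spacing

    def test_too_few_shared_points_raise(self, rng):
        ref = rng.normal(size=(6, 3))
        coords = np.full((6, 3), np.nan)
        coords[:3] = ref[:3]
        with pytest.raises(ValueError, match="shared"):
            estimate_missing_landmarks(LandmarkConfiguration("s", coords), ref)

    def test_original_points_untouched(self, rng):
        ref = rng.normal(size=(10, 3))
        coords = ref + rng.normal(scale=0.3, size=(10, 3))
        coords[2] = np.nan
        cfg = LandmarkConfiguration("s", coords)
        out = estimate_missing_landmarks(cfg, ref)
        keep = ~cfg.missing
        assert np.array_equal(out.coords[keep], cfg.coords[keep])
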