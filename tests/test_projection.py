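import numpy as np
import pandas as pd
import pytest

from gradientshift import (make_gradient_basis, project_map, projection_table,
                           shift_scores, shift_table, euclidean_shift,
                           region_shift_table)
from gradientshift.io import ActivationMap, Condition, RegionAtlas
from gradientshift.simulate import GradientBasis


def brute_force_pearson(x, y):
    """Textbook two-pass Pearson correlation."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def _proj_df(z_by_gradient):
    return pd.DataFrame({"gradient_id": list(range(1, len(z_by_gradient) + 1)),
                         "r": np.tanh(z_by_gradient), "z": z_by_gradient})


class TestProjectMap:
    def test_worked_value_equal_mixture(self):
        # map = 0.5 g1 + 0.5 g2 on an orthonormal basis: r = 1/sqrt(2)
        basis = make_gradient_basis(1000, K=5, seed=7)
        vec = 0.5 * basis.maps[:, 0] + 0.5 * basis.maps[:, 1]
        out = project_map(vec, basis)
        assert out.loc[0, "r"] == pytest.approx(0.7071, abs=1e-4)
        assert out.loc[0, "z"] == pytest.approx(0.8814, abs=1e-4)

    def test_identity_map_clipped_not_inf(self):
        basis = make_gradient_basis(500, K=2, seed=1)
        out = project_map(basis.maps[:, 0].copy(), basis)
        assert np.isfinite(out.loc[0, "z"])
        assert out.loc[0, "r"] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_map_zero(self):
        basis = make_gradient_basis(500, K=3, seed=2)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        x -= x.mean()
        # project out all gradients
        x -= basis.maps @ (basis.maps.T @ x)
        out = project_map(x, basis)
        assert np.max(np.abs(out["r"])) < 1e-10
        assert np.max(np.abs(out["z"])) < 1e-10

    def test_matches_brute_force_oracle(self, rng):
        # 100 random map/basis pairs against the two-pass loop
        for trial in range(100):
            V = int(rng.integers(20, 60))
            K = int(rng.integers(1, 5))
            basis = make_gradient_basis(V, K=K, seed=int(rng.integers(1e6)))
            x = rng.standard_normal(V)
            out = project_map(x, basis)
            for k in range(K):
                expect = brute_force_pearson(list(x), list(basis.maps[:, k]))
                assert out.loc[k, "r"] == pytest.approx(expect, abs=1e-12)

    def test_scale_invariance(self, basis400, rng):
        x = rng.standard_normal(basis400.n_voxels)
        a = project_map(x, basis400)
        b = project_map(3.7 * x, basis400)
        assert np.allclose(a["r"], b["r"], atol=1e-12)

    def test_gradient_sign_covariance(self, basis400, rng):
        x = rng.standard_normal(basis400.n_voxels)
        flipped = GradientBasis(maps=basis400.maps * np.array([-1, 1, 1, 1, 1]),
                                mask=basis400.mask)
        a = project_map(x, basis400)
        b = project_map(x, flipped)
        assert b.loc[0, "r"] == pytest.approx(-a.loc[0, "r"], abs=1e-12)
        assert np.allclose(a.loc[1:, "r"], b.loc[1:, "r"], atol=1e-14)

    def test_zero_variance_map_error(self, basis400):
        with pytest.raises(ValueError, match="zero-variance"):
            project_map(np.full(basis400.n_voxels, 2.0), basis400)


class TestShiftScores:
    def test_difference(self):
        assert shift_scores(_proj_df([0.3]), _proj_df([0.5]))[0] == pytest.approx(0.2)

    def test_identity_zero(self):
        p = _proj_df([0.1, 0.2, 0.3])
        assert np.allclose(shift_scores(p, p), 0.0)

    def test_antisymmetry(self):
        a, b = _proj_df([0.1, -0.4]), _proj_df([0.25, 0.3])
        assert np.allclose(shift_scores(a, b), -shift_scores(b, a))

    def test_mismatched_gradient_sets_error(self):
        with pytest.raises(ValueError, match="gradient sets"):
            shift_scores(_proj_df([0.1]), _proj_df([0.1, 0.2]))


class TestEuclideanShift:
    def test_3_4_5(self):
        look = _proj_df([0.0, 0.0, 0.0, 0.0, 0.0])
        reg = _proj_df([0.3, 0.4, 0.0, 0.0, 0.0])
        # scale by 10 via direct z values: use (3,4,0,0,0)
        look = _proj_df([0, 0, 0, 0, 0])
        reg = pd.DataFrame({"gradient_id": [1, 2, 3, 4, 5],
                            "z": [3.0, 4.0, 0, 0, 0], "r": 0.0})
        assert euclidean_shift(look, reg) == pytest.approx(5.0, abs=1e-12)

    def test_identical_zero(self):
        p = _proj_df([0.4, 0.1, 0.2])
        assert euclidean_shift(p, p) == 0.0

    def test_subspace_monotonicity(self, rng):
        for _ in range(1000):
            z = rng.standard_normal(5)
            look = _proj_df([0.0] * 5)
            reg = pd.DataFrame({"gradient_id": range(1, 6), "z": z, "r": 0.0})
            ed5 = euclidean_shift(look, reg)
            ed3 = euclidean_shift(look, reg, dims=[1, 2, 3])
            assert ed3 <= ed5 + 1e-12

    def test_all_ones_ed3(self):
        look = _proj_df([0.0] * 5)
        reg = pd.DataFrame({"gradient_id": range(1, 6), "z": [1.0] * 5,
                            "r": 0.0})
        assert euclidean_shift(look, reg, dims=[1, 2, 3]) == pytest.approx(
            np.sqrt(3), abs=1e-12)

    def test_empty_dims_error(self):
        p = _proj_df([0.1])
        with pytest.raises(ValueError, match="empty"):
            euclidean_shift(p, p, dims=[])


class TestTables:
    def test_shift_table_matches_manual(self, cohort, basis400):
        projections = projection_table(cohort.maps, basis400)
        shifts = shift_table(projections)
        assert len(shifts) == len(cohort.truth.subject_ids)
        # dG columns agree with the generator's realized shifts
        dg = shifts.set_index("subject_id").loc[
            cohort.truth.subject_ids, [f"dG{k}" for k in range(1, 6)]]
        assert np.allclose(dg.to_numpy(), cohort.truth.realized_dG, atol=1e-12)
        # ed5 is the norm of the dG vector
        assert np.allclose(shifts["ed5"],
                           np.linalg.norm(shifts[[f"dG{k}" for k in range(1, 6)]],
                                          axis=1), atol=1e-12)

    def test_region_shift_table_absent_regions(self, cohort, basis400):
        labels = np.zeros(basis400.mask.grid_shape, dtype=int)
        labels.ravel()[basis400.mask.indices[:50]] = 1
        labels.ravel()[basis400.mask.indices[50:52]] = 2  # too small (<3)
        atlas = RegionAtlas(labels=labels, region_ids=[1, 2], family="cortical")
        table = region_shift_table(cohort.maps[:4], basis400, atlas)
        r1 = table[table["region_id"] == 1]
        r2 = table[table["region_id"] == 2]
        assert r1["dG"].notna().all()
        assert r2["dG"].isna().all()
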