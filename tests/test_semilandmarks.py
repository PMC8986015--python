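"""TPS bending energy, semilandmark sliding, warps, mean-difference fields."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from morphosex.landmark_io import (
    CurveDefinition,
    LandmarkConfiguration,
    TemplateDefinition,
)
from morphosex.semilandmarks import (
    BendingEnergyModel,
    bending_energy,
    mean_difference_field,
    slide_semilandmarks,
    tps_warp,
)
from morphosex.superimposition import gpa_align
from morphosex.synthetic import simulate_dataset


@pytest.fixture(scope="module")
def grid_model():
    """3 x 3 flat grid reference (z = 0)."""
    g = np.array([[i, j, 0.0] for i in range(3) for j in range(3)], float)
    return BendingEnergyModel.from_reference(g)


def oracle_energy(reference, target):
    """Independent bending-energy route: solve the TPS interpolation system
    for the weights w and evaluate E = sum_axes w^T K w (instead of the
    L-inverse block quadratic form used by the implementation)."""
    ref = np.asarray(reference, float)
    k, dim = ref.shape
    r = np.sqrt(((ref[:, None] - ref[None]) ** 2).sum(-1))
    kmat = -r if dim == 3 else np.where(r > 0, r ** 2 * np.log(r ** 2 + (r == 0)), 0.0)
    q = np.column_stack([np.ones(k), ref])
    l = np.zeros((k + dim + 1, k + dim + 1))
    l[:k, :k] = kmat
    l[:k, k:] = q
    l[k:, :k] = q.T
    rhs = np.zeros((k + dim + 1, dim))
    rhs[:k] = np.asarray(target, float) - ref
    # lstsq: the TPS weights w are unique even when the affine block is
    # rank-deficient (coplanar 3D reference)
    coeffs, *_ = np.linalg.lstsq(l, rhs, rcond=None)
    w = coeffs[:k]
    return float(np.einsum("ia,ij,ja->", w, kmat, w))


class TestBendingEnergy:
    def test_zero_for_reference(self, grid_model):
        assert bending_energy(grid_model, grid_model.reference) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_for_affine_deformation(self, grid_model):
        rng = np.random.default_rng(0)
        a = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        target = grid_model.reference @ a.T + b
        assert bending_energy(grid_model, target) == pytest.approx(0.0, abs=1e-9)

    def test_normal_displacement_matches_independent_assembly(self, grid_model):
        target = grid_model.reference.copy()
        target[4, 2] += 0.1  # center point displaced normal to the plane
        e = bending_energy(grid_model, target)
        assert e > 0
        assert e == pytest.approx(oracle_energy(grid_model.reference, target),
                                  rel=1e-9)

    def test_random_target_matches_independent_assembly(self, grid_model):
        rng = np.random.default_rng(1)
        target = grid_model.reference + 0.05 * rng.normal(size=(9, 3))
        assert bending_energy(grid_model, target) == pytest.approx(
            oracle_energy(grid_model.reference, target), rel=1e-9
        )

    def test_matrix_symmetric_psd_annihilates_affine(self, grid_model):
        lk = grid_model.bending_energy_matrix
        np.testing.assert_allclose(lk, lk.T, atol=1e-12)
        assert np.linalg.eigvalsh(lk).min() > -1e-9
        q = np.column_stack([np.ones(9), grid_model.reference])
        np.testing.assert_allclose(lk @ q, 0.0, atol=1e-9)

    def test_rigid_motion_invariance_and_quadratic_scaling(self, grid_model):
        rng = np.random.default_rng(2)
        target = grid_model.reference + 0.05 * rng.normal(size=(9, 3))
        e = bending_energy(grid_model, target)
        rot = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        # rigid motion of the *displacement-carrying* target relative to an
        # affinely-moved reference leaves the non-affine part intact
        assert bending_energy(grid_model, target @ rot.T + 5.0) == pytest.approx(
            e, rel=1e-9
        )
        doubled = grid_model.reference + 2 * (target - grid_model.reference)
        assert bending_energy(grid_model, doubled) == pytest.approx(4 * e, rel=1e-9)

    def test_coincident_reference_rejected(self):
        bad = np.zeros((4, 3))
        bad[1:] = np.eye(3)
        bad[1] = bad[2]
        with pytest.raises(ValueError, match="singular"):
            BendingEnergyModel.from_reference(bad)


def curve_template_5pt():
    """5-point template: anchors 0 and 4 fixed, 1-3 sliding on one curve."""
    return TemplateDefinition(
        name="curve5", n_fixed=2, n_semi=3,
        curves=(CurveDefinition("c", (1, 2, 3), anchor_start=0, anchor_end=4),),
    )


class TestSliding:
    def test_single_semilandmark_matches_grid_search(self):
        """One sliding point on a 5-point curve: the slid position must match
        a 1-D grid search over tangent offsets (step 1e-5)."""
        tpl = TemplateDefinition(
            name="one", n_fixed=4, n_semi=1,
            curves=(CurveDefinition("c", (2,), anchor_start=1, anchor_end=3),),
        )
        # slightly bent planar curve; point 2 displaced along the chain
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.3, 0.0],
                [2.3, 0.55, 0.0],
                [3.0, 0.3, 0.0],
                [4.0, 0.0, 0.0],
            ]
        )
        ref = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.3, 0.0],
                [2.0, 0.5, 0.0],
                [3.0, 0.3, 0.0],
                [4.0, 0.0, 0.0],
            ]
        )
        model = BendingEnergyModel.from_reference(ref)
        # tangent at point 2: central difference of chain neighbors 1 and 3
        tan = coords[3] - coords[1]
        tan = tan / np.linalg.norm(tan)
        offsets = np.arange(-1.0, 1.0, 1e-5)
        targets = np.repeat(coords[None], len(offsets), axis=0)
        targets[:, 2] += offsets[:, None] * tan
        lk = model.bending_energy_matrix
        disp = targets - ref
        energies = np.einsum("nia,ij,nja->n", disp, lk, disp)
        best = targets[np.argmin(energies), 2]

        from morphosex.semilandmarks import _slide_one

        slid, e0, e1 = _slide_one(coords, tpl, model)
        np.testing.assert_allclose(slid[2], best, atol=1e-4)
        assert e1 <= e0 + 1e-9
        assert e1 <= energies.min() + 1e-9

    def test_energy_non_increasing_and_fixed_landmarks_immobile(
        self, template_ref, modes
    ):
        from conftest import clean_population_spec

        tpl, ref = template_ref
        spec = clean_population_spec(tpl, ref, modes, n_half=6, jitter_sd=0.01,
                                     seed=21)
        configs, _, _ = simulate_dataset(spec)
        result = slide_semilandmarks(configs, tpl, outer_iterations=3)
        for before, after in result.energy_history:
            assert np.all(after <= before + 1e-9)
        fixed = list(tpl.fixed_indices)
        for orig, slid in zip(configs, result.configs):
            np.testing.assert_array_equal(
                orig.coordinates[fixed], slid.coordinates[fixed]
            )

    def test_already_optimal_is_fixed_point(self, template_ref):
        """A specimen whose deformation from the reference is affine (zero
        bending-energy gradient) is already at the constrained optimum and
        must not move."""
        from morphosex.semilandmarks import _slide_one

        tpl, ref = template_ref
        refc = ref - ref.mean(axis=0)
        refc = refc / np.sqrt((refc ** 2).sum())
        model = BendingEnergyModel.from_reference(refc)
        # identity case
        slid, e0, e1 = _slide_one(refc, tpl, model)
        assert np.abs(slid - refc).max() < 1e-8
        # affine case
        rng = np.random.default_rng(40)
        a = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
        target = refc @ a.T
        slid, e0, e1 = _slide_one(target, tpl, model)
        assert np.abs(slid - target).max() < 1e-8

    def test_single_specimen_consensus_is_fixed_point(self, small_population):
        """With one specimen the sliding reference is the specimen itself,
        so nothing moves."""
        configs, _, _ = small_population
        one = [configs[0].copy()]
        result = slide_semilandmarks(one, configs[0].template, outer_iterations=2)
        np.testing.assert_allclose(
            result.slid_coordinates[0], configs[0].coordinates, atol=1e-8
        )
        np.testing.assert_allclose(result.bending_energy_after, 0.0, atol=1e-12)

    def test_order_independence(self, template_ref, modes):
        from conftest import clean_population_spec

        tpl, ref = template_ref
        spec = clean_population_spec(tpl, ref, modes, n_half=5, jitter_sd=0.01,
                                     seed=23)
        configs, _, _ = simulate_dataset(spec)
        fwd = slide_semilandmarks(configs, tpl, outer_iterations=2)
        rev = slide_semilandmarks(configs[::-1], tpl, outer_iterations=2)
        np.testing.assert_allclose(
            fwd.slid_coordinates, rev.slid_coordinates[::-1], atol=1e-8
        )

    def test_short_curve_rejected(self):
        tpl = TemplateDefinition(
            name="short", n_fixed=1, n_semi=1,
            curves=(CurveDefinition("c", (1,), anchor_start=0),),
        )
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], ])
        cfg = LandmarkConfiguration("s", coords, tpl)
        with pytest.raises(ValueError, match="< 3"):
            slide_semilandmarks([cfg, cfg], tpl)


@pytest.fixture(scope="module")
def solid_model():
    """Non-degenerate (non-coplanar) 3D reference."""
    rng = np.random.default_rng(99)
    return BendingEnergyModel.from_reference(rng.normal(size=(10, 3)))


class TestTpsWarp:
    def test_interpolates_landmarks(self, solid_model):
        rng = np.random.default_rng(3)
        target = solid_model.reference + 0.1 * rng.normal(size=(10, 3))
        out = tps_warp(solid_model, target, solid_model.reference)
        np.testing.assert_allclose(out, target, atol=1e-9)

    def test_identity_when_target_is_reference(self, solid_model):
        rng = np.random.default_rng(4)
        query = rng.normal(size=(20, 3)) * 2
        out = tps_warp(solid_model, solid_model.reference, query)
        np.testing.assert_allclose(out, query, atol=1e-9)

    def test_affine_target_gives_affine_map(self, solid_model):
        """With an affine target the warp equals the affine map fitted
        independently by least squares."""
        rng = np.random.default_rng(5)
        a = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        target = solid_model.reference @ a.T + b
        query = rng.normal(size=(15, 3)) * 3
        out = tps_warp(solid_model, target, query)
        design = np.column_stack([np.ones(10), solid_model.reference])
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        expected = np.column_stack([np.ones(15), query]) @ coef
        np.testing.assert_allclose(out, expected, atol=1e-8)


class TestMeanDifferenceField:
    def test_zero_field_for_same_group(self, small_population):
        configs, meta, _ = small_population
        aligned = gpa_align(configs)
        labels = np.array(["g"] * aligned.n)
        field, warps = mean_difference_field(aligned, labels, "g", "g")
        np.testing.assert_allclose(field, 0.0, atol=1e-15)
        np.testing.assert_allclose(warps[0.0], warps[1.0], atol=1e-15)

    def test_exaggeration_linearity(self, small_population):
        configs, meta, _ = small_population
        aligned = gpa_align(configs)
        sex = meta["sex"].to_numpy()
        f1, _ = mean_difference_field(aligned, sex, "F", "M", exaggeration=1)
        f2, _ = mean_difference_field(aligned, sex, "F", "M", exaggeration=2)
        np.testing.assert_allclose(f2, 2 * f1, atol=1e-12)

    def test_recovers_constructed_offset(self, template_ref, modes):
        from conftest import clean_population_spec

        tpl, ref = template_ref
        spec = clean_population_spec(
            tpl, ref, modes, n_half=60, d_shape=0.02, allometry_scale=0.0,
            size_log_sd=0.0, landmark_noise_sd=0.002, seed=31,
        )
        configs, meta, _ = simulate_dataset(spec)
        aligned = gpa_align(configs)
        field, _ = mean_difference_field(aligned, meta["sex"].to_numpy(), "F", "M")
        expected = spec.d_shape * spec.sex_field
        # noise floor ~ noise_sd * sqrt(2/n) per coordinate
        assert np.abs(field - expected).max() < 4 * 0.002 * np.sqrt(2 / 60)

    def test_empty_group_rejected(self, small_population):
        configs, meta, _ = small_population
        aligned = gpa_align(configs)
        with pytest.raises(ValueError, match="empty"):
            mean_difference_field(aligned, meta["sex"].to_numpy(), "F", "X")
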