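import numpy as np
import pytest

from acnm import (
    Contour,
    LevelSetField,
    SpeedParams,
    data_term_linear,
    data_term_nonlinear,
    dice,
    evolve_step,
    extract_contour,
    initial_contour_middle_slice,
    reinitialize,
    run_acnm_slice,
    signed_distance,
)
from acnm.errors import (
    DegenerateACNError,
    EmptyContourSignal,
    NumericalStabilityError,
    ValidationError,
)
from acnm.initialization import disk_structuring_element
from acnm.phantom import LABELS


class TestNonlinearDataTerm:
    def test_zero_crossing_at_belt_maximum(self):
        for mu, i_m, t in [(0.3, 0.8, 6), (0.1, 0.9, 2), (0.45, 0.5, 4)]:
            assert abs(data_term_nonlinear(i_m, mu, i_m, t)) < 1e-12

    def test_closed_form_spot_values(self):
        # just above mu the term jumps to 1 - e^(-2/t)
        assert data_term_nonlinear(0.5, 0.5, 0.9, 6.0) == pytest.approx(
            1 - np.exp(-1 / 3), abs=1e-6
        )
        assert data_term_nonlinear(0.3, 0.5, 0.9, 6.0) == pytest.approx(-0.9200444146, abs=1e-6)

    def test_sign_structure(self):
        mu, i_m, t = 0.35, 0.82, 6.0
        i = np.linspace(0, 1, 501)
        d = data_term_nonlinear(i, mu, i_m, t)
        assert (d[i < mu] < 0).all()
        assert (d[(i > mu + 1e-9) & (i < i_m - 1e-9)] > 0).all()
        assert (d[i > i_m + 1e-9] < 0).all()

    def test_branch_jump_at_mu_preserved(self):
        """The printed form is discontinuous at I = mu: left limit -1,
        right limit 1 - e^(-2/t). Both branch values are asserted as
        printed rather than smoothed over."""
        mu, i_m, t = 0.5, 0.9, 4.0
        assert data_term_nonlinear(mu - 1e-9, mu, i_m, t) == pytest.approx(-1.0, abs=1e-6)
        assert data_term_nonlinear(mu, mu, i_m, t) == pytest.approx(1 - np.exp(-2 / t), abs=1e-6)

    def test_t_trades_contraction_for_expansion(self):
        mu, i_m = 0.4, 0.9
        below, inside = 0.2, 0.6
        d2, d4, d6 = (data_term_nonlinear(below, mu, i_m, t) for t in (2, 4, 6))
        assert abs(d2) < abs(d4) < abs(d6)
        e2, e4, e6 = (data_term_nonlinear(inside, mu, i_m, t) for t in (2, 4, 6))
        assert e2 > e4 > e6 > 0

    def test_degenerate_belt_rejected(self):
        with pytest.raises(DegenerateACNError):
            data_term_nonlinear(0.5, 0.7, 0.7, 6.0)


class TestLinearDataTerm:
    def test_window_shape(self):
        assert data_term_linear(0.6, T=0.6, epsilon=0.3) == pytest.approx(0.3)
        assert data_term_linear(0.9, T=0.6, epsilon=0.3) == pytest.approx(0.0)
        assert data_term_linear(0.05, T=0.6, epsilon=0.3) < 0

    def test_invalid_epsilon(self):
        with pytest.raises(ValidationError):
            data_term_linear(0.5, T=0.5, epsilon=0.0)


class TestSignedDistance:
    def test_disk_center_depth(self, disk_region):
        field = signed_distance(disk_region(radius=10, shape=(81, 81), center=(40, 40)))
        assert field.phi[40, 40] == pytest.approx(10, abs=1.0)

    def test_sign_convention(self, disk_region):
        region = disk_region(radius=10)
        field = signed_distance(region)
        assert (field.phi[region] >= 0).all()
        assert (field.phi[~region] < 0).all()

    def test_unit_gradient_near_zero_set(self, disk_region):
        field = signed_distance(disk_region(radius=15, shape=(81, 81), center=(40, 40)))
        gy, gx = np.gradient(field.phi)
        gm = np.hypot(gx, gy)
        band = np.abs(field.phi) < 3
        # rasterization kinks allow isolated outliers; the bulk is unit-slope
        assert np.percentile(np.abs(gm[band] - 1), 75) <= 0.1
        assert np.abs(np.median(gm[band]) - 1) <= 0.05

    def test_empty_and_full_rejected(self):
        with pytest.raises(ValidationError):
            signed_distance(np.zeros((10, 10), bool))
        with pytest.raises(ValidationError):
            signed_distance(np.ones((10, 10), bool))


class TestEvolveStep:
    def test_off_belt_pixels_never_change(self, disk_region):
        rng = np.random.default_rng(3)
        field = signed_distance(disk_region(radius=10))
        belt = rng.random((80, 80)) > 0.6
        d = rng.normal(0, 0.5, (80, 80))
        g = rng.random((80, 80))
        out = evolve_step(field, d, g, SpeedParams(), belt)
        np.testing.assert_array_equal(out.phi[~belt], field.phi[~belt])

    def test_uniform_positive_speed_grows_a_disk(self, disk_region):
        region = disk_region(radius=10)
        field = signed_distance(region)
        params = SpeedParams(beta=0.0)
        belt = np.ones_like(region)
        d = np.full(region.shape, 0.5)
        g = np.ones_like(d)
        area0 = int(field.region.sum())
        for _ in range(10):
            field = evolve_step(field, d, g, params, belt)
        assert int(field.region.sum()) > area0

    def test_pure_curvature_flow_shrinks_a_disk(self, disk_region):
        region = disk_region(radius=12)
        field = signed_distance(region)
        params = SpeedParams(beta=1.0, dt=0.2)
        belt = np.ones_like(region)
        d = np.zeros(region.shape)
        g = np.ones_like(d)
        area0 = int(field.region.sum())
        for _ in range(100):
            field = evolve_step(field, d, g, params, belt)
        assert int(field.region.sum()) < area0

    def test_nonfinite_update_reported(self, disk_region):
        field = signed_distance(disk_region(radius=10))
        d = np.zeros((80, 80))
        d[40, 40] = np.inf
        with pytest.raises(NumericalStabilityError):
            evolve_step(field, d, np.ones_like(d), SpeedParams(beta=0), np.ones_like(d, bool))


class TestReinitialize:
    def test_fixed_point_on_fresh_signed_distance(self, disk_region):
        field = signed_distance(disk_region(radius=10))
        out = reinitialize(field)
        assert int((field.region ^ out.region).sum()) == 0
        band = np.abs(field.phi) < 2
        np.testing.assert_allclose(out.phi[band], field.phi[band], atol=0.5)

    def test_restores_band_gradient_after_evolution(self, disk_region):
        region = disk_region(radius=10, shape=(60, 60))
        field = signed_distance(region)
        d = np.full((60, 60), 0.3)
        g = np.ones((60, 60))
        params = SpeedParams(beta=0.5, dt=0.1)
        for _ in range(50):
            field = evolve_step(field, d, g, params, np.ones((60, 60), bool))
        out = reinitialize(field)
        gy, gx = np.gradient(out.phi)
        gm = np.hypot(gx, gy)
        band = np.abs(out.phi) < 3
        assert np.abs(gm[band] - 1).max() <= 0.1

    def test_smoothly_distorted_field_recovered(self):
        yy, xx = np.indices((60, 60))
        phi_true = 10.0 - np.hypot(yy - 30, xx - 30)
        out = reinitialize(LevelSetField(phi=2.5 * phi_true))
        assert int(((phi_true >= 0) ^ out.region).sum()) == 0
        band = np.abs(out.phi) < 3
        gy, gx = np.gradient(out.phi)
        assert np.abs(np.hypot(gx, gy)[band] - 1).max() <= 0.1


class TestExtractContour:
    def test_inverts_signed_distance(self, disk_region):
        region = disk_region(radius=10)
        contour = extract_contour(signed_distance(region))
        assert int((contour.region ^ region).sum()) <= len(np.argwhere(Contour(region=region).boundary))

    def test_small_components_dropped(self):
        phi = np.full((60, 60), -5.0)
        phi[10:35, 10:35] = 1.0  # 625 px
        phi[50:53, 50:53] = 1.0  # 9 px
        contour = extract_contour(LevelSetField(phi=phi), min_area=50)
        assert contour.region[20, 20] and not contour.region[51, 51]

    def test_holes_filled(self):
        phi = np.full((40, 40), -5.0)
        phi[5:35, 5:35] = 1.0
        phi[15:20, 15:20] = -1.0  # interior hole
        contour = extract_contour(LevelSetField(phi=phi))
        assert contour.region[17, 17]

    def test_all_negative_signals_empty(self):
        with pytest.raises(EmptyContourSignal):
            extract_contour(LevelSetField(phi=np.full((20, 20), -1.0)))


class TestRunSlice:
    def test_noiseless_middle_slice_recovery(self, noiseless_phantom):
        mid = noiseless_phantom.volume.shape[0] // 2
        sl = noiseless_phantom.volume.data[mid]
        truth = noiseless_phantom.truth.data[mid].astype(bool)
        out = run_acnm_slice(sl, initial_contour_middle_slice(sl))
        assert dice(out.region, truth) >= 0.95

    def test_self_seeded_run_is_stable(self, noiseless_phantom):
        mid = noiseless_phantom.volume.shape[0] // 2
        sl = noiseless_phantom.volume.data[mid]
        first = run_acnm_slice(sl, initial_contour_middle_slice(sl))
        second = run_acnm_slice(sl, first)
        assert dice(first.region, second.region) >= SpeedParams().converge_tol

    def test_eye_slice_not_swallowed(self, default_phantom):
        """Across the weak boundary the bright eyeball exceeds the belt
        maximum, so the nonlinear speed contracts instead of leaking — the
        linear window baseline picks up strictly more non-brain tissue."""
        from scipy import ndimage

        res = default_phantom
        eye = res.labels == LABELS["eye"]
        z = int(np.argwhere(eye.any(axis=(1, 2)))[:, 0].mean().round())
        sl = res.volume.data[z]
        truth = res.truth.data[z].astype(bool)
        init = Contour(region=ndimage.binary_erosion(truth, disk_structuring_element(2)))
        nonlinear = run_acnm_slice(sl, init)
        linear = run_acnm_slice(sl, init, SpeedParams(model="linear"))
        assert int((nonlinear.region & eye[z]).sum()) <= 5
        fp_nl = int((nonlinear.region & ~truth).sum())
        fp_lin = int((linear.region & ~truth).sum())
        assert fp_nl < fp_lin

    def test_degenerate_acn_raises(self):
        img = np.full((60, 60), 0.5)
        region = np.zeros((60, 60), bool)
        region[20:40, 20:40] = True
        with pytest.raises(DegenerateACNError):
            run_acnm_slice(img, Contour(region=region))

    def test_empty_init_rejected(self):
        with pytest.raises(EmptyContourSignal):
            run_acnm_slice(np.zeros((30, 30)), Contour(region=np.zeros((30, 30), bool)))
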