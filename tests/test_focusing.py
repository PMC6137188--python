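"""Lift-force model, equilibria, outlet assignment, and calibration."""

import math

import numpy as np
import pytest
from scipy import ndimage

from scarflow import focusing as F
from scarflow.errors import (
    CalibrationError,
    ConfigError,
    ModelConfigurationError,
    OutOfDomainError,
)
from scarflow.hydraulics import WATER, ChannelGeometry, FlowCondition


@pytest.fixture(scope="module")
def symmetric_profile(flow_1500):
    return F.axial_velocity_profile(flow_1500, model=None)


class TestVelocityProfile:
    def test_no_slip_at_both_walls(self, symmetric_profile):
        p = symmetric_profile
        assert abs(p.u(0.0)[0]) < 1e-9 * p.u(p.w / 2)[0]
        assert abs(p.u(p.w)[0]) < 1e-9 * p.u(p.w / 2)[0]

    def test_symmetric_peak_at_midwidth(self, symmetric_profile):
        p = symmetric_profile
        x = np.linspace(0, p.w, 4001)
        assert x[np.argmax(p.u(x))] == pytest.approx(p.w / 2, abs=p.w / 2000)

    def test_flux_matches_q_within_half_percent(self, flow_1500):
        p = F.axial_velocity_profile(flow_1500)
        q = flow_1500.q_ul_min * 1e-9 / 60.0
        assert p.flux() == pytest.approx(q, rel=5e-3)

    def test_2d_solution_matches_finite_difference_poisson_oracle(self, flow_1500):
        # brute-force: solve  lap(u) = const  on the duct cross-section with
        # no-slip walls, scale to the same flux, compare pointwise
        p = F.axial_velocity_profile(flow_1500)
        ny, nz = 120, 40
        w, h = p.w, p.h
        dy, dz = w / (ny + 1), h / (nz + 1)
        u = np.zeros((ny + 2, nz + 2))
        for _ in range(8000):
            u[1:-1, 1:-1] = (
                (u[2:, 1:-1] + u[:-2, 1:-1]) / dy**2
                + (u[1:-1, 2:] + u[1:-1, :-2]) / dz**2
                + 1.0
            ) / (2.0 / dy**2 + 2.0 / dz**2)
        flux_fd = u[1:-1, 1:-1].sum() * dy * dz
        u *= (flow_1500.q_ul_min * 1e-9 / 60.0) / flux_fd
        y = (np.arange(1, ny + 1)) * dy
        z = (np.arange(1, nz + 1)) * dz
        series = p.u2d(y, z)
        assert np.allclose(series, u[1:-1, 1:-1], rtol=0.02, atol=series.max() * 0.01)

    def test_skewed_kernel_peak_location(self, flow_1500):
        k = F.ParabolicLiftKernel(flow_1500, delta_frac=0.3)
        x = np.linspace(0, k.w, 4001)
        assert x[np.argmax(k.u(x))] == pytest.approx(0.8 * k.w, abs=k.w / 1000)

    def test_too_few_series_terms_rejected(self, flow_1500):
        from scarflow.errors import NumericConfigurationError

        with pytest.raises(NumericConfigurationError):
            F.MidplaneProfile(flow_1500, n_terms=2)


class TestForceScaling:
    """The three force terms scale exactly as a^4, a^6 and a^2."""

    @pytest.mark.parametrize("a", [3.0, 6.0])
    def test_shear_gradient_scales_as_a4(self, flow_1500, a):
        kern = F.lift_kernel(flow_1500, 0.2)
        x = 0.3 * kern.w
        f1 = F.shear_gradient_lift(F.Particle(a), x, kern)
        f2 = F.shear_gradient_lift(F.Particle(2 * a), x, kern)
        assert f2[0] / f1[0] == pytest.approx(16.0, rel=1e-12)

    @pytest.mark.parametrize("a", [3.0, 6.0])
    def test_wall_lift_scales_as_a6(self, flow_1500, a):
        kern = F.lift_kernel(flow_1500, 0.2)
        x = 0.2 * kern.w
        f1 = F.wall_lift(F.Particle(a), x, kern)
        f2 = F.wall_lift(F.Particle(2 * a), x, kern)
        assert f2[0] / f1[0] == pytest.approx(64.0, rel=1e-12)

    @pytest.mark.parametrize("a", [3.0, 6.0])
    def test_dean_force_scales_as_a2(self, flow_1500, a):
        x = 0.3 * flow_1500.geometry.width_m
        f1 = F.dean_centering_force(F.Particle(a), x, flow_1500)
        f2 = F.dean_centering_force(F.Particle(2 * a), x, flow_1500)
        assert f2[0] / f1[0] == pytest.approx(4.0, rel=1e-12)


class TestForceStructure:
    def test_shear_gradient_vanishes_at_velocity_peak(self, flow_1500):
        kern = F.lift_kernel(flow_1500, 0.25)
        f = F.shear_gradient_lift(F.Particle(5.0), kern.x_peak, kern)
        scale = abs(F.shear_gradient_lift(F.Particle(5.0), 0.3 * kern.w, kern)[0])
        assert abs(f[0]) < 1e-9 * scale

    def test_wall_lift_cancels_midchannel_and_diverges_at_wall(self, flow_1500):
        kern = F.lift_kernel(flow_1500, 0.0)  # symmetric
        p = F.Particle(5.0)
        assert F.wall_lift(p, kern.w / 2, kern)[0] == pytest.approx(0.0, abs=1e-30)
        near = F.wall_lift(p, 0.02 * kern.w, kern)[0]
        nearer = F.wall_lift(p, 0.013 * kern.w, kern)[0]
        assert nearer > near > 0  # repulsion growing toward the wall

    def test_dean_force_zero_at_centre_and_for_straight_channel(self, flow_1500):
        w = flow_1500.geometry.width_m
        assert F.dean_centering_force(F.Particle(5.0), w / 2, flow_1500)[0] == 0.0
        straight = FlowCondition(
            1500.0, ChannelGeometry(radius_um=math.inf), WATER
        )
        assert F.dean_centering_force(F.Particle(5.0), 0.3 * w, straight)[0] == 0.0

    def test_particle_touching_wall_rejected(self, flow_1500):
        kern = F.lift_kernel(flow_1500, 0.0)
        with pytest.raises(OutOfDomainError):
            F.shear_gradient_lift(F.Particle(10.0), 4e-6, kern)


class TestEquilibria:
    def test_small_particle_centre_trap(self, flow_1500):
        eq = F.equilibrium_positions(F.Particle(4.1), flow_1500)
        assert eq.dominant_regime == "center-trap"
        assert eq.dominant_frac == pytest.approx(0.5, abs=0.02)

    def test_large_particle_concave_focus(self, flow_1500):
        eq = F.equilibrium_positions(F.Particle(15.0), flow_1500)
        assert eq.dominant_regime == "concave-wall"
        assert eq.dominant_frac > 0.75

    def test_zero_model_raises(self, flow_1500):
        with pytest.raises(ModelConfigurationError):
            F.equilibrium_positions(
                F.Particle(5.0),
                flow_1500,
                F.ForceModel(c_sg=0.0, c_w=0.0, c_d=0.0, beta=0.0),
            )

    def test_roots_agree_with_dense_sign_scan_oracle(self, flow_1500):
        # brute force: sign changes of the net force on a very fine grid
        for a in (4.1, 8.0, 12.0):
            p = F.Particle(a)
            eq = F.equilibrium_positions(p, flow_1500)
            kern = F.lift_kernel(
                flow_1500, F.DEFAULT_FORCE_MODEL.skew_fraction(flow_1500.dean)
            )
            w = flow_1500.geometry.width_m
            x = np.linspace(a * 1e-6 / 2 * 1.001, w - a * 1e-6 / 2 * 1.001, 20001)
            f = F.net_force(p, x, flow_1500, profile=kern)
            sign_changes = x[:-1][np.diff(np.sign(f)) != 0] / w
            assert len(sign_changes) == len(eq.positions_frac)
            for root in eq.positions_frac:
                assert np.min(np.abs(sign_changes - root)) < 5e-3


class TestCriticalDiameter:
    def test_between_bead_sizes_at_operating_flow(self, flow_1500):
        cd = F.critical_diameter(flow_1500)
        assert cd.status == "ok"
        assert 4.1 < cd.value_um < 5.56

    def test_monotone_in_flow_rate(self):
        vals = [
            F.critical_diameter(FlowCondition(q)).value_um
            for q in (1200.0, 1500.0, 1800.0)
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_no_dean_force_gives_lower_bound(self, flow_1500):
        model = F.ForceModel(
            c_sg=F.DEFAULT_FORCE_MODEL.c_sg,
            c_w=F.DEFAULT_FORCE_MODEL.c_w,
            c_d=0.0,
            beta=F.DEFAULT_FORCE_MODEL.beta,
            sigma_f=0.1,
        )
        cd = F.critical_diameter(flow_1500, model)
        assert cd.status == "lower-bound"
        assert cd.value_um == 1.0


class TestOutletDistribution:
    def test_probabilities_normalise(self, flow_1500):
        for a in (3.0, 4.1, 5.56, 9.95, 15.0):
            dist = F.outlet_distribution(F.Particle(a), flow_1500)
            p = dist.as_array()
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_delta_limit_concentrates_in_single_bin(self, flow_1500):
        model = F.ForceModel(
            c_sg=F.DEFAULT_FORCE_MODEL.c_sg,
            c_w=F.DEFAULT_FORCE_MODEL.c_w,
            c_d=F.DEFAULT_FORCE_MODEL.c_d,
            beta=F.DEFAULT_FORCE_MODEL.beta,
            sigma_f=1e-12,
        )
        dist = F.outlet_distribution(F.Particle(15.0), flow_1500, model)
        assert np.max(dist.as_array()) == 1.0

    def test_bad_bin_edges_rejected(self, flow_1500):
        with pytest.raises(ConfigError):
            F.outlet_distribution(
                F.Particle(5.0), flow_1500, edges_frac=(0.0, 0.7, 0.3, 1.0)
            )

    def test_sampled_ports_conserve_particles(self, flow_1500):
        rng = np.random.default_rng(7)
        diam = np.full(3000, 5.56)
        ports = F.sample_ports(diam, flow_1500, F.DEFAULT_FORCE_MODEL, rng)
        assert len(ports) == 3000
        assert set(np.unique(ports)).issubset({1, 2, 3, 4, 5})


class TestStreakline:
    def test_empty_mixture(self, flow_1500):
        edges, counts, mode = F.streakline([], flow_1500)
        assert counts.sum() == 0 and math.isnan(mode)

    def test_delta_dispersion_single_bin(self, flow_1500):
        model = F.ForceModel(
            c_sg=F.DEFAULT_FORCE_MODEL.c_sg,
            c_w=F.DEFAULT_FORCE_MODEL.c_w,
            c_d=F.DEFAULT_FORCE_MODEL.c_d,
            beta=F.DEFAULT_FORCE_MODEL.beta,
            sigma_f=1e-12,
        )
        _, counts, _ = F.streakline([(F.Particle(9.95), 500)], flow_1500, model)
        assert (counts > 0).sum() == 1

    def test_young_yeast_mode_coincides_with_small_bead_mode(
        self, flow_1500, calibrated_model
    ):
        _, _, bead_mode = F.streakline(
            [(F.Particle(4.1), 4000)], flow_1500, calibrated_model, seed=1
        )
        # young-dominated yeast mixture: sizes of 0-2 scar cells
        yeast = [(F.Particle(d), 1000) for d in (2.3, 3.1, 3.9)]
        _, _, yeast_mode = F.streakline(yeast, flow_1500, calibrated_model, seed=2)
        assert abs(yeast_mode - bead_mode) <= 0.02 + 1e-9  # within one bin

    def test_mixture_of_small_and_large_is_bimodal(self, flow_1500, calibrated_model):
        _, counts, _ = F.streakline(
            [(F.Particle(4.1), 3000), (F.Particle(15.0), 3000)],
            flow_1500,
            calibrated_model,
            seed=3,
            n_bins=25,
        )
        smoothed = ndimage.uniform_filter1d(counts.astype(float), 3)
        peaks = [
            i
            for i in range(1, len(smoothed) - 1)
            if smoothed[i] >= smoothed[i - 1]
            and smoothed[i] >= smoothed[i + 1]
            and smoothed[i] > 0.2 * smoothed.max()
        ]
        locs = np.array(peaks) / 25.0
        assert locs.min() < 0.6 and locs.max() > 0.7


class TestCalibration:
    def test_reproduces_measured_bead_record(self, calibrated_model, flow_1500):
        cal = F.calibrate(F.default_bead_table())
        pred = cal.predicted
        centre = pred[(pred.diameter_um == 4.1) & (pred.port == 2)]
        assert abs(centre.predicted_yield.iloc[0] - 0.55) < 0.05
        concave = pred[pred.port == 4]
        assert (abs(concave.predicted_yield - 0.60) < 0.09).all()

    def test_underdetermined_table_rejected(self):
        table = F.default_bead_table().iloc[:2]
        with pytest.raises(CalibrationError):
            F.calibrate(table)

    def test_parameter_recovery_from_synthetic_table(self, flow_1500):
        # generate per-port yields from a known model, then refit from a
        # perturbed start: the gauge-shared parameters must come back
        truth = F.DEFAULT_FORCE_MODEL
        rows = []
        for d in (4.1, 5.56, 9.95):
            dist = F.outlet_distribution(F.Particle(d), flow_1500, truth)
            for port, y in enumerate(dist.probabilities, start=1):
                rows.append((d, 1500.0, port, y))
        import pandas as pd

        table = pd.DataFrame(
            rows, columns=["diameter_um", "flow_ul_min", "port", "yield_frac"]
        )
        from dataclasses import replace

        start = replace(truth, c_w=truth.c_w * 0.4, c_d=truth.c_d * 0.6, sigma_f=0.2)
        fitted = F.calibrate(table, start=start).model
        assert fitted.c_d == pytest.approx(truth.c_d, rel=0.1)
        assert fitted.sigma_f == pytest.approx(truth.sigma_f, rel=0.1)
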