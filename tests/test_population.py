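"""Age-structured culture simulation and the sorting transfer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scarflow import population as P
from scarflow.errors import UndefinedMetricError
from scarflow.focusing import DEFAULT_FORCE_MODEL
from scarflow.hydraulics import FlowCondition


class TestStableAgeDistribution:
    def test_closed_form(self):
        p = P.stable_age_distribution(10)
        assert p[0] == 0.5  # every division produces exactly one newborn
        assert p[1] == 0.25
        assert p.sum() == pytest.approx(1.0, abs=1e-15)
        assert p[-1] == 2.0**-10  # remainder mass

    def test_kmax_validation(self):
        with pytest.raises(ValueError):
            P.stable_age_distribution(0)

    def test_matches_discrete_event_simulation(self):
        """Chi-square test of the simulated exponential culture against
        the closed form must not reject at alpha = 0.01 (n = 1e5)."""
        cells = P.simulate_culture("exponential", 100000, seed=11)
        k = cells["scars"].to_numpy()
        kmax = 10
        observed = np.bincount(np.minimum(k, kmax), minlength=kmax + 1)
        expected = P.stable_age_distribution(kmax) * len(k)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=kmax)


class TestSimulateCulture:
    def test_exponential_newborn_fraction(self):
        cells = P.simulate_culture("exponential", 100000, seed=1)
        frac = (cells["scars"] == 0).mean()
        # analytic value 0.5, at the edge of the measured 51.5 +/- 1.5 band;
        # small extra allowance for the n = 1e5 subsampling noise
        assert abs(frac - 0.515) <= 0.015 + 0.004

    def test_high_density_age_fractions(self):
        cells = P.simulate_culture("high_density", 100000, seed=2)
        k = cells["scars"].to_numpy()
        assert 0.59 <= (k <= 2).mean() <= 0.75
        assert 0.25 <= (k >= 3).mean() <= 0.41
        assert (k >= 11).mean() < 0.005

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            P.simulate_culture("stationary", 10)

    def test_columns_and_invariants(self):
        cells = P.simulate_culture("high_density", 500, seed=3)
        assert {"cell_id", "scars", "diameter_um", "hsp104_foci"} <= set(cells.columns)
        assert (cells["scars"] >= 0).all()
        assert (cells["diameter_um"] > 0).all()
        assert (cells["hsp104_foci"] >= 0).all()


class TestDiameterModel:
    def test_noise_free_values(self):
        assert P.diameter_from_scars(0)[0] == pytest.approx(2.3)
        assert P.diameter_from_scars(11)[0] == pytest.approx(2.3 + 0.8 * 11)
        # plateau: no growth past k_sat
        assert P.diameter_from_scars(14)[0] == P.diameter_from_scars(11)[0]

    def test_linearity_step_is_exactly_the_slope(self):
        d5, d4 = P.diameter_from_scars([5, 4])
        assert d5 - d4 == pytest.approx(0.8)

    def test_noisy_draws_truncated_at_one_micron(self):
        rng = np.random.default_rng(0)
        d = P.diameter_from_scars(np.zeros(20000, dtype=int), rng=rng)
        assert d.min() >= 1.0
        assert d.mean() == pytest.approx(2.3, abs=0.05)


class TestHspPrevalence:
    def test_monotone_nondecreasing(self):
        p = P.hsp104_prevalence(np.arange(0, 15))
        assert np.all(np.diff(p) >= 0)

    def test_bounded_in_unit_interval(self):
        p = P.hsp104_prevalence(np.arange(0, 100))
        assert np.all((p >= 0) & (p <= 1))

    def test_step_limit(self):
        model = P.HspFociModel(floor=0.0, ceiling=1.0, k_half=4.0, steepness=1e6)
        p = P.hsp104_prevalence([3, 5], model)
        assert p[0] == pytest.approx(0.0, abs=1e-6)
        assert p[1] == pytest.approx(1.0, abs=1e-6)


class TestApplySort:
    def test_conserves_cells_and_is_order_invariant(self, flow_1500, calibrated_model):
        cells = P.simulate_culture("high_density", 2000, seed=5)
        srt = P.apply_sort(cells, flow_1500, calibrated_model, seed=6)
        assert len(srt) == len(cells)
        ports = P.split_ports(srt)
        assert sum(len(p) for p in ports.values()) == len(cells)
        shuffled = cells.iloc[::-1].reset_index(drop=True)
        srt2 = P.apply_sort(shuffled, flow_1500, calibrated_model, seed=6)
        # same per-port composition statistics regardless of row order
        for port in ports:
            a = srt[srt.port == port]["scars"]
            b = srt2[srt2.port == port]["scars"]
            assert abs(len(a) - len(b)) < 0.15 * max(len(a), 1) + 20

    def test_strong_size_selection_enriches_concave_port(self, flow_1500):
        """With Dean centering suppressed, large cells go concave and the
        concave-port mean scar count strictly exceeds the mixture mean."""
        from dataclasses import replace

        model = replace(DEFAULT_FORCE_MODEL, c_d=DEFAULT_FORCE_MODEL.c_d * 0.2,
                        sigma_f=0.02)
        cells = P.simulate_culture("high_density", 5000, seed=7)
        srt = P.apply_sort(cells, flow_1500, model, seed=8)
        concave = srt[srt.port >= 4]
        assert len(concave) > 50
        assert concave["scars"].mean() > cells["scars"].mean()

    def test_center_port_young_enrichment_matches_sorting_experiment(
        self, flow_1500, calibrated_model
    ):
        """A 77%-young mixture is enriched to ~89% young in the centre port."""
        culture = P.simulate_culture("high_density", 60000, seed=9)
        mixture = P.resample_to_young_fraction(culture, 0.77, 30000, seed=10)
        srt = P.apply_sort(mixture, flow_1500, calibrated_model, seed=11)
        center = srt[srt.port == 2]
        em = P.enrichment_metrics(center, mixture)
        assert abs(em.young_fraction - 0.89) <= 0.07


class TestEnrichmentMetrics:
    def test_identity_port(self):
        cells = P.simulate_culture("high_density", 1000, seed=12)
        em = P.enrichment_metrics(cells, cells)
        assert em.young_enrichment == pytest.approx(1.0)
        assert em.adult_enrichment == pytest.approx(1.0)

    def test_toy_hand_count(self):
        port = pd.DataFrame({"scars": [0, 1, 2]})
        mix = pd.DataFrame({"scars": [0, 1, 2, 5, 7]})
        em = P.enrichment_metrics(port, mix)
        assert em.young_fraction == 1.0
        assert em.mean_scars == pytest.approx(1.0)

    def test_empty_port_rejected(self):
        mix = pd.DataFrame({"scars": [0, 1]})
        with pytest.raises(UndefinedMetricError):
            P.enrichment_metrics(mix.iloc[:0], mix)


class TestResampleMixture:
    def test_hits_target_fraction(self):
        cells = P.simulate_culture("high_density", 20000, seed=13)
        mix = P.resample_to_young_fraction(cells, 0.77, 10000, seed=14)
        assert (mix["scars"] <= 2).mean() == pytest.approx(0.77, abs=0.001)

    def test_invalid_fraction_rejected(self):
        cells = P.simulate_culture("high_density", 100, seed=15)
        with pytest.raises(ValueError):
            P.resample_to_young_fraction(cells, 1.5, 100)
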