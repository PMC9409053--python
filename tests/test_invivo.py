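"""Biodistribution dosimetry and tumour-growth summaries."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from radbiodose.errors import DomainError, InsufficientDataError
from radbiodose.invivo import (
    BQ_PER_G_PER_PERCENT_AA_MBQ,
    KEV_TO_J,
    TumorGrowthSeries,
    absorbed_dose_per_mbq,
    compare_groups_at_day,
    regrowth_day,
    time_integrated_concentration,
)
from radbiodose.synthetic import generate_tumor_growth

FIXTURE_SAMPLES = [(3.0, 10.0), (24.0, 5.0)]


class TestTimeIntegration:
    def test_all_zero_samples(self, i131):
        ta = time_integrated_concentration([(3.0, 0.0), (24.0, 0.0)], i131)
        assert ta.a_tilde_bq_s_per_g_mbq == 0.0

    def test_monoexp_constant_decay_closed_form(self, at211):
        """Pure physical decay: ã = C₀/λ within 1% (mono-exponential scheme)."""
        lam_h = at211.decay_constant_per_s * 3600.0
        c0 = 20.0
        samples = [(t, c0 * math.exp(-lam_h * t)) for t in (3.0, 24.0)]
        ta = time_integrated_concentration(samples, at211, scheme="monoexp_fit")
        expected = c0 / lam_h * 3600.0 * BQ_PER_G_PER_PERCENT_AA_MBQ
        assert ta.a_tilde_bq_s_per_g_mbq == pytest.approx(expected, rel=0.01)

    def test_trapezoid_tail_matches_quadrature_oracle(self, i131):
        """Fixed fixture vs scipy.integrate.quad on the same piecewise model,
        agreement to 0.1%."""
        lam_h = i131.decay_constant_per_s * 3600.0
        (t1, c1), (t2, c2) = FIXTURE_SAMPLES
        rise, _ = quad(lambda t: c1 * t / t1, 0.0, t1)
        mid, _ = quad(lambda t: c1 + (c2 - c1) * (t - t1) / (t2 - t1), t1, t2)
        rate = max(math.log(c1 / c2) / (t2 - t1), lam_h)
        tail, _ = quad(lambda t: c2 * math.exp(-rate * (t - t2)), t2, 2000.0)
        oracle = (rise + mid + tail) * 3600.0 * BQ_PER_G_PER_PERCENT_AA_MBQ
        ta = time_integrated_concentration(FIXTURE_SAMPLES, i131,
                                           scheme="trapezoid_physical_tail")
        assert ta.a_tilde_bq_s_per_g_mbq == pytest.approx(oracle, rel=1e-3)

    def test_tail_fraction_smaller_for_shorter_half_life(self, at211, i131):
        """The physical floor truncates the At-211 tail harder than I-131's."""
        def tail_fraction(nuclide):
            lam_h = nuclide.decay_constant_per_s * 3600.0
            full = time_integrated_concentration(FIXTURE_SAMPLES, nuclide).a_tilde_bq_s_per_g_mbq
            (t1, c1), (t2, c2) = FIXTURE_SAMPLES
            rate = max(math.log(c1 / c2) / (t2 - t1), lam_h)
            tail = c2 / rate * 3600.0 * BQ_PER_G_PER_PERCENT_AA_MBQ
            return tail / full

        assert tail_fraction(at211) < tail_fraction(i131)

    def test_single_timepoint_insufficient(self, i131):
        with pytest.raises(InsufficientDataError):
            time_integrated_concentration([(3.0, 10.0)], i131)

    def test_unknown_scheme(self, i131):
        with pytest.raises(DomainError):
            time_integrated_concentration(FIXTURE_SAMPLES, i131, scheme="simpson")


class TestAbsorbedDose:
    def test_zero_a_tilde(self, at211):
        ta = time_integrated_concentration([(3.0, 0.0), (24.0, 0.0)], at211)
        assert absorbed_dose_per_mbq(ta, at211).gy_per_mbq == 0.0

    def test_constant_decay_closed_form(self, at211):
        """ã = 1/λ per (Bq/g) → dose = (1/λ)·Ē·1.602e-16·1000 ≈ 4.16e-5 Gy."""
        from radbiodose.invivo import TimeIntegratedActivity

        lam = at211.decay_constant_per_s
        ta = TimeIntegratedActivity("tumour", 1.0 / lam, "analytic")
        dose = absorbed_dose_per_mbq(ta, at211).gy_per_mbq
        expected = (1.0 / lam) * 6927.0 * KEV_TO_J * 1000.0
        assert dose == pytest.approx(expected, rel=1e-12)
        assert dose == pytest.approx(4.16e-5, rel=0.01)

    def test_linearity(self, at211):
        from radbiodose.invivo import TimeIntegratedActivity

        d1 = absorbed_dose_per_mbq(TimeIntegratedActivity("t", 1e9, "x"), at211)
        d2 = absorbed_dose_per_mbq(TimeIntegratedActivity("t", 2e9, "x"), at211)
        assert d2.gy_per_mbq == pytest.approx(2.0 * d1.gy_per_mbq, rel=1e-12)
        half = absorbed_dose_per_mbq(TimeIntegratedActivity("t", 1e9, "x"), at211,
                                     absorbed_fraction=0.5)
        assert half.gy_per_mbq == pytest.approx(0.5 * d1.gy_per_mbq, rel=1e-12)
        weighted = absorbed_dose_per_mbq(TimeIntegratedActivity("t", 1e9, "x"), at211,
                                         rbe_weight=5.0)
        assert weighted.gy_per_mbq == pytest.approx(5.0 * d1.gy_per_mbq, rel=1e-12)

    def test_invalid_absorbed_fraction(self, at211):
        from radbiodose.invivo import TimeIntegratedActivity

        with pytest.raises(DomainError):
            absorbed_dose_per_mbq(TimeIntegratedActivity("t", 1.0, "x"), at211,
                                  absorbed_fraction=1.5)


class TestRegrowthDay:
    def test_strictly_decreasing_never_regrows(self):
        s = TumorGrowthSeries("g", (0.0, 3.0, 6.0, 9.0), (1.0, 0.8, 0.6, 0.5))
        assert regrowth_day(s) is None

    def test_hand_applied_rule(self):
        """Rebound above 1.2× the minimum sustained for two measurements."""
        s = TumorGrowthSeries("g", (0.0, 2.0, 4.0, 6.0, 8.0),
                              (1.0, 0.5, 0.5, 0.7, 0.8))
        assert regrowth_day(s, rebound_fraction=0.2) == 6.0

    def test_single_spike_not_sustained(self):
        s = TumorGrowthSeries("g", (0.0, 2.0, 4.0, 6.0, 8.0),
                              (1.0, 0.5, 0.8, 0.5, 0.55))
        assert regrowth_day(s, rebound_fraction=0.2) is None

    def test_too_few_points(self):
        s = TumorGrowthSeries("g", (0.0, 2.0), (1.0, 0.9))
        with pytest.raises(InsufficientDataError):
            regrowth_day(s)

    def test_detects_generator_delay_within_one_interval(self):
        """Synthetic shrink-plateau-regrow curves: detection lands within one
        sampling interval of the generated delay in ≥ 90% of replicates."""
        delay = 30.0
        days = [float(d) for d in range(0, 61, 3)]
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            series_by_group, _ = generate_tumor_growth(
                [("g", 0.15, 1.5, delay)], days, n_animals=1, cv=0.05,
                seed=500 + rep,
            )
            detected = regrowth_day(series_by_group["g"][0])
            if detected is not None and abs(detected - delay) <= 3.0:
                hits += 1
        assert hits >= 0.9 * n_rep


class TestGroupComparison:
    @staticmethod
    def _series(group, values, day=10.0):
        return [TumorGrowthSeries(group, (0.0, 5.0, day), (1.0, 1.0, v))
                for v in values]

    def test_identical_groups_p_near_one(self):
        groups = {
            "a": self._series("a", [1.1, 1.2, 1.3, 1.4]),
            "b": self._series("b", [1.1, 1.2, 1.3, 1.4]),
        }
        p = compare_groups_at_day(groups, 10.0)
        assert p[("a", "b")] > 0.99

    def test_separated_groups_significant(self, rng):
        groups = {
            "a": self._series("a", 1.0 + 0.1 * rng.standard_normal(4)),
            "b": self._series("b", 100.0 + 0.1 * rng.standard_normal(4)),
        }
        assert compare_groups_at_day(groups, 10.0)[("a", "b")] < 0.001

    def test_bonferroni_triples_three_group_pvalues(self, rng):
        vals = {g: 1.0 + 0.3 * rng.standard_normal(4) for g in "abc"}
        groups = {g: self._series(g, v) for g, v in vals.items()}
        corrected = compare_groups_at_day(groups, 10.0)
        assert len(corrected) == 3
        from scipy import stats

        for (a, b), p in corrected.items():
            raw = stats.ttest_ind(vals[a], vals[b], equal_var=True).pvalue
            assert p == pytest.approx(min(1.0, raw * 3), rel=1e-9)

    def test_missing_day_is_error(self):
        groups = {"a": self._series("a", [1.0, 1.1]),
                  "b": self._series("b", [1.0, 1.1])}
        with pytest.raises(InsufficientDataError):
            compare_groups_at_day(groups, 99.0)
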