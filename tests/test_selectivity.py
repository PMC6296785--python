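"""The d' statistic, its early/late dynamics, change classification,
population summaries, the exact binomial sign test, and cross-area
correlations."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedyn.data import SiteRecording
from facedyn.processing import EARLY_WINDOW, LATE_WINDOW
from facedyn.selectivity import (
    DegenerateVarianceError,
    binomial_sign_test,
    classify_change,
    cross_area_correlation,
    dprime,
    early_late_selectivity,
    population_summary,
)

TIME = np.arange(-50, 250)

finite_rates = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=3, max_size=30)


def make_site(trials, region="pIT"):
    return SiteRecording(site_id="s0", region=region, animal="M1",
                         time_ms=TIME.copy(), trials=trials)


class TestDprime:
    def test_identical_groups_zero(self, rng):
        g = rng.normal(10, 2, size=20)
        assert dprime(g, g) == pytest.approx(0.0)

    def test_textbook_values(self):
        # sample means 3 and 1, sample variances both 1 -> d' = 2
        assert dprime([2, 3, 4], [0, 1, 2]) == pytest.approx(2.0)

    @given(a=finite_rates, b=finite_rates)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_independent_formula(self, a, b):
        a, b = np.array(a), np.array(b)
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2
        if pooled <= 0:
            with pytest.raises(DegenerateVarianceError):
                dprime(a, b)
        else:
            expected = (a.mean() - b.mean()) / np.sqrt(pooled)
            assert dprime(a, b) == pytest.approx(expected)

    @given(a=finite_rates, b=finite_rates,
           alpha=st.floats(min_value=0.1, max_value=10),
           beta=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetry_and_affine_invariance(self, a, b, alpha, beta):
        a, b = np.array(a), np.array(b)
        if (a.var(ddof=1) + b.var(ddof=1)) / 2 <= 1e-12:
            return
        d = dprime(a, b)
        assert dprime(b, a) == pytest.approx(-d, abs=1e-9)
        # common affine rescaling x -> alpha x + beta leaves d' unchanged
        assert dprime(alpha * a + beta, alpha * b + beta) == pytest.approx(
            d, rel=1e-6, abs=1e-9)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            dprime([1.0], [2.0, 3.0])


class TestEarlyLateSelectivity:
    def _two_class_site(self, early_gap, late_gap, rng, n_trials=30):
        """Typical trials exceed atypical by the given gaps in each window."""
        trials = {}
        for cls, sign in (("typ", 1.0), ("atyp", -1.0)):
            for k in range(2):
                trace = rng.normal(50, 6, size=(n_trials, TIME.size))
                trace[:, 110:140] += sign * early_gap / 2
                trace[:, 150:180] += sign * late_gap / 2
                trials[f"{cls}_{k}"] = trace
        return make_site(trials)

    def test_pools_trials_and_recovers_signs(self, rng):
        site = self._two_class_site(12.0, -12.0, rng)
        res = early_late_selectivity(site, ["typ_0", "typ_1"], ["atyp_0", "atyp_1"])
        assert res.d_early > 0 > res.d_late

    def test_label_swap_negates(self, rng):
        site = self._two_class_site(8.0, 3.0, rng)
        r1 = early_late_selectivity(site, ["typ_0", "typ_1"], ["atyp_0", "atyp_1"])
        r2 = early_late_selectivity(site, ["atyp_0", "atyp_1"], ["typ_0", "typ_1"])
        assert r2.d_early == pytest.approx(-r1.d_early)
        assert r2.d_late == pytest.approx(-r1.d_late)

    def test_empty_class_rejected(self, rng):
        site = self._two_class_site(1.0, 1.0, rng)
        with pytest.raises(ValueError):
            early_late_selectivity(site, [], ["atyp_0"])


class TestClassifyChange:
    def test_identical_windows_no_change(self, rng):
        trials = {}
        for cls in ("typ", "atyp"):
            base = rng.normal(40 if cls == "typ" else 30, 5,
                              size=(20, TIME.size))
            base[:, 150:180] = base[:, 110:140]   # late window copies early
            trials[f"{cls}_0"] = base
        site = make_site(trials)
        res = classify_change(site, ["typ_0"], ["atyp_0"], seed=1)
        assert res.change_class == "no_change"

    def test_constructed_reversal_detected(self, rng):
        trials = {}
        for cls, sign in (("typ", 1.0), ("atyp", -1.0)):
            trace = rng.normal(50, 2, size=(40, TIME.size))
            trace[:, 110:140] += sign * 10
            trace[:, 150:180] -= sign * 10
            trials[f"{cls}_0"] = trace
        site = make_site(trials)
        res = classify_change(site, ["typ_0"], ["atyp_0"], seed=1)
        assert res.change_class == "decreased"
        assert res.p_change < 0.01

    def test_type_one_error_rate(self, rng):
        """On exchangeable-window data the decreased+increased rate stays
        near the nominal alpha."""
        n_sites, flagged = 80, 0
        for k in range(n_sites):
            trials = {
                "typ_0": rng.normal(45, 6, size=(10, TIME.size)),
                "atyp_0": rng.normal(35, 6, size=(10, TIME.size)),
            }
            res = classify_change(make_site(trials), ["typ_0"], ["atyp_0"],
                                  alpha=0.01, n_boot=500, seed=k)
            flagged += res.change_class != "no_change"
        # binomial(80, 0.01) three-sigma upper bound
        assert flagged <= 4


class TestPopulationSummary:
    def _results(self, site, typ, atyp):
        return early_late_selectivity(site, typ, atyp)

    def test_all_positive_fraction_one(self, rng):
        results = []
        for k in range(6):
            trials = {
                "typ_0": rng.normal(60, 5, size=(15, TIME.size)),
                "atyp_0": rng.normal(30, 5, size=(15, TIME.size)),
            }
            results.append(self._results(make_site(trials), ["typ_0"], ["atyp_0"]))
        s = population_summary(results, "early", n_boot=200, seed=0)
        assert s.fraction_prefer_typical == 1.0
        assert s.median_dprime > 0

    def test_median_invariant_under_permutation(self, rng):
        results = []
        for k in range(9):
            trials = {
                "typ_0": rng.normal(40 + k, 5, size=(12, TIME.size)),
                "atyp_0": rng.normal(40, 5, size=(12, TIME.size)),
            }
            results.append(self._results(make_site(trials), ["typ_0"], ["atyp_0"]))
        s1 = population_summary(results, "late", n_boot=100, seed=0)
        s2 = population_summary(list(reversed(results)), "late", n_boot=100, seed=0)
        assert s1.median_dprime == pytest.approx(s2.median_dprime)
        assert s1.fraction_prefer_typical == pytest.approx(s2.fraction_prefer_typical)

    def test_requires_results(self):
        with pytest.raises(ValueError):
            population_summary([], "early")


class TestBinomialSignTest:
    def test_all_decreasing_closed_form(self):
        assert binomial_sign_test(10, 10) == pytest.approx(2.0 ** -10)

    def test_paper_scale_counts_are_significant(self):
        assert binomial_sign_test(43, 51) < 1e-6

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 5), (7, 12), (43, 51), (25, 50)])
    def test_matches_exact_fraction_sum(self, k, n):
        exact = sum(Fraction(comb(n, j), 2 ** n) for j in range(k, n + 1))
        assert binomial_sign_test(k, n) == pytest.approx(float(exact), rel=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_sign_test(6, 5)


class TestCrossAreaCorrelation:
    def _pop_from_rates(self, per_image_rates, region="pIT"):
        trials = {
            f"img_{k}": np.full((5, TIME.size), float(rate))
            for k, rate in enumerate(per_image_rates)
        }
        return [make_site(trials, region=region)]

    def test_identical_vectors_rho_one(self):
        rates = np.linspace(10, 60, 8)
        pop = self._pop_from_rates(rates)
        images = [f"img_{k}" for k in range(8)]
        cc = cross_area_correlation(pop, EARLY_WINDOW, pop, LATE_WINDOW, images,
                                    n_boot=50, seed=0)
        assert cc.rho == pytest.approx(1.0)

    def test_anticorrelated_vectors_rho_minus_one(self):
        rates = np.linspace(10, 60, 8)
        pop_a = self._pop_from_rates(rates)
        pop_b = self._pop_from_rates(rates[::-1], region="cIT")
        images = [f"img_{k}" for k in range(8)]
        cc = cross_area_correlation(pop_a, EARLY_WINDOW, pop_b, EARLY_WINDOW,
                                    images, n_boot=50, seed=0)
        assert cc.rho == pytest.approx(-1.0)

    def test_too_few_images(self):
        pop = self._pop_from_rates([1, 2, 3])
        with pytest.raises(ValueError):
            cross_area_correlation(pop, EARLY_WINDOW, pop, LATE_WINDOW,
                                   ["img_0", "img_1", "img_2"])

    def test_calibrated_world_is_anticorrelated(self, default_population,
                                                matched_sets):
        """Early cIT activity predicts late pIT activity negatively across
        the matched images, near the generator's configured strength."""
        typical, atypical, reference = matched_sets
        ds = default_population
        images = [i for i in typical + atypical if i != reference]
        cc = cross_area_correlation(ds.region_sites("cIT"), EARLY_WINDOW,
                                    ds.region_sites("pIT"), LATE_WINDOW,
                                    images, n_boot=300, seed=2)
        assert cc.rho < -0.2
        assert cc.rho == pytest.approx(-0.52, abs=0.25)
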