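"""The five conformity statistics, the digit Simpson index, and PD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

import benfordeco as b

EXP = b.BENFORD_PROBS


def _random_tallies():
    return st.lists(st.integers(min_value=0, max_value=60), min_size=9, max_size=9).filter(
        lambda c: sum(c) > 0
    )


def _random_distributions():
    return (
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=9,
            max_size=9,
        )
        .map(lambda w: [x / sum(w) for x in w])
    )


class TestMorrowDistance:
    @pytest.mark.parametrize(
        "case, printed",
        [("fish_ewh", 0.638), ("salamanders_post1990", 1.437)],
    )
    def test_printed_values(self, fixtures, case, printed):
        assert b.morrow_distance(fixtures[case].tally) == pytest.approx(printed, abs=5e-4)

    def test_zero_at_reference(self):
        tally = b.DigitTally(tuple(np.round(1e6 * EXP).astype(int)))
        assert b.morrow_distance(tally, tally.proportions()) == 0.0

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            b.morrow_distance(b.DigitTally((0,) * 9))

    def test_sqrt_n_scaling(self):
        # at fixed proportions, d*_n grows as sqrt(n)
        base = b.DigitTally((10, 8, 6, 5, 4, 3, 2, 1, 1))
        x4 = b.DigitTally(tuple(4 * c for c in base.counts))
        assert b.morrow_distance(x4) == pytest.approx(2 * b.morrow_distance(base))


class TestKossovskySSD:
    @pytest.mark.parametrize(
        "case, printed, tol",
        [("succession_early", 38.4, 0.05), ("combined_steady_state", 6.62, 0.005)],
    )
    def test_printed_values(self, fixtures, case, printed, tol):
        obs = fixtures[case].tally.proportions()
        assert b.kossovsky_ssd(obs) == pytest.approx(printed, abs=tol)

    def test_zero_at_reference(self):
        assert b.kossovsky_ssd(EXP) == 0.0

    def test_n_invariance(self):
        obs = b.DigitTally((10, 8, 6, 5, 4, 3, 2, 1, 1)).proportions()
        assert b.kossovsky_ssd(obs) == b.kossovsky_ssd(obs)  # pure function of proportions
        scaled = b.DigitTally((30, 24, 18, 15, 12, 9, 6, 3, 3)).proportions()
        assert b.kossovsky_ssd(scaled) == pytest.approx(b.kossovsky_ssd(obs))


class TestCohenW:
    @pytest.mark.parametrize(
        "case, printed", [("fish_ewh", 0.182), ("diatoms_large", 0.316)]
    )
    def test_printed_values(self, fixtures, case, printed):
        obs = fixtures[case].tally.proportions()
        assert b.cohen_w(obs) == pytest.approx(printed, abs=5e-4)

    def test_zero_at_reference(self):
        assert b.cohen_w(EXP) == 0.0

    def test_all_nine_printed_values(self, fixtures):
        # the square-root form reproduces every reported effect size
        for name, fix in fixtures.items():
            assert b.cohen_w(fix.tally.proportions()) == pytest.approx(
                fix.expected["cohen_w"], abs=5e-4
            ), name


class TestPearsonResiduals:
    def test_fish_digit_one(self, fixtures):
        pr = b.pearson_residuals(fixtures["fish_ewh"].tally)
        assert pr[0] == pytest.approx((47 - 141 * EXP[0]) / np.sqrt(141 * EXP[0]))
        assert pr[0] == pytest.approx(0.70, abs=5e-3)

    def test_diatoms_large_digit_three_magnitude(self, fixtures):
        # digit 3 on large islands: |PR| = 1.98 (27 observed vs 18.5 expected,
        # so the residual is positive)
        pr = b.pearson_residuals(fixtures["diatoms_large"].tally)
        assert abs(pr[2]) == pytest.approx(1.98, abs=5e-3)
        assert pr[2] > 0

    def test_zero_when_counts_match_expectation(self):
        n = 10**6
        tally = b.DigitTally(tuple(np.round(n * EXP).astype(int)))
        assert np.max(np.abs(b.pearson_residuals(tally))) < 0.01

    @given(_random_tallies())
    @settings(deadline=None)
    def test_sum_of_squares_is_chisquare(self, counts):
        # brute-force oracle: sum PR^2 equals the chi-square GOF statistic
        tally = b.DigitTally(tuple(counts))
        pr = b.pearson_residuals(tally)
        chi2 = chisquare(tally.as_array(), tally.n * EXP).statistic
        assert np.sum(pr**2) == pytest.approx(chi2, rel=1e-9)


class TestKLDivergence:
    @pytest.mark.parametrize(
        "case, printed", [("fish_ewh", 0.0083), ("succession_late", 0.0068)]
    )
    def test_printed_values(self, fixtures, case, printed):
        obs = fixtures[case].tally.proportions()
        assert b.kl_divergence(obs) == pytest.approx(printed, abs=5e-5)

    def test_zero_iff_identical(self):
        assert b.kl_divergence(EXP) == pytest.approx(0.0, abs=1e-15)

    def test_zero_cells_contribute_zero(self):
        obs = np.array([0.5, 0.5, 0, 0, 0, 0, 0, 0, 0])
        manual = 0.5 * np.log10(0.5 / EXP[0]) + 0.5 * np.log10(0.5 / EXP[1])
        assert b.kl_divergence(obs) == pytest.approx(manual)

    def test_base_parameter(self):
        obs = np.array([0.2, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05, 0.05, 0.05])
        assert b.kl_divergence(obs, base=np.e) == pytest.approx(
            b.kl_divergence(obs) * np.log(10)
        )

    @given(_random_distributions())
    @settings(deadline=None)
    def test_nonnegative(self, probs):
        # Gibbs' inequality over randomized valid distributions
        assert b.kl_divergence(probs) >= -1e-12


class TestSimpsonIndex:
    def test_benford_reference_value(self):
        assert b.simpson_index(EXP) == pytest.approx(0.165, abs=5e-4)

    def test_bounds(self):
        assert b.simpson_index(np.full(9, 1 / 9)) == pytest.approx(1 / 9)
        point_mass = np.zeros(9)
        point_mass[0] = 1.0
        assert b.simpson_index(point_mass) == 1.0

    @given(_random_distributions())
    @settings(deadline=None)
    def test_within_bounds_always(self, probs):
        d = b.simpson_index(probs)
        assert 1 / 9 - 1e-12 <= d <= 1.0 + 1e-12


class TestPercentageDifference:
    @pytest.mark.parametrize(
        "a, bb, expected, tol",
        [(0.0071, 0.0068, 4.32, 5e-3), (0.0125, 0.0238, 62.3, 0.05)],
    )
    def test_printed_values(self, a, bb, expected, tol):
        assert b.percentage_difference(a, bb) == pytest.approx(expected, abs=tol)

    def test_symmetric_and_zero_at_equality(self):
        assert b.percentage_difference(3.0, 7.0) == b.percentage_difference(7.0, 3.0)
        assert b.percentage_difference(0.42, 0.42) == 0.0

    def test_undefined_at_double_zero(self):
        with pytest.raises(ValueError):
            b.percentage_difference(0.0, 0.0)


class TestReportInvariants:
    def test_identity_on_all_fixtures(self, reports):
        # d*_n^2 = n * SSD * 1e-4 algebraically
        for name, rep in reports.items():
            assert rep.morrow_d**2 == pytest.approx(rep.n * rep.ssd * 1e-4, abs=1e-9), name

    @given(_random_tallies())
    @settings(deadline=None)
    def test_identity_on_random_tallies(self, counts):
        rep = b.conformity_report(b.DigitTally(tuple(counts)))
        assert rep.morrow_d**2 == pytest.approx(rep.n * rep.ssd * 1e-4, abs=1e-9)

    @given(_random_tallies())
    @settings(deadline=None)
    def test_statistics_zero_iff_obs_equals_exp(self, counts):
        tally = b.DigitTally(tuple(counts))
        obs = tally.proportions()
        if np.allclose(obs, EXP, atol=1e-15):
            return
        rep = b.conformity_report(tally)
        # any departure from the reference makes every distance positive
        assert rep.morrow_d > 0
        assert rep.ssd > 0
        assert rep.cohen_w > 0
        assert rep.kl_d > 0 or any(o == 0 for o in obs)  # zero cells only lower KL
        assert rep.max_abs_residual > 0

    def test_report_serialization_roundtrip(self, reports):
        import json

        payload = json.loads(reports["fish_ewh"].to_json())
        assert payload["n"] == 141
        assert payload["display"]["d*_n"] == 0.638
        assert len(payload["pearson_residuals"]) == 9
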