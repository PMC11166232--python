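"""Dynamic complexity: closed forms, brute-force oracles, surrogate layers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patternshift import (
    ComplexityParams,
    DegenerateInputError,
    build_crd,
    dc_profile,
    dc_series,
    distribution_measure,
    dynamic_complexity,
    fluctuation_intensity,
    instability_periods,
    surrogate_null,
)

from conftest import make_series


# --- independent oracles (direct transcription, no vectorization tricks) ---

def oracle_fluctuation(window, lo, hi):
    w = list(map(float, window))
    m = len(w)
    diffs = [w[i + 1] - w[i] for i in range(m - 1)]
    signs = [0 if d == 0 else (1 if d > 0 else -1) for d in diffs]
    # plateaus extend the running segment; leading plateau joins first one
    filled = signs[:]
    for i in range(1, len(filled)):
        if filled[i] == 0:
            filled[i] = filled[i - 1]
    for i in range(len(filled) - 2, -1, -1):
        if filled[i] == 0:
            filled[i] = filled[i + 1]
    total = 0.0
    start = 0
    for i in range(len(filled)):
        boundary = i == len(filled) - 1 or (
            filled[i] != filled[i + 1] and filled[i] != 0
        )
        if boundary:
            end = i + 1
            total += abs(w[end] - w[start]) / (end - start)
            start = end
    return total / ((hi - lo) * (m - 1))


def oracle_distribution(window, lo, hi):
    y = sorted(map(float, window))
    m = len(y)
    d = (hi - lo) / (m - 1)
    deficit = 0.0
    ideal = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            span = (j - i) * d
            ideal += span
            deficit += max(0.0, span - (y[j] - y[i]))
    return 1.0 - deficit / ideal


ALT = [0, 100, 0, 100, 0, 100, 0]
RAMP = list(np.linspace(0, 100, 7))


class TestClosedForms:
    @pytest.mark.parametrize(
        "window,f_expected,d_expected",
        [
            (ALT, 1.0, 0.75),
            (RAMP, (100 / 6) / 600, 1.0),
            ([50] * 7, 0.0, 0.0),
        ],
    )
    def test_worked_examples_match_hand_values(self, window, f_expected, d_expected):
        assert fluctuation_intensity(window, 0, 100) == pytest.approx(
            f_expected, abs=1e-12
        )
        assert distribution_measure(window, 0, 100) == pytest.approx(
            d_expected, abs=1e-12
        )

    def test_examples_match_independent_oracle(self):
        for window in (ALT, RAMP, [50] * 7, [0, 50, 50, 100, 20, 90, 10]):
            assert fluctuation_intensity(window, 0, 100) == pytest.approx(
                oracle_fluctuation(window, 0, 100), abs=1e-12
            )
            assert distribution_measure(window, 0, 100) == pytest.approx(
                oracle_distribution(window, 0, 100), abs=1e-12
            )


class TestOracleEquivalence:
    def test_exhaustive_windows_of_length_five(self):
        """All 3^5 windows over {0, 50, 100} agree with direct summation."""
        for window in itertools.product((0.0, 50.0, 100.0), repeat=5):
            f = fluctuation_intensity(window, 0, 100)
            d = distribution_measure(window, 0, 100)
            assert f == pytest.approx(oracle_fluctuation(window, 0, 100), abs=1e-12)
            assert d == pytest.approx(oracle_distribution(window, 0, 100), abs=1e-12)
            assert 0.0 <= f <= 1.0 and 0.0 <= d <= 1.0

    @given(
        # quarter-integer grid keeps a*x+b exactly representable, so the
        # monotone-segment structure survives the affine map bit-for-bit
        st.lists(
            st.integers(0, 400).map(lambda k: k / 4.0), min_size=3, max_size=12
        ),
        st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0]),
        st.integers(-200, 200).map(lambda k: k / 4.0),
    )
    @settings(derandomize=True, max_examples=80)
    def test_affine_invariance_and_bounds(self, window, a, b):
        f = fluctuation_intensity(window, 0, 100)
        d = distribution_measure(window, 0, 100)
        assert 0.0 <= f <= 1.0 and 0.0 <= d <= 1.0
        rescaled = [a * x + b for x in window]
        assert fluctuation_intensity(rescaled, b, 100 * a + b) == pytest.approx(
            f, abs=1e-9
        )
        assert distribution_measure(rescaled, b, 100 * a + b) == pytest.approx(
            d, abs=1e-9
        )
        span = max(window) - min(window)
        if span > 1e-6:  # meaningfully non-constant (beyond float cancellation)
            assert dynamic_complexity(window, 0, 100) > 0.0
        elif span == 0.0:
            assert dynamic_complexity(window, 0, 100) == 0.0

    def test_distribution_permutation_invariant_fluctuation_not(self):
        window = ALT
        sorted_w = sorted(window)
        assert distribution_measure(window, 0, 100) == pytest.approx(
            distribution_measure(sorted_w, 0, 100), abs=1e-12
        )
        assert fluctuation_intensity(window, 0, 100) != pytest.approx(
            fluctuation_intensity(sorted_w, 0, 100), abs=1e-6
        )


class TestDcSeries:
    def test_constant_channel_all_zero(self):
        s = make_series([[50.0] * 30])
        field = dc_series(s, ComplexityParams())
        assert np.all(field.dc[:, 6:] == 0.0)
        assert np.all(np.isnan(field.dc[:, :6]))

    def test_alternating_channel_hits_quarter_three(self):
        s = make_series([([0.0, 100.0] * 40)[:79]])
        field = dc_series(s, ComplexityParams())
        defined = field.dc[0, 6:]
        assert defined.size == 73  # 79-day series, window 7
        assert np.allclose(defined, 0.75, atol=1e-12)

    def test_profile_matches_per_window_evaluation(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 100, 25)
        prof = dc_profile(x, 7, 0, 100)
        for t in range(6, 25):
            expected = oracle_fluctuation(x[t - 6 : t + 1], 0, 100) * (
                oracle_distribution(x[t - 6 : t + 1], 0, 100)
            )
            assert prof[t] == pytest.approx(expected, abs=1e-12)


class TestSurrogates:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        s = make_series(rng.uniform(0, 100, (3, 40)))
        p = ComplexityParams(n_surrogates=100, seed=9)
        a, b = surrogate_null(s, p), surrogate_null(s, p)
        assert np.array_equal(a.q_gray, b.q_gray)
        assert np.array_equal(a.q_black, b.q_black)

    def test_constant_channel_gives_degenerate_null_and_empty_masks(self):
        s = make_series([[42.0] * 30])
        p = ComplexityParams(n_surrogates=100, seed=0)
        null = surrogate_null(s, p)
        assert null.sd[0] == 0.0 and null.mean[0] == 0.0
        field = build_crd(dc_series(s, p), null)
        assert not field.gray_mask.any()
        assert np.all(field.column_histogram == 0)

    def test_masks_nest_and_histogram_counts(self):
        rng = np.random.default_rng(2)
        s = make_series(rng.uniform(0, 100, (5, 60)))
        p = ComplexityParams(n_surrogates=150, seed=3)
        field = build_crd(dc_series(s, p), surrogate_null(s, p))
        assert not (field.black_mask & ~field.gray_mask).any()
        assert np.array_equal(
            field.column_histogram, (field.gray_mask | field.black_mask).sum(axis=0)
        )

    def test_degenerate_null_with_varying_dc_is_an_error(self):
        rng = np.random.default_rng(3)
        s = make_series(rng.uniform(0, 100, (1, 30)))
        p = ComplexityParams(n_surrogates=100, seed=1)
        null = surrogate_null(s, p)
        null.sd[:] = 0.0
        with pytest.raises(DegenerateInputError):
            build_crd(dc_series(s, p), null)


class TestInstabilityPeriods:
    @staticmethod
    def _field_and_null(values, seed=0, n_sur=200):
        s = make_series(values)
        p = ComplexityParams(n_surrogates=n_sur, seed=seed)
        field = dc_series(s, p)
        return field, surrogate_null(s, p)

    def test_quiet_series_yields_no_periods(self):
        rng = np.random.default_rng(4)
        field, null = self._field_and_null(50 + rng.normal(0, 2, (2, 50)).clip(-40, 40))
        periods = instability_periods(field, null, alpha=0.01)
        for per in periods:
            assert per.p_value > 0.001  # nothing overwhelming in quiet noise

    def test_gap_bridging_merges_runs(self):
        # planted burst with a 1-day lull still reports one period
        rng = np.random.default_rng(8)
        base = 50 + rng.normal(0, 1.5, 70)
        base[30:45] += rng.normal(0, 14, 15) * np.resize([1.0, -1.0], 15)
        field, null = self._field_and_null([np.clip(base, 0, 100)], seed=8)
        periods = instability_periods(field, null, alpha=0.05, max_gap=1)
        assert periods
        spans = [(p.start_day, p.end_day) for p in periods]
        assert any(a <= 45 and 30 <= b for a, b in spans)

    def test_planted_instability_window_detected_significantly(self):
        from patternshift import (
            SyntheticSpec,
            factor_scores,
            locf_impute,
            simulate_process,
        )

        hits = 0
        for seed in range(20):
            spec = SyntheticSpec(
                seed=seed, transition_day=None, instability_window=(20, 35)
            )
            s, _ = simulate_process(spec)
            fac = factor_scores(locf_impute(s))
            p = ComplexityParams(n_surrogates=200, seed=seed)
            field = dc_series(fac, p)
            null = surrogate_null(fac, p)
            periods = instability_periods(field, null, alpha=0.05)
            hits += any(
                per.overlaps(20, 35) and per.p_value < 0.05 for per in periods
            )
        assert hits >= 18  # >= 90% of seeded runs
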