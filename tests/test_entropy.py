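"""Entropy estimators: closed forms, degenerate cases, brute-force oracle
agreement and the qualitative irregularity ordering."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import entroadl as e
from entroadl.entropy import NoTemplateMatchesError, ShortSeriesError

from oracles import (
    oracle_apen,
    oracle_fuzzyen,
    oracle_peren,
    oracle_sampen,
    oracle_shannon,
)

TABLE2_AN = [3] * 5 + [5] + [1] * 4 + [5] + [7] * 49
PARAMS = e.EntropyParams()


class TestClosedForms:
    @pytest.mark.parametrize("measure", sorted(e.MEASURES))
    def test_constant_sequence_scores_zero(self, measure):
        value = e.compute_measure(measure, [7] * 60, PARAMS)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_uniform_two_symbol_shannon_is_ln2(self):
        assert e.shannon_entropy([1] * 30 + [3] * 30) == pytest.approx(math.log(2))

    def test_shannon_k_scales_linearly(self):
        x = [1, 3, 3, 5]
        assert e.shannon_entropy(x, k=2.0) == pytest.approx(2 * e.shannon_entropy(x))

    def test_table2_hour_shannon_matches_frequency_formula(self):
        freqs = [5 / 60, 2 / 60, 4 / 60, 49 / 60]
        expected = -sum(f * math.log(f) for f in freqs)
        assert e.shannon_entropy(TABLE2_AN) == pytest.approx(expected)

    def test_monotone_sequence_has_zero_permutation_entropy(self):
        assert e.permutation_entropy(list(range(10))) == pytest.approx(0.0)

    def test_one_up_one_down_pattern_gives_ln2(self):
        assert e.permutation_entropy([1, 3, 2], m=2) == pytest.approx(math.log(2))

    def test_coarse_grain_examples(self):
        assert list(e.coarse_grain([1, 3, 5, 7], 2)) == [2.0, 6.0]
        x = [1, 3, 2, 5]
        assert list(e.coarse_grain(x, 1)) == x
        assert list(e.coarse_grain(x, 4)) == [2.75]

    def test_single_scale_multiscale_equals_base(self):
        x = [1, 3, 1, 5, 3, 3, 1, 5, 1, 3] * 6
        params = e.EntropyParams(scales=(1,))
        assert e.multiscale_entropy(x, "PerEn", params) == pytest.approx(
            e.permutation_entropy(x)
        )
        assert e.multiscale_entropy(x, "FuzzyEn", params) == pytest.approx(
            e.fuzzy_entropy(x)
        )

    def test_multiscale_per_scale_values_match_single_scale_calls(self):
        rng = np.random.default_rng(3)
        x = rng.choice([1, 3, 5, 7], size=60)
        expected = np.mean(
            [e.permutation_entropy(e.coarse_grain(x, s)) for s in (1, 2, 3)]
        )
        assert e.multiscale_entropy(x, "PerEn", PARAMS) == pytest.approx(expected)


class TestDegenerateCases:
    def test_apen_template_example_matches_oracle(self):
        x = [1, 3, 1, 3, 1, 3, 1, 3]
        assert e.approximate_entropy(x, 2, 1.0) == pytest.approx(
            oracle_apen(x, 2, 1.0), abs=1e-12
        )

    def test_sampen_no_m_matches_raises(self):
        with pytest.raises(NoTemplateMatchesError):
            e.sample_entropy([1, 5, 9, 1, 7], m=2, r=0.5)

    def test_sampen_no_m1_matches_returns_finite_ceiling_with_warning(self):
        # length-2 templates repeat but no length-3 template does
        x = [1, 3, 9, 1, 3, 5]
        n, m = len(x), 2
        with pytest.warns(RuntimeWarning):
            value = e.sample_entropy(x, m=m, r=1.0)
        assert value == pytest.approx(-math.log(1 / ((n - m) * (n - m - 1))))

    def test_too_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            e.approximate_entropy([1, 2, 3], m=2)
        with pytest.raises(ShortSeriesError):
            e.sample_entropy([1, 2, 3], m=2)
        with pytest.raises(ShortSeriesError):
            e.permutation_entropy([1], m=2)

    def test_identical_fuzzy_templates_have_unit_membership(self):
        # ln(phi) = 0 on a series whose templates are all identical
        assert e.fuzzy_entropy([4] * 10, 2, 1.0) == pytest.approx(0.0)


def _random_symbol_series(rng, length=60):
    return rng.choice([1, 3, 5, 7, 9], size=length).astype(float)


class TestOracleAgreement:
    """Each estimator against an independent double-loop implementation."""

    def test_table2_hour_fuzzyen_matches_oracle(self):
        assert e.fuzzy_entropy(TABLE2_AN, 2, 1.0, 2.0) == pytest.approx(
            oracle_fuzzyen(TABLE2_AN, 2, 1.0, 2.0), abs=1e-10
        )

    def test_random_length_60_sequences_match_oracles(self):
        rng = np.random.default_rng(11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(25):
                x = _random_symbol_series(rng)
                xs = x.tolist()
                assert e.shannon_entropy(x) == pytest.approx(
                    oracle_shannon(xs), abs=1e-10
                )
                assert e.approximate_entropy(x) == pytest.approx(
                    oracle_apen(xs), abs=1e-10
                )
                assert e.permutation_entropy(x) == pytest.approx(
                    oracle_peren(xs), abs=1e-10
                )
                assert e.fuzzy_entropy(x) == pytest.approx(
                    oracle_fuzzyen(xs), abs=1e-10
                )
                expected = oracle_sampen(xs)
                if math.isnan(expected):
                    with pytest.raises(NoTemplateMatchesError):
                        e.sample_entropy(x)
                else:
                    assert e.sample_entropy(x) == pytest.approx(expected, abs=1e-10)


class TestProperties:
    def test_apen_non_negative_on_random_symbol_series(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            assert e.approximate_entropy(_random_symbol_series(rng)) >= -1e-12

    @given(st.lists(st.sampled_from([1, 3, 5, 7]), min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_shannon_bounded_by_log_alphabet(self, xs):
        value = e.shannon_entropy(xs)
        distinct = len(set(xs))
        assert -1e-12 <= value <= math.log(distinct) + 1e-12
        counts = {s: xs.count(s) for s in set(xs)}
        if len(set(counts.values())) == 1:  # uniform -> equality
            assert value == pytest.approx(math.log(distinct))

    @given(st.lists(st.sampled_from([1, 3, 5, 7, 9]), min_size=4, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_permutation_entropy_bounded_by_log_m_factorial(self, xs):
        for m in (2, 3):
            if len(xs) >= m:
                value = e.permutation_entropy(xs, m=m)
                assert -1e-12 <= value <= math.log(math.factorial(m)) + 1e-12

    @pytest.mark.parametrize("fn", [e.sample_entropy, e.fuzzy_entropy])
    def test_wider_tolerance_never_increases_entropy(self, fn):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = _random_symbol_series(rng)
            values = []
            for r in (0.5, 1.0, 2.0, 4.0, 8.0):
                try:
                    values.append(fn(x, 2, r))
                except NoTemplateMatchesError:
                    continue
            assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_transition_rich_scores_above_two_block_for_order_sensitive_measures(self):
        """A randomly transition-rich hour (every sample differs from its
        predecessor) is more irregular than a 2-block hour for every
        order-sensitive measure.  A strictly periodic alternation would NOT
        do for the template measures -- perfect periodicity is maximally
        self-similar, so ApEn/SampEn/FuzzyEn score it near zero -- hence the
        seeded irregular ensemble here.  ShEn sees only frequencies and
        cannot separate the two (the documented counterexample)."""
        rng = np.random.default_rng(0)
        blocks = [1] * 30 + [3] * 30
        for _ in range(10):
            x = [1]
            for _ in range(59):
                x.append(int(rng.choice([c for c in (1, 3, 5) if c != x[-1]])))
            for measure in ["ApEn", "SampEn", "PerEn", "MPE", "FuzzyEn", "MFE"]:
                high = e.compute_measure(measure, x, PARAMS)
                low = e.compute_measure(measure, blocks, PARAMS)
                assert high > low, measure
        assert e.shannon_entropy([1, 3] * 30) == pytest.approx(
            e.shannon_entropy(blocks)
        )

    def test_r_scaled_by_sd_switch_changes_effective_tolerance(self):
        x = np.array([1, 9, 1, 9, 3, 7, 1, 9, 5, 5] * 6, dtype=float)
        scaled = e.EntropyParams(r=1.0, r_scaled_by_sd=True)
        absolute = e.EntropyParams(r=1.0)
        v_scaled = e.compute_measure("FuzzyEn", x, scaled)
        v_abs = e.compute_measure("FuzzyEn", x, absolute)
        assert v_scaled != pytest.approx(v_abs)
        assert v_scaled == pytest.approx(
            e.fuzzy_entropy(x, 2, float(np.std(x)), 2.0)
        )
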