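"""Sample Entropy, coarse-graining, multiscale entropy, phase handling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirsentropy import (
    PhaseWindows,
    SampEnParams,
    coarse_grain,
    compute_complexity_table,
    homogenize_phase_lengths,
    multiscale_entropy,
    sample_entropy,
)
from nirsentropy.recording import HemoglobinRecording

from .oracles import coarse_grain_oracle, sampen_oracle


class TestSampleEntropy:
    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("delay", [1, 2])
    @pytest.mark.parametrize("n", [50, 127, 370])
    def test_matches_brute_force_oracle_exactly(self, m, delay, n):
        rng = np.random.default_rng(10 * n + 2 * m + delay)
        x = rng.standard_normal(n)
        params = SampEnParams(m=m, r_factor=0.2, delay=delay)
        expected = sampen_oracle(x, m, 0.2 * x.std(), T=delay)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                got = sample_entropy(x, params)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == expected

    def test_constant_series_is_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert sample_entropy(np.full(100, 3.0)) == 0.0

    def test_constant_with_explicit_tolerance_is_zero(self):
        # every template matches every other at both dimensions: A = B
        assert sample_entropy(np.full(100, 3.0), r=0.5) == 0.0

    def test_nonnegative_on_random_series(self):
        import warnings

        rng = np.random.default_rng(1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(20):
                v = sample_entropy(rng.standard_normal(80))
                assert math.isnan(v) or v >= 0.0

    def test_undefined_when_no_extended_matches(self):
        # strictly increasing series with huge steps: no template pairs match
        x = np.cumsum(np.arange(1.0, 31.0) ** 2)
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert math.isnan(sample_entropy(x, SampEnParams(m=2), r=1e-9))

    def test_iid_gaussian_approaches_analytic_limit(self):
        # P(|X-Y| <= 0.2 sd) = erf(0.1) for each added template coordinate
        x = np.random.default_rng(123).standard_normal(30_000)
        v = sample_entropy(x, SampEnParams(m=2, r_factor=0.2))
        assert v == pytest.approx(-math.log(math.erf(0.1)), rel=0.03)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.arange(5.0), SampEnParams(m=2, delay=2))

    def test_invalid_params_rejected(self):
        for kwargs in ({"m": 0}, {"r_factor": -0.1}, {"delay": 0}):
            with pytest.raises(ValueError):
                SampEnParams(**kwargs)


class TestCoarseGrain:
    def test_tau_one_is_identity(self):
        x = np.random.default_rng(0).standard_normal(57)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_allclose(
            coarse_grain([1, 2, 3, 4, 5, 6], 2), [1.5, 3.5, 5.5]
        )

    def test_exhaustive_small_cases_match_index_oracle(self):
        rng = np.random.default_rng(1)
        for n in range(1, 13):
            x = rng.standard_normal(n)
            for tau in range(1, min(n, 4) + 1):
                got = coarse_grain(x, tau)
                want = coarse_grain_oracle(x, tau)
                assert len(got) == n // tau
                np.testing.assert_allclose(got, want, atol=1e-14)

    def test_length_530_tau_3(self):
        x = np.random.default_rng(2).standard_normal(530)
        got = coarse_grain(x, 3)
        assert len(got) == 176
        np.testing.assert_allclose(got, coarse_grain_oracle(x, 3), atol=1e-14)

    @given(st.integers(min_value=1, max_value=200), st.integers(min_value=1, max_value=6))
    def test_property_matches_oracle(self, n, tau):
        if n < tau:
            return
        x = np.random.default_rng(n * 7 + tau).standard_normal(n)
        np.testing.assert_allclose(
            coarse_grain(x, tau), coarse_grain_oracle(x, tau), atol=1e-14
        )

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(10.0), 0)


class TestMultiscaleEntropy:
    def test_scale_one_equals_sampen(self):
        x = np.random.default_rng(3).standard_normal(400)
        mse = multiscale_entropy(x, scales=(1,))
        assert mse[1] == sample_entropy(x)

    def test_white_noise_mse_decreases_with_scale(self):
        """Averaging whitens less: over many seeds MSE(tau=1) > tau=2 > tau=3."""
        params = SampEnParams()
        diffs12, diffs23 = [], []
        for s in range(30):
            x = np.random.default_rng(100 + s).standard_normal(900)
            mse = multiscale_entropy(x, params, scales=(1, 2, 3))
            diffs12.append(mse[1] - mse[2])
            diffs23.append(mse[2] - mse[3])
        assert np.mean(np.array(diffs12) > 0) > 0.9
        assert np.mean(np.array(diffs23) > 0) > 0.9

    def test_autocorrelated_process_less_complex_than_white(self):
        from nirsentropy.synthetic import _ar2_process

        vals_white, vals_ar = [], []
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            vals_white.append(sample_entropy(rng.standard_normal(500)))
            vals_ar.append(sample_entropy(_ar2_process(rng, 500)))
        assert np.mean(vals_ar) < np.mean(vals_white)

    def test_period_two_series_coarse_grains_to_constant(self):
        # tolerance anchored to the (non-constant) original SD; the
        # coarse-grained series is constant so all templates match: 0
        x = np.tile([1.0, 3.0], 100)
        mse = multiscale_entropy(x, scales=(2,))
        assert mse[2] == 0.0

    def test_tolerance_fixed_from_original_series(self):
        x = np.random.default_rng(4).standard_normal(600)
        mse = multiscale_entropy(x, scales=(2,))
        direct = sample_entropy(coarse_grain(x, 2), r=0.2 * x.std())
        assert mse[2] == direct


class TestHomogenize:
    @staticmethod
    def _windows(cdt_len, dst_len):
        return PhaseWindows.from_durations(
            [("rest1", 60), ("CDT", cdt_len / 10), ("rest2", 60),
             ("DST", dst_len / 10), ("rest3", 60), ("CBTT", 53)],
            10.0,
        )

    def test_truncates_to_cohort_minimum(self):
        wins = {
            "a": self._windows(370, 400),
            "b": self._windows(400, 380),
            "c": self._windows(412, 395),
        }
        out = homogenize_phase_lengths(wins)
        assert all(w.length("CDT") == 370 for w in out.values())
        assert all(w.length("DST") == 380 for w in out.values())

    def test_equal_lengths_unchanged(self):
        wins = {"a": self._windows(370, 380), "b": self._windows(370, 380)}
        out = homogenize_phase_lengths(wins)
        for sid in wins:
            assert out[sid].windows == wins[sid].windows

    def test_truncation_keeps_start(self):
        wins = {"a": self._windows(370, 380), "b": self._windows(400, 380)}
        out = homogenize_phase_lengths(wins)
        assert out["b"].get("CDT")[0] == wins["b"].get("CDT")[0]

    def test_missing_phase_rejected(self):
        short = PhaseWindows.from_durations([("rest1", 60), ("CDT", 40)], 10.0)
        with pytest.raises(ValueError, match="missing"):
            homogenize_phase_lengths({"a": self._windows(370, 380), "b": short})


class TestComplexityTable:
    def test_shape_and_metadata(self, small_hb, small_config):
        table = compute_complexity_table(small_hb, "CDT")
        n_subjects = 2 * small_config.n_per_group
        assert table.values.shape == (n_subjects, small_config.n_channels)
        assert table.phase == "CDT"
        assert table.metric == "sampen"
        assert (table.groups == 1).sum() == small_config.n_per_group

    def test_mse_tagging(self, small_hb):
        table = compute_complexity_table(small_hb, "CBTT", metric="mse", tau=3)
        assert (table.metric, table.tau) == ("mse", 3)
        assert table.truncated_length >= 300

    def test_identical_subjects_zero_between_group_variance(self, small_hb):
        import dataclasses

        template = small_hb[0]
        clones = []
        for i, hb in enumerate(small_hb):
            clones.append(
                dataclasses.replace(
                    template,
                    subject_id=hb.subject_id,
                    group_label=hb.group_label,
                )
            )
        table = compute_complexity_table(clones, "CDT")
        assert np.allclose(table.values.var(axis=0), 0.0)

    def test_requires_cbsi(self, small_cohort):
        from nirsentropy import PreprocessParams, preprocess_cohort

        recordings, _ = small_cohort
        hb = preprocess_cohort(recordings[:4], PreprocessParams(apply_cbsi=False))
        with pytest.raises(ValueError, match="CBSI"):
            compute_complexity_table(hb, "CDT")

    def test_tidy_round_trip_columns(self, small_hb):
        tidy = compute_complexity_table(small_hb, "DST").to_tidy()
        assert list(tidy.columns) == [
            "subject_id", "group", "channel", "value", "phase", "metric",
            "tau", "n_samples",
        ]
        assert len(tidy) == small_hb[0].n_channels * len(small_hb)
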