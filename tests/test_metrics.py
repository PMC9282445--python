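"""Classic variability metrics: arithmetic, missing-day policy, behavior."""
import math

import numpy as np
import pytest

from affectvar import (
    ENTROPY_UNDEFINED,
    GenerativeParams,
    ar1_fit,
    entropy,
    rmssd,
    simulate_subject,
    summary_moments,
    tkeo_mean,
    variability_table,
)
from affectvar.exceptions import DegenerateRegressorError, InsufficientDataError
from affectvar.metrics import _sampen
from conftest import make_series

B5 = (0.0, 5.0)


class TestSummaryMoments:
    def test_basic_arithmetic(self):
        assert summary_moments(make_series([1, 2, 3], bounds=B5)) == (2.0, 1.0)

    def test_constant(self):
        mean, sd = summary_moments(make_series([0.5] * 5))
        assert (mean, sd) == (0.5, 0.0)

    def test_missing_skipped(self):
        mean, _ = summary_moments(make_series([0.2, np.nan, 0.8]))
        assert mean == pytest.approx(0.5)

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            summary_moments(make_series([0.5, np.nan, np.nan]))


class TestRmssd:
    def test_basic(self):
        assert rmssd(make_series([1, 2, 3], bounds=B5)) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        assert rmssd(make_series([0.4] * 10)) == 0.0

    def test_gap_pairs_excluded(self):
        # days 1 and 3 observed, day 2 missing: no consecutive pair exists
        with pytest.raises(InsufficientDataError):
            rmssd(make_series([0.0, 1.0], days=[1, 3]))

    def test_shift_invariant(self):
        a = make_series([1, 2, 1, 3, 2], bounds=(0, 10))
        b = make_series([3, 4, 3, 5, 4], bounds=(0, 10))
        assert rmssd(a) == pytest.approx(rmssd(b))


class TestTkeo:
    def test_basic(self):
        # Psi_2 = 2^2 - 1*3 = 1
        assert tkeo_mean(make_series([1, 2, 3], bounds=B5)) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        assert tkeo_mean(make_series([0.7] * 10)) == pytest.approx(0.0)

    def test_sinusoid_closed_form(self):
        # for y = c + A sin(w t), mean Psi -> A^2 sin^2(w) on long series
        w, amp = 0.7, 0.4
        t = np.arange(1, 5001)
        y = 0.5 + amp * np.sin(w * t)
        assert tkeo_mean(make_series(y)) == pytest.approx(amp**2 * math.sin(w) ** 2, rel=0.01)

    def test_gap_triples_excluded(self):
        with pytest.raises(InsufficientDataError):
            tkeo_mean(make_series([0.1, 0.2, 0.3, 0.4], days=[1, 2, 4, 5]))


class TestEntropy:
    def test_constant_is_zero(self):
        assert entropy(make_series([0.3] * 30)) == 0.0

    def test_sorting_reduces_entropy(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=500)
        e_raw = entropy(make_series(x))
        e_sorted = entropy(make_series(np.sort(x)))
        assert e_sorted < e_raw

    def test_periodic_series_is_regular(self):
        # alternating 0/1 over 100 days: template counts are combinatorial.
        # B (m=2): 50 of (0,1) and 49 of (1,0); A (m=3): 49 of each pattern.
        x = np.tile([0.0, 1.0], 50)
        b = math.comb(50, 2) + math.comb(49, 2)
        a = 2 * math.comb(49, 2)
        expected = -math.log(a / b)
        got = entropy(make_series(x), m=2)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got < 0.05  # near-zero: the series is almost perfectly regular

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=200)
        m, r = 2, 0.2 * x.std()

        def brute(mm):
            count = 0
            for i in range(len(x) - mm + 1):
                for j in range(i + 1, len(x) - mm + 1):
                    if max(abs(x[i + q] - x[j + q]) for q in range(mm)) <= r:
                        count += 1
            return count

        expected = -math.log(brute(m + 1) / brute(m))
        assert _sampen(x, m, r) == pytest.approx(expected, abs=1e-12)

    def test_no_matches_returns_sentinel(self):
        x = np.array([0.0, 0.9, 0.1, 1.0, 0.2, 0.5, 0.35, 0.65])
        assert _sampen(x, 2, 1e-6) == ENTROPY_UNDEFINED

    def test_uses_longest_consecutive_run(self):
        days = np.concatenate([np.arange(1, 4), np.arange(10, 40)])
        vals = np.concatenate([[0.5, 0.5, 0.5], np.random.default_rng(5).uniform(size=30)])
        # must not raise: the 30-day run is long enough even though the series is gappy
        entropy(make_series(vals, days=days))


class TestAr1:
    def test_exact_decay(self):
        y = 1.0 * 0.9 ** np.arange(20)
        slope, resid = ar1_fit(make_series(y, bounds=(0, 2)))
        assert slope == pytest.approx(0.9, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_linear_ramp(self):
        slope, resid = ar1_fit(make_series([1, 2, 3, 4], bounds=B5))
        assert slope == pytest.approx(1.0)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_slope_near_zero(self):
        rng = np.random.default_rng(6)
        slope, _ = ar1_fit(make_series(rng.uniform(size=2000)))
        assert abs(slope) < 0.1

    def test_degenerate_regressor(self):
        with pytest.raises(DegenerateRegressorError):
            ar1_fit(make_series([0.5, 0.5, 0.5, 0.9]))


class TestBehavior:
    def test_metrics_blind_to_labels(self):
        vals = np.random.default_rng(7).uniform(size=30)
        a = make_series(vals)
        b = make_series(vals, valence="negative")
        b.participant_id = "someone-else"
        assert rmssd(a) == rmssd(b)
        assert tkeo_mean(a) == tkeo_mean(b)

    def test_classic_metrics_rise_under_either_cause(self):
        """Both volatility and noise inflate SD/RMSSD/TKEO.

        This is the lack of diagnostic specificity that motivates the
        filter: the classic metrics respond to variability per se, not to
        its cause.
        """
        base = GenerativeParams(mu0=0.5, vmu0=0.005, sd0=0.02, n_steps=100)
        volatile = GenerativeParams(mu0=0.5, vmu0=0.05, sd0=0.02, n_steps=100)
        noisy = GenerativeParams(mu0=0.5, vmu0=0.005, sd0=0.12, n_steps=100)
        for raised in (volatile, noisy):
            wins = {"sd": 0, "rmssd": 0, "tkeo": 0}
            for seed in range(20):
                _, s_base = simulate_subject(base, 100 + seed)
                _, s_hi = simulate_subject(raised, 200 + seed)
                wins["sd"] += s_hi.observed_values.std() > s_base.observed_values.std()
                wins["rmssd"] += rmssd(s_hi) > rmssd(s_base)
                wins["tkeo"] += tkeo_mean(s_hi) > tkeo_mean(s_base)
            for metric, w in wins.items():
                assert w >= 16, f"{metric} did not rise under {raised}"

    def test_variability_table_shape(self):
        rng = np.random.default_rng(8)
        series = [
            make_series(rng.uniform(size=30), valence=v) for v in ("positive", "negative")
        ]
        table = variability_table(series)
        assert len(table) == 2
        assert {"mean", "sd", "rmssd", "entropy", "tkeo", "ar1_slope"} <= set(table.columns)
        assert table["rmssd"].notna().all()
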