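"""Fisher's g test: periodogram, statistic, exact p, q-values, PsP calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclesig.periodicity import (
    call_psps,
    fisher_g,
    fisher_g_pvalue,
    periodogram,
    storey_qvalues,
)


def brute_force_periodogram(x):
    """Direct DFT-sum oracle for the periodogram."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    m = (n - 1) // 2
    out = np.empty(m)
    t = np.arange(n)
    for k in range(1, m + 1):
        s = np.sum(xc * np.exp(-2j * np.pi * k * t / n))
        out[k - 1] = abs(s) ** 2 / n
    return out


class TestPeriodogram:
    def test_single_tone_concentrates_power(self):
        t = np.arange(64)
        x = np.cos(2 * np.pi * 4 * t / 64)
        pg = periodogram(x)
        assert pg.m == 31
        assert pg.power[3] == pytest.approx(16.0)
        others = np.delete(pg.power, 3)
        assert np.all(others < 1e-20)

    def test_constant_series_degenerate(self):
        pg = periodogram(np.full(64, 7.0))
        assert pg.degenerate
        with pytest.raises(ValueError):
            fisher_g(pg)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(1)
        for n in (15, 16, 64):
            x = rng.standard_normal(n)
            np.testing.assert_allclose(
                periodogram(x).power, brute_force_periodogram(x), atol=1e-10
            )

    def test_nonfinite_rejected(self):
        x = np.ones(64)
        x[3] = np.nan
        with pytest.raises(ValueError):
            periodogram(x)


class TestFisherG:
    def test_single_tone_g_is_one(self):
        t = np.arange(64)
        g, k = fisher_g(periodogram(np.cos(2 * np.pi * 4 * t / 64)))
        assert g == pytest.approx(1.0)
        assert k == 4

    def test_equal_tones_tie_toward_smaller_index(self):
        t = np.arange(64)
        x = np.cos(2 * np.pi * 4 * t / 64) + np.cos(2 * np.pi * 8 * t / 64)
        g, k = fisher_g(periodogram(x))
        assert g == pytest.approx(0.5)
        assert k in (4, 8)  # float rounding may perturb the exact tie
        # exact tie: constructed periodogram with equal maximal ordinates
        from cyclesig.periodicity import Periodogram

        pg = Periodogram(n=64, power=np.array([0.0, 1.0, 0.5, 1.0]))
        g, k = fisher_g(pg)
        assert g == pytest.approx(0.4)
        assert k == 2

    def test_white_noise_mean_g_matches_harmonic_number(self):
        # E[g] for m iid exponential ordinates is H_m / m
        m = 31
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20000, 64))
        g_vals = []
        for x in X:
            g, _ = fisher_g(periodogram(x))
            g_vals.append(g)
        h_m = np.sum(1.0 / np.arange(1, m + 1))
        expected = h_m / m
        se = np.std(g_vals) / np.sqrt(len(g_vals))
        assert abs(np.mean(g_vals) - expected) < 4 * se


class TestFisherGPvalue:
    def test_forced_p_one(self):
        assert fisher_g_pvalue(1.0, 1) == pytest.approx(1.0)

    def test_single_term_hand_value(self):
        # only j=1 contributes: C(7,1) * (1 - 0.9)^6 = 7e-6
        assert fisher_g_pvalue(0.9, 7) == pytest.approx(7e-6, rel=1e-9)

    def test_p_at_minimum_g_is_one(self):
        m = 31
        assert fisher_g_pvalue(1.0 / m + 1e-12, m) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decreasing_in_g(self):
        m = 31
        gs = np.linspace(0.05, 0.99, 40)
        ps = [fisher_g_pvalue(g, m) for g in gs]
        assert np.all(np.diff(ps) <= 1e-12)

    @pytest.mark.parametrize("m,n", [(7, 16), (15, 32), (31, 64)])
    def test_agrees_with_monte_carlo_null(self, m, n):
        rng = np.random.default_rng(m)
        draws = 40000
        X = rng.standard_normal((draws, n))
        Xc = X - X.mean(axis=1, keepdims=True)
        P = np.abs(np.fft.rfft(Xc, axis=1)) ** 2 / n
        I = P[:, 1 : m + 1]
        g = I.max(axis=1) / I.sum(axis=1)
        for target in (0.5, 0.9):
            gq = np.quantile(g, target)
            p_mc = (g > gq).mean()
            se = np.sqrt(p_mc * (1 - p_mc) / draws)
            assert abs(fisher_g_pvalue(gq, m) - p_mc) < 3 * se


class TestStoreyQvalues:
    def test_bh_equivalence_when_pi0_forced_to_one(self):
        # fewer than 100 p-values -> pi0 = 1 fallback, i.e. plain BH
        p = np.array([0.01, 0.02, 0.03, 0.04])
        with pytest.warns(UserWarning):
            q = storey_qvalues(p)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_uniform_pvalues_give_pi0_near_one(self):
        from cyclesig.periodicity import estimate_pi0

        rng = np.random.default_rng(3)
        p = rng.uniform(size=10000)
        assert 0.9 <= estimate_pi0(p) <= 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50)
    )
    def test_q_monotone_in_p(self, pvals):
        p = np.array(pvals)
        with pytest.warns(UserWarning):
            q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))


class TestCallPsps:
    @staticmethod
    def _results(q1, q2, f1, f2):
        return pd.DataFrame(
            [
                {"protein_id": "X", "techrep": 1, "testable": True,
                 "g": 0.5, "k_max": 4, "freq": f1, "p": q1 / 2, "q": q1},
                {"protein_id": "X", "techrep": 2, "testable": True,
                 "g": 0.5, "k_max": 4, "freq": f2, "p": q2 / 2, "q": q2},
            ]
        )

    def test_both_repeats_pass(self):
        calls = call_psps(self._results(0.05, 0.08, 1 / 16, 1 / 16))
        assert calls.loc["X", "is_psp"]

    def test_one_repeat_fails_q(self):
        calls = call_psps(self._results(0.05, 0.20, 1 / 16, 1 / 16))
        assert not calls.loc["X", "is_psp"]

    def test_disallowed_frequency_fails(self):
        calls = call_psps(self._results(0.01, 0.01, 3 / 16, 3 / 16))
        assert not calls.loc["X", "is_psp"]

    def test_second_harmonic_allowed(self):
        calls = call_psps(self._results(0.01, 0.01, 1 / 8, 1 / 8))
        assert calls.loc["X", "is_psp"]

    def test_untestable_never_psp(self):
        res = self._results(0.01, 0.01, 1 / 16, 1 / 16)
        res.loc[1, "testable"] = False
        res.loc[1, ["g", "freq", "p", "q"]] = np.nan
        calls = call_psps(res)
        assert not calls.loc["X", "is_psp"]
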