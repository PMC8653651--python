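"""Wavelength selection: MW-PLS, MC-UVE and interval random frog."""

import numpy as np
import pytest

from ftirquant import (
    IRFConfig,
    MCUVEConfig,
    cross_validate,
    interval_random_frog,
    mc_uve,
    mw_pls,
    select_intervals_by_probability,
    uve_cutoff,
)
from ftirquant.selection import IntervalProbabilities, _stability_from_runs, enumerate_intervals


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(777)
    n, p = 40, 24
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[8:13] = [1.0, 2.0, 1.5, -1.0, 0.5]  # informative block
    y = X @ beta + rng.normal(size=n) * 0.1
    return X, y


class TestMWPLS:
    def test_single_full_width_window_equals_full_spectrum(self, small_problem):
        X, y = small_problem
        res = mw_pls(X, y, widths=[X.shape[1]], scheme=5, max_nlvs=5, seed=1)
        full = cross_validate(X, y, 5, 5, seed=1)
        assert res.best_window == (0, X.shape[1])
        assert res.best_rmsecv == pytest.approx(full.rmsecv)

    def test_matches_brute_force_window_loop(self, small_problem):
        """Independent oracle: hand-sliced matrices through cross_validate."""
        X, y = small_problem
        res = mw_pls(X, y, widths=[5], scheme=4, max_nlvs=3, seed=2)
        for start, reported in zip(res.starts, res.rmsecv_per_window):
            cv = cross_validate(X[:, start : start + 5], y, 3, 4, seed=2)
            assert reported == pytest.approx(cv.rmsecv, abs=1e-12)

    def test_finds_planted_block(self, small_problem):
        X, y = small_problem
        res = mw_pls(X, y, widths=[5, 7], scheme=5, max_nlvs=4, seed=3)
        lo, hi = res.best_window
        assert lo < 13 and hi > 8  # overlaps the informative block [8, 13)

    def test_infeasible_width_rejected(self, small_problem):
        X, y = small_problem
        with pytest.raises(ValueError):
            mw_pls(X, y, widths=[X.shape[1] + 1])
        with pytest.raises(ValueError):
            mw_pls(X, y, widths=[1])


class TestMCUVE:
    def test_degenerate_identical_runs_all_flagged(self):
        """If every Monte-Carlo run returns the same b, every std is zero
        and every stability is a signed infinite sentinel, flagged."""
        B = np.tile(np.array([1.0, -2.0, 0.5]), (6, 1))
        s, flagged = _stability_from_runs(B)
        assert flagged.all()
        np.testing.assert_array_equal(np.sign(s), [1.0, -1.0, 1.0])
        assert np.all(np.isinf(s))

    def test_stability_scale_invariant(self, rng):
        B = rng.normal(size=(20, 10))
        s1, _ = _stability_from_runs(B)
        s2, _ = _stability_from_runs(3.7 * B)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_reproducible_under_seed(self, small_problem):
        X, y = small_problem
        cfg = MCUVEConfig(M=30, nlvs=4, seed=42)
        a, b = mc_uve(X, y, cfg), mc_uve(X, y, cfg)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.selected, b.selected)
        assert a.cutoff == b.cutoff

    def test_informative_variables_more_stable(self, small_problem):
        X, y = small_problem
        prof = mc_uve(X, y, MCUVEConfig(M=100, nlvs=5, seed=7))
        abs_s = np.abs(prof.s)
        informative = np.zeros(X.shape[1], dtype=bool)
        informative[8:13] = True
        assert abs_s[informative].mean() > abs_s[~informative].mean()
        assert prof.selected.size < X.shape[1]

    def test_noise_augmented_cutoff_kills_all_noise_data(self):
        """On pure-noise X with a noise y, the augmented-null cutoff should
        remove essentially every real variable."""
        fractions = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 30))
            y = rng.normal(size=40)
            prof = mc_uve(X, y, MCUVEConfig(M=60, nlvs=3, seed=seed))
            fractions.append(prof.selected.size / X.shape[1])
        assert np.mean(fractions) < 0.05

    def test_quantile_scan_never_worse_than_no_cutoff(self, small_problem):
        X, y = small_problem
        cfg = MCUVEConfig(M=60, nlvs=4, cutoff_rule="quantile_scan", seed=5)
        prof = mc_uve(X, y, cfg)
        baseline = cross_validate(X, y, 4, 5, seed=5).rmsecv
        selected_cv = cross_validate(X[:, prof.selected], y, min(4, prof.selected.size), 5, seed=5)
        assert selected_cv.rmsecv <= baseline + 1e-9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCUVEConfig(M=1)
        with pytest.raises(ValueError):
            MCUVEConfig(sampling_fraction=1.0)
        with pytest.raises(ValueError):
            MCUVEConfig(cutoff_rule="magic")


class TestIntervalEnumeration:
    def test_one_interval_per_point_with_truncated_edges(self):
        intervals, truncated = enumerate_intervals(100, 20)
        assert len(intervals) == 100
        widths = np.array([hi - lo for lo, hi in intervals])
        assert widths.max() == 20
        assert truncated.sum() == np.sum(widths < 20) > 0
        assert not truncated[50]

    def test_width_exceeding_axis_rejected(self):
        with pytest.raises(ValueError):
            enumerate_intervals(10, 20)


class TestIRF:
    def test_probability_is_exact_integer_ratio(self, small_problem):
        X, y = small_problem
        cfg = IRFConfig(interval_width=4, N=40, Q0=3, seed=11)
        ip = interval_random_frog(X, y, cfg)
        assert np.all((ip.probability >= 0) & (ip.probability <= 1))
        np.testing.assert_array_equal(ip.probability * cfg.N, ip.n_j)
        assert ip.n_j.dtype.kind == "i"

    def test_reproducible_under_seed(self, small_problem):
        X, y = small_problem
        cfg = IRFConfig(interval_width=4, N=40, Q0=3, seed=13)
        a, b = interval_random_frog(X, y, cfg), interval_random_frog(X, y, cfg)
        np.testing.assert_array_equal(a.n_j, b.n_j)

    def test_informative_intervals_more_probable(self, small_problem):
        X, y = small_problem
        cfg = IRFConfig(interval_width=4, N=150, Q0=3, seed=17)
        ip = interval_random_frog(X, y, cfg)
        informative = np.zeros(len(ip.intervals), dtype=bool)
        for j, (lo, hi) in enumerate(ip.intervals):
            if lo < 13 and hi > 8:
                informative[j] = True
        prob = ip.probability
        assert prob[informative].mean() > prob[~informative].mean()

    def test_selection_from_probabilities(self, small_problem):
        X, y = small_problem
        intervals, _ = enumerate_intervals(X.shape[1], 4)
        n_j = np.zeros(len(intervals), dtype=np.int64)
        n_j[10] = 50  # interval centered on the informative block
        ip = IntervalProbabilities(intervals, n_j, 50, np.zeros(len(intervals), dtype=bool))
        chosen = select_intervals_by_probability(ip, X, y, scheme=5, max_nlvs=3)
        np.testing.assert_array_equal(chosen, np.arange(*intervals[10]))

    def test_all_zero_probabilities_rejected(self, small_problem):
        X, y = small_problem
        intervals, _ = enumerate_intervals(X.shape[1], 4)
        ip = IntervalProbabilities(
            intervals, np.zeros(len(intervals), dtype=np.int64), 10,
            np.zeros(len(intervals), dtype=bool),
        )
        with pytest.raises(ValueError, match="increase"):
            select_intervals_by_probability(ip, X, y)

    def test_best_window_achieves_scan_minimum(self, small_problem):
        X, y = small_problem
        res = mw_pls(X, y, widths=[5], scheme=5, max_nlvs=3, seed=2)
        assert res.rmsecv_per_window.min() == res.best_rmsecv


class TestPlantedSpectralData:
    """Qualitative study-mirroring behavior on the planted-band dataset."""

    def test_all_methods_beat_full_spectrum_and_select_fewer_variables(
        self, planted_calibration
    ):
        X, y, inside = planted_calibration
        p = X.shape[1]
        full = cross_validate(X, y, 10, 5, seed=0)

        mw = mw_pls(X, y, widths=[40], scheme=5, max_nlvs=10, stride=4, seed=1)
        uve = mc_uve(X, y, MCUVEConfig(M=100, nlvs=full.chosen_nlvs, seed=2))
        irf_ip = interval_random_frog(X, y, IRFConfig(N=200, seed=3))
        irf_vars = select_intervals_by_probability(irf_ip, X, y, scheme=5, max_nlvs=10, seed=3)

        for vars_ in (mw.selected_variables, uve.selected, irf_vars):
            assert 0 < vars_.size < p
            cv = cross_validate(X[:, vars_], y, min(10, vars_.size), 5, seed=0)
            assert cv.rmsecv <= full.rmsecv + 1e-9

    def test_stability_and_probability_concentrate_in_planted_window(
        self, planted_calibration
    ):
        X, y, inside = planted_calibration
        uve = mc_uve(X, y, MCUVEConfig(M=100, nlvs=2, seed=5))
        abs_s = np.abs(uve.s)
        finite = np.isfinite(abs_s)
        assert abs_s[inside & finite].mean() > abs_s[~inside & finite].mean()

        ip = interval_random_frog(X, y, IRFConfig(N=200, seed=6))
        prob = ip.probability
        assert prob[inside].mean() > prob[~inside].mean()
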