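import numpy as np
import pytest

from oracles import higuchi_fd_naive
from resteeg.hfd import (PlateauNotFoundError, hfd_sweep, hfd_table,
                         higuchi_fd, select_kmax)
from resteeg.io import Recording


class TestHiguchiEstimator:
    def test_linear_ramp_has_dimension_one(self):
        """For x_i = c*i, L(k) is proportional to 1/k, so the log-log slope
        is exactly -1."""
        fd = higuchi_fd(3.7 * np.arange(1000), kmax=20).fd
        assert fd == pytest.approx(1.0, abs=0.01)

    def test_white_noise_near_two(self):
        fds = [higuchi_fd(np.random.default_rng(s).standard_normal(4096),
                          82).fd for s in range(20)]
        assert np.mean(fds) == pytest.approx(2.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 1200))
        kmax = int(rng.integers(2, min(25, n // 3)))
        x = np.cumsum(rng.standard_normal(n))
        assert higuchi_fd(x, kmax).fd == pytest.approx(
            higuchi_fd_naive(x, kmax), abs=1e-10)

    def test_fit_quality_reported(self):
        est = higuchi_fd(np.random.default_rng(0).standard_normal(2000), 30)
        assert 0.9 < est.fit_r2 <= 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="undefined|degenerate"):
            higuchi_fd(np.ones(1000), 10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            higuchi_fd(np.arange(50), 20)

    def test_kmax_lower_bound(self):
        with pytest.raises(ValueError, match="kmax"):
            higuchi_fd(np.arange(100), 1)


def _geometric_curve(pcts, start=1.0):
    """Curve whose consecutive percentage changes equal ``pcts``."""
    vals = [start]
    for p in pcts:
        vals.append(vals[-1] * (1 + p / 100.0))
    return np.array(vals)


class TestSelectKmax:
    def test_transient_dip_is_not_the_plateau(self):
        """pct sequence {0.2, 0.04, 0.2, 0.03, 0.02, 0.01} on k=3..8: the
        dip at k=4 is transient; the persistent plateau starts at k=6."""
        g = _geometric_curve([0.2, 0.04, 0.2, 0.03, 0.02, 0.01])
        k_grid = np.arange(2, 9)
        sel = select_kmax({"N": g, "A+P+": g.copy()}, k_grid, search_hi=8)
        assert sel.first_minimum_k == 4
        assert sel.plateau_start_k == 6
        # identical groups: D == 0 everywhere, tie-break to plateau start
        assert all(v == 0.0 for v in sel.distance_sum.values())
        assert sel.selected_kmax == 6

    def test_distance_argmax_selects_kmax(self):
        """Three curves sharing a grand mean; pairwise separation is largest
        at k=9 inside the plateau, so k_max = 9."""
        k_grid = np.arange(2, 13)
        base = _geometric_curve([0.1, 0.1] + [0.01] * 8, start=1.8)
        d = np.zeros(len(k_grid))
        d[k_grid >= 5] = 0.002
        d[k_grid == 9] = 0.01
        curves = {"N": base + d, "A+P-": base - d, "A+P+": base.copy()}
        sel = select_kmax(curves, k_grid, search_hi=12)
        assert sel.plateau_start_k == 5
        # D(k) = |2d| + |d| + |d| = 4 d(k), maximal at the k=9 bump
        assert sel.distance_sum[9] == pytest.approx(0.04)
        assert sel.selected_kmax == 9

    def test_no_plateau_raises(self):
        g = _geometric_curve([0.2] * 10)
        with pytest.raises(PlateauNotFoundError):
            select_kmax({"N": g, "A+P+": g * 1.01}, np.arange(2, 13),
                        search_hi=12)

    def test_invariant_to_uniform_rescaling(self):
        k_grid = np.arange(2, 13)
        base = _geometric_curve([0.1, 0.1] + [0.01] * 8, start=1.8)
        d = np.zeros(len(k_grid))
        d[k_grid >= 6] = 0.001
        d[k_grid == 8] = 0.008
        curves = {"N": base + d, "A+P+": base - d}
        sel1 = select_kmax(curves, k_grid, search_hi=12)
        sel2 = select_kmax({g: 3.0 * c for g, c in curves.items()}, k_grid,
                           search_hi=12)
        assert sel1.selected_kmax == sel2.selected_kmax == 8
        assert sel1.plateau_start_k == sel2.plateau_start_k

    def test_needs_two_groups_and_full_grid(self):
        g = _geometric_curve([0.01] * 10)
        with pytest.raises(ValueError, match="two group"):
            select_kmax({"N": g}, np.arange(2, 13), search_hi=12)
        with pytest.raises(ValueError, match="search_hi"):
            select_kmax({"N": g, "A+P+": g}, np.arange(2, 13), search_hi=50)


class TestSweep:
    @staticmethod
    def _rec(rng, sid="s1", group="N", n_ch=2, identical=False):
        n = 250 * 30
        if identical:
            x = rng.standard_normal(n)
            data = np.vstack([x] * n_ch)
        else:
            data = rng.standard_normal((n_ch, n))
        return Recording(sid, 250.0, [f"c{i}" for i in range(n_ch)], data,
                         group)

    def test_identical_channels_identical_scopes(self, rng):
        rec = self._rec(rng, identical=True)
        table = hfd_table([rec], clusters=None, kmax=30, epoch_len_s=None)
        assert table["fd"].nunique() == 1

    def test_identical_groups_zero_distance(self, rng):
        x = rng.standard_normal((2, 250 * 30))
        recs = [Recording("s1", 250.0, ["c0", "c1"], x.copy(), "N"),
                Recording("s2", 250.0, ["c0", "c1"], x.copy(), "A+P+")]
        curves, k_grid, _ = hfd_sweep(recs, k_hi=40, epoch_len_s=None)
        np.testing.assert_array_equal(curves["N"], curves["A+P+"])
        sel = select_kmax(curves, k_grid, search_hi=40)
        assert sel.selected_kmax == sel.plateau_start_k

    def test_risk_group_curve_below_control(self):
        """Steeper aperiodic slope in double-risk carriers lowers the whole
        HFD-vs-k curve at coarse scales."""
        from resteeg.synth import ad_like_groups, gen_resting_eeg

        recs, _ = gen_resting_eeg(ad_like_groups(4, seed=2), 4, 250, 60)
        curves, k_grid, _ = hfd_sweep(recs, k_hi=60, epoch_len_s=None)
        sel = k_grid >= 20
        assert np.all(curves["A+P+"][sel] < curves["N"][sel])

    def test_epoch_averaging_close_to_whole_series(self, rng):
        rec = self._rec(rng)
        t_epoch = hfd_table([rec], kmax=40, epoch_len_s=4.0)
        t_whole = hfd_table([rec], kmax=40, epoch_len_s=None)
        g_e = t_epoch[t_epoch["scope"] == "global"]["fd"].iloc[0]
        g_w = t_whole[t_whole["scope"] == "global"]["fd"].iloc[0]
        assert g_e == pytest.approx(g_w, abs=0.05)
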