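"""Edge-corrected pair cross-correlation, variances, PMF and density."""

import numpy as np
import pandas as pd
import pytest

import ssxcorr as sx
from ssxcorr.paircorr import PairHistogram
from conftest import make_uniform_table, square_roi


def _table(rows, frame_interval=1.0):
    return sx.LocalizationTable(
        pd.DataFrame(rows, columns=["x", "y", "frame", "channel"]),
        frame_interval=frame_interval,
    )


def _square_W_oracle(r, L, n_theta=20000):
    """Angle-averaged set covariance of an LxL square at radius r (exact
    factorized form (1-|dx|/L)(1-|dy|/L))."""
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    dx, dy = np.abs(r * np.cos(th)), np.abs(r * np.sin(th))
    vals = np.where((dx < L) & (dy < L), (1 - dx / L) * (1 - dy / L), 0.0)
    return vals.mean()


class TestEdgeFactor:
    def test_square_matches_closed_form(self):
        L = 10_000.0
        roi = square_roi(L, pixel_size=100.0)
        b = sx.RadialBinning.from_max(50.0, 6000.0)
        W = sx.edge_factor(roi, b).W
        # oracle: area-weighted average of the closed form over each annulus
        for i in range(0, len(b), 6):
            lo, hi = b.edges[i], b.edges[i + 1]
            rs = np.sqrt(np.linspace(lo**2, hi**2, 30))
            want = np.mean([_square_W_oracle(r, L) for r in rs])
            assert abs(W[i] - want) < 0.01

    def test_near_zero_lag_is_one(self):
        roi = square_roi(5000.0, pixel_size=50.0)
        b = sx.RadialBinning.from_max(10.0, 500.0)
        W = sx.edge_factor(roi, b).W
        assert W[0] == pytest.approx(1.0, abs=0.01)
        assert np.all(np.diff(W) <= 1e-9)

    def test_vanishes_beyond_roi_diameter(self):
        L = 2000.0
        roi = square_roi(L, pixel_size=50.0)
        b = sx.RadialBinning.from_max(100.0, 4000.0)
        W = sx.edge_factor(roi, b).W
        assert np.all(W[b.centers > L * np.sqrt(2)] < 1e-9)

    def test_bins_beyond_padded_support_rejected(self):
        roi = square_roi(1000.0, pixel_size=50.0)
        b = sx.RadialBinning.from_max(100.0, 50_000.0)
        with pytest.raises(ValueError, match="beyond the padded"):
            sx.edge_factor(roi, b)


class TestPairHistogram:
    def test_total_pairs_sum_over_frames(self):
        rows = (
            [(i * 10.0, 0.0, 0, 1) for i in range(2)]
            + [(i * 10.0, 50.0, 1, 1) for i in range(3)]
            + [(i * 10.0, 100.0, 0, 2) for i in range(4)]
            + [(i * 10.0, 150.0, 1, 2) for i in range(1)]
        )
        roi = square_roi(1000.0, pixel_size=50.0)
        b = sx.RadialBinning.from_max(100.0, 900.0)
        h = sx.pair_histogram(_table(rows), roi, b, tau=0)
        assert h.N == 2 * 4 + 3 * 1 == 11
        assert h.F == 2

    def test_single_distance_lands_in_half_open_bin(self):
        rows = [(0.0, 0.0, 0, 1), (3.0, 0.0, 0, 2)]
        roi = square_roi(10.0, pixel_size=1.0)
        b = sx.RadialBinning(centers=np.array([0.5, 1.5, 2.5, 3.5]), width=1.0)
        h = sx.pair_histogram(_table(rows), roi, b, tau=0)
        assert h.M.tolist() == [0, 0, 0, 1]  # d=3.0 belongs to [3, 4)
        assert h.N == 1

    def test_all_pairs_counted_when_rmax_exceeds_diagonal(self):
        rng = np.random.default_rng(0)
        box = 1000.0
        rows = [(x, y, 0, 1) for x, y in rng.uniform(0, box, (50, 2))]
        rows += [(x, y, 0, 2) for x, y in rng.uniform(0, box, (40, 2))]
        roi = square_roi(box, pixel_size=25.0)
        b = sx.RadialBinning.from_max(25.0, box * np.sqrt(2) + 25.0)
        h = sx.pair_histogram(_table(rows), roi, b, tau=0)
        assert h.M.sum() == h.N == 2000

    def test_time_averaged_mode_counts_all_cross_pairs(self):
        rng = np.random.default_rng(1)
        t = make_uniform_table(rng, 1000.0, 60, 5)
        roi = square_roi(1000.0, pixel_size=25.0)
        b = sx.RadialBinning.from_max(25.0, 1500.0)
        h = sx.pair_histogram(t, roi, b, tau=sx.TAU_ALL)
        assert h.N == 60 * 60
        assert h.M.sum() == h.N

    def test_lagged_pairs_use_shifted_frames(self):
        rows = [(0.0, 0.0, 0, 1), (100.0, 0.0, 1, 2), (0.0, 0.0, 1, 1)]
        roi = square_roi(500.0, pixel_size=25.0)
        b = sx.RadialBinning.from_max(25.0, 400.0)
        h = sx.pair_histogram(_table(rows), roi, b, tau=1)
        assert h.N == 1  # ch1@0 x ch2@1 only
        assert h.M[b.histogram(np.array([100.0])).argmax()] == 1

    def test_empty_window_rejected(self):
        t = _table([(0.0, 0.0, 0, 1)])
        roi = square_roi(100.0, pixel_size=25.0)
        b = sx.RadialBinning.from_max(25.0, 80.0)
        with pytest.raises(ValueError, match="empty frame window"):
            sx.pair_histogram(t, roi, b, tau=0, window=(3, 3))


def _manual_hist(M, N, binning, area, F=1):
    return PairHistogram(
        M=np.asarray(M, np.int64), N=N, F=F, rho0=N / area,
        binning=binning, tau=0, area=area,
    )


class TestCorrelation:
    def test_direct_normalization_arithmetic(self):
        # one bin at r=1 um, dr=0.1 um, M=63, N=1000, A=100 um^2, W=1
        b = sx.RadialBinning(centers=np.array([1000.0]), width=100.0)
        hist = _manual_hist([63], 1000, b, area=1e8)
        edge = sx.EdgeCurve(W=np.array([1.0]), binning=b)
        c = sx.correlation_from_histogram(hist, edge)
        assert c.C[0] == pytest.approx(10.03, abs=0.01)

    def test_variance_propagation_arithmetic(self):
        # C=2, M=100, N=1e4 -> var = 4*(1/100 + 1/1e4) = 0.0404
        b = sx.RadialBinning(centers=np.array([500.0]), width=100.0)
        mu_target = 50.0  # mu = M / C
        area = 2 * np.pi * 500 * 100 * 10_000 / mu_target
        hist = _manual_hist([100], 10_000, b, area=area)
        edge = sx.EdgeCurve(W=np.array([1.0]), binning=b)
        c = sx.correlation_from_histogram(hist, edge, sparse=False)
        assert c.C[0] == pytest.approx(2.0)
        assert c.var_C[0] == pytest.approx(0.0404)
        assert c.sigma[0] == pytest.approx(0.201, abs=0.001)

    def test_sparse_mode_keeps_empty_bins_finite(self):
        b = sx.RadialBinning(centers=np.array([100.0, 300.0]), width=200.0)
        hist = _manual_hist([0, 10], 100, b, area=1e7)
        edge = sx.EdgeCurve(W=np.array([1.0, 1.0]), binning=b)
        c = sx.correlation_from_histogram(hist, edge, sparse=True)
        assert c.C[0] == 0.0
        assert np.isfinite(c.var_C[0]) and c.var_C[0] > 0

    def test_no_pairs_is_an_error(self):
        b = sx.RadialBinning(centers=np.array([100.0]), width=200.0)
        hist = _manual_hist([0], 0, b, area=1e6)
        edge = sx.EdgeCurve(W=np.array([1.0]), binning=b)
        with pytest.raises(ValueError, match="no pairs"):
            sx.correlation_from_histogram(hist, edge)

    def test_uniform_channels_consistent_with_one(self):
        rng = np.random.default_rng(7)
        box = 10_000.0
        t = make_uniform_table(rng, box, 10_000, 20)
        roi = square_roi(box, pixel_size=100.0)
        b = sx.RadialBinning.from_max(25.0, 1000.0)
        c = sx.cross_correlation(t, roi, b, tau=0)
        z = (c.C[c.defined] - 1.0) / c.sigma[c.defined]
        assert np.mean(np.abs(z) < 3.0) >= 0.99

    def test_colocalized_limit_matches_brute_force(self):
        rng = np.random.default_rng(8)
        box, n = 5000.0, 400
        pts = rng.uniform(50, box - 50, (n, 2))
        rows = [(x, y, 0, 1) for x, y in pts] + [(x, y, 0, 2) for x, y in pts]
        roi = square_roi(box, pixel_size=50.0)
        b = sx.RadialBinning.from_max(25.0, 500.0)
        c = sx.cross_correlation(_table(rows), roi, b, tau=0)
        # brute-force expectation: n zero-distance pairs out of n^2 land in bin 1
        mu1 = b.ring_areas[0] * (n * n / roi.area) * c.W[0]
        expect = n / mu1
        assert expect > 10  # strongly co-localized regime
        assert c.C[0] == pytest.approx(expect, rel=0.15)

    def test_channel_swap_symmetric_at_tau_zero_only(self):
        rng = np.random.default_rng(9)
        box = 4000.0
        t = make_uniform_table(rng, box, 500, 10)
        roi = square_roi(box, pixel_size=50.0)
        b = sx.RadialBinning.from_max(50.0, 800.0)
        a = sx.cross_correlation(t, roi, b, tau=0, channels=(1, 2))
        s = sx.cross_correlation(t, roi, b, tau=0, channels=(2, 1))
        np.testing.assert_array_equal(a.M, s.M)
        assert a.N == s.N
        # with a deterministic drift of channel 1 between frames, tau>0 breaks it
        rows = [(100.0, 100.0, 0, 1), (400.0, 100.0, 1, 1),
                (100.0, 100.0, 0, 2), (100.0, 100.0, 1, 2)]
        td = _table(rows)
        f = sx.pair_histogram(td, roi, b, tau=1, channels=(1, 2))
        r = sx.pair_histogram(td, roi, b, tau=1, channels=(2, 1))
        assert not np.array_equal(f.M, r.M)


class TestScrambledResample:
    def test_single_window_sd_flagged_undefined(self):
        rng = np.random.default_rng(10)
        t = make_uniform_table(rng, 2000.0, 2000, 20)
        roi = square_roi(2000.0, pixel_size=50.0)
        b = sx.RadialBinning.from_max(50.0, 400.0)
        rs = sx.scrambled_resample(t, roi, b, windows=1, window_frames=20, rng=1)
        assert np.all(np.isnan(rs.sd_C))
        assert len(rs.curves) == 1

    def test_insufficient_frames_rejected(self):
        rng = np.random.default_rng(11)
        t = make_uniform_table(rng, 2000.0, 200, 10)
        roi = square_roi(2000.0, pixel_size=50.0)
        b = sx.RadialBinning.from_max(50.0, 400.0)
        with pytest.raises(ValueError, match="frames"):
            sx.scrambled_resample(t, roi, b, windows=3, window_frames=5, rng=1)

    def test_scrambling_preserves_time_averaged_curve(self):
        rng = np.random.default_rng(12)
        t = make_uniform_table(rng, 3000.0, 800, 40)
        roi = square_roi(3000.0, pixel_size=50.0)
        b = sx.RadialBinning.from_max(50.0, 600.0)
        before = sx.cross_correlation(t, roi, b, tau=sx.TAU_ALL)
        perm = np.random.default_rng(13).permutation(40)
        data = t.data.copy()
        data["frame"] = perm[data["frame"].to_numpy()]
        after = sx.cross_correlation(t.with_data(data), roi, b, tau=sx.TAU_ALL)
        np.testing.assert_allclose(after.C, before.C)


class TestTauCombination:
    def _curve(self, C, var, tau=1):
        b = sx.RadialBinning(centers=np.array([100.0]), width=50.0)
        n = 1
        return sx.CorrelationCurve(
            binning=b, tau=tau, C=np.array([C]), var_C=np.array([var]),
            M=np.array([1.0]), N=1.0, W=np.array([1.0]), mu=np.array([1.0]),
            defined=np.array([True]),
        )

    def test_weighted_mean_arithmetic(self):
        avg = sx.average_over_tau([self._curve(1.0, 0.01), self._curve(2.0, 0.04)])
        assert avg.C[0] == pytest.approx(1.2)

    def test_identical_curves_reduce_variance_by_k(self):
        K = 5
        avg = sx.average_over_tau([self._curve(1.7, 0.09, tau=k) for k in range(K)])
        assert avg.C[0] == pytest.approx(1.7)
        assert avg.var_C[0] == pytest.approx(0.09 / K)

    def test_static_coclusters_tau_average_matches_tau_zero(self):
        # immobile co-clustered channels: averaging over 0<tau<=5 should agree
        # with the simultaneous curve within 2 combined s.e.
        rng = np.random.default_rng(14)
        box, n_mol = 8000.0, 120
        centers = rng.uniform(200, box - 200, (n_mol, 2))
        rows = []
        for f in range(30):
            for ch in (1, 2):
                on = rng.random(n_mol) < 0.6
                pts = centers[on] + rng.normal(0, 20.0, (on.sum(), 2))
                rows += [(x, y, f, ch) for x, y in pts]
        t = _table(rows)
        roi = square_roi(box, pixel_size=100.0)
        b = sx.RadialBinning.from_max(50.0, 600.0)
        edge = sx.edge_factor(roi, b)
        c0 = sx.cross_correlation(t, roi, b, tau=0, edge=edge)
        avg = sx.average_over_tau(
            [sx.cross_correlation(t, roi, b, tau=k, edge=edge) for k in range(1, 6)]
        )
        se = np.sqrt(c0.var_C + avg.var_C)
        ok = c0.defined & avg.defined
        assert np.all(np.abs(c0.C[ok] - avg.C[ok]) < 2.5 * se[ok])

    def test_extrapolation_constant_mode_returns_constant(self):
        curves = [self._curve(1.5, 0.01, tau=k) for k in range(6)]
        ext = sx.extrapolate_tau_zero(curves, exclude=(0,), mode="constant")
        assert ext.C[0] == pytest.approx(1.5)

    def test_extrapolation_linear_mode_exact_on_linear_decay(self):
        curves = [self._curve(2.0 - 0.1 * k, 0.01, tau=k) for k in range(8)]
        ext = sx.extrapolate_tau_zero(curves, exclude=(0, 1), mode="linear")
        assert ext.C[0] == pytest.approx(2.0, abs=1e-9)

    def test_too_few_tau_points_rejected(self):
        curves = [self._curve(1.0, 0.01, tau=k) for k in range(3)]
        with pytest.raises(ValueError, match=">= 3"):
            sx.extrapolate_tau_zero(curves, exclude=(0,))


class TestPhysicalConversions:
    def _curve(self, C, var=None, dr=25.0):
        C = np.asarray(C, float)
        b = sx.RadialBinning(centers=dr / 2 + dr * np.arange(len(C)), width=dr)
        var = np.full(len(C), 0.01) if var is None else np.asarray(var, float)
        return sx.CorrelationCurve(
            binning=b, tau=0, C=C, var_C=var, M=C, N=100.0,
            W=np.ones(len(C)), mu=np.ones(len(C)), defined=np.isfinite(C),
        )

    def test_pmf_log_identities(self):
        c = self._curve([1.0, np.e, 1.0 / np.e])
        pot = sx.pmf_from_correlation(c)
        assert pot.pmf[0] == pytest.approx(0.0)
        assert pot.pmf[1] == pytest.approx(-1.0)
        assert pot.pmf[2] == pytest.approx(1.0)

    def test_pmf_zero_bins_flagged_not_infinite(self):
        pot = sx.pmf_from_correlation(self._curve([0.0, 2.0]))
        assert not pot.defined[0] and np.isnan(pot.pmf[0])
        assert pot.defined[1]

    def test_pmf_variance_propagation(self):
        pot = sx.pmf_from_correlation(self._curve([2.0], var=[0.04]))
        assert pot.var_pmf[0] == pytest.approx(0.04 / 4.0)

    def test_uniform_density_has_no_excess(self):
        rho = 5e-6  # 5 per um^2
        d = sx.density_from_correlation(self._curve(np.ones(10)), rho)
        assert np.allclose(d.rho, rho)
        assert np.allclose(d.cumulative_excess, 0.0)

    def test_cumulative_excess_is_prefix_sum(self):
        C = np.array([3.0, 2.0, 1.0, 1.5])
        rho = 1e-5
        d = sx.density_from_correlation(self._curve(C), rho)
        b = d.binning
        manual = np.cumsum((C - 1) * rho * b.ring_areas)
        np.testing.assert_allclose(d.cumulative_excess, manual)

    def test_constructed_partners_counted_within_radius(self):
        # k extra channel-2 partners placed within 100 nm of each channel-1
        # point; the integrated excess at 100 nm should report ~k
        rng = np.random.default_rng(15)
        box, n_red, k = 20_000.0, 300, 3
        red = rng.uniform(500, box - 500, (n_red, 2))
        ang = rng.uniform(0, 2 * np.pi, (n_red, k))
        rad = 100.0 * np.sqrt(rng.uniform(0, 1, (n_red, k)))
        green = np.column_stack(
            [
                (red[:, :1] + rad * np.cos(ang)).ravel(),
                (red[:, 1:] + rad * np.sin(ang)).ravel(),
            ]
        )
        rows = [(x, y, 0, 1) for x, y in red] + [(x, y, 0, 2) for x, y in green]
        t = _table(rows)
        roi = square_roi(box, pixel_size=100.0)
        b = sx.RadialBinning.from_max(20.0, 400.0)
        c = sx.cross_correlation(t, roi, b, tau=0)
        mean_density = len(green) / roi.area
        d = sx.density_from_correlation(c, mean_density)
        i100 = np.searchsorted(b.edges, 100.0) - 1
        assert d.cumulative_excess[i100] == pytest.approx(k, rel=0.1)


class TestImageMethod:
    def test_uniform_channels_near_one(self):
        rng = np.random.default_rng(16)
        box = 8000.0
        t = make_uniform_table(rng, box, 8000, 1)
        roi = square_roi(box, pixel_size=25.0)
        b = sx.RadialBinning.from_max(25.0, 800.0)
        c = sx.correlation_image_method(sx.reconstruct_image(t, roi), b)
        sel = c.defined & (b.centers >= 50)
        assert np.nanmean(c.C[sel]) == pytest.approx(1.0, abs=0.05)

    def test_agrees_with_pairwise_time_averaged_mode(self):
        rng = np.random.default_rng(17)
        box, n = 8000.0, 6000
        x1, y1 = rng.uniform(0, box, n), rng.uniform(0, box, n)
        m = n // 2
        x2 = np.r_[x1[:m] + rng.normal(0, 30, m), rng.uniform(0, box, n - m)]
        y2 = np.r_[y1[:m] + rng.normal(0, 30, m), rng.uniform(0, box, n - m)]
        rows = [(x, y, 0, 1) for x, y in zip(x1, y1)]
        rows += [(x, y, 0, 2) for x, y in zip(x2, y2)]
        t = _table(rows)
        roi = square_roi(box, pixel_size=25.0)
        b = sx.RadialBinning.from_max(25.0, 600.0)
        pairwise = sx.cross_correlation(t, roi, b, tau=sx.TAU_ALL)
        image = sx.correlation_image_method(sx.reconstruct_image(t, roi), b)
        sel = b.centers >= 50.0  # r >= 2 pixels
        rel = np.abs(image.C[sel] - pairwise.C[sel]) / pairwise.C[sel]
        assert rel.max() < 0.05

    def test_empty_channel_rejected(self):
        roi = square_roi(1000.0, pixel_size=25.0)
        t = _table([(100.0, 100.0, 0, 1)])
        img = sx.reconstruct_image(t, roi)
        b = sx.RadialBinning.from_max(25.0, 200.0)
        with pytest.raises(ValueError, match="empty channel"):
            sx.correlation_image_method(img, b)
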