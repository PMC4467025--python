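"""Steady-state pair cross-correlation for point-localization data.

The central quantity is the time-lag-resolved cross-correlation

    C(r, tau) = M(r, tau) / mu(r),      mu(r) = dA(r) * rho0 * W(r),

the relative probability, versus a uniform distribution, of finding a pair of
differently coloured localizations separated by distance ``r`` at time lag
``tau``.  ``M`` is the histogram of cross-channel pair distances, ``dA(r) =
2*pi*r*dr`` the annulus area of a radial bin, ``rho0 = N / A_ROI`` the mean
pair density with ``N`` the total number of pairs counted, and ``W(r)`` the
radially averaged normalized autocorrelation of the ROI mask, which corrects
for the finite, possibly irregular analysis region.

For a steady-state window of ``F`` frames at lag ``tau`` (in frames),
``N = sum_i n1_i * n2_{i+tau}``; in time-averaged <tau> mode every
cross-channel pair contributes irrespective of time and ``N = n1 * n2``.

Counting statistics give ``var(M) = M`` (optionally ``M + 1`` in sparse mode)
and ``var(N) = N``, which propagate to

    var(C) = C^2 * (var(M)/M^2 + var(N)/N^2) = C^2 * (1/M + 1/N).

The potential of mean force follows as ``PMF(r) = -ln C(r)`` in units of
k_B*T, and ``rho(r) = C(r) * <rho>`` converts the correlation into a radial
partner density around the average labelled molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .locdata import LocalizationTable, RadialBinning, ROIMask, ReconstructedImage

__all__ = [
    "TAU_ALL",
    "PairHistogram",
    "EdgeCurve",
    "CorrelationCurve",
    "PotentialCurve",
    "DensityCurve",
    "ScrambledResample",
    "edge_factor",
    "pair_histogram",
    "correlation_from_histogram",
    "correlation_variance",
    "cross_correlation",
    "scrambled_resample",
    "correlation_image_method",
    "average_over_tau",
    "extrapolate_tau_zero",
    "pmf_from_correlation",
    "density_from_correlation",
]

#: sentinel for the time-averaged <tau> mode (all pairs irrespective of time)
TAU_ALL = "all"

#: sparse-mode trigger: total pair count below which var(M)=M+1 is used
SPARSE_PAIR_THRESHOLD = 100


@dataclass
class PairHistogram:
    """Binned cross-channel pair counts for one time lag."""

    M: np.ndarray
    N: int
    F: int
    rho0: float
    binning: RadialBinning
    tau: int | str
    area: float


@dataclass
class EdgeCurve:
    """Edge factor W(r): per-bin, area-weighted mean of the normalized ROI set
    covariance over the annulus.  W -> 1 for r -> 0 and decays to 0 beyond the
    ROI diameter."""

    W: np.ndarray
    binning: RadialBinning


@dataclass
class CorrelationCurve:
    binning: RadialBinning
    tau: int | str
    C: np.ndarray
    var_C: np.ndarray
    M: np.ndarray
    N: float
    W: np.ndarray
    mu: np.ndarray
    defined: np.ndarray
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def r(self) -> np.ndarray:
        return self.binning.centers

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.var_C)

    @property
    def tau_seconds(self) -> float | None:
        if self.tau == TAU_ALL:
            return None
        return self.tau * self.frame_interval


@dataclass
class PotentialCurve:
    """Potential of mean force, -ln C(r), in units of k_B*T."""

    binning: RadialBinning
    pmf: np.ndarray
    var_pmf: np.ndarray
    defined: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return self.binning.centers


@dataclass
class DensityCurve:
    """Radial partner density rho(r) = C(r) * <rho> and its running excess.

    ``cumulative_excess(r)`` is the expected number of excess partners within
    ``r`` of an average molecule: the prefix sum of ``(C - 1) * <rho> * dA``
    over bins (undefined bins contribute zero).
    """

    binning: RadialBinning
    rho: np.ndarray
    cumulative_excess: np.ndarray
    mean_density: float
    defined: np.ndarray


# ---------------------------------------------------------------------------
# edge factor


def _annulus_points(binning: RadialBinning, n_rad: int, n_ang: int):
    """Deterministic area-uniform sample radii/angles per annulus."""
    edges = binning.edges
    lo2, hi2 = edges[:-1] ** 2, edges[1:] ** 2
    frac = (np.arange(n_rad) + 0.5) / n_rad
    radii = np.sqrt(lo2[:, None] + frac[None, :] * (hi2 - lo2)[:, None])
    angles = 2.0 * np.pi * (np.arange(n_ang) + 0.5) / n_ang
    return radii, angles


def _radial_average(
    image: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    binning: RadialBinning,
    n_rad: int = 8,
    n_ang: int = 72,
) -> np.ndarray:
    """Area-weighted annulus means of a lag-space image at the bin radii."""
    radii, angles = _annulus_points(binning, n_rad, n_ang)
    cosA, sinA = np.cos(angles), np.sin(angles)
    rows = center[0] + radii[:, :, None] * sinA / pixel_size
    cols = center[1] + radii[:, :, None] * cosA / pixel_size
    vals = ndimage.map_coordinates(
        image, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(len(binning), -1)
    return vals.mean(axis=1)


def _mask_autocorrelation(
    grid: np.ndarray, min_lag: int = 0
) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-padded FFT autocorrelation of a raster; returns the lag image with
    the zero-lag pixel at the returned center index.  Padding is at least
    twice the raster (no wraparound) and covers ``min_lag`` pixels of lag."""
    n0 = sfft.next_fast_len(max(2 * grid.shape[0], grid.shape[0] + 2 * min_lag))
    n1 = sfft.next_fast_len(max(2 * grid.shape[1], grid.shape[1] + 2 * min_lag))
    F = sfft.rfft2(grid.astype(float), s=(n0, n1))
    ac = sfft.irfft2(F * np.conj(F), s=(n0, n1))
    ac = np.fft.fftshift(ac)
    return ac, (n0 // 2, n1 // 2)


def edge_factor(
    roi: ROIMask,
    binning: RadialBinning,
    max_pixel: float = 25.0,
) -> EdgeCurve:
    """Edge factor W(r) of an ROI mask, computed with FFTs.

    The mask is upsampled (by integer pixel subdivision) to a raster no
    coarser than ``min(binning.width, max_pixel)``, zero-padded to at least
    twice its extent to avoid wraparound, autocorrelated by FFT and
    normalized so the zero-lag value is 1; W at each bin is the area-weighted
    annulus mean of this normalized set covariance.
    """
    diag = float(np.hypot(*roi.grid.shape)) * roi.pixel_size
    if binning.edges[-1] > 2 * diag:
        raise ValueError(
            f"binning extends to {binning.edges[-1]:g} nm, beyond the padded "
            f"support (W is identically 0 past the ROI diameter {diag:g} nm)"
        )
    target = min(binning.width, max_pixel, roi.pixel_size)
    reps = max(1, int(np.ceil(roi.pixel_size / target - 1e-9)))
    grid = np.repeat(np.repeat(roi.grid, reps, axis=0), reps, axis=1)
    px = roi.pixel_size / reps
    min_lag = int(np.ceil(binning.edges[-1] / px)) + 2
    ac, center = _mask_autocorrelation(grid, min_lag=min_lag)
    support = min(center) * px
    if binning.edges[-1] > support:
        raise ValueError(
            f"binning extends to {binning.edges[-1]:g} nm, beyond the padded "
            f"autocorrelation support {support:g} nm"
        )
    W = _radial_average(ac, center, px, binning) / ac[center]
    return EdgeCurve(W=np.clip(W, 0.0, None), binning=binning)


# ---------------------------------------------------------------------------
# pair histograms


def _cross_histogram(p1: np.ndarray, p2: np.ndarray, binning: RadialBinning) -> np.ndarray:
    """Histogram of all cross distances between two point sets (half-open bins)."""
    if len(p1) == 0 or len(p2) == 0:
        return np.zeros(len(binning), np.int64)
    if len(p1) * len(p2) <= 2_000_000:
        return binning.histogram(cdist(p1, p2))
    # large problems: KD-tree cumulative counts; strict '<' at each edge keeps
    # the half-open bin convention exact
    t1, t2 = cKDTree(p1), cKDTree(p2)
    edges_minus = np.nextafter(binning.edges, -np.inf)
    cum = t1.count_neighbors(t2, edges_minus)
    return np.diff(cum).astype(np.int64)


def _roi_filter(table: LocalizationTable, roi: ROIMask) -> LocalizationTable:
    inside = roi.contains(table.data["x"].to_numpy(), table.data["y"].to_numpy())
    return table.with_data(table.data[inside].reset_index(drop=True))


def pair_histogram(
    table: LocalizationTable,
    roi: ROIMask,
    binning: RadialBinning,
    tau: int | str = 0,
    window: tuple[int, int] | None = None,
    channels: tuple[int, int] = (1, 2),
) -> PairHistogram:
    """Cross-channel pair-distance histogram M(r) at one time lag.

    For integer ``tau``, distances are measured between ``channels[0]``
    localizations in frame ``i`` and ``channels[1]`` localizations in frame
    ``i + tau`` for every frame ``i`` in the half-open ``window``;
    ``N = sum_i n1_i * n2_{i+tau}``.  With ``tau=TAU_ALL`` every cross-channel
    pair counts irrespective of time and ``N = n1 * n2``.

    Only localizations inside the ROI mask enter the histogram.
    """
    table = _roi_filter(table, roi)
    if window is None:
        window = (0, table.n_frames)
    start, stop = window
    if stop <= start:
        raise ValueError("empty frame window")
    F = stop - start
    c1, c2 = channels

    if tau == TAU_ALL:
        sel = (table.data["frame"] >= start) & (table.data["frame"] < stop)
        sub = table.data[sel]
        p1 = sub[sub["channel"] == c1][["x", "y"]].to_numpy(float)
        p2 = sub[sub["channel"] == c2][["x", "y"]].to_numpy(float)
        M = _cross_histogram(p1, p2, binning)
        N = len(p1) * len(p2)
    else:
        tau = int(tau)
        if tau < 0:
            raise ValueError("tau must be >= 0 (or TAU_ALL)")
        by1 = table.positions_by_frame(c1)
        by2 = table.positions_by_frame(c2)
        M = np.zeros(len(binning), np.int64)
        N = 0
        for i in range(start, stop - tau):
            p1 = by1.get(i)
            p2 = by2.get(i + tau)
            if p1 is None or p2 is None:
                continue
            M += _cross_histogram(p1, p2, binning)
            N += len(p1) * len(p2)
    return PairHistogram(
        M=M, N=int(N), F=F, rho0=N / roi.area, binning=binning, tau=tau, area=roi.area
    )


def correlation_variance(
    hist: PairHistogram, curve: CorrelationCurve, sparse: bool = False
) -> CorrelationCurve:
    """Attach Poisson-propagated variances to a correlation curve.

    ``var(M) = M`` (``M + 1`` in sparse mode, which keeps the error estimate
    finite in empty bins), ``var(N) = N``; the curve variance is
    ``var(C) = var(M)/mu^2 + C^2/N`` — algebraically equal to
    ``C^2 (var(M)/M^2 + 1/N)`` but finite when ``M = 0``.
    """
    var_M = hist.M.astype(float) + (1.0 if sparse else 0.0)
    var_N = float(hist.N)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_C = np.where(
            curve.defined, var_M / curve.mu**2 + curve.C**2 * var_N / hist.N**2, np.nan
        )
    return replace(curve, var_C=var_C, meta={**curve.meta, "sparse": sparse})


def correlation_from_histogram(
    hist: PairHistogram,
    edge: EdgeCurve,
    sparse: bool | None = None,
    frame_interval: float = 1.0,
) -> CorrelationCurve:
    """Normalize a pair histogram into C(r, tau) = M / (dA * rho0 * W).

    Bins where the edge factor vanishes (annulus outside the ROI support) are
    flagged undefined rather than reported.  ``sparse=None`` enables the
    var(M)=M+1 fallback automatically when the histogram holds fewer than
    ``SPARSE_PAIR_THRESHOLD`` pairs.
    """
    if hist.binning is not edge.binning and not np.allclose(
        hist.binning.centers, edge.binning.centers
    ):
        raise ValueError("histogram and edge factor use different binnings")
    if hist.N == 0:
        raise ValueError("no pairs in window (N = 0); cannot normalize")
    mu = hist.binning.ring_areas * hist.rho0 * edge.W
    defined = mu > 0
    C = np.full(len(hist.binning), np.nan)
    C[defined] = hist.M[defined] / mu[defined]
    if sparse is None:
        sparse = hist.M.sum() < SPARSE_PAIR_THRESHOLD
    curve = CorrelationCurve(
        binning=hist.binning,
        tau=hist.tau,
        C=C,
        var_C=np.full(len(hist.binning), np.nan),
        M=hist.M.astype(float),
        N=float(hist.N),
        W=edge.W,
        mu=mu,
        defined=defined,
        frame_interval=frame_interval,
        meta={"F": hist.F, "rho0": hist.rho0, "area": hist.area},
    )
    return correlation_variance(hist, curve, sparse=sparse)


def cross_correlation(
    table: LocalizationTable,
    roi: ROIMask,
    binning: RadialBinning,
    tau: int | str = 0,
    window: tuple[int, int] | None = None,
    edge: EdgeCurve | None = None,
    sparse: bool | None = None,
    channels: tuple[int, int] = (1, 2),
) -> CorrelationCurve:
    """One-call C(r, tau): edge factor + pair histogram + normalization."""
    if edge is None:
        edge = edge_factor(roi, binning)
    hist = pair_histogram(table, roi, binning, tau=tau, window=window, channels=channels)
    return correlation_from_histogram(
        hist, edge, sparse=sparse, frame_interval=table.frame_interval
    )


# ---------------------------------------------------------------------------
# resampling validation of the variance model


@dataclass
class ScrambledResample:
    """Per-window C(r, tau=0) after scrambling the time order of frames."""

    curves: list[CorrelationCurve]
    mean_C: np.ndarray
    sd_C: np.ndarray
    predicted_sigma: np.ndarray
    defined: np.ndarray


def scrambled_resample(
    table: LocalizationTable,
    roi: ROIMask,
    binning: RadialBinning,
    windows: int,
    window_frames: int,
    rng: np.random.Generator | int | None = None,
    edge: EdgeCurve | None = None,
) -> ScrambledResample:
    """Scramble frame order, tile into ``windows`` consecutive blocks of
    ``window_frames`` frames, and tabulate C(r, tau=0) per block.

    The empirical per-bin s.d. across blocks is the resampling estimate of
    sigma_C, to be compared with the analytic Poisson prediction.
    """
    rng = np.random.default_rng(rng)
    n_frames = table.n_frames
    if windows * window_frames > n_frames:
        raise ValueError(
            f"need {windows * window_frames} frames, table has {n_frames}"
        )
    if edge is None:
        edge = edge_factor(roi, binning)
    perm = rng.permutation(n_frames)
    remap = np.empty(n_frames, np.int64)
    remap[perm] = np.arange(n_frames)
    data = table.data.copy()
    data["frame"] = remap[data["frame"].to_numpy()]
    scrambled = table.with_data(data)

    # group per frame once; windows then only sum per-frame histograms
    filtered = _roi_filter(scrambled, roi)
    by1 = filtered.positions_by_frame(1)
    by2 = filtered.positions_by_frame(2)
    curves = []
    for w in range(windows):
        start, stop = w * window_frames, (w + 1) * window_frames
        M = np.zeros(len(binning), np.int64)
        N = 0
        for i in range(start, stop):
            p1, p2 = by1.get(i), by2.get(i)
            if p1 is None or p2 is None:
                continue
            M += _cross_histogram(p1, p2, binning)
            N += len(p1) * len(p2)
        hist = PairHistogram(
            M=M, N=int(N), F=window_frames, rho0=N / roi.area,
            binning=binning, tau=0, area=roi.area,
        )
        curves.append(
            correlation_from_histogram(hist, edge, frame_interval=table.frame_interval)
        )
    Cs = np.array([c.C for c in curves])
    defined = np.all([c.defined for c in curves], axis=0)
    if windows > 1:
        sd = np.nanstd(Cs, axis=0, ddof=1)
    else:
        sd = np.full(len(binning), np.nan)
    pred = np.sqrt(np.nanmean([c.var_C for c in curves], axis=0))
    return ScrambledResample(
        curves=curves,
        mean_C=np.nanmean(Cs, axis=0),
        sd_C=sd,
        predicted_sigma=pred,
        defined=defined,
    )


# ---------------------------------------------------------------------------
# image (FFT) route to C(r, <tau>)


def correlation_image_method(
    img: ReconstructedImage,
    binning: RadialBinning,
    channels: tuple[int, int] = (1, 2),
) -> CorrelationCurve:
    """Time-averaged cross-correlation from reconstructed images.

    ``C(r, <tau>)`` is the annulus average of the FFT cross-correlation of the
    two channel images, normalized by the channel densities and divided by the
    ROI edge correction — implemented as the ratio of the radially averaged
    numerator ``Re{IFFT(FFT(I1) conj(FFT(I2)))}`` to the radially averaged
    ``rho1 * rho2 * (mask set covariance)``.  This agrees with the pairwise
    <tau>-mode estimate up to pixel discretization.

    The same-channel (I1 = I2) variant carries a large self-pair density spike
    at r -> 0 and is not meaningful there.
    """
    c1, c2 = channels
    I1 = img.pixels[c1].astype(float)
    I2 = img.pixels[c2].astype(float)
    n1, n2 = I1.sum(), I2.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("empty channel image")
    mask = img.roi.grid.astype(float)
    n0 = sfft.next_fast_len(2 * mask.shape[0])
    m1 = sfft.next_fast_len(2 * mask.shape[1])
    shape = (n0, m1)
    F1 = sfft.rfft2(I1, s=shape)
    F2 = sfft.rfft2(I2, s=shape)
    Fm = sfft.rfft2(mask, s=shape)
    num = np.fft.fftshift(sfft.irfft2(np.conj(F1) * F2, s=shape))
    den = np.fft.fftshift(sfft.irfft2(Fm * np.conj(Fm), s=shape))
    center = (n0 // 2, m1 // 2)
    px = img.pixel_size
    npix = mask.sum()
    rho1, rho2 = n1 / npix, n2 / npix

    num_avg = _radial_average(num, center, px, binning)
    den_avg = _radial_average(den, center, px, binning)
    defined = den_avg > 1e-9 * npix
    C = np.full(len(binning), np.nan)
    C[defined] = num_avg[defined] / (rho1 * rho2 * den_avg[defined])

    # approximate Poisson errors through the pairwise-equivalent bookkeeping
    area = img.roi.area
    N = n1 * n2
    rho0 = N / area
    W = den_avg / npix
    mu = binning.ring_areas * rho0 * W
    M_est = np.where(defined, C * mu, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_C = np.where(defined & (M_est > 0), C**2 * (1 / M_est + 1 / N), np.nan)
    return CorrelationCurve(
        binning=binning,
        tau=TAU_ALL,
        C=C,
        var_C=var_C,
        M=M_est,
        N=float(N),
        W=W,
        mu=mu,
        defined=defined,
        meta={"method": "image", "rho_pix": (rho1, rho2)},
    )


# ---------------------------------------------------------------------------
# combining curves across tau


def average_over_tau(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Per-bin inverse-variance weighted mean of curves sharing a binning.

    The attached variance is that of the weighted mean, ``1 / sum(w)``; K
    identical curves therefore return the same curve with variance divided
    by K.
    """
    if not curves:
        raise ValueError("no curves to average")
    binning = curves[0].binning
    for c in curves[1:]:
        if not np.allclose(c.binning.centers, binning.centers):
            raise ValueError("curves use different binnings")
    C = np.array([c.C for c in curves])
    V = np.array([c.var_C for c in curves])
    ok = np.array([c.defined for c in curves]) & np.isfinite(V) & (V > 0)
    w = np.where(ok, 1.0 / np.where(ok, V, 1.0), 0.0)
    wsum = w.sum(axis=0)
    defined = wsum > 0
    mean = np.full(len(binning), np.nan)
    var = np.full(len(binning), np.nan)
    mean[defined] = (w * np.where(ok, C, 0.0)).sum(axis=0)[defined] / wsum[defined]
    var[defined] = 1.0 / wsum[defined]
    taus = [c.tau for c in curves]
    return CorrelationCurve(
        binning=binning,
        tau=TAU_ALL,
        C=mean,
        var_C=var,
        M=np.sum([c.M for c in curves], axis=0),
        N=float(np.sum([c.N for c in curves])),
        W=curves[0].W,
        mu=np.sum([c.mu for c in curves], axis=0),
        defined=defined,
        frame_interval=curves[0].frame_interval,
        meta={"method": "tau-average", "taus": taus},
    )


def extrapolate_tau_zero(
    curves: Sequence[CorrelationCurve],
    exclude: Iterable[int] = (0,),
    mode: str = "constant",
) -> CorrelationCurve:
    """Extrapolate C(r, tau) to tau = 0, excluding bleed-through-affected lags.

    Bleed-through produces spurious simultaneous pair counts, inflating only
    the smallest lags (and tau=0 most of all); fitting C versus tau per bin
    over the clean lags and evaluating at tau=0 recovers the bleed-free value.
    ``mode`` is ``"constant"`` (weighted mean) or ``"linear"`` (weighted
    straight-line fit).
    """
    exclude = set(int(t) for t in exclude)
    usable = [c for c in curves if c.tau != TAU_ALL and int(c.tau) not in exclude]
    if len(usable) < 3:
        raise ValueError("need >= 3 usable tau points after exclusion")
    binning = usable[0].binning
    taus = np.array([float(c.tau) for c in usable])
    C = np.array([c.C for c in usable])
    V = np.array([c.var_C for c in usable])
    ok = np.array([c.defined for c in usable]) & np.isfinite(V) & (V > 0)

    nb = len(binning)
    out_C = np.full(nb, np.nan)
    out_V = np.full(nb, np.nan)
    for b in range(nb):
        m = ok[:, b]
        npts = int(m.sum())
        if npts < (2 if mode == "linear" else 1):
            continue
        w = 1.0 / V[m, b]
        if mode == "constant":
            out_C[b] = np.sum(w * C[m, b]) / w.sum()
            out_V[b] = 1.0 / w.sum()
        elif mode == "linear":
            # weighted normal equations for C = a + b*tau; intercept at tau=0
            t = taus[m]
            S, Sx, Sxx = w.sum(), (w * t).sum(), (w * t * t).sum()
            Sy, Sxy = (w * C[m, b]).sum(), (w * t * C[m, b]).sum()
            det = S * Sxx - Sx * Sx
            if det <= 0:
                continue
            out_C[b] = (Sxx * Sy - Sx * Sxy) / det
            out_V[b] = Sxx / det
        else:
            raise ValueError(f"unknown mode {mode!r}")
    defined = np.isfinite(out_C)
    return CorrelationCurve(
        binning=binning,
        tau=0,
        C=out_C,
        var_C=out_V,
        M=np.full(nb, np.nan),
        N=float(np.sum([c.N for c in usable])),
        W=usable[0].W,
        mu=np.full(nb, np.nan),
        defined=defined,
        frame_interval=usable[0].frame_interval,
        meta={"method": f"tau0-extrapolation/{mode}", "taus": taus.tolist()},
    )


# ---------------------------------------------------------------------------
# physical conversions


def pmf_from_correlation(curve: CorrelationCurve) -> PotentialCurve:
    """Potential of mean force PMF(r) = -k_B*T ln C(r), in k_B*T units.

    Valid when the observed organization can be treated as an equilibrium
    steady state.  Bins with C = 0 (or undefined C) are flagged undefined
    rather than mapped to infinity; var(PMF) = var(C)/C^2 by propagation.
    """
    defined = curve.defined & np.isfinite(curve.C) & (curve.C > 0)
    pmf = np.full(len(curve.binning), np.nan)
    var = np.full(len(curve.binning), np.nan)
    pmf[defined] = -np.log(curve.C[defined])
    var[defined] = curve.var_C[defined] / curve.C[defined] ** 2
    return PotentialCurve(binning=curve.binning, pmf=pmf, var_pmf=var, defined=defined)


def density_from_correlation(
    curve: CorrelationCurve, mean_density: float
) -> DensityCurve:
    """Convert C(r) to a radial partner density and its integrated excess.

    ``rho(r) = C(r) * <rho>`` and ``cumulative_excess(r)`` prefix-sums
    ``(C - 1) * <rho> * dA`` over bins up to r — the expected number of excess
    partners within r of the average molecule.  Undefined bins contribute no
    excess.
    """
    if mean_density <= 0:
        raise ValueError("mean_density must be positive")
    rho = np.where(curve.defined, curve.C * mean_density, np.nan)
    excess = np.where(
        curve.defined, (curve.C - 1.0) * mean_density * curve.binning.ring_areas, 0.0
    )
    return DensityCurve(
        binning=curve.binning,
        rho=rho,
        cumulative_excess=np.cumsum(excess),
        mean_density=mean_density,
        defined=curve.defined,
    )
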