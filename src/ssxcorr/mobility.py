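"""Single-molecule mobility from displacement correlations and trajectories.

The time-resolved autocorrelation G(r, tau) is tabulated from localizations of
the *same* fluorophore detected ``tau`` frames apart, using the same
edge-corrected normalization machinery as the cross-correlation.  Normalizing
G so the two-dimensional area under the curve is one yields the probability
density of a molecule stepping a distance r in lag tau, without trajectory
reconstruction.  For Brownian motion this PDF is a zero-centred Gaussian whose
width is the mean squared displacement,

    PDF(r, tau) = exp(-r^2 / MSD) / (pi * MSD),        MSD(tau) = 4 D tau,

and a two-population mixture adds a slow/fast split with weight ``alpha`` on
the slow component.  The decay of alpha with tau, alpha(tau) = alpha0 *
exp(-tau/tau0), estimates the off-rate of the slow (bound) state.

A conventional trajectory route (greedy linking with ambiguity termination,
MSD fit through its 2nd-4th points) is provided for cross-checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .locdata import LocalizationTable, RadialBinning, ROIMask
from .paircorr import CorrelationCurve, EdgeCurve, cross_correlation

__all__ = [
    "DisplacementPDF",
    "DiffusionFitOne",
    "DiffusionFitTwo",
    "AlphaDecayFit",
    "Trajectory",
    "CorrelatedSteps",
    "auto_correlation",
    "pdf_from_G",
    "displacement_pdf",
    "fit_single",
    "fit_two",
    "alpha_vs_tau",
    "fit_alpha_decay",
    "link_trajectories",
    "trajectory_diffusion",
    "correlated_steps",
]


@dataclass
class DisplacementPDF:
    """Area-normalized displacement probability density at one lag."""

    binning: RadialBinning
    tau: int
    frame_interval: float
    pdf: np.ndarray
    var_pdf: np.ndarray | None
    defined: np.ndarray
    G: CorrelationCurve | None = None

    @property
    def r(self) -> np.ndarray:
        return self.binning.centers

    @property
    def tau_seconds(self) -> float:
        return self.tau * self.frame_interval

    def area(self) -> float:
        ok = self.defined
        return float(np.sum(self.pdf[ok] * self.binning.ring_areas[ok]))


@dataclass
class DiffusionFitOne:
    msd: float
    msd_se: float
    tau_seconds: float

    @property
    def D(self) -> float:
        return self.msd / (4.0 * self.tau_seconds)

    @property
    def D_se(self) -> float:
        return self.msd_se / (4.0 * self.tau_seconds)


@dataclass
class DiffusionFitTwo:
    """Two-population displacement fit; msd1 <= msd2 (slow first)."""

    alpha: float
    msd1: float
    msd2: float
    alpha_se: float
    msd1_se: float
    msd2_se: float
    tau_seconds: float
    covariance: np.ndarray
    identifiable: bool = True


@dataclass
class AlphaDecayFit:
    alpha0: float
    tau0: float
    alpha0_se: float
    tau0_se: float
    decaying: bool = True


@dataclass
class Trajectory:
    """One linked single-molecule track (consecutive frames)."""

    frames: np.ndarray
    xy: np.ndarray
    channel: int

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    def msd(self, max_lag: int) -> np.ndarray:
        """Time-averaged MSD at lags 1..max_lag (nan where unsupported)."""
        out = np.full(max_lag, np.nan)
        for k in range(1, max_lag + 1):
            if len(self.xy) > k:
                d = self.xy[k:] - self.xy[:-k]
                out[k - 1] = np.mean(np.sum(d * d, axis=1))
        return out


# ---------------------------------------------------------------------------
# displacement correlation -> PDF


def auto_correlation(
    table: LocalizationTable,
    channel: int,
    roi: ROIMask,
    binning: RadialBinning,
    tau: int,
    window: tuple[int, int] | None = None,
    edge: EdgeCurve | None = None,
) -> CorrelationCurve:
    """Same-channel lag correlation G(r, tau) (edge-corrected, Eq.-1 style).

    G(r, tau=0) only reports the instantaneous density of emitters, not
    motion, and is flagged accordingly.
    """
    if tau == 0:
        warnings.warn(
            "G(r, tau=0) reflects emitter density, not displacements; "
            "it is typically disregarded"
        )
    return cross_correlation(
        table, roi, binning, tau=tau, window=window, edge=edge, channels=(channel, channel)
    )


def pdf_from_G(g: CorrelationCurve) -> DisplacementPDF:
    """Normalize G(r, tau) so the 2-D area under the curve is one."""
    ok = g.defined & np.isfinite(g.C)
    total = np.sum(g.C[ok] * g.binning.ring_areas[ok])
    if not total > 0:
        raise ValueError("G sums to zero; cannot normalize")
    pdf = np.where(ok, g.C / total, np.nan)
    var = np.where(ok, g.var_C / total**2, np.nan)
    return DisplacementPDF(
        binning=g.binning,
        tau=int(g.tau),
        frame_interval=g.frame_interval,
        pdf=pdf,
        var_pdf=var,
        defined=ok,
        G=g,
    )


def displacement_pdf(
    table: LocalizationTable,
    channel: int,
    roi: ROIMask,
    binning: RadialBinning,
    tau: int,
    window: tuple[int, int] | None = None,
    edge: EdgeCurve | None = None,
) -> DisplacementPDF:
    """One call from table to normalized displacement PDF at one lag."""
    return pdf_from_G(auto_correlation(table, channel, roi, binning, tau, window, edge))


# ---------------------------------------------------------------------------
# Gaussian step models


def _gauss2d(r: np.ndarray, msd: float) -> np.ndarray:
    return np.exp(-(r**2) / msd) / (np.pi * msd)


def _fit_sigma(pdf: DisplacementPDF, ok: np.ndarray) -> np.ndarray:
    if pdf.var_pdf is None or not np.any(np.isfinite(pdf.var_pdf[ok])):
        return np.ones(int(ok.sum()))
    s = np.sqrt(pdf.var_pdf[ok])
    floor = 1e-6 * np.nanmax(pdf.pdf[ok])
    return np.clip(s, floor, None)


def fit_single(pdf: DisplacementPDF, tau_seconds: float | None = None) -> DiffusionFitOne:
    """Weighted fit of the one-population Gaussian step model.

    Returns MSD(tau) and hence D = MSD / (4 tau).  Localization noise adds a
    constant offset ~ 4 * sigma_loc^2 to the apparent MSD; it is reported, not
    subtracted.
    """
    if tau_seconds is None:
        tau_seconds = pdf.tau_seconds
    ok = pdf.defined & np.isfinite(pdf.pdf)
    r, y = pdf.r[ok], pdf.pdf[ok]
    sigma = _fit_sigma(pdf, ok)
    msd0 = max(float(np.sum(y * r**2 * pdf.binning.ring_areas[ok])), pdf.binning.width**2)
    try:
        popt, pcov = curve_fit(
            _gauss2d, r, y, p0=[msd0], sigma=sigma, absolute_sigma=False,
            bounds=(1e-12, np.inf), maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"single-population fit did not converge: {err}") from err
    return DiffusionFitOne(msd=float(popt[0]), msd_se=float(np.sqrt(pcov[0, 0])), tau_seconds=tau_seconds)


def _mixture(r: np.ndarray, alpha: float, msd1: float, msd2: float) -> np.ndarray:
    return alpha * _gauss2d(r, msd1) + (1.0 - alpha) * _gauss2d(r, msd2)


def fit_two(
    pdf: DisplacementPDF,
    tau_seconds: float | None = None,
    init: tuple[float, float, float] | None = None,
    restarts: int = 5,
    seed: int = 0,
) -> DiffusionFitTwo:
    """Weighted fit of the two-population Gaussian mixture.

    Parameters are (alpha, MSD1, MSD2) with 0 <= alpha <= 1 and the slow
    population first (MSD1 <= MSD2 enforced by post-ordering).  Initialisation
    is method-of-moments at the half-mass radius, with a few seeded restarts;
    the best weighted SSE wins.  A fit with MSD2/MSD1 < 2 is flagged
    unidentifiable.
    """
    if tau_seconds is None:
        tau_seconds = pdf.tau_seconds
    ok = pdf.defined & np.isfinite(pdf.pdf)
    r, y = pdf.r[ok], pdf.pdf[ok]
    sigma = _fit_sigma(pdf, ok)
    dA = pdf.binning.ring_areas[ok]

    if init is None:
        mass = np.cumsum(y * dA)
        total = mass[-1] if mass[-1] > 0 else 1.0
        half = int(np.searchsorted(mass, 0.5 * total))
        inner = slice(0, max(half, 1))
        outer = slice(max(half, 1), None)
        m_in = float(np.sum(y[inner] * r[inner] ** 2 * dA[inner]) / max(np.sum(y[inner] * dA[inner]), 1e-300))
        m_out = float(np.sum(y[outer] * r[outer] ** 2 * dA[outer]) / max(np.sum(y[outer] * dA[outer]), 1e-300))
        init = (0.5, max(m_in, 1e-9), max(m_out, 2e-9))

    rng = np.random.default_rng(seed)
    bounds = ([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf])
    best = None
    for k in range(restarts):
        p0 = np.array(init, float)
        if k:
            p0 = p0 * np.array([1.0, rng.uniform(0.3, 3.0), rng.uniform(0.3, 3.0)])
            p0[0] = np.clip(init[0] + rng.uniform(-0.3, 0.3), 0.05, 0.95)
        try:
            popt, pcov = curve_fit(
                _mixture, r, y, p0=p0, sigma=sigma, absolute_sigma=False,
                bounds=bounds, maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum(((y - _mixture(r, *popt)) / sigma) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError("two-population fit did not converge from any start")
    _, popt, pcov = best
    alpha, m1, m2 = popt
    se = np.sqrt(np.diag(pcov))
    if m1 > m2:  # reorder slow-first; alpha follows its component
        m1, m2 = m2, m1
        alpha = 1.0 - alpha
        se = se[[0, 2, 1]]
        pcov = pcov[np.ix_([0, 2, 1], [0, 2, 1])]
    identifiable = m2 >= 2.0 * m1
    if not identifiable:
        warnings.warn(
            f"two-population fit weakly identifiable: MSD2/MSD1 = {m2 / max(m1, 1e-300):.2f} < 2"
        )
    return DiffusionFitTwo(
        alpha=float(alpha), msd1=float(m1), msd2=float(m2),
        alpha_se=float(se[0]), msd1_se=float(se[1]), msd2_se=float(se[2]),
        tau_seconds=tau_seconds, covariance=pcov, identifiable=identifiable,
    )


def alpha_vs_tau(
    table: LocalizationTable,
    channel: int,
    roi: ROIMask,
    binning: RadialBinning,
    taus: np.ndarray,
    window: tuple[int, int] | None = None,
    edge: EdgeCurve | None = None,
    init: tuple[float, float, float] | None = None,
) -> list[tuple[float, DiffusionFitTwo]]:
    """Two-population fits across a series of frame lags.

    Returns (tau_seconds, fit) pairs; feed the alphas to ``fit_alpha_decay``.
    The fit of each lag seeds the next one's initialisation.
    """
    out = []
    for tau in taus:
        pdf = displacement_pdf(table, channel, roi, binning, int(tau), window, edge)
        fit = fit_two(pdf, init=init)
        init = (fit.alpha, fit.msd1, fit.msd2)
        out.append((pdf.tau_seconds, fit))
    return out


def fit_alpha_decay(
    taus: np.ndarray, alphas: np.ndarray, se: np.ndarray | None = None
) -> AlphaDecayFit:
    """Weighted exponential fit alpha(tau) = alpha0 * exp(-tau / tau0).

    A series that does not decay over its span is reported with
    ``decaying=False`` (tau0 unbounded above within error).
    """
    taus = np.asarray(taus, float)
    alphas = np.asarray(alphas, float)
    if len(taus) < 3:
        raise ValueError("need >= 3 tau points for the decay fit")
    span = taus.max() - taus.min()

    def model(t, a0, tau0):
        return a0 * np.exp(-t / tau0)

    p0 = [max(alphas.max(), 1e-3), max(span / 2, 1e-6)]
    try:
        popt, pcov = curve_fit(
            model, taus, alphas, p0=p0, sigma=se, absolute_sigma=se is not None,
            bounds=([0.0, 1e-12], [1.0, np.inf]), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"alpha decay fit did not converge: {err}") from err
    a0, tau0 = popt
    se_a0, se_tau0 = np.sqrt(np.diag(pcov))
    decaying = np.isfinite(se_tau0) and tau0 - 2 * se_tau0 < np.inf and tau0 < 100 * span
    if not decaying or not np.isfinite(se_tau0):
        warnings.warn("alpha(tau) series is consistent with no decay")
        decaying = False
    return AlphaDecayFit(
        alpha0=float(a0), tau0=float(tau0),
        alpha0_se=float(se_a0), tau0_se=float(se_tau0), decaying=decaying,
    )


# ---------------------------------------------------------------------------
# trajectories


def link_trajectories(
    table: LocalizationTable, channel: int, radius: float = 500.0
) -> list[Trajectory]:
    """Greedy frame-to-frame linking with ambiguity termination.

    A link between frames f and f+1 is made iff exactly one candidate lies
    within ``radius`` for both endpoints (one forward candidate, one backward
    candidate).  Any ambiguity terminates the trajectories involved at that
    frame; ambiguous next-frame points may still start new trajectories.  The
    result does not depend on the row order of the input.
    """
    if radius <= 0:
        raise ValueError("link radius must be positive")
    by_frame = table.positions_by_frame(channel)
    if not by_frame:
        return []
    frames = sorted(by_frame)
    # canonical within-frame order so the result is row-order invariant
    for f in frames:
        pts = by_frame[f]
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        by_frame[f] = pts[order]

    done: list[Trajectory] = []
    active: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    for fi, f in enumerate(frames):
        pts = by_frame[f]
        nxt = by_frame.get(f + 1) if fi + 1 < len(frames) and frames[fi + 1] == f + 1 else None
        links: dict[int, int] = {}
        if nxt is not None and len(nxt):
            tree = cKDTree(nxt)
            fwd = tree.query_ball_point(pts, r=radius)
            back_count = np.zeros(len(nxt), int)
            for cands in fwd:
                for j in cands:
                    back_count[j] += 1
            for i, cands in enumerate(fwd):
                if len(cands) == 1 and back_count[cands[0]] == 1:
                    links[i] = cands[0]
        new_active: dict[int, tuple[list[int], list[np.ndarray]]] = {}
        for i in range(len(pts)):
            traj = active.pop(i, None)
            if traj is None:
                traj = ([], [])
            traj[0].append(f)
            traj[1].append(pts[i])
            if i in links:
                new_active[links[i]] = traj
            else:
                done.append(Trajectory(np.array(traj[0]), np.array(traj[1]), channel))
        active = new_active
    for traj in active.values():
        done.append(Trajectory(np.array(traj[0]), np.array(traj[1]), channel))
    return done


@dataclass
class EnsembleDiffusion:
    """Pooled MSD analysis over linked trajectories."""

    msd: np.ndarray
    lags_seconds: np.ndarray
    D: float
    D_se: float
    n_trajectories: int
    n_excluded: int
    single_D: np.ndarray = field(default_factory=lambda: np.array([]))


def _fit_msd_points(lags_s: np.ndarray, msd: np.ndarray) -> tuple[float, float]:
    """D and s.e. from a straight line through the 2nd-4th MSD points."""
    t, y = lags_s[1:4], msd[1:4]
    A = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = len(t) - 2
    if dof > 0 and len(res):
        s2 = res[0] / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        slope_se = float(np.sqrt(cov[0, 0]))
    else:
        slope_se = float("nan")
    return float(coef[0] / 4.0), slope_se / 4.0


def trajectory_diffusion(
    trajs: list[Trajectory],
    frame_interval: float,
    min_length: int = 4,
    max_lag: int = 4,
    single_min_segments: int = 10,
) -> EnsembleDiffusion:
    """Ensemble and single-trajectory diffusion coefficients from MSD(tau).

    MSD is pooled over all displacement pairs of trajectories with at least
    ``max(min_length, 4)`` steps; D comes from a linear fit through the 2nd-4th
    MSD points.  Per-trajectory D values are reported for trajectories longer
    than ``single_min_segments`` steps.
    """
    min_len = max(min_length, max_lag)
    used = [t for t in trajs if t.n_steps >= min_len]
    excluded = len(trajs) - len(used)
    if not used:
        raise ValueError("no trajectory long enough for MSD fitting")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for t in used:
        for k in range(1, max_lag + 1):
            if len(t.xy) > k:
                d = t.xy[k:] - t.xy[:-k]
                sums[k - 1] += np.sum(d * d)
                counts[k - 1] += len(d)
    msd = sums / counts
    lags_s = frame_interval * np.arange(1, max_lag + 1)
    D, D_se = _fit_msd_points(lags_s, msd)
    single = []
    for t in used:
        if t.n_steps > single_min_segments:
            m = t.msd(max_lag)
            if np.all(np.isfinite(m)):
                single.append(_fit_msd_points(lags_s, m)[0])
    return EnsembleDiffusion(
        msd=msd, lags_seconds=lags_s, D=D, D_se=D_se,
        n_trajectories=len(used), n_excluded=excluded, single_D=np.array(single),
    )


@dataclass
class CorrelatedSteps:
    """Channel-1 displacement steps split by simultaneous channel-2 proximity."""

    all_lengths: np.ndarray
    selected: np.ndarray

    @property
    def selected_lengths(self) -> np.ndarray:
        return self.all_lengths[self.selected]

    def msd_selected(self) -> float:
        return float(np.mean(self.selected_lengths**2)) if self.selected.any() else float("nan")

    def msd_all(self) -> float:
        return float(np.mean(self.all_lengths**2)) if len(self.all_lengths) else float("nan")


def correlated_steps(
    table: LocalizationTable,
    r_c: float = 50.0,
    channels: tuple[int, int] = (1, 2),
    mode: str = "either",
    link_radius: float = 500.0,
) -> CorrelatedSteps:
    """Select channel-1 steps adjacent to simultaneous channel-2 localizations.

    A step (two consecutive-frame localizations of a linked channel-1
    trajectory) is selected when its start and/or end localization has a
    same-frame channel-2 localization within ``r_c`` (``mode`` = ``"either"``
    endpoint, the default, or ``"both"``).
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    c1, c2 = channels
    trees = {f: cKDTree(p) for f, p in table.positions_by_frame(c2).items()}

    def near(frame: int, point: np.ndarray) -> bool:
        tree = trees.get(frame)
        return tree is not None and len(tree.query_ball_point(point, r=r_c)) > 0

    lengths, selected = [], []
    for traj in link_trajectories(table, c1, radius=link_radius):
        for k in range(traj.n_steps):
            step = traj.xy[k + 1] - traj.xy[k]
            lengths.append(float(np.hypot(*step)))
            a = near(int(traj.frames[k]), traj.xy[k])
            b = near(int(traj.frames[k + 1]), traj.xy[k + 1])
            selected.append((a or b) if mode == "either" else (a and b))
    return CorrelatedSteps(all_lengths=np.array(lengths), selected=np.array(selected, bool))
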