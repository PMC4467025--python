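"""Ground-truth simulators and the stochastic SMLM observation model.

Three generators:

* ``lj_simulate`` — a 2-D NVE molecular-dynamics run of a Lennard-Jones fluid
  in reduced units (sigma = epsilon = mass = 1): 64 atoms at reduced density
  0.05 (box side sqrt(64/0.05) ~ 35.8 sigma), velocity-Verlet propagation at
  dt = 0.005, periodic boundaries with minimum-image convention, positions
  saved every 5 steps.  Atoms are randomly split into two equal colour groups,
  so the cross-colour pair correlation estimates the fluid's g(r) and its
  negative log the pair potential (in k_B*T).
* ``brownian_simulate`` — Brownian particles in a reflecting box with optional
  two-state binding kinetics: channel-1 particles switch between a free state
  (D_free) and a bound state with exponential waiting times; channel-2
  particles diffuse slowly and can serve as immobilized anchor sites.
* ``observe_smlm`` — turns ground-truth positions into a localization table by
  Bernoulli per-frame blinking (P_on), Gaussian localization noise, and
  optional spectral bleed-through, in which a channel-1 localization spawns a
  simultaneous, position-correlated channel-2 record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locdata import LocalizationTable

__all__ = [
    "LJConfig",
    "LJResult",
    "BlinkModel",
    "BrownianResult",
    "lj_simulate",
    "brownian_simulate",
    "observe_smlm",
]


# ---------------------------------------------------------------------------
# Lennard-Jones molecular dynamics


@dataclass
class LJConfig:
    """Reduced-unit parameters of the 2-D Lennard-Jones run."""

    n_atoms: int = 64
    reduced_density: float = 0.05
    dt: float = 0.005
    n_steps: int = 200_000
    equil_steps: int = 40_000
    save_every: int = 5
    temperature: float = 1.0
    cutoff: float = 2.5
    seed: int = 0

    @property
    def box_side(self) -> float:
        return float(np.sqrt(self.n_atoms / self.reduced_density))

    @property
    def n_snapshots(self) -> int:
        return self.n_steps // self.save_every


@dataclass
class LJResult:
    """Saved production snapshots of an LJ run."""

    positions: np.ndarray  # (n_snapshots, n_atoms, 2), wrapped into the box
    colors: np.ndarray  # (n_atoms,), labels 1/2, random equal split
    config: LJConfig
    total_energy: np.ndarray  # per-snapshot total energy (reduced units)
    temperature_measured: float  # production mean kinetic temperature

    @property
    def box_side(self) -> float:
        return self.config.box_side

    @property
    def energy_drift(self) -> float:
        """Max |E - <E>| / |<E>| over production."""
        e = self.total_energy
        return float(np.max(np.abs(e - e.mean())) / abs(e.mean()))

    def channel_positions(self, scale: float = 1.0) -> dict[int, np.ndarray]:
        """Per-channel position stacks (snapshots as frames), optionally
        scaled from sigma units to nm."""
        return {
            c: self.positions[:, self.colors == c, :] * scale for c in (1, 2)
        }


def _lj_forces(pos: np.ndarray, box: float, cutoff: float, f_rc: float, u_rc: float):
    """Forces and potential of the force-shifted LJ (force and energy both
    continuous at the cutoff, so NVE energy is conserved cleanly)."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    np.fill_diagonal(r2, np.inf)
    within = r2 < cutoff * cutoff
    inv_r2 = np.where(within, 1.0 / r2, 0.0)
    inv_r6 = inv_r2**3
    r = np.where(within, np.sqrt(r2), np.inf)
    # F_lj(r)/r = 24 (2 r^-12 - r^-6) / r^2 ; force-shift subtracts F_lj(rc)
    f_over_r = 24.0 * (2.0 * inv_r6**2 - inv_r6) * inv_r2 - np.where(within, f_rc / r, 0.0)
    forces = np.einsum("ij,ijk->ik", f_over_r, d)
    u_pair = 4.0 * (inv_r6**2 - inv_r6) - u_rc + (r - cutoff) * f_rc
    pot = 0.5 * np.sum(np.where(within, u_pair, 0.0))
    return forces, pot


def lj_simulate(config: LJConfig | None = None) -> LJResult:
    """Run the 2-D Lennard-Jones NVE simulation.

    Initial positions maximize spacing (square lattice); initial velocities
    are Gaussian with zero net momentum, rescaled to the target reduced
    temperature.  Velocities are re-rescaled periodically during
    equilibration only; production is pure NVE, and the total energy per
    snapshot is recorded so conservation can be checked.
    """
    cfg = config or LJConfig()
    box = cfg.box_side
    if cfg.cutoff > box / 2:
        raise ValueError(
            f"cutoff {cfg.cutoff} exceeds half the box side {box / 2:.3f}; "
            "minimum-image convention would break"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_atoms
    side = int(np.ceil(np.sqrt(n)))
    grid = np.array(
        [(i, j) for i in range(side) for j in range(side)][:n], float
    )
    pos = (grid + 0.5) * (box / side)
    vel = rng.normal(size=(n, 2))
    vel -= vel.mean(axis=0)

    ndof = 2 * n - 2  # momentum conserved in both directions

    def rescale(v: np.ndarray) -> np.ndarray:
        ke = 0.5 * np.sum(v * v)
        return v * np.sqrt(cfg.temperature * ndof / (2.0 * ke))

    vel = rescale(vel)
    rc = cfg.cutoff
    u_rc = 4.0 * (rc**-12 - rc**-6)
    f_rc = 24.0 * (2.0 * rc**-13 - rc**-7)
    forces, pot = _lj_forces(pos, box, rc, f_rc, u_rc)

    def step(pos, vel, forces):
        vel = vel + 0.5 * cfg.dt * forces
        pos = (pos + cfg.dt * vel) % box
        forces, pot = _lj_forces(pos, box, rc, f_rc, u_rc)
        vel = vel + 0.5 * cfg.dt * forces
        return pos, vel, forces, pot

    for k in range(cfg.equil_steps):
        pos, vel, forces, pot = step(pos, vel, forces)
        if (k + 1) % 200 == 0:
            vel = rescale(vel)

    n_snap = cfg.n_snapshots
    snapshots = np.empty((n_snap, n, 2))
    energies = np.empty(n_snap)
    kin_sum = 0.0
    isnap = 0
    for k in range(cfg.n_steps):
        pos, vel, forces, pot = step(pos, vel, forces)
        if (k + 1) % cfg.save_every == 0:
            ke = 0.5 * np.sum(vel * vel)
            snapshots[isnap] = pos
            energies[isnap] = ke + pot
            kin_sum += 2.0 * ke / ndof
            isnap += 1
    colors = np.ones(n, np.int64)
    colors[rng.permutation(n)[: n // 2]] = 2
    return LJResult(
        positions=snapshots,
        colors=colors,
        config=cfg,
        total_energy=energies,
        temperature_measured=kin_sum / max(isnap, 1),
    )


# ---------------------------------------------------------------------------
# Brownian dynamics with two-state binding


@dataclass
class BrownianResult:
    positions: dict[int, np.ndarray]  # channel -> (frames, n, 2) nm
    bound: np.ndarray  # (frames, n1) channel-1 bound flag at frame instants
    dwell_bound: np.ndarray  # completed bound dwell times, s
    dwell_free: np.ndarray
    frame_interval: float
    box: float


def _state_epochs(rng, k_on, k_off, total, start_bound):
    """Continuous-time alternating (state, duration) epochs covering [0, total]."""
    t, bound = 0.0, start_bound
    epochs = []
    while t < total:
        rate = k_off if bound else k_on
        dur = rng.exponential(1.0 / rate) if rate > 0 else total - t + 1.0
        epochs.append((bound, t, min(t + dur, total)))
        t += dur
        bound = not bound
    return epochs


def brownian_simulate(
    n: int = 200,
    D_free: float = 2.0e5,
    D_slow: float = 1.0e4,
    k_on: float = 0.0,
    k_off: float = 0.0,
    sites: np.ndarray | None = None,
    frames: int = 1000,
    frame_interval: float = 0.03,
    box: float = 10_000.0,
    seed: int | None = 0,
    n2: int | None = None,
    capture_radius: float = 50.0,
) -> BrownianResult:
    """Brownian mixture with two-state binding in a reflecting square box.

    Channel-1 particles alternate between free diffusion at ``D_free``
    (nm^2/s) and a bound state with exponential waiting times (rates ``k_on``,
    ``k_off`` in 1/s).  Without anchor ``sites``, state switching is exact in
    continuous time and a bound particle simply diffuses at ``D_slow`` from
    where it bound; each frame displacement uses the exact time-in-state
    variance decomposition.  With ``sites`` (an (m, 2) array of anchor
    positions), binding is gated on proximity (within ``capture_radius`` of a
    site at a frame boundary, per-frame switching probabilities) and a bound
    particle co-moves with its anchor; the anchors are returned as the
    channel-2 particles, performing a shared D_slow walk.  Without sites,
    channel-2 particles (``n2``, default ``n``) are independent D_slow
    walkers.
    """
    rng = np.random.default_rng(seed)
    dt = frame_interval
    total = frames * dt

    def reflect(x):
        x = np.mod(x, 2 * box)
        return np.where(x > box, 2 * box - x, x)

    dwell_b, dwell_f = [], []
    pos1 = np.empty((frames, n, 2))
    bound_flags = np.zeros((frames, n), bool)

    if sites is None:
        p_eq = k_on / (k_on + k_off) if (k_on + k_off) > 0 else 0.0
        for i in range(n):
            start_bound = bool(rng.random() < p_eq) and k_on > 0
            epochs = _state_epochs(rng, k_on, k_off, total, start_bound)
            for b, t0, t1 in epochs:
                if t1 - t0 < total and t0 > 0 and t1 < total:
                    (dwell_b if b else dwell_f).append(t1 - t0)
            # time bound within each frame interval
            tb = np.zeros(frames)
            for b, t0, t1 in epochs:
                if not b:
                    continue
                f0, f1 = int(t0 / dt), min(int(np.ceil(t1 / dt)), frames)
                for f in range(f0, f1):
                    tb[f] += max(0.0, min(t1, (f + 1) * dt) - max(t0, f * dt))
                # bound flag at frame instants f*dt within [t0, t1)
                fa = int(np.ceil(t0 / dt - 1e-12))
                fb = min(int(np.ceil(t1 / dt - 1e-12)), frames)
                if fb > fa:
                    bound_flags[fa:fb, i] = True
            tf = dt - tb
            var = 2.0 * (D_free * tf + D_slow * tb)
            steps = rng.normal(size=(frames, 2)) * np.sqrt(var)[:, None]
            start = rng.uniform(0, box, 2)
            x = np.concatenate([[start], steps[:-1]]).cumsum(axis=0)
            pos1[:, i, :] = reflect(x)
        m2 = n if n2 is None else n2
        steps2 = rng.normal(scale=np.sqrt(2.0 * D_slow * dt), size=(frames, m2, 2))
        start2 = rng.uniform(0, box, size=(1, m2, 2))
        pos2 = reflect(np.concatenate([start2, steps2[:-1]]).cumsum(axis=0))
    else:
        sites = np.asarray(sites, float)
        m2 = len(sites)
        p_bind = 1.0 - np.exp(-k_on * dt) if k_on > 0 else 0.0
        p_unbind = 1.0 - np.exp(-k_off * dt) if k_off > 0 else 0.0
        site_steps = rng.normal(scale=np.sqrt(2.0 * D_slow * dt), size=(frames, m2, 2))
        pos2 = reflect(np.concatenate([sites[None], site_steps[:-1]]).cumsum(axis=0))
        x = rng.uniform(0, box, size=(n, 2))
        anchor = -np.ones(n, int)
        since = np.zeros(n)
        from scipy.spatial import cKDTree

        for f in range(frames):
            pos1[f] = x
            bound_flags[f] = anchor >= 0
            tree = cKDTree(pos2[f])
            dist, nearest = tree.query(x)
            unbind = (anchor >= 0) & (rng.random(n) < p_unbind)
            for i in np.flatnonzero(unbind):
                dwell_b.append(since[i])
            anchor[unbind] = -1
            bindable = (anchor < 0) & (dist <= capture_radius)
            bind = bindable & (rng.random(n) < p_bind)
            anchor[bind] = nearest[bind]
            since[bind] = 0.0
            since[anchor >= 0] += dt
            free = anchor < 0
            x = x + np.where(
                free[:, None],
                rng.normal(scale=np.sqrt(2.0 * D_free * dt), size=(n, 2)),
                site_steps[f, np.clip(anchor, 0, m2 - 1)],
            )
            x = reflect(x)

    return BrownianResult(
        positions={1: pos1, 2: pos2},
        bound=bound_flags,
        dwell_bound=np.array(dwell_b),
        dwell_free=np.array(dwell_f),
        frame_interval=frame_interval,
        box=box,
    )


# ---------------------------------------------------------------------------
# stochastic SMLM observation


@dataclass
class BlinkModel:
    """Per-frame stochastic observation of ground-truth particles."""

    p_on: float = 1.0
    loc_noise: float = 0.0  # nm s.d. per axis
    bleed_prob: float = 0.0  # channel-1 emission also localized in channel 2
    bleed_noise: float = 0.0  # nm s.d. of the bleed-through copy's extra jitter
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_on, self.bleed_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def observe_smlm(
    positions: dict[int, np.ndarray],
    model: BlinkModel,
    frame_interval: float = 1.0,
) -> LocalizationTable:
    """Apply blinking, localization noise and bleed-through to ground truth.

    ``positions`` maps channel label -> (frames, n, 2) ground-truth position
    stack (nm).  Each particle is localized in its own channel per frame with
    probability ``p_on``, jittered by ``loc_noise``; each channel-1
    localization additionally spawns a simultaneous channel-2 record jittered
    by ``bleed_noise`` with probability ``bleed_prob`` (position-correlated
    bleed-through, which disproportionally inflates C(r, tau=0)).
    """
    rng = np.random.default_rng(model.seed)
    frames_list, xs, ys, chans = [], [], [], []
    for ch in sorted(positions):
        stack = positions[ch]
        n_frames, n, _ = stack.shape
        on = rng.random((n_frames, n)) < model.p_on
        f_idx, p_idx = np.nonzero(on)
        obs = stack[f_idx, p_idx, :]
        if model.loc_noise > 0:
            obs = obs + rng.normal(scale=model.loc_noise, size=obs.shape)
        frames_list.append(f_idx)
        xs.append(obs[:, 0])
        ys.append(obs[:, 1])
        chans.append(np.full(len(f_idx), ch))
        if ch == 1 and model.bleed_prob > 0:
            bleed = rng.random(len(f_idx)) < model.bleed_prob
            copy = obs[bleed]
            if model.bleed_noise > 0:
                copy = copy + rng.normal(scale=model.bleed_noise, size=copy.shape)
            frames_list.append(f_idx[bleed])
            xs.append(copy[:, 0])
            ys.append(copy[:, 1])
            chans.append(np.full(bleed.sum(), 2))
    data = pd.DataFrame(
        {
            "x": np.concatenate(xs),
            "y": np.concatenate(ys),
            "frame": np.concatenate(frames_list),
            "channel": np.concatenate(chans),
        }
    ).sort_values(["frame", "channel"], kind="stable").reset_index(drop=True)
    return LocalizationTable(data, frame_interval=frame_interval)
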