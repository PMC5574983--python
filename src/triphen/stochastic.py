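"""Langevin dynamics of the two-gene circuit.

The stochastic model adds independent Gaussian white noise to each
deterministic velocity component::

    dx_i/dt = F_i(x) + xi_i(t),   <xi_i(t) xi_i(s)> = 2 D delta(t - s)

with a single noise intensity D for both genes (total of intrinsic and
extrinsic fluctuations).  Integration is Euler-Maruyama,

    x <- x + F(x) dt + sqrt(2 D dt) eta,   eta ~ N(0, 1),

which is exact in distribution for additive noise up to O(dt) weak error;
higher-order schemes add nothing here because the diffusion is constant.
Concentrations are kept non-negative by reflection at zero (``x <- |x|``),
consistent with the no-flux boundary used by the landscape solver.

All ensemble routines draw replicate streams from independently spawned
`numpy` SeedSequences, so results are reproducible and replicates remain
independent under any execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ModelParams, drift
from .mfpt import MfptResult
from .steady_state import FixedPoint, basin_map

__all__ = [
    "NoiseSpec",
    "Trajectory",
    "OccupancyResult",
    "MfptResult",
    "simulate",
    "estimate_occupancy",
    "first_passage_times",
    "first_passage_times_1d",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise intensity and RNG seed for one stochastic experiment."""

    D: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("noise intensity D must be >= 0")


@dataclass
class Trajectory:
    """A single recorded sample path."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), 2)
    dt: float
    params: ModelParams
    noise: NoiseSpec


@dataclass
class OccupancyResult:
    """Long-run fraction of time spent in each phenotype's basin."""

    probabilities: dict  # phenotype -> probability
    stderr: dict  # phenotype -> replicate-based standard error
    t_total: float
    burn_in: float
    n_replicates: int


def _em_step(x: np.ndarray, params: ModelParams, dt: float, amp: float,
             rng: np.random.Generator, reflect: bool) -> np.ndarray:
    f1, f2 = drift((x[:, 0], x[:, 1]), params)
    x = x + np.stack([f1, f2], axis=1) * dt
    if amp > 0:
        x = x + amp * rng.standard_normal(x.shape)
    if reflect:
        np.abs(x, out=x)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            "state overflowed during Euler-Maruyama integration; reduce dt")
    return x


def simulate(
    params: ModelParams,
    noise: NoiseSpec,
    x_init: tuple[float, float],
    dt: float = 1e-3,
    t_end: float = 10.0,
    record_every: int = 1,
    reflect: bool = True,
) -> Trajectory:
    """Integrate one Euler-Maruyama sample path and record it.

    With ``D = 0`` this is a fixed-step deterministic (Euler) integration;
    identical ``(seed, dt, t_end, params)`` give bit-identical output.
    ``record_every`` thins the stored samples without changing the path.
    """
    if dt <= 0 or t_end < dt:
        raise ValueError("need dt > 0 and t_end >= dt")
    nsteps = int(round(t_end / dt))
    rng = np.random.default_rng(noise.seed)
    amp = np.sqrt(2.0 * noise.D * dt)
    x = np.array([x_init], dtype=float)
    times = [0.0]
    states = [x[0].copy()]
    for k in range(1, nsteps + 1):
        x = _em_step(x, params, dt, amp, rng, reflect)
        if k % record_every == 0 or k == nsteps:
            times.append(k * dt)
            states.append(x[0].copy())
    return Trajectory(np.array(times), np.array(states), dt, params, noise)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_ensemble(
    params: ModelParams,
    noise: NoiseSpec,
    x_init: tuple[float, float],
    dt: float,
    t_end: float,
    burn_in: float,
    n_replicates: int,
    record_every: int = 10,
    reflect: bool = True,
) -> np.ndarray:
    """Post-burn-in samples from ``n_replicates`` independent paths.

    Returns an array of shape (n_replicates, n_recorded, 2).  The replicate
    axis is kept so callers can form replicate-based standard errors.
    """
    nsteps = int(round(t_end / dt))
    nburn = int(round(burn_in / dt))
    streams = _spawn_rngs(noise.seed, n_replicates)
    amp = np.sqrt(2.0 * noise.D * dt)
    x = np.tile(np.asarray(x_init, float), (n_replicates, 1))
    rec: list[np.ndarray] = []
    # independent stream per replicate; noise drawn in chunks so the step
    # loop stays vectorised across replicates
    chunk = 8192
    k = 0
    while k < nsteps:
        m = min(chunk, nsteps - k)
        if amp > 0:
            eta = np.stack([r.standard_normal((m, 2)) for r in streams])
        for j in range(m):
            k += 1
            f1, f2 = drift((x[:, 0], x[:, 1]), params)
            x = x + np.stack([f1, f2], axis=1) * dt
            if amp > 0:
                x = x + amp * eta[:, j, :]
            if reflect:
                np.abs(x, out=x)
            if k > nburn and k % record_every == 0:
                rec.append(x.copy())
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("state overflowed; reduce dt")
    return np.stack(rec, axis=1)


def estimate_occupancy(
    params: ModelParams,
    noise: NoiseSpec,
    attractors: Sequence[FixedPoint],
    dt: float = 2e-3,
    t_end: float = 2000.0,
    burn_in: float = 100.0,
    n_replicates: int = 8,
    record_every: int = 20,
    basin_resolution: int = 120,
) -> OccupancyResult:
    """Time-fraction of each phenotype basin from long stochastic runs.

    Samples are assigned to basins through a precomputed
    deterministic-relaxation map (states relaxed under the noiseless flow
    to the attractor they approach), evaluated on a grid and looked up per
    sample; cells the relaxation cannot resolve count as ``other``.
    """
    stable = [fp for fp in attractors if fp.stability == "stable"]
    if not stable:
        raise ValueError("estimate_occupancy needs stable attractors")
    if t_end <= burn_in:
        raise ValueError("t_end must exceed burn_in")
    # domain sized to the invariant box plus noise excursions
    hi1 = (params.a1 + params.b1) / params.k1 + 6 * np.sqrt(noise.D)
    hi2 = (params.a2 + params.b2) / params.k2 + 6 * np.sqrt(noise.D)
    ax1 = np.linspace(0, hi1, basin_resolution)
    ax2 = np.linspace(0, hi2, basin_resolution)
    bmap = basin_map(params, stable, ax1, ax2)

    x_init = stable[0].location
    samples = sample_ensemble(params, noise, x_init, dt, t_end, burn_in,
                              n_replicates, record_every)
    i1 = np.clip(np.searchsorted(ax1, samples[..., 0]) - 1, 0, len(ax1) - 1)
    i2 = np.clip(np.searchsorted(ax2, samples[..., 1]) - 1, 0, len(ax2) - 1)
    lab = bmap[i1, i2]  # (n_rep, n_samples)

    names = [fp.phenotype for fp in stable]
    keys = ["L", "B", "S", "other"]
    per_rep = {k: np.zeros(n_replicates) for k in keys}
    nrec = lab.shape[1]
    for idx, name in enumerate(names):
        key = name if name in keys else "other"
        per_rep[key] += np.sum(lab == idx, axis=1) / nrec
    per_rep["other"] += np.sum(lab < 0, axis=1) / nrec
    probs = {k: float(np.mean(v)) for k, v in per_rep.items()}
    se = {k: float(np.std(v, ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1
          else float("nan") for k, v in per_rep.items()}
    return OccupancyResult(probs, se, t_end, burn_in, n_replicates)


def first_passage_times(
    params: ModelParams,
    noise: NoiseSpec,
    source: FixedPoint,
    target: FixedPoint,
    n_samples: int = 200,
    dt: float = 1e-3,
    t_max: float = 2000.0,
    capture_radius: float = 0.05,
) -> MfptResult:
    """Monte-Carlo mean first-passage time between two stable attractors.

    Each sample starts at the source attractor and stops on first entry
    into the max-norm disk of ``capture_radius`` around the target.  Paths
    still running at ``t_max`` are censored at ``t_max`` (biasing the mean
    low); a warning is attached when more than half are censored.
    """
    if source.stability != "stable" or target.stability != "stable":
        raise ValueError("source and target must be stable fixed points")
    if max(abs(source.x1 - target.x1), abs(source.x2 - target.x2)) <= capture_radius:
        raise ValueError("source lies inside the target capture disk")
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed).spawn(1)[0])
    amp = np.sqrt(2.0 * noise.D * dt)
    x = np.tile(np.asarray(source.location, float), (n_samples, 1))
    alive = np.ones(n_samples, dtype=bool)
    hit_time = np.full(n_samples, t_max)
    tgt = np.asarray(target.location)
    nsteps = int(round(t_max / dt))
    for k in range(1, nsteps + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        xa = x[idx]
        f1, f2 = drift((xa[:, 0], xa[:, 1]), params)
        xa = xa + np.stack([f1, f2], axis=1) * dt
        xa = np.abs(xa + amp * rng.standard_normal(xa.shape))
        x[idx] = xa
        hit = np.max(np.abs(xa - tgt), axis=1) <= capture_radius
        hit_time[idx[hit]] = k * dt
        alive[idx[hit]] = False
    n_cens = int(np.sum(alive))
    mean = float(np.mean(hit_time))
    se = float(np.std(hit_time, ddof=1) / np.sqrt(n_samples))
    warning = None
    if n_cens > n_samples // 2:
        warning = (f"{n_cens}/{n_samples} samples censored at t_max={t_max}; "
                   "the estimate is badly biased low")
    return MfptResult(mean, "monte-carlo",
                      (source.phenotype, target.phenotype),
                      noise.D, se, n_samples, n_cens, warning)


def first_passage_times_1d(
    params: ModelParams,
    noise: NoiseSpec,
    x0: float,
    start: float,
    stop: float,
    n_samples: int = 200,
    dt: float = 1e-3,
    t_max: float = 2000.0,
) -> MfptResult:
    """MFPT of the reduced x2 dynamics with x1 clamped at ``x0``.

    The passage criterion is the first crossing of the point ``stop``
    (matching the exact double-integral theory for a 1-D diffusion);
    reflection at zero keeps the concentration non-negative.
    """
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed).spawn(1)[0])
    amp = np.sqrt(2.0 * noise.D * dt)
    y = np.full(n_samples, float(start))
    side0 = np.sign(start - stop)
    alive = np.ones(n_samples, dtype=bool)
    hit_time = np.full(n_samples, t_max)
    nsteps = int(round(t_max / dt))
    p = params
    inh = p.b2 * p.theta**p.n / (p.theta**p.n + x0**p.n)
    tn = p.theta**p.n
    for k in range(1, nsteps + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        ya = y[idx]
        yn = np.power(ya, p.n)
        f2 = p.a2 * yn / (tn + yn) + inh - p.k2 * ya
        ya = np.abs(ya + f2 * dt + amp * rng.standard_normal(ya.shape))
        y[idx] = ya
        hit = np.sign(ya - stop) != side0
        hit_time[idx[hit]] = k * dt
        alive[idx[hit]] = False
    n_cens = int(np.sum(alive))
    mean = float(np.mean(hit_time))
    se = float(np.std(hit_time, ddof=1) / np.sqrt(n_samples))
    warning = None
    if n_cens > n_samples // 2:
        warning = f"{n_cens}/{n_samples} samples censored at t_max={t_max}"
    direction = ("B", "S") if start < stop else ("S", "B")
    return MfptResult(mean, "monte-carlo", direction, noise.D, se,
                      n_samples, n_cens, warning)
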