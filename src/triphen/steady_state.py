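"""Fixed points, phenotype labels, bifurcation and phase-diagram scans.

The deterministic circuit is a skew product: F1 depends on x1 only, so
every fixed point sits on an x1 root of F1, with x2 solving
F2(x1, x2) = 0 on that branch.  Root finding is therefore two nested 1-D
problems (dense bracketing + Brent), which is far more robust than 2-D
Newton iterations from random seeds.

Stable states are labelled with the three breast-cancer phenotypes:

* ``B`` (basal):     x1 high, x2 low  — mesenchymal-like, E-cadherin off
* ``S`` (stem-like): x1 high, x2 high
* ``L`` (luminal):   x1 low,  x2 high — epithelial, ZEB1 off

where high/low is relative to the Hill threshold ``theta``, the model's
only intrinsic concentration scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, drift, hill_activation, invariant_box, jacobian

__all__ = [
    "FixedPoint",
    "PhaseMap",
    "BifurcationBranch",
    "BracketError",
    "find_fixed_points",
    "classify_phenotype",
    "phase_diagram",
    "bifurcation_scan",
    "critical_hill",
    "relax",
    "basin_map",
]

#: canonical phenotype letter order used in region codes (L < B < S)
_LETTER_ORDER = "LBS"

# degenerate-eigenvalue band: |Re lambda| below this is reported unstable
_EIG_TIE = 1e-9

_DEDUP_TOL = 1e-7


class BracketError(ValueError):
    """A bisection bracket does not straddle the sought transition."""


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the deterministic system."""

    x1: float
    x2: float
    stability: str  # "stable" | "saddle" | "unstable"
    eigenvalues: tuple[float, float]
    phenotype: str  # "L" | "B" | "S" | "other" | "none"

    @property
    def location(self) -> tuple[float, float]:
        return (self.x1, self.x2)


@dataclass
class PhaseMap:
    """Stability-region codes over a 2-D parameter grid."""

    axis1_name: str
    axis2_name: str
    axis1: np.ndarray
    axis2: np.ndarray
    cell_label: np.ndarray  # (len(axis1), len(axis2)) array of region codes
    n_stable: np.ndarray
    n_unstable: np.ndarray


@dataclass
class BifurcationBranch:
    """All fixed points along a one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    points: list[list[FixedPoint]]
    region_codes: list[str]


def _roots_1d(f: Callable[[float], float], xs: np.ndarray, fs: np.ndarray,
              xtol: float) -> list[float]:
    """Roots of f bracketed by sign changes of the pre-evaluated samples."""
    roots = [float(xs[i]) for i in np.nonzero(fs == 0.0)[0]]
    sign = np.sign(fs)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        roots.append(brentq(f, xs[i], xs[i + 1], xtol=xtol))
    return sorted(roots)


def _x1_roots(params: ModelParams, seeds: int, xtol: float) -> list[float]:
    p = params
    hi = (p.a1 + p.b1) / p.k1 * 1.02 + 10 * xtol
    xs = np.linspace(0.0, hi, seeds)
    fs = p.a1 * hill_activation(xs, p.theta, p.n) + p.b1 - p.k1 * xs

    def f1(x: float) -> float:
        return p.a1 * hill_activation(x, p.theta, p.n) + p.b1 - p.k1 * x

    return _roots_1d(f1, xs, fs, xtol)


def _x2_roots(params: ModelParams, x0: float, seeds: int, xtol: float) -> list[float]:
    p = params
    inh = p.b2 * p.theta**p.n / (p.theta**p.n + x0**p.n)
    hi = (p.a2 + p.b2) / p.k2 * 1.02 + 10 * xtol
    xs = np.linspace(0.0, hi, seeds)
    fs = p.a2 * hill_activation(xs, p.theta, p.n) + inh - p.k2 * xs

    def f2(y: float) -> float:
        return p.a2 * hill_activation(y, p.theta, p.n) + inh - p.k2 * y

    return _roots_1d(f2, xs, fs, xtol)


def classify_phenotype(fp: FixedPoint, params: ModelParams) -> str:
    """Phenotype letter for a stable fixed point; ``"none"`` otherwise."""
    if fp.stability != "stable":
        return "none"
    return _phenotype(fp.x1, fp.x2, params.theta)


def _phenotype(x1: float, x2: float, theta: float) -> str:
    hi1, hi2 = x1 >= theta, x2 >= theta
    if hi1 and not hi2:
        return "B"
    if hi1 and hi2:
        return "S"
    if not hi1 and hi2:
        return "L"
    return "other"


def _classify(x1: float, x2: float, params: ModelParams) -> FixedPoint:
    jac = jacobian((x1, x2), params)
    lam = (jac[0, 0], jac[1, 1])  # triangular Jacobian: diagonal = spectrum
    if abs(lam[0]) < _EIG_TIE or abs(lam[1]) < _EIG_TIE:
        warnings.warn(
            f"near-degenerate eigenvalue at fixed point ({x1:.6g}, {x2:.6g}); "
            "classifying as unstable", stacklevel=3)
        stability = "unstable"
    elif lam[0] < 0 and lam[1] < 0:
        stability = "stable"
    elif lam[0] * lam[1] < 0:
        stability = "saddle"
    else:
        stability = "unstable"
    pheno = _phenotype(x1, x2, params.theta) if stability == "stable" else "none"
    return FixedPoint(x1, x2, stability, lam, pheno)


def find_fixed_points(
    params: ModelParams,
    domain: tuple[tuple[float, float], tuple[float, float]] | None = None,
    seeds_per_axis: int = 400,
    tol: float = 1e-9,
) -> list[FixedPoint]:
    """Enumerate and classify all fixed points of the deterministic system.

    Solves F1(x1) = 0 by dense bracketing on x1, then F2(x1, x2) = 0 on x2
    for each x1 root, deduplicates, classifies stability from the Jacobian
    eigenvalues, and returns the points sorted by (x1, x2).

    ``domain``, when given, must contain the invariant trapping box; it
    only widens the bracketing interval and is otherwise unused.
    """
    if domain is not None:
        (lo1, hi1), (lo2, hi2) = domain
        box = invariant_box(params)
        if lo1 > box[0][0] or hi1 < box[0][1] or lo2 > box[1][0] or hi2 < box[1][1]:
            raise ValueError("domain must contain the invariant box "
                             f"{box}; got {domain}")
    out: list[FixedPoint] = []
    for x0 in _x1_roots(params, seeds_per_axis, tol):
        for y in _x2_roots(params, x0, seeds_per_axis, tol):
            if any(max(abs(fp.x1 - x0), abs(fp.x2 - y)) < _DEDUP_TOL for fp in out):
                continue
            out.append(_classify(x0, y, params))
    if not out:
        raise RuntimeError(
            "no fixed point found although the drift is inward on the "
            "invariant box boundary; increase seeds_per_axis")
    return sorted(out, key=lambda fp: (fp.x1, fp.x2))


def _region_code(fps: Sequence[FixedPoint]) -> str:
    letters = {fp.phenotype for fp in fps if fp.stability == "stable"}
    known = [c for c in _LETTER_ORDER if c in letters]
    if "other" in letters or not known:
        return "other"
    return "".join(known)


def phase_diagram(
    params_base: ModelParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    seeds_per_axis: int = 240,
) -> PhaseMap:
    """Region-code map over any two kinetic parameters (e.g. ``a1`` x ``a2``)."""
    name1, grid1 = axis1
    name2, grid2 = axis2
    for name in (name1, name2):
        if name not in params_base.to_dict():
            raise KeyError(f"unknown model parameter {name!r}")
    grid1 = np.asarray(grid1, float)
    grid2 = np.asarray(grid2, float)
    for g, name in ((grid1, name1), (grid2, name2)):
        if g.ndim != 1 or len(g) < 1 or np.any(np.diff(g) <= 0):
            raise ValueError(f"grid for {name} must be strictly increasing")
    labels = np.empty((len(grid1), len(grid2)), dtype=object)
    n_st = np.zeros(labels.shape, dtype=int)
    n_un = np.zeros(labels.shape, dtype=int)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            p = params_base.with_(**{name1: float(v1), name2: float(v2)})
            fps = find_fixed_points(p, seeds_per_axis=seeds_per_axis)
            labels[i, j] = _region_code(fps)
            n_st[i, j] = sum(fp.stability == "stable" for fp in fps)
            n_un[i, j] = len(fps) - n_st[i, j]
    return PhaseMap(name1, name2, grid1, grid2, labels, n_st, n_un)


def bifurcation_scan(
    params_base: ModelParams,
    parameter: str,
    grid: np.ndarray,
    seeds_per_axis: int = 240,
) -> BifurcationBranch:
    """Fixed points (x2 with stability) along a one-parameter sweep."""
    if parameter not in params_base.to_dict():
        raise KeyError(f"unknown model parameter {parameter!r}")
    grid = np.asarray(grid, float)
    points, codes = [], []
    for v in grid:
        fps = find_fixed_points(params_base.with_(**{parameter: float(v)}),
                                seeds_per_axis=seeds_per_axis)
        points.append(fps)
        codes.append(_region_code(fps))
    return BifurcationBranch(parameter, grid, points, codes)


def _tristable_cell(params: ModelParams, seeds: int) -> bool:
    """True iff the cell has three stable states labelled L, B and S.

    Fast path for n-scans: bails out early unless F1 is bistable, which is
    a necessary condition for an L state to coexist with B/S.
    """
    x1r = _x1_roots(params, seeds, 1e-9)
    stable_x1 = [x for i, x in enumerate(x1r) if i % 2 == 0]  # outer roots stable
    if len(x1r) < 3:
        return False
    letters = set()
    for x0 in stable_x1:
        x2r = _x2_roots(params, x0, seeds, 1e-9)
        for i in range(0, len(x2r), 2):  # alternation: even-index roots stable
            letters.add(_phenotype(x0, x2r[i], params.theta))
    return {"L", "B", "S"} <= letters


def _tristable_anywhere(params_base: ModelParams, n: float,
                        a1_grid: np.ndarray, a2_grid: np.ndarray,
                        seeds: int) -> bool:
    for a1 in a1_grid:
        p1 = params_base.with_(a1=float(a1), n=float(n))
        if len(_x1_roots(p1, seeds, 1e-9)) < 3:
            continue  # x1 monostable: no cell in this column can be tristable
        for a2 in a2_grid:
            if _tristable_cell(p1.with_(a2=float(a2)), seeds):
                return True
    return False


def critical_hill(
    params_base: ModelParams | None = None,
    a1_range: tuple[float, float] = (0.05, 2.0),
    a2_range: tuple[float, float] = (0.05, 2.0),
    grid_points: int = 80,
    n_bracket: tuple[float, float] = (2.0, 3.0),
    tol: float = 0.02,
    seeds_per_axis: int = 240,
) -> float:
    """Critical Hill coefficient below which tristability disappears.

    For each candidate ``n`` the (a1, a2) plane is scanned on a
    ``grid_points`` x ``grid_points`` grid; tristability is declared if any
    cell carries three stable states labelled S, B and L.  Bisection on
    ``n`` then returns the infimum with tristability, to width ``tol``.

    Raises :class:`BracketError` when both bracket ends agree (widen the
    bracket), since bisection then has nothing to localise.
    """
    if params_base is None:
        params_base = ModelParams(a1=0.8, a2=0.85)
    a1_grid = np.linspace(*a1_range, grid_points)
    a2_grid = np.linspace(*a2_range, grid_points)

    def has_tri(n: float) -> bool:
        return _tristable_anywhere(params_base, n, a1_grid, a2_grid, seeds_per_axis)

    lo, hi = n_bracket
    tri_lo, tri_hi = has_tri(lo), has_tri(hi)
    if tri_lo or not tri_hi:
        raise BracketError(
            f"tristability at n={lo} is {tri_lo} and at n={hi} is {tri_hi}; "
            "the bracket must go from absent to present — widen it")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if has_tri(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# deterministic relaxation / basin assignment


def relax(params: ModelParams, points: np.ndarray, t_end: float = 40.0,
          dt: float = 0.05) -> np.ndarray:
    """Integrate the noiseless dynamics from many points at once (RK4).

    ``points`` has shape (m, 2); returns the states at ``t_end``.  Used to
    assign states to basins of attraction by letting them fall into their
    attractor, which is watershed-correct without computing separatrices.
    """
    x = np.array(points, dtype=float)
    nsteps = max(1, int(round(t_end / dt)))

    def f(y):
        f1, f2 = drift((y[:, 0], y[:, 1]), params)
        return np.stack([f1, f2], axis=1)

    for _ in range(nsteps):
        k1 = f(x)
        k2 = f(np.clip(x + 0.5 * dt * k1, 0.0, None))
        k3 = f(np.clip(x + 0.5 * dt * k2, 0.0, None))
        k4 = f(np.clip(x + dt * k3, 0.0, None))
        x = np.clip(x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)
    return x


def basin_map(
    params: ModelParams,
    attractors: Sequence[FixedPoint],
    x1_axis: np.ndarray,
    x2_axis: np.ndarray,
    t_end: float = 40.0,
    capture: float = 0.05,
) -> np.ndarray:
    """Attractor index for each cell of a rectangular grid (-1 if unresolved).

    Grid centres are relaxed with :func:`relax` and matched to the nearest
    attractor within ``capture`` (max-norm).
    """
    stable = [fp for fp in attractors if fp.stability == "stable"]
    if not stable:
        raise ValueError("basin_map needs at least one stable attractor")
    g1, g2 = np.meshgrid(x1_axis, x2_axis, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    final = relax(params, pts, t_end=t_end)
    lab = np.full(len(pts), -1, dtype=int)
    locs = np.array([fp.location for fp in stable])
    d = np.max(np.abs(final[:, None, :] - locs[None, :, :]), axis=2)
    nearest = np.argmin(d, axis=1)
    ok = d[np.arange(len(pts)), nearest] <= capture
    lab[ok] = nearest[ok]
    return lab.reshape(g1.shape)
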