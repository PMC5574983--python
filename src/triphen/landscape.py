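"""Stationary probability landscape of the noisy two-gene circuit.

The joint density P(x1, x2, t) obeys a Fokker-Planck equation with drift
(F1, F2) and isotropic diffusion D.  Its stationary solution P_st defines
the effective (Waddington-style) potential U_st = -ln P_st; minima of
U_st are the phenotypic states.

The grid solver discretises the equation in conservative finite-volume
form — first-order upwind advection plus centred diffusion, no-flux
(reflecting) boundary fluxes — and marches to the stationary state with
backward-Euler steps, reusing one sparse LU factorisation.  Upwinding
keeps the density non-negative; the flux form conserves total probability
to rounding at every step.  The same landscape can be estimated
empirically as a normalised 2-D histogram of long Langevin runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import splu

from .model import ModelParams, drift, hill_activation
from .steady_state import FixedPoint, basin_map

__all__ = [
    "LandscapeGrid",
    "solve_stationary_fpe",
    "histogram_landscape",
    "basin_probabilities",
    "probability_modes",
    "total_variation",
]

_DEFAULT_DOMAIN = ((0.0, 2.0), (0.0, 2.5))


@dataclass
class LandscapeGrid:
    """P_st and U_st = -ln P_st on a uniform rectangular grid.

    ``x1``/``x2`` hold cell-centre coordinates; ``P`` integrates to 1 over
    the domain; ``U`` is masked (NaN) where ``P`` falls below the floor.
    """

    x1: np.ndarray
    x2: np.ndarray
    P: np.ndarray  # (len(x1), len(x2))
    U: np.ndarray
    D: float
    params: ModelParams
    method: str  # "fpe" | "histogram"
    residual: float = 0.0

    @property
    def cell_area(self) -> float:
        return float((self.x1[1] - self.x1[0]) * (self.x2[1] - self.x2[0]))


def _potential_from_density(P: np.ndarray, floor: float) -> np.ndarray:
    cutoff = floor * P.max()
    with np.errstate(divide="ignore"):
        U = np.where(P > cutoff, -np.log(np.maximum(P, cutoff)), np.nan)
    return U


def _fv_operator(params: ModelParams, D: float, x1: np.ndarray,
                 x2: np.ndarray) -> "coo_matrix":
    """Sparse finite-volume generator A with dP/dt = A P and no-flux walls."""
    n1, n2 = len(x1), len(x2)
    h1 = x1[1] - x1[0]
    h2 = x2[1] - x2[0]
    rows, cols, vals = [], [], []

    def idx(i, j):
        return i * n2 + j

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # x1-direction faces between (i, j) and (i+1, j)
    xf = 0.5 * (x1[:-1] + x1[1:])
    p = params
    v1f = p.a1 * hill_activation(xf, p.theta, p.n) + p.b1 - p.k1 * xf
    for i in range(n1 - 1):
        v = v1f[i]
        for j in range(n2):
            a, b = idx(i, j), idx(i + 1, j)
            up = a if v > 0 else b
            add(a, up, -v / h1)
            add(b, up, v / h1)
            d = D / h1**2
            add(a, b, d), add(a, a, -d), add(b, a, d), add(b, b, -d)

    # x2-direction faces between (i, j) and (i, j+1)
    yf = 0.5 * (x2[:-1] + x2[1:])
    for i in range(n1):
        _, v2f = drift((np.full(n2 - 1, x1[i]), yf), params)
        for j in range(n2 - 1):
            v = v2f[j]
            a, b = idx(i, j), idx(i, j + 1)
            up = a if v > 0 else b
            add(a, up, -v / h2)
            add(b, up, v / h2)
            d = D / h2**2
            add(a, b, d), add(a, a, -d), add(b, a, d), add(b, b, -d)

    n = n1 * n2
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def solve_stationary_fpe(
    params: ModelParams,
    D: float,
    domain: tuple = _DEFAULT_DOMAIN,
    resolution: int | tuple[int, int] = 128,
    convergence_tol: float = 1e-9,
    dt: float = 5.0,
    max_iter: int = 400,
    probability_floor: float = 1e-12,
) -> LandscapeGrid:
    """Stationary solution of the 2-D Fokker-Planck equation on a grid.

    Backward-Euler time-marching of the finite-volume semi-discretisation
    from a uniform density until ``||dP/dt||_inf < convergence_tol``; the
    large implicit step damps all fast modes, so convergence is limited
    only by the slow inter-basin exchange.  The result is renormalised to
    unit mass.
    """
    if D <= 0:
        raise ValueError("D must be > 0 for a smooth stationary density")
    n1, n2 = (resolution, resolution) if np.isscalar(resolution) else resolution
    if min(n1, n2) < 64:
        raise ValueError("resolution must be at least 64 cells per axis")
    (lo1, hi1), (lo2, hi2) = domain
    h1, h2 = (hi1 - lo1) / n1, (hi2 - lo2) / n2
    x1 = lo1 + h1 * (np.arange(n1) + 0.5)
    x2 = lo2 + h2 * (np.arange(n2) + 0.5)
    A = _fv_operator(params, D, x1, x2)
    M = (identity(n1 * n2, format="csc") - dt * A).tocsc()
    lu = splu(M)
    area = h1 * h2
    P = np.full(n1 * n2, 1.0 / ((hi1 - lo1) * (hi2 - lo2)))
    residual = np.inf
    for _ in range(max_iter):
        P = lu.solve(P)
        P = np.clip(P, 0.0, None)
        P /= P.sum() * area
        residual = float(np.max(np.abs(A @ P)))
        if residual < convergence_tol:
            break
    else:
        raise RuntimeError(
            f"stationary FPE solve did not converge: ||dP/dt||_inf = "
            f"{residual:.3e} after {max_iter} iterations of dt={dt}")
    Pg = P.reshape(n1, n2)
    U = _potential_from_density(Pg, probability_floor)
    return LandscapeGrid(x1, x2, Pg, U, D, params, "fpe", residual)


def histogram_landscape(
    samples: np.ndarray,
    domain: tuple = _DEFAULT_DOMAIN,
    resolution: int | tuple[int, int] = 128,
    probability_floor: float = 1e-12,
    params: ModelParams | None = None,
    D: float = float("nan"),
) -> LandscapeGrid:
    """Empirical landscape: normalised 2-D histogram of post-burn-in samples.

    ``samples`` is any array reshapeable to (m, 2), e.g. the output of
    :func:`triphen.stochastic.sample_ensemble`.
    """
    samples = np.asarray(samples, float).reshape(-1, 2)
    if samples.size == 0:
        raise ValueError("empty sample ensemble")
    n1, n2 = (resolution, resolution) if np.isscalar(resolution) else resolution
    (lo1, hi1), (lo2, hi2) = domain
    counts, e1, e2 = np.histogram2d(
        samples[:, 0], samples[:, 1], bins=(n1, n2),
        range=((lo1, hi1), (lo2, hi2)))
    area = (e1[1] - e1[0]) * (e2[1] - e2[0])
    P = counts / (counts.sum() * area)
    U = _potential_from_density(P, probability_floor)
    x1 = 0.5 * (e1[:-1] + e1[1:])
    x2 = 0.5 * (e2[:-1] + e2[1:])
    return LandscapeGrid(x1, x2, P, U, D, params, "histogram")


def basin_probabilities(
    grid: LandscapeGrid,
    attractors: Sequence[FixedPoint],
    params: ModelParams | None = None,
) -> dict:
    """Mass of P_st in each phenotype's basin of attraction.

    Grid cells are assigned by deterministic relaxation (see
    :func:`triphen.steady_state.basin_map`); unresolved cells count as
    ``other``.  The returned probabilities sum to 1.
    """
    params = params or grid.params
    if params is None:
        raise ValueError("model parameters required for basin assignment")
    stable = [fp for fp in attractors if fp.stability == "stable"]
    for fp in stable:
        if not (grid.x1[0] <= fp.x1 <= grid.x1[-1]
                and grid.x2[0] <= fp.x2 <= grid.x2[-1]):
            raise ValueError(f"attractor {fp.location} outside the grid domain")
    bmap = basin_map(params, stable, grid.x1, grid.x2)
    mass = grid.P * grid.cell_area
    out = {"L": 0.0, "B": 0.0, "S": 0.0, "other": 0.0}
    for idx, fp in enumerate(stable):
        key = fp.phenotype if fp.phenotype in out else "other"
        out[key] += float(mass[bmap == idx].sum())
    out["other"] += float(mass[bmap < 0].sum())
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def probability_modes(grid: LandscapeGrid, min_rel: float = 1e-4) -> list:
    """Locations of strict interior local maxima of P (8-neighbourhood).

    Maxima below ``min_rel`` of the global peak are ignored — they are
    discretisation ripples in the deep-tail region.
    """
    P = grid.P
    core = P[1:-1, 1:-1]
    mask = np.ones_like(core, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            mask &= core > P[1 + di:P.shape[0] - 1 + di,
                             1 + dj:P.shape[1] - 1 + dj]
    mask &= core >= min_rel * P.max()
    ii, jj = np.nonzero(mask)
    return [(float(grid.x1[i + 1]), float(grid.x2[j + 1])) for i, j in zip(ii, jj)]


def total_variation(a: LandscapeGrid, b: LandscapeGrid) -> float:
    """Total-variation distance between two landscapes on the same grid."""
    if a.P.shape != b.P.shape:
        raise ValueError("landscapes must share a grid")
    return float(0.5 * np.sum(np.abs(a.P - b.P)) * a.cell_area)
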