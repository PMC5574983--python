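"""One-dimensional reduction and first-passage theory for B <-> S switching.

Because F1 does not depend on x2, the x1 coordinate relaxes to a stable
root of F1 independently of x2; the basal (B) and stem-like (S) states
share the *same* high-x1 root, so their interconversion is governed by the
one-variable dynamics of x2 with x1 clamped at that root ``x0``::

    dx2/dt = F2(x0, x2) = -U'(x2),

a gradient flow in the double-well potential ``U(x0, x2)``.  For the
default Hill coefficient n = 4 the antiderivative of -F2 has a closed
form combining an arctangent and a logarithm (from integrating
x^4/(theta^4 + x^4)); for other n the potential is obtained by adaptive
quadrature of -F2.

Three estimates of the mean first-passage time (MFPT) are provided:

* the exact double integral for a 1-D diffusion with stationary density
  P_st ∝ exp(-U/D) and a reflecting origin,
* the steepest-descent (Kramers) approximation
  tau = 2*pi / sqrt(|U''(min) U''(saddle)|) * exp(dU / D),
* Monte-Carlo sampling of the clamped Langevin dynamics (in
  :mod:`triphen.stochastic`).

The crossing noise intensity D_c at which tau_BS = tau_SB reverses the
preferred switching direction; for the Kramers estimate it has the closed
form D_c = (dU_B - dU_S) / (0.5 * ln(U''_B / U''_S)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model import ModelParams, hill_derivative
from .steady_state import BracketError, _x1_roots, _x2_roots

__all__ = [
    "MfptResult",
    "ReducedPotential",
    "BarrierHeights",
    "NotBistableError",
    "stationary_x1",
    "reduced_potential",
    "mfpt_integral",
    "mfpt_kramers",
    "barrier_heights",
    "barrier_heights_from_profile",
    "stationary_density_1d",
    "find_noise_threshold",
    "closed_form_noise_threshold",
]


class NotBistableError(ValueError):
    """The reduced potential does not have two minima at these parameters."""


@dataclass(frozen=True)
class MfptResult:
    """A mean first-passage time with its provenance.

    ``uncertainty`` is 0 for the deterministic methods (integral, kramers)
    and the replicate standard error for Monte-Carlo estimates.
    """

    value: float
    method: str  # "integral" | "kramers" | "monte-carlo"
    direction: tuple[str, str]
    D: float
    uncertainty: float = 0.0
    n_samples: int = 0
    n_censored: int = 0
    warning: str | None = None


@dataclass(frozen=True)
class BarrierHeights:
    """Potential differences between the saddle u1 and the two minima."""

    dU_u1B: float
    dU_u1S: float
    source: str  # "deterministic" | "effective"


def stationary_x1(params: ModelParams, branch: str = "high"):
    """Stable root(s) of F1 (the clamp level x0 for the 1-D reduction).

    ``branch`` selects ``"low"``, ``"high"`` (the root shared by the B and
    S states) or ``"all"`` (every stable root, ascending).
    """
    roots = _x1_roots(params, 400, 1e-12)
    stable = [x for x in roots
              if params.a1 * hill_derivative(x, params.theta, params.n)
              - params.k1 < 0]
    if not stable:
        raise RuntimeError("no stable root of F1 found")
    if branch == "all":
        return stable
    if branch not in ("low", "high"):
        raise ValueError(f"unknown branch {branch!r}; use 'low', 'high' or 'all'")
    want = [x for x in stable
            if (x < params.theta) == (branch == "low")]
    if not want:
        present = {("low" if x < params.theta else "high"): x for x in stable}
        raise ValueError(
            f"x1 has no stable {branch} branch here; present: "
            + ", ".join(f"{k} at {v:.6g}" for k, v in present.items()))
    return want[0] if branch == "low" else want[-1]


class ReducedPotential:
    """Double-well potential of the x2 dynamics at clamped x1 = x0.

    Attributes ``x2_B`` and ``x2_S`` are the low/high minima (basal and
    stem-like expression levels of x2), ``x2_u`` the interior maximum (the
    saddle u1 of the 2-D system), with analytic curvatures ``curv_B``,
    ``curv_S`` (positive) and ``curv_u`` (negative).
    """

    def __init__(self, params: ModelParams, x0: float):
        if x0 < 0:
            raise ValueError("x0 must be >= 0")
        self.params = params
        self.x0 = float(x0)
        p = params
        self._inh = p.b2 * p.theta**p.n / (p.theta**p.n + x0**p.n)
        crit = _x2_roots(params, x0, 600, 1e-12)
        if len(crit) < 3:
            raise NotBistableError(
                f"reduced potential at x0={x0:.6g} has stationary points "
                f"{crit}; two minima are required for first-passage theory")
        if len(crit) > 3:  # keep the dominant triple (deepest wells)
            crit = crit[:3]
        self.x2_B, self.x2_u, self.x2_S = crit
        self.curv_B = self.curvature(self.x2_B)
        self.curv_u = self.curvature(self.x2_u)
        self.curv_S = self.curvature(self.x2_S)
        if not (self.curv_B > 0 and self.curv_S > 0 and self.curv_u < 0):
            raise NotBistableError(
                "stationary points are not an ordered minimum/maximum/minimum "
                f"triple: curvatures ({self.curv_B:.3g}, {self.curv_u:.3g}, "
                f"{self.curv_S:.3g})")

    # -- potential ---------------------------------------------------------

    def __call__(self, x):
        """Potential U(x0, x); U' = -F2(x0, .)."""
        p = self.params
        if p.n == 4:
            return self._closed_form(np.asarray(x, float))
        return self._numeric(np.asarray(x, float))

    def _closed_form(self, x):
        # antiderivative of a2*x^4/(th^4+x^4) is
        #   a2*[x - th/(2 sqrt 2) * (arctan((x^2-th^2)/(sqrt2 th x))
        #       - 1/2 ln((x^2-sqrt2 th x+th^2)/(x^2+sqrt2 th x+th^2)))] + C
        # so U collects the arctan/log pair, the quadratic decay term and
        # the linear production term -(b2*th^4/(th^4+x0^4) + a2) x.
        p = self.params
        th = p.theta
        s2 = np.sqrt(2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            atan = np.where(x > 0,
                            np.arctan((x * x - th * th) / (s2 * th * np.where(x > 0, x, 1.0))),
                            -np.pi / 2)
            lg = np.where(
                x > 0,
                np.log((x * x - s2 * th * x + th * th)
                       / (x * x + s2 * th * x + th * th)),
                0.0,
            )
        u = (p.a2 * th / (2 * s2) * (atan - 0.5 * lg)
             + 0.5 * p.k2 * x * x - (self._inh + p.a2) * x)
        return u if np.ndim(u) else float(u)

    def _numeric(self, x):
        scalar = np.ndim(x) == 0
        xs = np.atleast_1d(x)
        out = np.array([quad(lambda t: -self.force(t), 0.0, xi,
                             limit=200)[0] for xi in xs])
        return float(out[0]) if scalar else out

    def force(self, x):
        """F2(x0, x) = -U'(x)."""
        p = self.params
        xn = np.power(np.asarray(x, float), p.n)
        f = p.a2 * xn / (p.theta**p.n + xn) + self._inh - p.k2 * np.asarray(x, float)
        return f if np.ndim(f) else float(f)

    def curvature(self, x):
        """U''(x) = k2 - a2 * h'(x)."""
        p = self.params
        return p.k2 - p.a2 * hill_derivative(x, p.theta, p.n)

    # -- convenience -------------------------------------------------------

    def minimum(self, label: str) -> tuple[float, float]:
        """(location, curvature) of the ``"B"`` or ``"S"`` minimum."""
        if label == "B":
            return self.x2_B, self.curv_B
        if label == "S":
            return self.x2_S, self.curv_S
        raise ValueError(f"label must be 'B' or 'S', got {label!r}")


def reduced_potential(params: ModelParams, x0: float) -> ReducedPotential:
    """Build the reduced double-well potential at clamp level ``x0``."""
    return ReducedPotential(params, x0)


def barrier_heights(potential: ReducedPotential) -> BarrierHeights:
    """Saddle-minus-minimum potential differences of the deterministic well."""
    uu = potential(potential.x2_u)
    return BarrierHeights(uu - potential(potential.x2_B),
                          uu - potential(potential.x2_S),
                          source="deterministic")


def barrier_heights_from_profile(x: np.ndarray, u: np.ndarray) -> BarrierHeights:
    """Barriers read off a sampled effective-potential section (e.g. -ln P_st).

    Locates the interior maximum between the two lowest local minima of the
    profile; masked (non-finite) cells are ignored.
    """
    x = np.asarray(x, float)
    u = np.asarray(u, float)
    ok = np.isfinite(u)
    x, u = x[ok], u[ok]
    if len(u) < 5:
        raise ValueError("profile too short to locate a double well")
    interior = np.arange(1, len(u) - 1)
    mins = interior[(u[1:-1] < u[:-2]) & (u[1:-1] <= u[2:])]
    if len(mins) < 2:
        raise NotBistableError("profile does not show two local minima")
    mins = sorted(sorted(mins, key=lambda i: u[i])[:2])
    lo, hi = mins
    isad = lo + int(np.argmax(u[lo:hi + 1]))
    return BarrierHeights(float(u[isad] - u[lo]), float(u[isad] - u[hi]),
                          source="effective")


def stationary_density_1d(potential: ReducedPotential, D: float,
                          x: np.ndarray) -> np.ndarray:
    """Normalised stationary density exp(-U/D) of the reduced dynamics.

    Solves the zero-flux stationary form of the 1-D Fokker-Planck equation
    on the given grid (trapezoidal normalisation).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    x = np.asarray(x, float)
    u = potential(x)
    w = np.exp(-(u - u.min()) / D)
    z = np.trapezoid(w, x)
    return w / z


def _upper_cutoff(potential: ReducedPotential, D: float) -> float:
    """x above which exp(-U/D) is negligible (40 D above the S well)."""
    target = potential(potential.x2_S) + 40.0 * D
    x = potential.x2_S
    step = 0.5
    while potential(x) < target:
        x += step
        if x > potential.x2_S + 50:  # pragma: no cover - defensive
            break
    return x


def mfpt_integral(potential: ReducedPotential, D: float,
                  y1: float, y2: float) -> MfptResult:
    """Exact MFPT double integral for the reduced 1-D diffusion.

    tau = int_{y1}^{y2} dy / (D P_st(y)) * int_lower^y P_st(k) dk with
    P_st ∝ exp(-U/D).  The lower limit is the reflecting origin 0 (the
    density is negligible below 0 anyway); for passages towards smaller x2
    the mirrored form with the upper reflecting cutoff is used.  The
    exponentials are shifted by a common reference so the two factors never
    overflow separately.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if y1 == y2:
        raise ValueError("y1 and y2 must differ")
    uref = min(potential(y1), potential(y2))

    def wplus(y):  # ∝ 1 / P_st
        return np.exp((potential(y) - uref) / D)

    def wminus(y):  # ∝ P_st
        return np.exp(-(potential(y) - uref) / D)

    if y1 < y2:
        def outer(y):
            inner = quad(wminus, 0.0, y, limit=200)[0]
            return wplus(y) * inner / D
        val, _ = quad(outer, y1, y2, limit=200)
    else:
        ub = _upper_cutoff(potential, D)

        def outer(y):
            inner = quad(wminus, y, ub, limit=200)[0]
            return wplus(y) * inner / D
        val, _ = quad(outer, y2, y1, limit=200)
    if not np.isfinite(val):
        raise FloatingPointError(
            "MFPT quadrature overflowed (barrier/D too large); "
            "use the kramers method")
    direction = ("B", "S") if y1 < y2 else ("S", "B")
    return MfptResult(float(val), "integral", direction, D)


def mfpt_kramers(potential: ReducedPotential, D: float,
                 direction: str = "BS") -> MfptResult:
    """Steepest-descent (Kramers) MFPT over the reduced double well.

    tau = 2 pi / sqrt(|U''(min) U''(saddle)|) * exp((U(saddle)-U(min))/D).
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    if direction not in ("BS", "SB"):
        raise ValueError("direction must be 'BS' or 'SB'")
    src = direction[0]
    xm, curv = potential.minimum(src)
    du = potential(potential.x2_u) - potential(xm)
    pref = 2.0 * np.pi / np.sqrt(abs(curv * potential.curv_u))
    return MfptResult(float(pref * np.exp(du / D)), "kramers",
                      (direction[0], direction[1]), D)


def closed_form_noise_threshold(potential: ReducedPotential) -> float:
    """D_c of the Kramers estimates: (dU_B - dU_S) / (ln(U''_B/U''_S)/2).

    Derived by equating the two Kramers times; raises for a symmetric well
    (equal curvatures), where the times never cross.
    """
    bh = barrier_heights(potential)
    denom = 0.5 * np.log(potential.curv_B / potential.curv_S)
    if denom == 0.0:
        raise BracketError(
            "symmetric double well: tau_BS and tau_SB coincide for every D; "
            "no crossing exists")
    return float((bh.dU_u1B - bh.dU_u1S) / denom)


def find_noise_threshold(
    potential: ReducedPotential,
    D_bracket: tuple[float, float] = (0.05, 0.12),
    method: str = "kramers",
) -> float:
    """Noise intensity at which tau_BS(D) = tau_SB(D), by bisection.

    Below the threshold the S -> B passage is faster (the cell prefers the
    basal state); above it the direction reverses.
    """
    if method == "kramers":
        def gap(D):
            return (mfpt_kramers(potential, D, "BS").value
                    - mfpt_kramers(potential, D, "SB").value)
    elif method == "integral":
        def gap(D):
            return (mfpt_integral(potential, D, potential.x2_B,
                                  potential.x2_S).value
                    - mfpt_integral(potential, D, potential.x2_S,
                                    potential.x2_B).value)
    else:
        raise ValueError("method must be 'kramers' or 'integral'")
    lo, hi = D_bracket
    glo, ghi = gap(lo), gap(hi)
    if glo == 0.0 and ghi == 0.0:
        raise BracketError(
            "tau_BS and tau_SB coincide at both bracket ends (symmetric "
            "well): the crossing is degenerate, no threshold exists")
    if glo == 0.0:
        return float(lo)
    if ghi == 0.0:
        return float(hi)
    if np.sign(glo) == np.sign(ghi):
        table = "; ".join(
            f"D={d:.4g}: tau_BS-tau_SB={gap(d):.4g}"
            for d in np.linspace(lo, hi, 5))
        raise BracketError(
            f"tau_BS - tau_SB does not change sign on [{lo}, {hi}] ({table}); "
            "widen the bracket")
    return float(brentq(gap, lo, hi, xtol=1e-10))
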