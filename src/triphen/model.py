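"""Core two-gene regulatory kinetics.

The model describes the mutual regulation of the EMT transcription factor
ZEB1 (``x1``) and E-cadherin (``x2``) in a single breast-cancer cell, in
dimensionless form::

    dx1/dt = a1 * x1^n / (theta^n + x1^n) + b1 - k1*x1          = F1(x1)
    dx2/dt = a2 * x2^n / (theta^n + x2^n)
             + b2 * theta^n / (theta^n + x1^n) - k2*x2          = F2(x1, x2)

Gene 1 self-activates through a Hill function and is produced at a basal
rate ``b1``; gene 2 self-activates and is additionally repressed by gene 1
(strength ``b2``).  Both decay linearly.  The drift is *triangular*: F1
does not depend on ``x2``, which every downstream solver exploits.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "hill_activation",
    "hill_derivative",
    "drift",
    "jacobian",
    "invariant_box",
]


@dataclass(frozen=True)
class ModelParams:
    """The eight kinetic constants of the two-gene circuit.

    ``a1``/``a2`` are the self-activation rates of genes 1 (zeb1) and 2
    (cdh1); ``b1`` is the basal production rate of gene 1; ``b2`` the
    strength of the repression of gene 2 by gene 1; ``k1``/``k2`` linear
    degradation rates; ``theta`` the Hill threshold shared by all
    regulation terms; ``n`` the Hill coefficient (any real > 0).

    All quantities are dimensionless.
    """

    a1: float
    a2: float
    b1: float = 0.2
    b2: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    theta: float = 0.5
    n: float = 4.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "k1", "k2", "theta", "n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("b1", "b2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with some fields replaced (e.g. for parameter scans)."""
        return replace(self, **kw)


def hill_activation(x, theta: float, n: float):
    """Sigmoidal activation ``x^n / (theta^n + x^n)``.

    Accepts scalars or arrays; ``x`` must be non-negative, ``theta`` and
    ``n`` strictly positive.  ``x = 0`` returns the limit 0 for every
    ``n > 0``; non-integer ``n`` is evaluated through real powers.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_activation requires x >= 0")
    if not (theta > 0 and n > 0):
        raise ValueError("hill_activation requires theta > 0 and n > 0")
    xn = np.power(x, n)
    out = xn / (theta**n + xn)
    return out if out.ndim else float(out)


def hill_derivative(x, theta: float, n: float):
    """d/dx of :func:`hill_activation`: ``n theta^n x^(n-1) / (theta^n + x^n)^2``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_derivative requires x >= 0")
    tn = theta**n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            x > 0, n * tn * np.power(x, n - 1) / (tn + np.power(x, n)) ** 2, 0.0
        )
    # limit at 0 is 0 for n > 1, 1/theta for n == 1, +inf for n < 1
    if n == 1:
        out = np.where(x == 0, 1.0 / theta, out)
    elif n < 1:
        out = np.where(x == 0, np.inf, out)
    return out if out.ndim else float(out)


def drift(state, params: ModelParams):
    """Deterministic velocity ``(F1, F2)`` at ``state = (x1, x2)``.

    ``state`` may be a pair of scalars or a pair of equally shaped arrays.
    F1 depends only on x1 (skew-product structure).
    """
    x1, x2 = np.asarray(state[0], float), np.asarray(state[1], float)
    p = params
    f1 = p.a1 * hill_activation(x1, p.theta, p.n) + p.b1 - p.k1 * x1
    inh = p.theta**p.n / (p.theta**p.n + np.power(x1, p.n))
    f2 = p.a2 * hill_activation(x2, p.theta, p.n) + p.b2 * inh - p.k2 * x2
    if np.ndim(f1) == 0:
        return float(f1), float(f2)
    return f1, f2


def jacobian(state, params: ModelParams) -> np.ndarray:
    """2x2 matrix of partial derivatives of the drift at ``state``.

    Lower-triangular because F1 is independent of x2; the eigenvalues are
    therefore the two diagonal entries.
    """
    x1, x2 = float(state[0]), float(state[1])
    p = params
    tn = p.theta**p.n
    j11 = p.a1 * hill_derivative(x1, p.theta, p.n) - p.k1
    j21 = (
        -p.b2 * p.n * tn * x1 ** (p.n - 1) / (tn + x1**p.n) ** 2 if x1 > 0 else 0.0
    )
    j22 = p.a2 * hill_derivative(x2, p.theta, p.n) - p.k2
    return np.array([[j11, 0.0], [j21, j22]])


def invariant_box(params: ModelParams) -> tuple[tuple[float, float], tuple[float, float]]:
    """Rectangle ``[0, (a1+b1)/k1] x [0, (a2+b2)/k2]`` that traps all trajectories.

    Outside it each velocity component points inward, because the Hill and
    repression terms are bounded by their maxima while degradation grows
    linearly.
    """
    p = params
    return (0.0, (p.a1 + p.b1) / p.k1), (0.0, (p.a2 + p.b2) / p.k2)
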