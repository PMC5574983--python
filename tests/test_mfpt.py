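import numpy as np
import pytest

from triphen import (
    BracketError,
    NotBistableError,
    barrier_heights,
    barrier_heights_from_profile,
    closed_form_noise_threshold,
    drift,
    find_noise_threshold,
    mfpt_integral,
    mfpt_kramers,
    reduced_potential,
    stationary_density_1d,
    stationary_x1,
)

from conftest import ORACLE_REDUCED

# Frozen oracle values at the reference point (numerical quadrature /
# bracketing oracles, see conftest): barrier heights of the reduced well
# and the Kramers crossing noise intensity.
ORACLE_BARRIERS = (0.0342724305, 0.0112069050)
ORACLE_DC = 0.0827723655


def test_stationary_x1_branches(params):
    lo = stationary_x1(params, "low")
    hi = stationary_x1(params, "high")
    assert lo == pytest.approx(0.2409107754260, abs=1e-9)
    assert hi == pytest.approx(0.9409199919319, abs=1e-9)
    assert stationary_x1(params, "all") == pytest.approx([lo, hi])
    for x in (lo, hi):
        assert abs(drift((x, 0.5), params)[0]) <= 1e-10


def test_stationary_x1_missing_branch_errors(params):
    # a1 = 0.3 is monostable on the low branch: no high branch exists
    with pytest.raises(ValueError, match="branch"):
        stationary_x1(params.with_(a1=0.3), "high")
    assert stationary_x1(params.with_(a1=0.3), "low") < 0.5
    with pytest.raises(ValueError):
        stationary_x1(params, "sideways")


def test_closed_form_is_antiderivative_of_minus_drift(params, potential):
    """The arctan/log potential differentiates back to -F2 everywhere."""
    xs = np.linspace(0.01, 2.0, 1000)
    h = 1e-6
    du = (potential(xs + h) - potential(xs - h)) / (2 * h)
    f2 = np.array([drift((potential.x0, x), params)[1] for x in xs])
    assert np.max(np.abs(du + f2)) < 1e-8


def test_numeric_potential_used_for_other_hill_coefficients(params):
    p = params.with_(n=3.5, a1=0.9)
    x0 = stationary_x1(p, "high")
    pot = reduced_potential(p, x0)
    h = 1e-5
    for x in (0.2, 0.6, 1.1):
        du = (pot(x + h) - pot(x - h)) / (2 * h)
        assert du == pytest.approx(-pot.force(x), abs=1e-6)


def test_reduced_potential_stationary_points(potential):
    assert potential.x2_B == pytest.approx(ORACLE_REDUCED["x2_B"], abs=1e-9)
    assert potential.x2_u == pytest.approx(ORACLE_REDUCED["x2_u"], abs=1e-9)
    assert potential.x2_S == pytest.approx(ORACLE_REDUCED["x2_S"], abs=1e-9)
    assert potential.curv_B > 0 and potential.curv_S > 0
    assert potential.curv_u < 0


def test_reduced_potential_errors_when_monostable(params):
    p = params.with_(a1=0.3, a2=0.8)
    with pytest.raises(NotBistableError):
        reduced_potential(p, stationary_x1(p, "low"))


def test_barrier_heights_against_quadrature_oracle(potential):
    bh = barrier_heights(potential)
    assert bh.dU_u1B == pytest.approx(ORACLE_BARRIERS[0], abs=1e-8)
    assert bh.dU_u1S == pytest.approx(ORACLE_BARRIERS[1], abs=1e-8)
    assert bh.dU_u1B >= 0 and bh.dU_u1S >= 0


def test_larger_barrier_means_larger_kramers_time(potential):
    # dU_u1B > dU_u1S, so escaping B takes longer at small D
    assert (mfpt_kramers(potential, 0.02, "BS").value
            > mfpt_kramers(potential, 0.02, "SB").value)


def test_mfpt_integral_grows_as_noise_vanishes(potential):
    taus = [mfpt_integral(potential, d, potential.x2_B, potential.x2_S).value
            for d in (0.2, 0.1, 0.05)]
    assert taus[0] < taus[1] < taus[2]


def test_kramers_exponential_structure(potential):
    """log tau is affine in 1/D with slope equal to the barrier height."""
    ds = np.array([0.02, 0.04, 0.06, 0.08])
    lt = np.log([mfpt_kramers(potential, d, "BS").value for d in ds])
    slope, intercept = np.polyfit(1.0 / ds, lt, 1)
    assert slope == pytest.approx(barrier_heights(potential).dU_u1B, abs=1e-10)
    pref = 2 * np.pi / np.sqrt(potential.curv_B * abs(potential.curv_u))
    assert intercept == pytest.approx(np.log(pref), abs=1e-10)
    resid = lt - (slope / ds + intercept)
    assert np.max(np.abs(resid)) < 1e-10


def test_integral_approaches_kramers_at_small_noise(potential):
    devs = []
    for d in (0.05, 0.03, 0.02):
        ratio = (mfpt_integral(potential, d, potential.x2_B, potential.x2_S).value
                 / mfpt_kramers(potential, d, "BS").value)
        devs.append(abs(1.0 - ratio))
    assert devs[0] > devs[1] > devs[2]
    assert 0.8 < 1.0 - devs[2] < 1.25


def test_noise_threshold_bisection_matches_closed_form(potential):
    dc_closed = closed_form_noise_threshold(potential)
    dc_bisect = find_noise_threshold(potential, (0.05, 0.12), method="kramers")
    assert abs(dc_closed - dc_bisect) < 1e-6
    assert dc_bisect == pytest.approx(ORACLE_DC, abs=1e-8)


def test_noise_threshold_reports_missing_crossing(potential):
    with pytest.raises(BracketError):
        find_noise_threshold(potential, (0.005, 0.02))


class _SymmetricWell:
    """Quartic double well with equal barriers and curvatures."""

    x2_B, x2_u, x2_S = -1.0, 0.0, 1.0
    curv_B = curv_S = 8.0
    curv_u = -4.0

    def __call__(self, x):
        x = np.asarray(x, float)
        return x**4 - 2 * x**2

    def minimum(self, label):
        return (self.x2_B, self.curv_B) if label == "B" else (self.x2_S, self.curv_S)


def test_symmetric_well_has_no_threshold():
    pot = _SymmetricWell()
    assert (mfpt_kramers(pot, 0.07, "BS").value
            == mfpt_kramers(pot, 0.07, "SB").value)
    with pytest.raises(BracketError):
        closed_form_noise_threshold(pot)
    with pytest.raises(BracketError):
        find_noise_threshold(pot, (0.05, 0.12))


def test_switching_direction_reverses_at_threshold(potential):
    """Below D_c the stem-to-basal passage is faster; above it the order flips."""
    dc = closed_form_noise_threshold(potential)
    below, above = 0.8 * dc, 1.25 * dc
    assert (mfpt_kramers(potential, below, "SB").value
            < mfpt_kramers(potential, below, "BS").value)
    assert (mfpt_kramers(potential, above, "SB").value
            > mfpt_kramers(potential, above, "BS").value)


def test_stationary_density_peaks_at_minima(potential):
    xs = np.linspace(0.0, 2.0, 2001)
    p = stationary_density_1d(potential, 0.05, xs)
    assert np.trapezoid(p, xs) == pytest.approx(1.0, abs=1e-10)
    for xmin in (potential.x2_B, potential.x2_S):
        i = np.argmin(np.abs(xs - xmin))
        lo, hi = max(0, i - 40), i + 40
        assert abs(xs[np.argmax(p[lo:hi]) + lo] - xmin) < 0.01


def test_effective_potential_barriers_scale_inversely_with_noise(potential):
    """-ln P_st sections reproduce the deterministic barriers divided by D."""
    xs = np.linspace(0.0, 2.0, 4001)
    for D in (0.02, 0.05):
        u_eff = -np.log(stationary_density_1d(potential, D, xs))
        bh = barrier_heights_from_profile(xs, u_eff)
        det = barrier_heights(potential)
        assert bh.dU_u1B == pytest.approx(det.dU_u1B / D, rel=1e-3)
        assert bh.dU_u1S == pytest.approx(det.dU_u1S / D, rel=1e-3)


def test_profile_barriers_reject_single_well():
    xs = np.linspace(-1, 1, 100)
    with pytest.raises(NotBistableError):
        barrier_heights_from_profile(xs, xs**2)
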