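import itertools

import numpy as np
import pytest

from triphen import (
    BracketError,
    ModelParams,
    bifurcation_scan,
    classify_phenotype,
    critical_hill,
    drift,
    find_fixed_points,
    phase_diagram,
    relax,
)
from triphen.steady_state import _tristable_anywhere

from conftest import ORACLE_SADDLES, ORACLE_STABLE


def test_tristable_census_at_reference_point(fixed_points):
    """Three attractors (L, B, S) and two saddles at a1=0.8, a2=0.85."""
    stable = [fp for fp in fixed_points if fp.stability == "stable"]
    saddles = [fp for fp in fixed_points if fp.stability == "saddle"]
    assert len(fixed_points) == 5
    assert len(stable) == 3 and len(saddles) == 2
    assert sorted(fp.phenotype for fp in stable) == ["B", "L", "S"]


def test_fixed_point_locations_match_oracle(fixed_points):
    by_pheno = {fp.phenotype: fp for fp in fixed_points if fp.stability == "stable"}
    for name, (x1, x2) in ORACLE_STABLE.items():
        assert by_pheno[name].x1 == pytest.approx(x1, abs=1e-8)
        assert by_pheno[name].x2 == pytest.approx(x2, abs=1e-8)
    saddles = sorted(fp.location for fp in fixed_points if fp.stability == "saddle")
    for got, want in zip(saddles, sorted(ORACLE_SADDLES)):
        assert got == pytest.approx(want, abs=1e-8)


def test_residual_and_eigenvalue_consistency(fixed_points, params):
    for fp in fixed_points:
        f1, f2 = drift(fp.location, params)
        assert max(abs(f1), abs(f2)) < 1e-8
        if fp.stability == "stable":
            assert all(ev < 0 for ev in fp.eigenvalues)
        elif fp.stability == "saddle":
            assert fp.eigenvalues[0] * fp.eigenvalues[1] < 0


def test_basal_and_stem_share_x1(fixed_points):
    by_pheno = {fp.phenotype: fp for fp in fixed_points if fp.stability == "stable"}
    assert abs(by_pheno["B"].x1 - by_pheno["S"].x1) <= 1e-9


def test_seed_density_invariance(params, fixed_points):
    again = find_fixed_points(params, seeds_per_axis=800)
    assert len(again) == len(fixed_points)
    for a, b in zip(again, fixed_points):
        assert a.location == pytest.approx(b.location, abs=1e-7)
        assert a.stability == b.stability


def test_stable_points_confirmed_by_forward_integration(params, fixed_points):
    stable = [fp for fp in fixed_points if fp.stability == "stable"]
    starts = np.array([np.array(fp.location) + 1e-3 for fp in stable])
    ends = relax(params, starts, t_end=80.0, dt=0.02)
    for fp, end in zip(stable, ends):
        assert np.max(np.abs(end - np.array(fp.location))) < 1e-4


def test_stability_alternates_along_x2(fixed_points):
    branch = sorted(
        (fp for fp in fixed_points if abs(fp.x1 - 0.9409199919319) < 1e-6),
        key=lambda fp: fp.x2,
    )
    assert [fp.stability for fp in branch] == ["stable", "saddle", "stable"]


def test_monostable_basal_at_strong_zeb1_activation(params):
    fps = find_fixed_points(params.with_(a1=0.95, a2=0.8))
    stable = [fp for fp in fps if fp.stability == "stable"]
    assert len(stable) == 1 and stable[0].phenotype == "B"


def test_classify_phenotype_requires_stability(fixed_points, params):
    saddle = next(fp for fp in fixed_points if fp.stability == "saddle")
    assert classify_phenotype(saddle, params) == "none"
    stable = next(fp for fp in fixed_points if fp.phenotype == "L")
    assert classify_phenotype(stable, params) == "L"


@pytest.mark.parametrize(
    "a1, a2, region",
    [(0.8, 0.85, "LBS"), (0.3, 0.8, "L"), (0.95, 0.8, "B")],
)
def test_phase_diagram_region_codes(params, a1, a2, region):
    pm = phase_diagram(params, ("a1", np.array([a1])), ("a2", np.array([a2])))
    assert pm.cell_label[0, 0] == region


def test_phase_diagram_rejects_unknown_parameter(params):
    with pytest.raises(KeyError):
        phase_diagram(params, ("zzz", np.array([0.5])), ("a2", np.array([0.8])))


def test_bifurcation_sweep_region_sequence(params):
    """Sweeping the TGF-beta proxy a1 down from 0.95 crosses B, LB, LBS, LS, L."""
    br = bifurcation_scan(params.with_(a2=0.8), "a1", np.linspace(0.3, 0.95, 131))
    counts = [sum(fp.stability == "stable" for fp in fps) for fps in br.points]
    assert [k for k, _ in itertools.groupby(counts)] == [1, 2, 3, 2, 1]
    codes = [k for k, _ in itertools.groupby(br.region_codes)]
    assert codes == ["L", "LS", "LBS", "LB", "B"]  # increasing a1


def test_tristability_present_at_default_hill_absent_at_two(params):
    a_grid = np.linspace(0.05, 2.0, 40)
    assert _tristable_anywhere(params, 4.0, a_grid, a_grid, seeds=240)
    assert not _tristable_anywhere(params, 2.0, a_grid, a_grid, seeds=240)


def test_critical_hill_demands_straddling_bracket(params):
    with pytest.raises(BracketError):
        critical_hill(params, n_bracket=(2.0, 2.5), grid_points=40)


def test_critical_hill_localises_the_transition(params):
    nc = critical_hill(params, n_bracket=(2.0, 4.0), grid_points=40, tol=0.05)
    assert not _tristable_anywhere(params, nc - 0.05,
                                   np.linspace(0.05, 2.0, 40),
                                   np.linspace(0.05, 2.0, 40), seeds=240)
    assert _tristable_anywhere(params, nc,
                               np.linspace(0.05, 2.0, 40),
                               np.linspace(0.05, 2.0, 40), seeds=240)
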