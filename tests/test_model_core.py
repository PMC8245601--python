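"""Single-cell model: currents, gates, gap conductance, equilibria, basins."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from depolwave.model_core import (CellParameters, STANDARD,
                                  cell_gate_conductance,
                                  depolarization_current, find_equilibria,
                                  integrate_single_cell, pair_conductance,
                                  polarization_current, single_cell_rhs)

# closed-form oracle values, computed directly from the current definitions
I_DEP_AT_M60 = 2.0 * (-60.0) / (1.0 + math.exp(102.0 / 26.0))      # -2.3276 pA
I_POL_AT_0 = 60.0 / (1.0 + math.exp(3.0))                          # 2.8456 pA
G_GATE_AT_M60 = 1.5 / (1.0 + math.exp(-180.0 / 26.0))              # 1.49852 nS


@pytest.mark.parametrize("V,expected", [
    (0.0, 0.0),                  # zero driving force at E_dep
    (-26.0, -26.0),              # sigmoid midpoint: 2*(-26)/2
    (-60.0, I_DEP_AT_M60),
])
def test_depolarization_current_values(V, expected):
    assert depolarization_current(V, STANDARD) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("V,expected", [
    (-60.0, 0.0),                # zero driving force at E_pol
    (-26.0, 17.0),               # sigmoid midpoint: 1*34/2
    (0.0, I_POL_AT_0),
])
def test_polarization_current_values(V, expected):
    assert polarization_current(V, STANDARD) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("V,expected", [
    (0.0, 0.75),                 # V = V_half: half of G0_max
    (-60.0, G_GATE_AT_M60),
    (1e4, 0.0),                  # gate fully closed in the depolarized limit
])
def test_cell_gate_conductance_values(V, expected):
    assert cell_gate_conductance(V, STANDARD) == pytest.approx(expected, abs=1e-9)


def test_pair_conductance_chain():
    # identical polarized pair: series of equal conductances, cosh(0) = 1
    g = cell_gate_conductance(-60.0, STANDARD)
    assert pair_conductance(-60.0, -60.0, STANDARD, STANDARD) == \
        pytest.approx(g / 2.0, rel=1e-12)
    # mixed pair, full chain evaluated independently
    gi, gj = G_GATE_AT_M60, 0.75
    series = gi * gj / (gi + gj)
    expected = 2.0 * series / (1.0 + math.cosh(-60.0 / 24.0))
    assert pair_conductance(-60.0, 0.0, STANDARD, STANDARD) == \
        pytest.approx(expected, rel=1e-12)


def test_pair_conductance_both_gates_zero():
    p = CellParameters(G0_max=0.0)
    assert pair_conductance(-60.0, 0.0, p, p) == 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(vi=st.floats(-200, 200), vj=st.floats(-200, 200),
       gmax_i=st.floats(0.1, 5.0), gmax_j=st.floats(0.1, 5.0))
def test_pair_conductance_symmetry_and_bounds(vi, vj, gmax_i, gmax_j):
    pi = CellParameters(G0_max=gmax_i)
    pj = CellParameters(G0_max=gmax_j)
    gij = pair_conductance(vi, vj, pi, pj)
    gji = pair_conductance(vj, vi, pj, pi)
    assert gij == gji  # exact symmetry under the simultaneous swap
    gi = cell_gate_conductance(vi, pi)
    gj = cell_gate_conductance(vj, pj)
    assert 0.0 < gij <= min(gi, gj) + 1e-15


@settings(max_examples=100, deadline=None, derandomize=True)
@given(v=st.floats(-150, 150))
def test_gate_factors_bounded(v):
    p = STANDARD
    # away from the reversal potentials the gate can be recovered from the
    # current without catastrophic cancellation
    assume(abs(v - p.E_dep) > 1e-6 and abs(v - p.E_pol) > 1e-6)
    gate_dep = depolarization_current(v, p) / (p.G0_dep * (v - p.E_dep)) \
        if v != p.E_dep else 0.5
    gate_pol = polarization_current(v, p) / (p.G0_pol * (v - p.E_pol)) \
        if v != p.E_pol else 0.5
    for gate in (gate_dep, gate_pol):
        assert 0.0 < gate < 1.0
    assert 0.0 < cell_gate_conductance(v, p) < p.G0_max


@pytest.mark.parametrize("func", [depolarization_current, polarization_current,
                                  cell_gate_conductance])
def test_nonfinite_voltage_rejected(func):
    with pytest.raises(ValueError):
        func(float("nan"), STANDARD)


def test_single_cell_rhs_examples():
    # midpoint voltage: (26 - 17)/100, pushing toward the depolarized state
    assert single_cell_rhs(-26.0, STANDARD) == pytest.approx(0.09, abs=1e-12)
    assert single_cell_rhs(50.0, STANDARD) < 0.0


def test_parameter_validation():
    with pytest.raises(ValueError):
        CellParameters(C=-1.0).validate()
    with pytest.raises(ValueError):
        CellParameters(E_pol=10.0, E_dep=0.0).validate()
    with pytest.raises(ValueError):
        CellParameters(V_T=0.0).validate()


class TestEquilibria:
    def test_standard_tristability(self):
        roots = find_equilibria(STANDARD)
        assert [k for _, k in roots] == ["stable", "unstable", "stable"]
        vs = [v for v, _ in roots]
        # the polarized/depolarized attractors and the separatrix
        assert vs[0] == pytest.approx(-56.726, abs=1e-2)
        assert vs[1] == pytest.approx(-34.811, abs=1e-2)
        assert vs[2] == pytest.approx(-1.780, abs=1e-2)

    def test_roots_are_roots_and_signs_alternate(self):
        roots = find_equilibria(STANDARD)
        for v, _ in roots:
            assert abs(single_cell_rhs(v, STANDARD)) < 1e-6
        vs = [v for v, _ in roots]
        for lo, hi in zip([-90.0] + vs, vs + [20.0]):
            inner = np.linspace(lo + 1e-3, hi - 1e-3, 200)
            signs = np.sign([single_cell_rhs(v, STANDARD) for v in inner])
            assert len(set(signs)) == 1

    def test_single_channel_limits(self):
        only_pol = find_equilibria(CellParameters(G0_dep=0.0))
        assert len(only_pol) == 1
        v, kind = only_pol[0]
        assert kind == "stable" and v == pytest.approx(-60.0, abs=1e-4)
        only_dep = find_equilibria(CellParameters(G0_pol=0.0))
        assert len(only_dep) == 1
        v, kind = only_dep[0]
        assert kind == "stable" and v == pytest.approx(0.0, abs=1e-4)

    def test_vanishing_channel_continuity(self):
        # the lowest stable root approaches E_pol as G0_dep -> 0
        roots = find_equilibria(CellParameters(G0_dep=1e-6))
        assert roots[0][0] == pytest.approx(-60.0, abs=1e-3)

    def test_monostable_range_returns_empty(self):
        assert find_equilibria(STANDARD, search_range=(10.0, 20.0)) == []


class TestIntegrateSingleCell:
    def test_basins_of_attraction(self):
        for v0, target in [(-34.0, -1.780), (-36.0, -56.726)]:
            _, V = integrate_single_cell(v0, STANDARD, t_end=5000.0, dt=1.0)
            assert V[-1] == pytest.approx(target, abs=0.5)

    def test_fixed_point_stays(self):
        v_star = find_equilibria(STANDARD)[0][0]
        _, V = integrate_single_cell(v_star, STANDARD, t_end=2000.0, dt=1.0)
        assert np.max(np.abs(V - v_star)) < 1e-6

    def test_dt_refinement_order(self):
        # Euler: halving dt roughly halves the endpoint error
        _, v_fine = integrate_single_cell(-30.0, STANDARD, 500.0, dt=0.01,
                                          method="rk4")
        ref = v_fine[-1]
        errs = []
        for dt in (1.0, 0.5):
            _, V = integrate_single_cell(-30.0, STANDARD, 500.0, dt=dt)
            errs.append(abs(V[-1] - ref))
        assert errs[1] < 0.75 * errs[0]

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            integrate_single_cell(-30.0, STANDARD, 100.0, dt=50.0)
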