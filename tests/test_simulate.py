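"""Coupled integrator: oracle agreement, conservation, symmetry, stability."""

import numpy as np
import pytest

from depolwave.model_core import (depolarization_current, pair_conductance,
                                  polarization_current, single_cell_rhs)
from depolwave.perturbations import (InterventionSpec, PerturbationSpec,
                                     apply_perturbation, init_quiescent)
from depolwave.simulate import TissueState, run, step
from depolwave.tissue import (HeterogeneitySpec, LatticeSpec, build_adjacency,
                              sample_parameters)


def brute_force_step(V, fld, lattice, dt):
    """Independent per-cell scalar evaluation of the charge balance."""
    adj = build_adjacency(lattice)
    out = np.empty_like(V)
    flat_V = V.ravel()
    for i, idx in enumerate(np.ndindex(*lattice.shape)):
        p = fld.cell(idx)
        I = -depolarization_current(flat_V[i], p) \
            - polarization_current(flat_V[i], p)
        for j in adj.neighbors(i):
            jdx = np.unravel_index(j, lattice.shape)
            pj = fld.cell(jdx)
            gij = pair_conductance(flat_V[i], flat_V[j], p, pj)
            I += gij * (flat_V[j] - flat_V[i])
        out[idx] = V[idx] + dt / p.C * I
    return out


@pytest.mark.parametrize("kernel", ["fast", "symmetric"])
def test_step_matches_brute_force_oracle(kernel):
    lat = LatticeSpec((3, 3))
    fld = sample_parameters(lat, HeterogeneitySpec(3.0), seed=11)
    rng = np.random.default_rng(12)
    V0 = rng.uniform(-70.0, 5.0, lat.shape)
    expected = brute_force_step(V0, fld, lat, dt=1.0)
    got = step(TissueState(V0), fld, lat, dt=1.0, kernel=kernel)
    np.testing.assert_allclose(got.V, expected, rtol=0, atol=1e-12)


def test_isolated_cell_step_is_single_cell_euler():
    lat = LatticeSpec((1, 1))
    fld = sample_parameters(lat, HeterogeneitySpec(0.0), seed=1)
    v0 = -30.0
    got = step(TissueState(np.full((1, 1), v0)), fld, lat, dt=1.0)
    expected = v0 + 1.0 * single_cell_rhs(v0, fld.cell((0, 0)))
    assert got.V[0, 0] == pytest.approx(expected, abs=1e-14)


def test_equal_voltage_pair_follows_single_cell_dynamics():
    lat = LatticeSpec((1, 2))
    fld = sample_parameters(lat, HeterogeneitySpec(0.0), seed=1)
    got = step(TissueState(np.full((1, 2), -30.0)), fld, lat, dt=1.0)
    expected = -30.0 + single_cell_rhs(-30.0, fld.cell((0, 0)))
    np.testing.assert_allclose(got.V, expected, atol=1e-14)


@pytest.mark.parametrize("kernel", ["fast", "symmetric"])
def test_coupling_conserves_total_charge(kernel):
    lat = LatticeSpec((12, 12))
    fld = sample_parameters(lat, HeterogeneitySpec(3.0), seed=21)
    fld.arrays["G0_dep"][:] = 0.0
    fld.arrays["G0_pol"][:] = 0.0
    rng = np.random.default_rng(22)
    state = TissueState(rng.uniform(-70.0, 0.0, lat.shape))
    q0 = float((fld["C"] * state.V).sum())
    for _ in range(50):
        state = step(state, fld, lat, dt=1.0, kernel=kernel)
    q = float((fld["C"] * state.V).sum())
    assert q == pytest.approx(q0, rel=1e-12)


def test_mirror_symmetry_preserved_exactly():
    # homogeneous tissue, centered noiseless patch: every reflection of the
    # square is preserved bit-for-bit by the symmetric kernel
    lat = LatticeSpec((31, 31))
    fld = sample_parameters(lat, HeterogeneitySpec(0.0), seed=1)
    state = init_quiescent(lat, sd=0.0)
    state = apply_perturbation(
        state, PerturbationSpec("circle", 6, "center", depol_sd=0.0), lat)
    V = state.V
    for _ in range(300):
        V = step(TissueState(V), fld, lat, dt=1.0, kernel="symmetric").V
    assert np.array_equal(V, V[::-1, :])
    assert np.array_equal(V, V[:, ::-1])
    assert np.array_equal(V, V.T)


def test_kernels_agree():
    lat = LatticeSpec((20, 20))
    fld = sample_parameters(lat, HeterogeneitySpec(3.0), seed=31)
    state = init_quiescent(lat, seed=32)
    state = apply_perturbation(state, PerturbationSpec("random_fraction", 0.3),
                               lat, seed=33)
    a = run(lat, fld, state, t_end=200.0, kernel="fast")
    b = run(lat, fld, state, t_end=200.0, kernel="symmetric")
    np.testing.assert_allclose(a.final_state.V, b.final_state.V, atol=1e-10)
    assert np.array_equal(a.depol_counts, b.depol_counts)


def test_dt_refinement(small_lattice, small_field, seeded_state):
    res1 = run(small_lattice, small_field, seeded_state, t_end=2000.0, dt=1.0)
    res2 = run(small_lattice, small_field, seeded_state, t_end=2000.0, dt=0.5)
    assert res1.final_count == res2.final_count
    assert np.max(np.abs(res1.final_state.V - res2.final_state.V)) < 0.5


def test_quiescent_tissue_stays_polarized():
    lat = LatticeSpec((50, 50))
    fld = sample_parameters(lat, HeterogeneitySpec(3.0), seed=41)
    res = run(lat, fld, init_quiescent(lat, seed=42), t_end=3000.0)
    assert res.final_count == 0


def test_voltage_stays_in_physiological_envelope(small_lattice, small_field,
                                                 seeded_state):
    res = run(small_lattice, small_field, seeded_state, t_end=3000.0,
              report_every=100.0)
    V = res.final_state.V
    assert V.min() > -90.0 and V.max() < 20.0
    assert np.all(res.depol_counts >= 0)
    assert np.all(res.depol_counts <= res.n_active)
    assert np.all(np.diff(res.times) > 0)


def test_walls_block_wave_propagation():
    # a fully depolarized slab never flips a cell across an electric wall
    from depolwave.tissue import insert_walls

    lat = insert_walls(LatticeSpec((21, 20)), 1)
    fld = sample_parameters(lat, HeterogeneitySpec(3.0), seed=61)
    state = init_quiescent(lat, seed=62)
    state.V[:10, :] = 0.0  # slab above the wall at row 10
    res = run(lat, fld, state, t_end=2000.0)
    below = res.final_state.V[11:, :]
    assert np.all(below < -35.0)
    above = res.final_state.V[:10, :]
    assert (above > -35.0).mean() > 0.9


def test_intervention_repolarizes_depolarized_tissue():
    lat = LatticeSpec((10, 10))
    fld = sample_parameters(lat, HeterogeneitySpec(3.0), seed=51)
    state = init_quiescent(lat, mean=0.0, sd=3.0, seed=52)
    res = run(lat, fld, state, t_end=3000.0,
              interventions=[InterventionSpec(0.0, factor_pol=4.0)])
    assert res.final_count == 0
    # without the intervention the tissue stays depolarized
    res0 = run(lat, fld, state, t_end=3000.0)
    assert res0.final_count == res0.n_active


def test_snapshots_and_early_stop(small_lattice, small_field, seeded_state):
    res = run(small_lattice, small_field, seeded_state, t_end=500.0,
              snapshot_times=[0.0, 200.0, 500.0])
    assert [t for t, _ in res.snapshots] == [0.0, 200.0, 500.0]
    assert res.snapshots[0][1].shape == small_lattice.shape
    stopped = run(small_lattice, small_field, seeded_state, t_end=5000.0,
                  stop=lambda t, c: "bail" if t >= 300.0 else None)
    assert stopped.outcome == "bail"
    assert stopped.times[-1] == 300.0


def test_unstable_dt_rejected(small_lattice, small_field, seeded_state):
    with pytest.raises(ValueError):
        run(small_lattice, small_field, seeded_state, t_end=100.0, dt=20.0)


def test_nonfinite_state_aborts(small_lattice, small_field):
    V = np.full(small_lattice.shape, -60.0)
    V[3, 3] = np.inf
    with pytest.raises(FloatingPointError):
        run(small_lattice, small_field, TissueState(V), t_end=200.0)
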