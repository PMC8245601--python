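"""Tissue-scale experiments: thresholds, patch minima, front velocity, sweeps.

The central dichotomy is bistable: a perturbed tissue either relaxes back to
the polarized resting state (depolarized count -> 0) or ignites a
depolarization wave that converts the whole electrically connected domain.
Threshold searches bisect over the perturbation size and classify each
replicate by its resolved outcome:

* ``committed`` (random seeding) -- success once the depolarized count
  reaches half the active cells, which at standard parameters is
  irreversible; failure when the count hits zero; 30 s horizon so
  near-threshold runs resolve.
* ``ignition`` (geometric patches) -- success when the count exceeds
  max(5x the initial patch, 2% of the domain) within 10 s, i.e. the patch
  has launched a growing wave rather than being eroded away; failure at
  count zero.  Domain-wide conversion then follows at the front velocity.

Front velocity is measured from planar-front snapshots on a strip: the
front position is the transverse mean of the largest depolarized
coordinate, and the speed is the least-squares slope of position vs time,
converted to mm/s via the cell width (10 um by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .perturbations import (InterventionSpec, PerturbationSpec,
                            apply_perturbation, init_quiescent)
from .simulate import DEPOL_THRESHOLD, SimulationResult, run
from .tissue import (HeterogeneitySpec, LatticeSpec, PARAMETER_MEANS,
                     insert_walls, sample_parameters)

__all__ = [
    "BaseConfig",
    "ThresholdEstimate",
    "VelocityEstimate",
    "run_trial",
    "success_probability",
    "estimate_critical_fraction",
    "estimate_min_patch",
    "front_velocity",
    "measure_front_velocity",
    "repolarization_trial",
    "sensitivity_sweep",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class BaseConfig:
    """Shared experiment configuration: lattice, heterogeneity, integrator."""

    shape: Tuple[int, ...] = (100, 100)
    neighborhood: str = "moore"
    sigma: float = 3.0
    dt: float = 1.0
    t_end: float = 10_000.0
    report_every: float = 100.0
    depol_threshold: float = DEPOL_THRESHOLD
    n_walls: int = 0
    wall_orientation: int = 0
    factor_pol: float = 1.0   # static conductance rescaling of the sampled field
    factor_dep: float = 1.0
    factor_max: float = 1.0
    capacitance_mean: float = PARAMETER_MEANS["C"]

    def lattice(self) -> LatticeSpec:
        lat = LatticeSpec(self.shape, self.neighborhood)
        if self.n_walls:
            lat = insert_walls(lat, self.n_walls, self.wall_orientation)
        return lat

    def heterogeneity(self) -> HeterogeneitySpec:
        return HeterogeneitySpec(sigma=self.sigma)


@dataclass
class ThresholdEstimate:
    """A 50%-success crossing from a bisection search."""

    quantity: str            # "fraction" | "patch_size"
    value: float             # percent (fraction) or cell widths (patch)
    uncertainty: float       # half-width of the final bracket
    replicates: int
    history: List[Tuple[float, float]] = field(default_factory=list)  # (probe, p)


@dataclass
class VelocityEstimate:
    """Front speed with its fit diagnostics."""

    speed_mm_s: float
    cell_width_um: float
    speed_cells_per_s: float
    times_ms: np.ndarray
    positions_cells: np.ndarray
    residual_cells: float    # rms residual of the linear fit


def _trial_seeds(master_seed: int, replicate: int, salt: int = 0):
    ss = np.random.SeedSequence([int(master_seed), int(replicate), int(salt)])
    return ss.spawn(3)


def run_trial(
    bc: BaseConfig,
    perturbation: Optional[PerturbationSpec],
    master_seed: int,
    replicate: int = 0,
    interventions: Sequence[InterventionSpec] = (),
    init_mean: float = -60.0,
    init_sd: float = 3.0,
    stop: Optional[Callable[[float, int], Optional[str]]] = None,
    t_end: Optional[float] = None,
    snapshot_times: Sequence[float] = (),
    salt: int = 0,
) -> SimulationResult:
    """One seeded simulation: sample field, initialize, perturb, integrate.

    The replicate index, not the swept value, determines the seeds, so
    sweeps can use common random numbers across values.
    """
    s_field, s_init, s_pert = _trial_seeds(master_seed, replicate, salt)
    lat = bc.lattice()
    fld = sample_parameters(lat, bc.heterogeneity(), seed=s_field)
    if (bc.factor_pol, bc.factor_dep, bc.factor_max) != (1.0, 1.0, 1.0):
        fld = fld.rescale_conductances(bc.factor_pol, bc.factor_dep, bc.factor_max)
    if bc.capacitance_mean != PARAMETER_MEANS["C"]:
        fld.arrays["C"] *= bc.capacitance_mean / PARAMETER_MEANS["C"]
    state = init_quiescent(lat, mean=init_mean, sd=init_sd, seed=s_init)
    if perturbation is not None:
        state = apply_perturbation(state, perturbation, lat, seed=s_pert)
    return run(
        lat, fld, state,
        interventions=interventions,
        t_end=bc.t_end if t_end is None else t_end,
        dt=bc.dt,
        report_every=bc.report_every,
        snapshot_times=snapshot_times,
        depol_threshold=bc.depol_threshold,
        stop=stop,
    )


# ---------------------------------------------------------------------------
# Success rules
# ---------------------------------------------------------------------------

#: Horizon (ms) for outcome-resolved random-seeding searches.
COMMIT_HORIZON = 30_000.0
#: Committed-success fraction: a depolarized majority never reverts at
#: standard parameters, so reaching it decides the bistable outcome.
COMMIT_FRACTION = 0.5
#: Ignition rule for geometric patches: the wave must exceed this multiple
#: of the initial patch and this fraction of the domain within the horizon.
IGNITION_MULTIPLE = 5.0
IGNITION_DOMAIN_FRACTION = 0.02


def _committed_stop(n_active: int):
    goal = math.ceil(COMMIT_FRACTION * n_active)

    def stop(t: float, c: int):
        if c >= goal:
            return "success"
        if c == 0 and t > 0:
            return "fail"
        return None

    return stop, goal


def _ignition_stop(n_active: int, n_initial: int):
    goal = max(math.ceil(IGNITION_MULTIPLE * max(n_initial, 1)),
               math.ceil(IGNITION_DOMAIN_FRACTION * n_active))

    def stop(t: float, c: int):
        if c >= goal:
            return "success"
        if c == 0 and t > 0:
            return "fail"
        return None

    return stop, goal


def _patch_trial_success(bc: BaseConfig, spec: PerturbationSpec,
                         master_seed: int, replicate: int) -> bool:
    lat = bc.lattice()
    n_active = lat.n_active
    from .perturbations import patch_mask

    n0 = int((patch_mask(lat, spec) & lat.active_mask()).sum())
    stop, goal = _ignition_stop(n_active, n0)
    res = run_trial(bc, spec, master_seed, replicate, stop=stop)
    if res.outcome is not None:
        return res.outcome == "success"
    return res.final_count >= goal


def _fraction_trial_success(bc: BaseConfig, fraction: float,
                            master_seed: int, replicate: int) -> bool:
    lat = bc.lattice()
    stop, goal = _committed_stop(lat.n_active)
    spec = PerturbationSpec("random_fraction", fraction)
    res = run_trial(bc, spec, master_seed, replicate, stop=stop,
                    t_end=max(bc.t_end, COMMIT_HORIZON))
    if res.outcome is not None:
        return res.outcome == "success"
    return res.final_count >= goal


def success_probability(
    trial: Callable[[float, int], bool],
    value: float,
    replicates: int,
) -> float:
    """Proportion of replicates 0..replicates-1 for which ``trial`` succeeds."""
    wins = sum(bool(trial(value, rep)) for rep in range(replicates))
    return wins / replicates


def _check_bracket(trial, low, high, replicates):
    n_probe = max(3, replicates // 3)
    p_low = success_probability(trial, low, n_probe)
    p_high = success_probability(trial, high, n_probe)
    if p_low >= 0.5 or p_high < 0.5:
        raise ValueError(
            f"bracket does not straddle the transition: "
            f"p({low})={p_low:.2f}, p({high})={p_high:.2f}"
        )


def estimate_critical_fraction(
    bc: BaseConfig = BaseConfig(),
    bracket: Tuple[float, float] = (0.15, 0.40),
    replicates: int = 20,
    resolution: float = 0.01,
    master_seed: int = 0,
    runner: Optional[Callable[[float, int], bool]] = None,
    check_bracket: bool = True,
) -> ThresholdEstimate:
    """Critical randomly-seeded depolarized fraction for a chain reaction.

    Bisects the seeded fraction; at each midpoint runs ``replicates``
    simulations and measures the proportion igniting a domain-wide
    depolarization.  Returns the 50%-success crossing as a percentage, to
    ``resolution`` (default one percentage point).  ``runner`` may replace
    the simulation trial (for testing the search itself).
    """
    trial = runner or (lambda f, rep: _fraction_trial_success(bc, f, master_seed, rep))
    lo, hi = bracket
    if check_bracket:
        _check_bracket(trial, lo, hi, replicates)
    history: List[Tuple[float, float]] = []
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        p = success_probability(trial, mid, replicates)
        history.append((mid, p))
        if p >= 0.5:
            hi = mid
        else:
            lo = mid
    return ThresholdEstimate(
        quantity="fraction",
        value=100.0 * 0.5 * (lo + hi),
        uncertainty=100.0 * 0.5 * (hi - lo),
        replicates=replicates,
        history=history,
    )


def estimate_min_patch(
    bc: BaseConfig,
    kind: str,
    placement: str,
    size_range: Tuple[int, int],
    replicates: int = 20,
    master_seed: int = 0,
    runner: Optional[Callable[[float, int], bool]] = None,
    check_bracket: bool = True,
) -> ThresholdEstimate:
    """Smallest patch (side length or radius, cells) igniting a wave.

    Integer bisection over the size: returns the smallest size whose
    ignition proportion over ``replicates`` is >= 0.5.
    """
    def default_runner(size: float, rep: int) -> bool:
        spec = PerturbationSpec(kind, float(size), placement)
        return _patch_trial_success(bc, spec, master_seed, rep)

    trial = runner or default_runner
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo >= hi:
        raise ValueError("size_range must be an increasing pair")
    if check_bracket:
        _check_bracket(trial, lo, hi, replicates)
    history: List[Tuple[float, float]] = []
    while hi - lo > 1:
        mid = (lo + hi) // 2
        p = success_probability(trial, mid, replicates)
        history.append((float(mid), p))
        if p >= 0.5:
            hi = mid
        else:
            lo = mid
    return ThresholdEstimate(
        quantity="patch_size",
        value=float(hi),
        uncertainty=0.5,
        replicates=replicates,
        history=history,
    )


# ---------------------------------------------------------------------------
# Front velocity
# ---------------------------------------------------------------------------

def front_velocity(
    result: SimulationResult,
    cell_width_um: float = 10.0,
    threshold: float = DEPOL_THRESHOLD,
    axis: int = 1,
    trim: float = 0.1,
) -> VelocityEstimate:
    """Front speed from a planar-front run with snapshots.

    For each snapshot the front position is the transverse mean of the
    largest ``axis`` coordinate with V > threshold.  Snapshots where the
    front has reached the far boundary are dropped; at least three must
    remain.  The first and last ``trim`` fraction of positions are excluded
    from the least-squares fit to avoid initialization and boundary
    transients.  With cell width w um, speed[mm/s] = slope[cells/ms] * w.
    """
    if len(result.snapshots) < 3:
        raise ValueError("need at least 3 snapshots; extend the snapshot schedule")
    length = result.snapshots[0][1].shape[axis]
    times, positions = [], []
    for t, V in result.snapshots:
        mask = np.moveaxis(V > threshold, axis, -1)
        flat = mask.reshape(-1, length)
        has = flat.any(axis=1)
        if not has.all():
            continue
        pos = (length - 1 - np.argmax(flat[:, ::-1], axis=1)).mean()
        if pos >= length - 2:     # front at the far boundary: unusable
            continue
        times.append(t)
        positions.append(pos)
    if len(times) < 3:
        raise ValueError(
            "fewer than 3 usable snapshots before the front reached the "
            "boundary; use a longer domain or a shorter horizon"
        )
    times = np.asarray(times)
    positions = np.asarray(positions)
    k = len(times)
    cut = int(trim * k)
    sl = slice(cut, k - cut) if k - 2 * cut >= 3 else slice(None)
    slope, intercept = np.polyfit(times[sl], positions[sl], 1)
    fitted = slope * times[sl] + intercept
    rms = float(np.sqrt(np.mean((positions[sl] - fitted) ** 2)))
    return VelocityEstimate(
        speed_mm_s=float(slope * cell_width_um),
        cell_width_um=cell_width_um,
        speed_cells_per_s=float(slope * 1000.0),
        times_ms=times,
        positions_cells=positions,
        residual_cells=rms,
    )


def measure_front_velocity(
    length: int = 200,
    width: int = 50,
    slab_columns: int = 10,
    capacitance_mean: float = PARAMETER_MEANS["C"],
    sigma: float = 3.0,
    dt: float = 1.0,
    t_end: float = 10_000.0,
    snapshot_every: float = 500.0,
    cell_width_um: float = 10.0,
    master_seed: int = 0,
) -> VelocityEstimate:
    """Planar-front experiment: depolarize the leftmost columns of a strip.

    Runs a ``width x length`` strip with the first ``slab_columns`` columns
    depolarized and tracks the front along the strip.  Reducing the
    capacitance mean accelerates every rate in proportion (time enters the
    charge balance only through dt/C), so the front speed scales as 1/C.
    """
    bc = BaseConfig(shape=(width, length), dt=dt, sigma=sigma,
                    capacitance_mean=capacitance_mean)
    s_field, s_init, s_pert = _trial_seeds(master_seed, 0, salt=11)
    lat = bc.lattice()
    fld = sample_parameters(lat, bc.heterogeneity(), seed=s_field)
    if capacitance_mean != PARAMETER_MEANS["C"]:
        fld.arrays["C"] *= capacitance_mean / PARAMETER_MEANS["C"]
    state = init_quiescent(lat, seed=s_init)
    rng = np.random.default_rng(s_pert)
    state.V[:, :slab_columns] = rng.normal(0.0, 3.0, size=(width, slab_columns))
    snaps = np.arange(0.0, t_end + 1e-9, snapshot_every)
    res = run(lat, fld, state, t_end=t_end, dt=dt,
              report_every=max(dt, snapshot_every), snapshot_times=snaps)
    return front_velocity(res, cell_width_um=cell_width_um)


# ---------------------------------------------------------------------------
# Therapies, sweeps, ensembles
# ---------------------------------------------------------------------------

def repolarization_trial(
    bc: BaseConfig,
    intervention: InterventionSpec,
    master_seed: int,
    replicate: int = 0,
    success_fraction: float = 0.01,
) -> bool:
    """Does a fully depolarized tissue repolarize under the intervention?

    The tissue starts with every cell depolarized (V ~ Normal(0, 3) mV);
    success means fewer than ``success_fraction`` of active cells remain
    depolarized by the horizon.
    """
    lat = bc.lattice()
    n_active = lat.n_active
    goal = success_fraction * n_active

    def stop(t, c):
        return "success" if (t > 0 and c < goal) else None

    res = run_trial(bc, None, master_seed, replicate,
                    interventions=[intervention],
                    init_mean=0.0, init_sd=3.0, stop=stop, salt=7)
    return res.outcome == "success" or res.final_count < goal


_SWEEPABLE = {"G0_pol", "G0_max", "sigma"}


def sensitivity_sweep(
    bc: BaseConfig,
    parameter: str,
    values: Sequence[float],
    perturbation: PerturbationSpec,
    replicates: int = 20,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Ensemble count-vs-time series for each value of a swept parameter.

    ``parameter`` is one of G0_pol, G0_max (values in nS, rescaling the
    sampled field around its mean) or sigma (heterogeneity multiplier).
    Replicate seeds are shared across values (common random numbers), so
    orderings between values are sharper than independent sampling.
    Returns a tidy frame: parameter, value, time_ms, mean_count, sd_of_mean.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(_SWEEPABLE)}")
    frames = []
    for value in values:
        if value < 0 or not np.isfinite(value):
            raise ValueError("swept values must be finite and non-negative")
        if parameter == "sigma":
            bcv = replace(bc, sigma=float(value))
        elif parameter == "G0_pol":
            bcv = replace(bc, factor_pol=float(value) / PARAMETER_MEANS["G0_pol"])
        else:
            bcv = replace(bc, factor_max=float(value) / PARAMETER_MEANS["G0_max"])
        results = [run_trial(bcv, perturbation, master_seed, rep)
                   for rep in range(replicates)]
        times, mean, sdom = summarize_ensemble(results)
        frames.append(pd.DataFrame({
            "parameter": parameter,
            "value": float(value),
            "time_ms": times,
            "mean_count": mean,
            "sd_of_mean": sdom,
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_ensemble(
    results: Sequence[SimulationResult],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation of the mean of count series."""
    if not results:
        raise ValueError("empty ensemble")
    times = results[0].times
    for r in results[1:]:
        if r.times.shape != times.shape or not np.allclose(r.times, times):
            raise ValueError("ensemble members have mismatched time grids")
    counts = np.stack([r.depol_counts for r in results])
    mean = counts.mean(axis=0)
    n = counts.shape[0]
    sdom = counts.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean, dtype=float)
    return times, mean, sdom
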