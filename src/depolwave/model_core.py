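"""Single-cell bioelectric model: channel currents, gap-junction gating, equilibria.

The membrane potential ``V`` (mV) of an isolated cell obeys

    C dV/dt = -I_dep(V) - I_pol(V)

with a depolarizing and a polarizing current, each gated by a Boltzmann
sigmoid in ``V``.  Between coupled cells, current flows through voltage-gated
gap junctions whose conductance is the series combination of the two cells'
single-cell conductances attenuated by a ``cosh`` function of the voltage
difference.

Units are fixed package-wide: capacitance pF, conductance nS, potential mV,
time ms.  In these units currents come out in pA and ``dV/dt`` in mV/ms with
no conversion constants (the slow time scale C/G0_pol = 100 ms is explicit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Literal, Sequence, Tuple

import numpy as np

__all__ = [
    "CellParameters",
    "STANDARD",
    "EXP_CLAMP",
    "depolarization_current",
    "polarization_current",
    "cell_gate_conductance",
    "series_conductance",
    "pair_conductance",
    "single_cell_rhs",
    "find_equilibria",
    "integrate_single_cell",
]

#: Sigmoid/cosh arguments are clamped to +-EXP_CLAMP before exponentiation.
#: exp(500) ~ 7e216 is finite in float64 and indistinguishable from the limit.
EXP_CLAMP = 500.0


@dataclass(frozen=True)
class CellParameters:
    """Electrical constants of one cell.

    Attributes
    ----------
    C : float
        Membrane capacitance, pF.
    G0_pol, G0_dep : float
        Maximal conductance of the polarization / depolarization ion
        channels, nS.
    G0_max : float
        Maximal single-cell gap-junction conductance, nS.
    z : float
        Channel gating charge (sigmoid steepness), dimensionless.
    E_dep, E_pol : float
        Equilibrium (reversal) potentials of the two channel families, mV.
    V_T : float
        Threshold potential setting the sigmoid scale, mV.
    V_half : float
        Potential at which the single-cell gap-junction conductance is
        halved, mV.
    V_0 : float
        Width of the transjunctional voltage-gating function, mV.
    """

    C: float = 100.0
    G0_pol: float = 1.0
    G0_dep: float = 2.0
    G0_max: float = 1.5
    z: float = 3.0
    E_dep: float = 0.0
    E_pol: float = -60.0
    V_T: float = 26.0
    V_half: float = 0.0
    V_0: float = 24.0

    def validate(self) -> "CellParameters":
        if not (self.C > 0):
            raise ValueError(f"C must be positive, got {self.C}")
        for name in ("G0_pol", "G0_dep", "G0_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not (self.V_T > 0):
            raise ValueError(f"V_T must be positive, got {self.V_T}")
        if not (self.V_0 > 0):
            raise ValueError(f"V_0 must be positive, got {self.V_0}")
        if not (self.E_pol < self.E_dep):
            raise ValueError("E_pol must lie below E_dep")
        return self

    def rescaled(self, factor_pol: float = 1.0, factor_dep: float = 1.0,
                 factor_max: float = 1.0) -> "CellParameters":
        """Return a copy with channel conductances multiplied by the factors."""
        return replace(self, G0_pol=self.G0_pol * factor_pol,
                       G0_dep=self.G0_dep * factor_dep,
                       G0_max=self.G0_max * factor_max)


#: Population-mean parameter set (the model's standard cell).
STANDARD = CellParameters()


def _check_finite(V) -> None:
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")


def _sigmoid_gate(arg):
    """1/(1+exp(arg)) with the argument clamped against overflow."""
    return 1.0 / (1.0 + np.exp(np.clip(arg, -EXP_CLAMP, EXP_CLAMP)))


def depolarization_current(V, p: CellParameters):
    """Depolarizing channel current I_dep at potential ``V`` (mV), in pA.

    ``I_dep = G0_dep (V - E_dep) / (1 + exp(-z (V + V_T)/V_T))``.
    Negative (inward, depolarizing) for V below E_dep.
    """
    _check_finite(V)
    gate = _sigmoid_gate(-p.z * (V + p.V_T) / p.V_T)
    return p.G0_dep * (V - p.E_dep) * gate


def polarization_current(V, p: CellParameters):
    """Polarizing channel current I_pol at potential ``V`` (mV), in pA.

    ``I_pol = G0_pol (V - E_pol) / (1 + exp(+z (V + V_T)/V_T))``.
    """
    _check_finite(V)
    gate = _sigmoid_gate(p.z * (V + p.V_T) / p.V_T)
    return p.G0_pol * (V - p.E_pol) * gate


def cell_gate_conductance(V, p: CellParameters):
    """Single-cell gap-junction conductance G_i0 at potential ``V``, in nS.

    ``G_i0 = G0_max / (1 + exp(z (V - V_half)/V_T))`` -- an open-channel
    fraction that decreases sigmoidally with depolarization: depolarized
    cells couple more weakly than polarized ones.
    """
    _check_finite(V)
    return p.G0_max * _sigmoid_gate(p.z * (V - p.V_half) / p.V_T)


def series_conductance(g_i, g_j):
    """Series combination g_i g_j / (g_i + g_j); zero when both are zero."""
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    total = g_i + g_j
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0.0, g_i * g_j / np.where(total > 0.0, total, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def pair_conductance(V_i, V_j, p_i: CellParameters, p_j: CellParameters):
    """Gap-junction conductance G_ij between two coupled cells, nS.

    The per-cell conductances combine in series and the result is attenuated
    by the transjunctional voltage difference:

        G_ij = 2 G_ij0 / (1 + cosh((V_i - V_j)/V_0)),
        G_ij0 = G_i0 G_j0 / (G_i0 + G_j0).

    Symmetric under simultaneous swap of (V_i, p_i) and (V_j, p_j).
    """
    g_i = cell_gate_conductance(V_i, p_i)
    g_j = cell_gate_conductance(V_j, p_j)
    g_series = series_conductance(g_i, g_j)
    arg = np.clip((np.asarray(V_i, float) - np.asarray(V_j, float)) / p_i.V_0,
                  -EXP_CLAMP, EXP_CLAMP)
    return 2.0 * g_series / (1.0 + np.cosh(arg))


def single_cell_rhs(V, p: CellParameters):
    """dV/dt of an isolated cell, mV/ms: (-I_dep - I_pol)/C."""
    return (-depolarization_current(V, p) - polarization_current(V, p)) / p.C


def find_equilibria(
    p: CellParameters,
    search_range: Tuple[float, float] = (-90.0, 20.0),
    n_grid: int = 1000,
    rhs_tol: float = 1e-9,
    v_tol: float = 1e-6,
) -> List[Tuple[float, Literal["stable", "unstable"]]]:
    """Locate equilibria of the isolated-cell dynamics in ``search_range``.

    Scans ``single_cell_rhs`` on an ``n_grid``-point grid for sign changes,
    refines each bracket by bisection to ``v_tol`` (mV), and classifies
    stability from a centered finite-difference derivative of the rhs.
    Returns roots sorted ascending; an empty list means the parameterization
    is monostable outside the range (no sign change found).
    """
    lo, hi = search_range
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([single_cell_rhs(v, p) for v in grid])
    roots: List[Tuple[float, str]] = []
    sign = np.sign(vals)
    for k in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        a, b = float(grid[k]), float(grid[k + 1])
        fa = float(vals[k])
        while b - a > v_tol:
            m = 0.5 * (a + b)
            fm = single_cell_rhs(m, p)
            if abs(fm) < rhs_tol:
                a = b = m
                break
            if fa * fm < 0:
                b = m
            else:
                a, fa = m, fm
        root = 0.5 * (a + b)
        h = 1e-4
        deriv = (single_cell_rhs(root + h, p) - single_cell_rhs(root - h, p)) / (2 * h)
        roots.append((root, "stable" if deriv < 0 else "unstable"))
    # grid points landing exactly on a root would be missed by the product
    # test; treat exact zeros as roots too
    for k in np.flatnonzero(vals == 0.0):
        v = float(grid[k])
        if not any(abs(v - r) < 10 * v_tol for r, _ in roots):
            h = 1e-4
            deriv = (single_cell_rhs(v + h, p) - single_cell_rhs(v - h, p)) / (2 * h)
            roots.append((v, "stable" if deriv < 0 else "unstable"))
    roots.sort(key=lambda rv: rv[0])
    return roots


def stability_bound_dt(p: CellParameters, degree: int = 0) -> float:
    """Conservative explicit-Euler step bound C/(G0_dep + G0_pol + degree*G0_max), ms."""
    g = p.G0_dep + p.G0_pol + degree * p.G0_max
    return math.inf if g == 0 else p.C / g


def integrate_single_cell(
    V0: float,
    p: CellParameters,
    t_end: float,
    dt: float = 1.0,
    method: Literal["euler", "rk4"] = "euler",
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate the isolated-cell ODE from ``V0``; returns (t, V) arrays.

    Deterministic explicit integration (forward Euler by default, classical
    RK4 on request).  ``dt`` must respect the explicit stability bound
    ``C/(G0_dep + G0_pol)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bound = stability_bound_dt(p)
    if dt > bound:
        raise ValueError(f"dt={dt} ms exceeds the explicit stability bound {bound:.3g} ms")
    _check_finite(V0)
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    V = np.empty(n + 1)
    V[0] = V0
    v = float(V0)
    if method == "euler":
        for k in range(n):
            v = v + dt * single_cell_rhs(v, p)
            V[k + 1] = v
    elif method == "rk4":
        for k in range(n):
            k1 = single_cell_rhs(v, p)
            k2 = single_cell_rhs(v + 0.5 * dt * k1, p)
            k3 = single_cell_rhs(v + 0.5 * dt * k2, p)
            k4 = single_cell_rhs(v + dt * k3, p)
            v = v + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            V[k + 1] = v
    else:
        raise ValueError(f"unknown method {method!r}")
    return t, V
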