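"""Initial conditions and interventions.

Quiescent tissue starts polarized: V ~ Normal(-60, 3) mV per cell.
Perturbations depolarize a subset of cells -- a random fraction of the
domain or a geometric patch (square/cube block, circle/sphere) -- by
redrawing their potential from Normal(0, 3) mV around the depolarization
reversal potential.  Repolarization "therapies" are timed multiplicative
rescalings of the channel conductances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .tissue import LatticeSpec, ParameterField

__all__ = [
    "PerturbationSpec",
    "InterventionSpec",
    "init_quiescent",
    "patch_mask",
    "apply_perturbation",
    "apply_intervention",
]

_KINDS = ("random_fraction", "square", "circle", "cube", "sphere")


@dataclass(frozen=True)
class PerturbationSpec:
    """A depolarizing perturbation.

    ``kind`` selects random seeding (``magnitude`` = fraction of active
    cells) or a geometric patch (``magnitude`` = side length for
    square/cube, radius for circle/sphere, in cell widths).  ``placement``
    anchors patches at the coordinate-origin corner or the domain center;
    corner circles/spheres keep only the in-domain quadrant/octant.
    Depolarized cells are redrawn from Normal(depol_mean, depol_sd) mV.
    """

    kind: str
    magnitude: float
    placement: str = "center"
    depol_mean: float = 0.0
    depol_sd: float = 3.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "random_fraction" and not (0.0 <= self.magnitude <= 1.0):
            raise ValueError("random fraction must be within [0, 1]")
        if self.kind != "random_fraction" and self.magnitude < 0:
            raise ValueError("patch size must be non-negative")
        if self.placement not in ("corner", "center"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.depol_sd < 0:
            raise ValueError("depol_sd must be non-negative")


@dataclass(frozen=True)
class InterventionSpec:
    """A timed multiplicative rescaling of channel conductances.

    Applied instantaneously at ``time`` (ms): G0_pol, G0_dep, G0_max are
    multiplied cell-wise by the corresponding factors (default 1 = no-op).
    """

    time: float = 0.0
    factor_pol: float = 1.0
    factor_dep: float = 1.0
    factor_max: float = 1.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("intervention time must be >= 0")
        if min(self.factor_pol, self.factor_dep, self.factor_max) < 0:
            raise ValueError("rescaling factors must be non-negative")


def init_quiescent(
    lattice: LatticeSpec,
    mean: float = -60.0,
    sd: float = 3.0,
    seed=None,
) -> "TissueState":
    """Polarized resting tissue: V ~ Normal(mean, sd) mV on active cells.

    Wall cells carry the mean value but are excluded from the dynamics and
    from any counting.
    """
    from .simulate import TissueState

    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    V = np.full(lattice.shape, mean, dtype=float)
    if sd > 0:
        act = lattice.active_mask()
        V[act] = rng.normal(mean, sd, size=int(act.sum()))
    return TissueState(V=V, t=0.0)


def patch_mask(lattice: LatticeSpec, spec: PerturbationSpec) -> np.ndarray:
    """Boolean mask of the cells selected by a geometric perturbation.

    Block patches are axis-aligned; round patches include every cell whose
    integer-coordinate Euclidean distance to the anchor cell is <= radius.
    The anchor is the origin (corner) or floor(shape/2) (center).  Raises if
    a block patch exceeds the domain.
    """
    if spec.kind == "random_fraction":
        raise ValueError("random_fraction has no geometric mask")
    dims = lattice.dims
    if spec.kind in ("square", "cube"):
        want = 2 if spec.kind == "square" else 3
        if dims != want:
            raise ValueError(f"{spec.kind} patch requires a {want}D lattice")
        side = int(round(spec.magnitude))
        if side > min(lattice.shape):
            raise ValueError("patch exceeds the domain bounds")
        if spec.placement == "corner":
            starts = (0,) * dims
        else:
            starts = tuple(c - side // 2 for c in lattice.center())
        if any(s < 0 or s + side > n for s, n in zip(starts, lattice.shape)):
            raise ValueError("patch exceeds the domain bounds")
        mask = np.zeros(lattice.shape, dtype=bool)
        mask[tuple(slice(s, s + side) for s in starts)] = True
        return mask
    # circle / sphere
    want = 2 if spec.kind == "circle" else 3
    if dims != want:
        raise ValueError(f"{spec.kind} patch requires a {want}D lattice")
    anchor = (0,) * dims if spec.placement == "corner" else lattice.center()
    grids = np.ogrid[tuple(slice(0, n) for n in lattice.shape)]
    d2 = sum((g - a) ** 2 for g, a in zip(grids, anchor))
    if spec.placement == "center" and any(
        a + spec.magnitude > n - 1 or a - spec.magnitude < 0
        for a, n in zip(anchor, lattice.shape)
    ):
        raise ValueError("patch exceeds the domain bounds")
    return d2 <= spec.magnitude ** 2


def apply_perturbation(
    state: "TissueState",
    spec: PerturbationSpec,
    lattice: LatticeSpec,
    seed=None,
) -> "TissueState":
    """Depolarize the selected cells; returns a new state.

    Random-fraction selection draws round(fraction * N_active) distinct
    active cells uniformly without replacement; geometric patches use
    ``patch_mask`` restricted to active cells.  Selected cells' potentials
    are redrawn from Normal(depol_mean, depol_sd).
    """
    from .simulate import TissueState

    rng = np.random.default_rng(seed)
    V = state.V.copy()
    act = lattice.active_mask()
    if spec.kind == "random_fraction":
        ids = np.flatnonzero(act.ravel())
        k = int(round(spec.magnitude * ids.size))
        chosen = rng.choice(ids, size=k, replace=False)
        sel = np.zeros(lattice.n_cells, dtype=bool)
        sel[chosen] = True
        sel = sel.reshape(lattice.shape)
    else:
        sel = patch_mask(lattice, spec) & act
    n_sel = int(sel.sum())
    if n_sel:
        if spec.depol_sd > 0:
            V[sel] = rng.normal(spec.depol_mean, spec.depol_sd, size=n_sel)
        else:
            V[sel] = spec.depol_mean
    return TissueState(V=V, t=state.t)


def apply_intervention(field: ParameterField, spec: InterventionSpec) -> ParameterField:
    """Rescale channel conductances cell-wise; other parameters untouched."""
    return field.rescale_conductances(
        factor_pol=spec.factor_pol,
        factor_dep=spec.factor_dep,
        factor_max=spec.factor_max,
    )
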