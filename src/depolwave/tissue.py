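"""Lattice geometry, neighborhoods, electric walls, and quenched parameter fields.

The tissue is a 2D (default 100x100) or 3D (50x50x50) lattice of cells with
Moore (8 / 26 neighbors) or von Neumann (4 / 6) adjacency and open (no-flux)
boundaries: the domain is electrically isolated from its surroundings.
Cell-to-cell diversity is quenched disorder -- each electrical parameter is
drawn once per cell from a normal distribution around its population mean
and held fixed for the whole run.

Walls ("electric walls") are one-cell-thick bands of removed cells: they
carry no state, have no neighbors, and split the domain into electrically
isolated slabs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import CellParameters, STANDARD

__all__ = [
    "LatticeSpec",
    "HeterogeneitySpec",
    "ParameterField",
    "Adjacency",
    "PARAMETER_MEANS",
    "parameter_sds",
    "sample_parameters",
    "build_adjacency",
    "insert_walls",
    "half_offsets",
    "all_offsets",
]

#: Population means of the cell parameters (pF / nS / mV; z dimensionless).
PARAMETER_MEANS: Dict[str, float] = {
    "C": 100.0,
    "G0_pol": 1.0,
    "G0_dep": 2.0,
    "G0_max": 1.5,
    "z": 3.0,
    "E_dep": 0.0,
    "E_pol": -60.0,
    "V_T": 26.0,
    "V_half": 0.0,
    "V_0": 24.0,
}

#: Parameters that must remain strictly positive after sampling.
_POSITIVE = ("C", "G0_pol", "G0_dep", "G0_max", "V_T")


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice geometry: shape, neighborhood scheme, wall mask.

    ``wall_mask`` is a boolean array of the lattice shape marking removed
    (non-participating) cells; ``None`` means no walls.
    """

    shape: Tuple[int, ...]
    neighborhood: str = "moore"
    wall_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError("lattice must be 2D or 3D")
        if any(s < 1 for s in shape):
            raise ValueError("all lattice dimensions must be >= 1")
        if self.neighborhood not in ("moore", "neumann"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.wall_mask is not None:
            mask = np.asarray(self.wall_mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("wall_mask shape must match the lattice shape")
            object.__setattr__(self, "wall_mask", mask)

    @property
    def dims(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def active_mask(self) -> np.ndarray:
        """Boolean array: True for cells that participate in the dynamics."""
        if self.wall_mask is None:
            return np.ones(self.shape, dtype=bool)
        return ~self.wall_mask

    @property
    def n_active(self) -> int:
        return int(self.active_mask().sum())

    def center(self) -> Tuple[int, ...]:
        return tuple(s // 2 for s in self.shape)


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Cell-to-cell variability of the quenched parameter field.

    ``sigma`` is the global variability multiplier (default 3).  Relative
    noise 0.02*sigma applies to C, G0_pol, G0_dep, G0_max; absolute noise of
    ``sigma`` mV applies to E_dep, E_pol, V_T, V_half; the gating charge z
    has a fixed absolute spread ``z_sd`` (0.1 by default, not sigma-scaled;
    it is dropped together with the rest when sigma = 0 so that sigma = 0
    reproduces the population means exactly); V_0 does not vary.
    """

    sigma: float = 3.0
    z_sd: Optional[float] = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.z_sd is None:
            object.__setattr__(self, "z_sd", 0.1 if self.sigma > 0 else 0.0)
        if self.z_sd < 0:
            raise ValueError("z_sd must be non-negative")


def parameter_sds(het: HeterogeneitySpec) -> Dict[str, float]:
    """Standard deviation of every parameter under a heterogeneity spec."""
    s = het.sigma
    return {
        "C": 0.02 * s * PARAMETER_MEANS["C"],
        "G0_pol": 0.02 * s * PARAMETER_MEANS["G0_pol"],
        "G0_dep": 0.02 * s * PARAMETER_MEANS["G0_dep"],
        "G0_max": 0.02 * s * PARAMETER_MEANS["G0_max"],
        "z": het.z_sd,
        "E_dep": s,
        "E_pol": s,
        "V_T": s,
        "V_half": s,
        "V_0": 0.0,
    }


@dataclass
class ParameterField:
    """Per-cell electrical parameters as one array per parameter name.

    Arrays have the lattice shape.  The field is quenched: it only changes
    through explicit interventions (conductance rescaling).
    """

    lattice: LatticeSpec
    arrays: Dict[str, np.ndarray]

    def __post_init__(self):
        for name in PARAMETER_MEANS:
            if name not in self.arrays:
                raise ValueError(f"missing parameter array {name!r}")
            if self.arrays[name].shape != self.lattice.shape:
                raise ValueError(f"array {name!r} has wrong shape")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def cell(self, index: Tuple[int, ...]) -> CellParameters:
        """The CellParameters of a single lattice site."""
        return CellParameters(**{k: float(v[index]) for k, v in self.arrays.items()})

    def mean_cell(self) -> CellParameters:
        """Cell built from the spatial mean of each parameter (active cells)."""
        act = self.lattice.active_mask()
        return CellParameters(**{k: float(v[act].mean()) for k, v in self.arrays.items()})

    def rescale_conductances(self, factor_pol: float = 1.0, factor_dep: float = 1.0,
                             factor_max: float = 1.0) -> "ParameterField":
        """Return a new field with channel conductances multiplied cell-wise."""
        if min(factor_pol, factor_dep, factor_max) < 0:
            raise ValueError("conductance rescaling factors must be non-negative")
        arrays = {k: v.copy() for k, v in self.arrays.items()}
        arrays["G0_pol"] *= factor_pol
        arrays["G0_dep"] *= factor_dep
        arrays["G0_max"] *= factor_max
        return ParameterField(self.lattice, arrays)

    def copy(self) -> "ParameterField":
        return ParameterField(self.lattice, {k: v.copy() for k, v in self.arrays.items()})

    def save(self, path) -> None:
        """Export the field as an .npz archive (one array per parameter),
        for exact-rerun provenance."""
        np.savez(path, **self.arrays)

    @classmethod
    def load(cls, path, lattice: LatticeSpec) -> "ParameterField":
        with np.load(path) as data:
            arrays = {k: data[k].copy() for k in data.files}
        return cls(lattice, arrays)


def sample_parameters(
    lattice: LatticeSpec,
    het: HeterogeneitySpec = HeterogeneitySpec(),
    seed=None,
) -> ParameterField:
    """Draw the quenched per-cell parameter field.

    Each parameter is drawn independently per cell from
    Normal(mean, sd) with the population means and the spreads given by
    ``parameter_sds``.  Strictly positive parameters (capacitance,
    conductances, V_T) are redrawn, not clipped, on the rare non-positive
    draw.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sds = parameter_sds(het)
    arrays: Dict[str, np.ndarray] = {}
    for name, mean in PARAMETER_MEANS.items():
        sd = sds[name]
        if sd == 0.0:
            arr = np.full(lattice.shape, mean, dtype=float)
        else:
            arr = rng.normal(mean, sd, size=lattice.shape)
            if name in _POSITIVE:
                bad = arr <= 0.0
                while bad.any():
                    arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                    bad = arr <= 0.0
        arrays[name] = arr
    return ParameterField(lattice, arrays)


# ---------------------------------------------------------------------------
# Neighborhood offsets and adjacency
# ---------------------------------------------------------------------------

def all_offsets(dims: int, neighborhood: str) -> List[Tuple[int, ...]]:
    """Every neighbor offset of the scheme (8/26 moore, 4/6 neumann)."""
    rng = (-1, 0, 1)
    if dims == 2:
        offs = [(dx, dy) for dx in rng for dy in rng if (dx, dy) != (0, 0)]
    else:
        offs = [(dx, dy, dz) for dx in rng for dy in rng for dz in rng
                if (dx, dy, dz) != (0,) * 3]
    if neighborhood == "neumann":
        offs = [o for o in offs if sum(abs(c) for c in o) == 1]
    return offs


def half_offsets(dims: int, neighborhood: str) -> List[Tuple[int, ...]]:
    """One offset per unordered neighbor pair (lexicographically positive).

    Ordered so that axis offsets come first, then diagonals; the simulator
    relies on this ordering for a reflection-symmetric pairwise summation.
    """
    offs = [o for o in all_offsets(dims, neighborhood) if o > (0,) * dims]
    offs.sort(key=lambda o: (sum(abs(c) for c in o), o))
    return offs


@dataclass
class Adjacency:
    """Neighbor lists over flattened (C-order) cell indices, CSR style.

    Wall cells have empty neighbor lists and never appear as neighbors.
    """

    lattice: LatticeSpec
    indptr: np.ndarray
    indices: np.ndarray

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def to_sparse(self):
        """scipy CSR adjacency matrix (unit weights)."""
        from scipy.sparse import csr_matrix

        n = self.lattice.n_cells
        data = np.ones(len(self.indices), dtype=np.int8)
        return csr_matrix((data, self.indices, self.indptr), shape=(n, n))

    def n_components(self, active_only: bool = True) -> int:
        """Connected components of the adjacency graph over active cells."""
        from scipy.sparse.csgraph import connected_components

        g = self.to_sparse()
        n, labels = connected_components(g, directed=False)
        if active_only:
            act = self.lattice.active_mask().ravel()
            return int(np.unique(labels[act]).size)
        return int(n)


def build_adjacency(lattice: LatticeSpec) -> Adjacency:
    """Neighbor index structure for the lattice.

    Boundary cells have truncated neighbor sets (no wraparound); wall cells
    are excluded both as sources and as targets.
    """
    shape = lattice.shape
    active = lattice.active_mask()
    n = lattice.n_cells
    offs = all_offsets(lattice.dims, lattice.neighborhood)
    coords = np.indices(shape)  # (dims, *shape)
    neighbor_lists: List[np.ndarray] = []
    counts = np.zeros(n, dtype=np.int64)
    strides = np.array([int(np.prod(shape[k + 1:])) for k in range(len(shape))])

    flat_active = active.ravel()
    src_ids = np.arange(n).reshape(shape)
    pairs_src: List[np.ndarray] = []
    pairs_dst: List[np.ndarray] = []
    for off in offs:
        src_slices = tuple(slice(max(0, -d), s - max(0, d)) for d, s in zip(off, shape))
        dst_slices = tuple(slice(max(0, d), s + min(0, d)) for d, s in zip(off, shape))
        a = src_ids[src_slices].ravel()
        b = src_ids[dst_slices].ravel()
        ok = flat_active[a] & flat_active[b]
        pairs_src.append(a[ok])
        pairs_dst.append(b[ok])
    src = np.concatenate(pairs_src)
    dst = np.concatenate(pairs_dst)
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return Adjacency(lattice, indptr, dst)


def insert_walls(
    lattice: LatticeSpec,
    n_walls: int,
    orientation: int = 0,
    thickness: int = 1,
) -> LatticeSpec:
    """Insert equally spaced full-width wall bands perpendicular to ``orientation``.

    The ``n_walls`` one-cell-thick (configurable) bands mark cells as removed
    and split the domain into ``n_walls + 1`` electrically isolated slabs.
    Walls touching a domain edge raise an error.
    """
    if n_walls < 0:
        raise ValueError("n_walls must be >= 0")
    if n_walls == 0:
        return lattice
    if not (0 <= orientation < lattice.dims):
        raise ValueError("orientation must index a lattice axis")
    size = lattice.shape[orientation]
    positions = [round((k + 1) * size / (n_walls + 1)) for k in range(n_walls)]
    mask = np.zeros(lattice.shape, dtype=bool) if lattice.wall_mask is None \
        else lattice.wall_mask.copy()
    for pos in positions:
        lo, hi = pos, pos + thickness
        if lo <= 0 or hi >= size:
            raise ValueError(f"wall at {lo}:{hi} overlaps the domain edge")
        sl = [slice(None)] * lattice.dims
        sl[orientation] = slice(lo, hi)
        mask[tuple(sl)] = True
    return replace(lattice, wall_mask=mask)
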