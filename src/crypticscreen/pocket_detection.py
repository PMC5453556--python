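"""Grid-based cryptic pocket detection (protein–solvent–protein scanning).

The detector follows the LIGSITE family of algorithms.  The structure is
embedded in a cubic lattice; a voxel is *occupied* when its center falls
inside the van der Waals sphere of any heavy atom (optionally inflated by
a probe radius).  Each solvent voxel is then scanned along seven lines —
the three lattice axes and the four cube diagonals — and a direction
counts as a protein–solvent–protein (PSP) event when protein occupancy is
found on *both* sides of the voxel along that line.  Voxels with at least
``min_psp`` of the seven directions enclosed are pocket elements;
contiguous pocket elements are grouped into pockets and small groups are
discarded.

Defaults follow the published protocol for TEM β-lactamase ensembles:
1.0 Å grid step, minPSP = 6, minimum pocket size 30 elements (≈30 Å³).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .core_io import Structure
from .errors import ConfigError, ContractError, ResourceError

#: The seven scan directions: lattice axes plus the four cube diagonals.
SCAN_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class PocketDetectionParams:
    """Tunable knobs of the grid scan.

    grid_step
        Lattice spacing in Å (default 1.0).
    min_psp
        Minimum number of enclosed scan directions, out of 7, for a
        solvent voxel to count as a pocket element (default 6).
    min_elements
        Pockets smaller than this many voxels are discarded (default 30,
        ≈30 Å³ at a 1 Å step).
    padding
        Margin in Å added around the atom bounding box so the protein is
        surrounded by genuine solvent (default 4.0).
    probe_radius
        Å added to every atom radius when testing occupancy (default 0.0:
        pure van der Waals volume).
    connectivity
        Voxel adjacency (6, 18 or 26) used when grouping pocket elements
        into contiguous pockets (default 26).
    voxel_budget
        Hard cap on the total number of lattice points.
    """

    grid_step: float = 1.0
    min_psp: int = 6
    min_elements: int = 30
    padding: float = 4.0
    probe_radius: float = 0.0
    connectivity: int = 26
    voxel_budget: int = 10**8

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be positive")
        if not 1 <= self.min_psp <= len(SCAN_DIRECTIONS):
            raise ConfigError(f"min_psp must be in [1, {len(SCAN_DIRECTIONS)}]")
        if self.min_elements < 1:
            raise ConfigError("min_elements must be >= 1")
        if self.connectivity not in _CONNECTIVITY_STRUCTS:
            raise ConfigError("connectivity must be one of 6, 18, 26")
        if self.padding < 0 or self.probe_radius < 0:
            raise ConfigError("padding and probe_radius must be non-negative")


@dataclass
class PocketGrid:
    """Voxel lattice with protein occupancy and per-voxel PSP counts."""

    origin: np.ndarray  # (3,) Å — center of voxel (0,0,0)
    step: float
    occupancy: np.ndarray  # (nx, ny, nz) bool, True = protein
    psp_count: np.ndarray | None = None  # (nx, ny, nz) int in [0, 7]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        """Cartesian coordinates (Å) of a voxel center."""
        return self.origin + self.step * np.asarray(index, dtype=float)


@dataclass(frozen=True)
class Pocket:
    """A contiguous group of pocket elements from one structure."""

    source_state: str
    voxel_indices: frozenset[tuple[int, int, int]]
    step: float
    center_of_mass: tuple[float, float, float]

    @property
    def n_elements(self) -> int:
        return len(self.voxel_indices)

    @property
    def volume(self) -> float:
        """Pocket volume in Å³ (element count × step³)."""
        return self.n_elements * self.step**3

    def min_index(self) -> tuple[int, int, int]:
        return min(self.voxel_indices)


# ---------------------------------------------------------------------------


def voxelize_structure(structure: Structure, params: PocketDetectionParams) -> PocketGrid:
    """Embed a structure in a lattice and mark protein-occupied voxels.

    The grid spans the atom bounding box plus ``padding`` on every side;
    the origin is the componentwise minimum atom coordinate minus the
    padding.  A voxel is occupied iff its center lies within
    ``radius + probe_radius`` of some atom center.
    """
    if not structure.has_radii:
        raise ContractError(
            f"structure {structure.identifier!r} has unset radii; run assign_radii"
        )
    coords = structure.coordinates
    radii = structure.radii + params.probe_radius
    step = params.grid_step

    origin = coords.min(axis=0) - params.padding
    upper = coords.max(axis=0) + params.padding
    dims = np.floor((upper - origin) / step).astype(int) + 1
    if int(np.prod(dims)) > params.voxel_budget:
        raise ResourceError(
            f"grid of {np.prod(dims)} voxels exceeds budget {params.voxel_budget}"
        )

    occ = np.zeros(tuple(dims), dtype=bool)
    for center, r in zip(coords, radii):
        lo = np.maximum(np.ceil((center - r - origin) / step).astype(int), 0)
        hi = np.minimum(np.floor((center + r - origin) / step).astype(int), dims - 1)
        if np.any(hi < lo):
            continue
        axes = [
            origin[k] + step * np.arange(lo[k], hi[k] + 1) - center[k] for k in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        occ[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= d2 <= r * r
    return PocketGrid(origin=origin, step=step, occupancy=occ)


def _shift(a: np.ndarray, d: Sequence[int]) -> np.ndarray:
    """Shift a 3-D array by integer offsets, zero-filling (no wraparound)."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(d):
        if s > 0:
            dst[ax], src[ax] = slice(s, None), slice(None, -s)
        elif s < 0:
            dst[ax], src[ax] = slice(None, s), slice(-s, None)
    if all(abs(s) < n for s, n in zip(d, a.shape)):
        out[tuple(dst)] = a[tuple(src)]
    return out


def _directional_or(occ: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """For each voxel: is any occupied voxel found along direction -d?

    ``result[v] = OR_{k>=1} occ[v - k*d]`` computed with logarithmic
    doubling of the shift distance.
    """
    acc = _shift(occ, d)
    k = 1
    n = max(occ.shape)
    while k < n:
        acc |= _shift(acc, tuple(s * k for s in d))
        k *= 2
    return acc


def scan_psp(grid: PocketGrid) -> PocketGrid:
    """Fill ``grid.psp_count`` with per-voxel enclosed-direction counts.

    A direction contributes 1 to a solvent voxel when protein occupancy is
    encountered on both sides of the voxel along that scan line (anywhere
    within the grid).  Occupied voxels get 0.
    """
    occ = grid.occupancy
    count = np.zeros(occ.shape, dtype=np.int8)
    for d in SCAN_DIRECTIONS:
        before = _directional_or(occ, d)
        after = _directional_or(occ, tuple(-s for s in d))
        count += (before & after).astype(np.int8)
    count[occ] = 0
    grid.psp_count = count
    return grid


def extract_pockets(
    grid: PocketGrid,
    params: PocketDetectionParams,
    source_state: str = "",
) -> list[Pocket]:
    """Group qualifying voxels into pockets and drop the small ones.

    Pocket elements are solvent voxels with ``psp_count >= min_psp``;
    connected components are computed under the configured connectivity;
    components below ``min_elements`` are discarded.  Pockets come back
    sorted by descending size, ties broken by smallest voxel index, so
    repeated runs are reproducible.
    """
    if grid.psp_count is None:
        raise ContractError("psp_count not filled; call scan_psp first")
    qualifying = (grid.psp_count >= params.min_psp) & ~grid.occupancy
    labels, n_comp = ndimage.label(
        qualifying, structure=_CONNECTIVITY_STRUCTS[params.connectivity]
    )
    pockets: list[Pocket] = []
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < params.min_elements:
            continue
        centers = grid.origin + grid.step * idx.astype(float)
        pockets.append(
            Pocket(
                source_state=source_state,
                voxel_indices=frozenset(map(tuple, idx.tolist())),
                step=grid.step,
                center_of_mass=tuple(centers.mean(axis=0)),
            )
        )
    pockets.sort(key=lambda p: (-p.n_elements, p.min_index()))
    return pockets


def detect_pockets(
    structure: Structure,
    params: PocketDetectionParams | None = None,
    source_state: str | None = None,
) -> list[Pocket]:
    """Convenience pipeline: voxelize → PSP scan → pocket extraction."""
    params = params or PocketDetectionParams()
    grid = voxelize_structure(structure, params)
    scan_psp(grid)
    return extract_pockets(
        grid, params, source_state if source_state is not None else structure.identifier
    )


def pockets_to_records(pockets: Iterable[Pocket]) -> list[dict]:
    """JSON-ready report rows: state, rank, size, volume, center of mass."""
    return [
        {
            "state_id": p.source_state,
            "pocket_rank": rank,
            "n_elements": p.n_elements,
            "volume_A3": p.volume,
            "com_xyz": [round(c, 4) for c in p.center_of_mass],
        }
        for rank, p in enumerate(pockets, start=1)
    ]
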