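"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to this toolkit — conformational ensembles from molecular
dynamics, docking score matrices, plate-reader traces — are expensive to
produce and carry no known truth to test against.  This module generates
stand-ins whose correct answer is known by construction:

* hollow-shell pseudo-protein structures whose interior cavity voxel set
  is enumerated by an independent brute-force scan (the oracle for the
  production pocket detector);
* state ensembles mixing pocket-open (hollow) and pocket-closed (solid)
  structures with assigned equilibrium populations;
* docking score matrices with planted high-scoring binders;
* assay velocities and traces simulated from the Michaelis–Menten,
  mixed-activation and dose-response models with proportional Gaussian
  noise.

Every generator is deterministic under a fixed seed.  Default kinetic
parameters mirror the TEM β-lactamase study conditions (kcat 100 s⁻¹,
Km 100 μM, 1 nM enzyme, substrate 10–200 μM, dose series to 400 μM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AtomRecord, EnsembleState, Structure, StructureEnsemble
from .errors import ConfigError, FixtureError
from .kinetics import (
    AssayCondition,
    AssayTrace,
    activation_velocity,
    dose_response_curve,
    mm_velocity,
)
from .pocket_detection import SCAN_DIRECTIONS, PocketDetectionParams

# ---------------------------------------------------------------------------
# Brute-force oracle for the PSP scan (independent of the production code)


def brute_force_psp_counts(occupancy: np.ndarray) -> np.ndarray:
    """Per-voxel enclosed-direction counts by naive ray walking.

    For every solvent voxel and every scan direction, walk voxel by voxel
    to both grid edges and check whether protein occupancy appears on
    each side.  Quadratic and slow — this is the reference the fast
    production scan is tested against, deliberately sharing none of its
    machinery.
    """
    occ = np.asarray(occupancy, dtype=bool)
    nx, ny, nz = occ.shape
    counts = np.zeros(occ.shape, dtype=int)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if occ[i, j, k]:
                    continue
                c = 0
                for d in SCAN_DIRECTIONS:
                    hit_both = True
                    for sgn in (1, -1):
                        x, y, z = i + sgn * d[0], j + sgn * d[1], k + sgn * d[2]
                        found = False
                        while 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                            if occ[x, y, z]:
                                found = True
                                break
                            x, y, z = x + sgn * d[0], y + sgn * d[1], z + sgn * d[2]
                        if not found:
                            hit_both = False
                            break
                    if hit_both:
                        c += 1
                counts[i, j, k] = c
    return counts


def _bfs_component(
    qualifying: np.ndarray, seed: tuple[int, int, int], connectivity: int
) -> set[tuple[int, int, int]]:
    """Connected component of a seed voxel by plain breadth-first search."""
    if connectivity == 6:
        steps = [d for d in np.ndindex(3, 3, 3)
                 if sum(abs(s - 1) for s in d) == 1]
    elif connectivity == 18:
        steps = [d for d in np.ndindex(3, 3, 3)
                 if 1 <= sum(abs(s - 1) for s in d) <= 2]
    else:
        steps = [d for d in np.ndindex(3, 3, 3) if d != (1, 1, 1)]
    offsets = [(d[0] - 1, d[1] - 1, d[2] - 1) for d in steps]

    nx, ny, nz = qualifying.shape
    seen = {seed}
    frontier = [seed]
    while frontier:
        nxt = []
        for (i, j, k) in frontier:
            for di, dj, dk in offsets:
                v = (i + di, j + dj, k + dk)
                if (
                    0 <= v[0] < nx and 0 <= v[1] < ny and 0 <= v[2] < nz
                    and v not in seen and qualifying[v]
                ):
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return seen


def _brute_force_occupancy(
    coords: np.ndarray, radii: np.ndarray, origin: np.ndarray, dims, step: float
) -> np.ndarray:
    """Occupancy by exhaustive voxel-vs-atom distance check."""
    axes = [origin[k] + step * np.arange(dims[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    occ = np.zeros(len(pts), dtype=bool)
    for c, r in zip(coords, radii):
        occ |= np.einsum("ij,ij->i", pts - c, pts - c) <= r * r
    return occ.reshape(tuple(dims))


# ---------------------------------------------------------------------------
# Cavity structures


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass(frozen=True)
class CavitySpec:
    """A hollow pseudo-protein shell enclosing a known interior cavity.

    ``mouth_deg`` > 0 removes shell atoms within that half-angle of the
    +z axis, turning the closed cavity into an open pocket.
    """

    outer_radius: float = 8.0  # Å, radius of the atom shell
    inner_radius: float = 3.0  # Å, guaranteed-empty interior radius
    spacing: float = 1.0  # Å, target spacing between shell atoms
    atom_radius: float = 1.7  # Å, carbon-like shell atoms
    mouth_deg: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius >= self.outer_radius:
            raise FixtureError("inner_radius must be < outer_radius")
        if self.spacing > 2 * self.atom_radius:
            raise FixtureError(
                "shell atom spacing exceeds the atom diameter; the shell "
                "would be porous to solvent"
            )
        if not 0 <= self.mouth_deg <= 180:
            raise FixtureError("mouth_deg must be in [0, 180]")


@dataclass
class CavityOracle:
    """Ground truth for one cavity fixture at given detection parameters."""

    n_elements: int
    voxel_indices: frozenset[tuple[int, int, int]]
    origin: np.ndarray
    step: float


def make_cavity_structure(
    spec: CavitySpec,
    params: PocketDetectionParams | None = None,
    identifier: str = "cavity",
) -> tuple[Structure, CavityOracle]:
    """Build a hollow shell structure plus the brute-force cavity oracle.

    The shell is a golden-spiral lattice of carbon-like pseudo-atoms at
    ``outer_radius``; the oracle enumerates, entirely by brute force, the
    interior solvent voxels with at least ``min_psp`` enclosed directions.
    A closed shell whose interior leaks to the outside (spacing too coarse
    for the grid step) raises a FixtureError rather than returning a bad
    oracle.
    """
    params = params or PocketDetectionParams()
    n_atoms = max(12, int(round(4 * math.pi * spec.outer_radius**2 / spec.spacing**2)))
    dirs = _fibonacci_sphere(n_atoms)
    if spec.mouth_deg > 0:
        keep = np.degrees(np.arccos(np.clip(dirs[:, 2], -1, 1))) > spec.mouth_deg
        dirs = dirs[keep]
    center = np.asarray(spec.center, dtype=float)
    coords = center + spec.outer_radius * dirs

    atoms = tuple(
        AtomRecord(
            element="C",
            name="C",
            residue_index=i + 1,
            chain_id="A",
            position=tuple(xyz),
            radius=spec.atom_radius,
        )
        for i, xyz in enumerate(coords)
    )
    structure = Structure(identifier=identifier, atoms=atoms)

    # oracle, by brute force: occupancy, PSP walk, then a hand-rolled BFS
    # over qualifying voxels from the cavity center
    step = params.grid_step
    origin = coords.min(axis=0) - params.padding
    upper = coords.max(axis=0) + params.padding
    dims = np.floor((upper - origin) / step).astype(int) + 1
    radii = np.full(len(coords), spec.atom_radius + params.probe_radius)
    occ = _brute_force_occupancy(coords, radii, origin, dims, step)

    psp = brute_force_psp_counts(occ)
    qualifying = (psp >= params.min_psp) & ~occ

    seed_idx = tuple(int(round(c)) for c in (center - origin) / step)
    component: set[tuple[int, int, int]] = set()
    if (
        all(0 <= seed_idx[k] < dims[k] for k in range(3))
        and qualifying[seed_idx]
    ):
        component = _bfs_component(qualifying, seed_idx, params.connectivity)

    if spec.mouth_deg == 0:
        touches_edge = any(
            v[k] in (0, dims[k] - 1) for v in component for k in range(3)
        )
        if not component or touches_edge:
            raise FixtureError(
                "shell is porous at this grid step; decrease spacing or the step"
            )

    idx = frozenset(component)
    return structure, CavityOracle(
        n_elements=len(idx), voxel_indices=idx, origin=origin, step=step
    )


def make_solid_ball(
    radius: float = 8.0,
    spacing: float = 1.5,
    atom_radius: float = 1.7,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    identifier: str = "ball",
) -> Structure:
    """A solid sphere of pseudo-atoms: a pocketless 'closed' conformation."""
    center = np.asarray(center, dtype=float)
    n = int(radius / spacing) + 1
    grid = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius] + center
    atoms = tuple(
        AtomRecord(
            element="C",
            name="C",
            residue_index=i + 1,
            chain_id="A",
            position=tuple(p),
            radius=atom_radius,
        )
        for i, p in enumerate(pts)
    )
    return Structure(identifier=identifier, atoms=atoms)


# ---------------------------------------------------------------------------
# Ensembles


def make_state_ensemble(
    n_states: int,
    open_fraction: float,
    population_law: Literal["uniform", "geometric"] = "geometric",
    seed: int = 0,
    geometric_ratio: float = 0.85,
    cavity_spec: CavitySpec | None = None,
) -> tuple[StructureEnsemble, set[str]]:
    """An ensemble of pocket-open and pocket-closed states with populations.

    Open states carry a hollow-cavity structure, closed states a solid
    ball at the same location.  Populations are uniform or geometric
    (ratio 0.85 spans roughly an order of magnitude over 15 states, like
    the published target set) and normalized to sum to 1.  Returns the
    ensemble and the ground-truth set of open state ids.
    """
    if n_states < 1:
        raise ConfigError("n_states must be >= 1")
    if not 0 <= open_fraction <= 1:
        raise ConfigError("open_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_open = int(round(n_states * open_fraction))
    open_rows = set(rng.choice(n_states, size=n_open, replace=False).tolist())

    spec = cavity_spec or CavitySpec()
    open_structure, _ = make_cavity_structure(spec, identifier="open")
    closed_structure = make_solid_ball(
        radius=spec.outer_radius, center=spec.center, identifier="closed"
    )

    if population_law == "uniform":
        pops = np.full(n_states, 1.0 / n_states)
    elif population_law == "geometric":
        pops = geometric_ratio ** np.arange(n_states, dtype=float)
        pops /= pops.sum()
    else:
        raise ConfigError("population_law must be 'uniform' or 'geometric'")

    states = []
    open_ids: set[str] = set()
    for i in range(n_states):
        sid = f"s{i + 1}"
        if i in open_rows:
            struct = Structure(identifier=f"open-{sid}", atoms=open_structure.atoms)
            open_ids.add(sid)
        else:
            struct = Structure(identifier=f"closed-{sid}", atoms=closed_structure.atoms)
        states.append(EnsembleState(state_id=sid, structure=struct, population=pops[i]))
    return StructureEnsemble(tuple(states)), open_ids


# ---------------------------------------------------------------------------
# Score matrices


def make_score_matrix(
    n_compounds: int,
    n_states: int,
    planted: Sequence[tuple[str, float]] = (),
    noise_sd: float = 1.0,
    baseline: float = 5.0,
    seed: int = 0,
):
    """Gaussian baseline docking scores with planted strong binders.

    Planted compounds get their bonus added in every state, so under any
    positive population vector their Boltzmann score exceeds the field by
    the bonus; requiring bonus > 3·noise_sd keeps rank-1 recovery all but
    certain.  Returns a ScoreMatrix.
    """
    from .ensemble_scoring import ScoreMatrix

    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    for cid, bonus in planted:
        if noise_sd > 0 and bonus <= 3 * noise_sd:
            raise ConfigError(
                f"planted bonus {bonus} for {cid!r} must exceed 3*noise_sd for "
                "separability"
            )
    rng = np.random.default_rng(seed)
    compounds = [f"cmpd-{i + 1:04d}" for i in range(n_compounds)]
    states = [f"s{j + 1}" for j in range(n_states)]
    scores = baseline + rng.normal(0.0, noise_sd, size=(n_compounds, n_states))
    df = pd.DataFrame(scores, index=pd.Index(compounds, name="compound_id"),
                      columns=states)
    for cid, bonus in planted:
        if cid not in df.index:
            raise ConfigError(f"planted compound {cid!r} not in matrix")
        df.loc[cid] += bonus
    return ScoreMatrix(scores=df, higher_better=True)


# ---------------------------------------------------------------------------
# Kinetic simulations

#: Study-condition defaults: TEM-like enzyme, nitrocefin-like substrate design.
DEFAULT_KCAT = 100.0  # s⁻¹
DEFAULT_KM = 100.0  # μM
DEFAULT_ENZYME = 0.001  # μM (1 nM)
DEFAULT_SUBSTRATE_GRID = (10.0, 25.0, 50.0, 100.0, 200.0)  # μM
DEFAULT_DOSE_GRID = (0.0, 1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0)  # μM
DEFAULT_ACTIVATION_DOSES = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0)  # μM
DEFAULT_SCREEN_DOSES = (0.5, 50.0, 100.0)  # μM


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated assay dataset."""

    model: Literal["mm", "activation", "dose_response"]
    params: Mapping[str, float] = field(default_factory=dict)
    substrate: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID
    compound: tuple[float, ...] = (0.0,)
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        # amplitude is signed (negative = inhibitor); everything else positive
        bad = [k for k, v in self.params.items() if k != "amplitude" and v <= 0]
        if bad:
            raise ConfigError(f"non-positive model parameters: {bad}")
        if self.params.get("amplitude") == 0:
            raise ConfigError("amplitude must be nonzero")


def _noisy(values: np.ndarray, noise_cv: float, n_replicates: int,
           rng: np.random.Generator) -> np.ndarray:
    reps = np.repeat(values[None, :], n_replicates, axis=0)
    if noise_cv > 0:
        reps = reps * (1.0 + noise_cv * rng.standard_normal(reps.shape))
    return reps


def simulate_kinetics(spec: SimSpec) -> pd.DataFrame:
    """Simulate replicate velocities (or relative velocities) from a model.

    Proportional Gaussian noise: each observation is model·(1 + ε) with
    ε ~ N(0, noise_cv²).  Output columns: substrate_uM, compound_uM,
    velocity (or rel_velocity for dose_response), replicate.
    """
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    kcat = p.get("kcat", DEFAULT_KCAT)
    km = p.get("km", DEFAULT_KM)
    enzyme = p.get("enzyme_conc", DEFAULT_ENZYME)

    if spec.model == "mm":
        S = np.asarray(spec.substrate, dtype=float)
        A = np.zeros_like(S)
        v = mm_velocity(S, kcat, km, enzyme)
        value_col = "velocity"
    elif spec.model == "activation":
        S, A = np.meshgrid(
            np.asarray(spec.substrate, dtype=float),
            np.asarray(spec.compound, dtype=float),
            indexing="ij",
        )
        S, A = S.ravel(), A.ravel()
        v = activation_velocity(S, A, kcat, km, p["beta"], p["kact"], enzyme)
        value_col = "velocity"
    elif spec.model == "dose_response":
        A = np.asarray(spec.compound, dtype=float)
        S = np.full_like(A, spec.substrate[0] if spec.substrate else 50.0)
        v = dose_response_curve(A, p["ec50"], p["amplitude"])
        value_col = "rel_velocity"
    else:
        raise ConfigError(f"unknown simulation model {spec.model!r}")

    reps = _noisy(np.asarray(v, dtype=float), spec.noise_cv, spec.n_replicates, rng)
    rows = []
    for r in range(spec.n_replicates):
        for s, a, val in zip(S, A, reps[r]):
            rows.append({"substrate_uM": s, "compound_uM": a,
                         value_col: val, "replicate": r + 1})
    return pd.DataFrame(rows)


def make_linear_traces(
    velocities: pd.DataFrame,
    duration: float = 25.0,
    dt: float = 1.0,
    baseline: float = 0.0,
) -> list[AssayTrace]:
    """Turn a velocity table into linear signal traces (slope = velocity)."""
    traces = []
    times = tuple(np.arange(0.0, duration + dt / 2, dt))
    for _, row in velocities.iterrows():
        v = float(row.get("velocity", row.get("rel_velocity", 0.0)))
        signal = tuple(baseline + v * t for t in times)
        traces.append(
            AssayTrace(
                times=times,
                signal=signal,
                condition=AssayCondition(
                    substrate_conc=float(row.get("substrate_uM", 0.0)),
                    compound_conc=float(row.get("compound_uM", 0.0)),
                    replicate_id=int(row.get("replicate", 0)),
                ),
            )
        )
    return traces
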