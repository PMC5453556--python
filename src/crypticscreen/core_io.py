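"""Structures, ensembles and PDB input/output.

This module holds the structural containers the rest of the toolkit works
on: an :class:`AtomRecord` (element, coordinates, van der Waals radius), a
:class:`Structure` (one conformation), and a :class:`StructureEnsemble`
(ordered conformational states, each carrying an equilibrium population —
typically the stationary probabilities of a Markov state model).

PDB reading and writing is delegated to :mod:`gemmi`; coordinates are in
Ångström throughout and insertion codes are ignored.  Equilibrium
populations are supplied separately as a two-column TSV
(``state_id<TAB>population``) and joined onto an ensemble by state id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError, ParseError

logger = logging.getLogger(__name__)

#: Bondi (1964) van der Waals radii in Å for common protein/ligand elements.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: Fallback radius in Å for elements missing from a radius table.
DEFAULT_RADIUS = 1.8

RADIUS_SETS: dict[str, Mapping[str, float]] = {"bondi": BONDI_RADII}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element, identity, position (Å) and optional radius (Å)."""

    element: str
    name: str
    residue_index: int
    chain_id: str
    position: tuple[float, float, float]
    radius: float | None = None

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ContractError(f"non-finite coordinates for atom {self.name}")
        if self.radius is not None and not (0.5 < self.radius < 3.0):
            raise ContractError(
                f"radius {self.radius} Å for atom {self.name} outside (0.5, 3.0)"
            )


@dataclass(frozen=True)
class Structure:
    """A single conformation: an identifier and an ordered list of atoms."""

    identifier: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ContractError("structure identifier must be non-empty")
        if len(self.atoms) == 0:
            raise ContractError(f"structure {self.identifier!r} has no atoms")
        if not isinstance(self.atoms, tuple):
            object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of positions in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(n_atoms,) array of radii in Å; raises if any atom lacks one."""
        vals = [a.radius for a in self.atoms]
        if any(v is None for v in vals):
            raise ContractError(
                f"structure {self.identifier!r} has atoms without radii; "
                "call assign_radii first"
            )
        return np.array(vals, dtype=float)

    @property
    def has_radii(self) -> bool:
        return all(a.radius is not None for a in self.atoms)


@dataclass(frozen=True)
class EnsembleState:
    state_id: str
    structure: Structure
    population: float


@dataclass(frozen=True)
class StructureEnsemble:
    """Ordered conformational states with equilibrium populations.

    Populations are fractions in [0, 1]; they need not sum to 1 (a selected
    subset of a larger model keeps its original, unrenormalized weights).
    """

    states: tuple[EnsembleState, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.states, tuple):
            object.__setattr__(self, "states", tuple(self.states))
        ids = [s.state_id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ContractError("duplicate state_ids in ensemble")
        pops = np.array([s.population for s in self.states], dtype=float)
        if len(pops) and pops.min() < 0:
            raise ContractError("negative population in ensemble")
        if pops.sum() > 1 + 1e-9:
            raise ContractError(f"populations sum to {pops.sum():.6g} > 1")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]

    @property
    def populations(self) -> dict[str, float]:
        return {s.state_id: s.population for s in self.states}

    def get(self, state_id: str) -> EnsembleState:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(state_id)

    def with_populations(self, table: Mapping[str, float]) -> "StructureEnsemble":
        """Return a copy with populations joined from ``table`` by state_id."""
        missing = [s.state_id for s in self.states if s.state_id not in table]
        if missing:
            raise ConfigError(f"population table missing state_ids: {missing}")
        return StructureEnsemble(
            tuple(replace(s, population=float(table[s.state_id])) for s in self.states)
        )


# ---------------------------------------------------------------------------
# PDB reading


def _validate_pdb_text(path: Path) -> None:
    """Raise ParseError with a line number for malformed coordinate fields."""
    n_coord_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_coord_records += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}: malformed coordinate field {fieldtxt!r} "
                            f"on line {lineno}"
                        ) from None
    if n_coord_records == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")


def read_structures(
    path: str | Path,
    model_policy: str = "all",
    *,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a StructureEnsemble.

    One Structure per MODEL record (``model_policy='all'``) or only the
    first model (``'first'``).  Hydrogens and waters are dropped by default
    so that pocket detection is insensitive to whether the input carries
    protons.  Populations are set to a uniform placeholder (1/n_states)
    until a population table is attached with
    :meth:`StructureEnsemble.with_populations`.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if model_policy not in ("first", "all"):
        raise ConfigError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    _validate_pdb_text(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise ParseError(f"{path}: {exc}") from exc

    models = list(st)
    if model_policy == "first":
        models = models[:1]

    structures: list[Structure] = []
    for i, model in enumerate(models):
        atoms: list[AtomRecord] = []
        for chain in model:
            for res in chain:
                if not keep_waters and res.is_water():
                    continue
                for atom in res:
                    if not keep_hydrogens and atom.is_hydrogen():
                        continue
                    atoms.append(
                        AtomRecord(
                            element=atom.element.name.upper(),
                            name=atom.name,
                            residue_index=res.seqid.num,
                            chain_id=(chain.name or " ")[0],
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        )
                    )
        if not atoms:
            raise ParseError(f"{path}: no atoms retained in model {model.num}")
        ident = f"{path.stem}" if len(models) == 1 else f"{path.stem}:{model.num}"
        structures.append(Structure(identifier=ident, atoms=tuple(atoms)))

    n = len(structures)
    return StructureEnsemble(
        tuple(
            EnsembleState(state_id=s.identifier, structure=s, population=1.0 / n)
            for s in structures
        )
    )


# ---------------------------------------------------------------------------
# Radii


def assign_radii(
    structure: Structure,
    radius_set: str | Mapping[str, float] = "bondi",
    default: float = DEFAULT_RADIUS,
) -> Structure:
    """Return a copy of ``structure`` with van der Waals radii assigned.

    ``radius_set`` is a named table (``'bondi'``), a mapping
    element → radius (Å), or ``'keep'`` to leave existing radii untouched.
    Unknown elements fall back to ``default`` (one warning per element).
    """
    if radius_set == "keep":
        if not structure.has_radii:
            raise ContractError("radius_set='keep' but structure has atoms without radii")
        return structure
    if isinstance(radius_set, str):
        try:
            table = RADIUS_SETS[radius_set.lower()]
        except KeyError:
            raise ConfigError(f"unknown radius set {radius_set!r}") from None
    else:
        table = radius_set
    if not table:
        raise ConfigError("empty radius table")
    table = {k.upper(): float(v) for k, v in table.items()}

    warned: set[str] = set()
    new_atoms = []
    for atom in structure.atoms:
        r = table.get(atom.element)
        if r is None:
            if atom.element not in warned:
                logger.warning(
                    "element %r not in radius table; using default %.2f Å",
                    atom.element,
                    default,
                )
                warned.add(atom.element)
            r = default
        new_atoms.append(replace(atom, radius=r))
    return Structure(identifier=structure.identifier, atoms=tuple(new_atoms))


# ---------------------------------------------------------------------------
# PDB writing


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.identifier
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i, atom in enumerate(structure.atoms):
        ch = chains.get(atom.chain_id)
        if ch is None:
            ch = gemmi.Chain(atom.chain_id)
            chains[atom.chain_id] = ch
        if len(ch) == 0 or ch[-1].seqid.num != atom.residue_index:
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(atom.residue_index, " ")
            ch.add_residue(res)
        a = gemmi.Atom()
        a.name = atom.name
        a.element = gemmi.Element(atom.element.capitalize())
        a.pos = gemmi.Position(*atom.position)
        ch[-1].add_atom(a)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as single-model PDB."""
    _to_gemmi(structure).write_pdb(str(path))


def write_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per state)."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for i, state in enumerate(ensemble, start=1):
        single = _to_gemmi(state.structure)
        model = single[0]
        model.num = i
        st.add_model(model)
    st.write_pdb(str(path))


def write_pocket_overlay(pocket, grid, path: str | Path) -> None:
    """Write pocket voxels as HETATM pseudo-atoms at voxel-center coordinates.

    The overlay loads alongside the source structure in any molecular
    viewer and renders the detected cavity as a cloud of pseudo-atoms —
    the file analogue of drawing the pocket as a sphere on the fold.
    """
    indices = sorted(pocket.voxel_indices)
    if not indices:
        raise ContractError("refusing to write empty pocket")
    st = gemmi.Structure()
    st.name = "pocket"
    model = gemmi.Model("1")
    chain = gemmi.Chain("P")
    res = gemmi.Residue()
    res.name = "PKT"
    res.seqid = gemmi.SeqId(1, " ")
    for idx in indices:
        center = grid.voxel_center(idx)
        a = gemmi.Atom()
        a.name = "PS"
        a.element = gemmi.Element("He")
        a.pos = gemmi.Position(*center)
        res.add_atom(a)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write pocket overlay to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Population tables


def read_populations(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV ``state_id<TAB>population`` into a dict."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["state_id", "population"]:
        raise ParseError(
            f"{path}: expected header 'state_id<TAB>population', got {list(df.columns)}"
        )
    pops = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
    if any(v < 0 for v in pops.values()):
        raise ParseError(f"{path}: negative population")
    return pops


def write_populations(table: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"state_id": list(table.keys()), "population": list(table.values())}
    ).to_csv(path, sep="\t", index=False)
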