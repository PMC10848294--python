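"""Domain types and shared tables.

Everything downstream (SASA, interfacial area, SAP, conformation metrics)
operates on the types defined here: :class:`MolecularSystem` for a single
structure, :class:`Trajectory` for an ordered set of frames over a fixed
atom table, and the residue-level lookup tables (hydrophobicity scale,
reference exposed side-chain SASA, van der Waals radii).

Unit conventions: all lengths are nm, all areas nm², times ns.  PDB
Ångström coordinates are converted on read (see :mod:`surfads.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "MolecularSystem",
    "Trajectory",
    "ResidueEntry",
    "HydrophobicityScale",
    "ReferenceExposedSASA",
    "RadiiSet",
    "UnknownElementError",
    "UnknownResidueError",
    "load_default_radii",
    "load_default_scale",
    "load_default_reference_sasa",
    "assign_radii",
    "classify_hydrophobic",
    "DEFAULT_HYDROPHOBIC_SET",
    "BACKBONE_ATOM_NAMES",
    "STANDARD_RESIDUES",
    "ONE_TO_THREE",
    "ATOMIC_MASSES",
]

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Backbone atom names and their terminal/hydrogen variants.  Glycine's
# HA2/HA3 are deliberately NOT listed: they act as the side-chain proxy
# for SASA bookkeeping (glycine contributes zero to SAP regardless,
# because its hydrophobicity is zero on the shifted scale).
BACKBONE_ATOM_NAMES = frozenset({
    "N", "CA", "C", "O", "OXT", "H", "HA",
    "H1", "H2", "H3", "HN", "HT1", "HT2", "HT3", "OT1", "OT2",
})

# Hydrophobic residues under the shifted Black & Mould ranking; the set is
# configurable at call sites.  CYS and GLY are excluded.
DEFAULT_HYDROPHOBIC_SET = frozenset({
    "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "TYR",
})

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904,
}


class UnknownElementError(KeyError):
    """Raised when a radii set has no entry for an atom's element."""


class UnknownResidueError(KeyError):
    """Raised when a residue code is missing from a lookup table."""


@dataclass(frozen=True)
class Atom:
    """One atom: identity, residue membership, and assigned vdW radius (nm).

    ``radius`` is ``None`` until :func:`assign_radii` has run; geometry
    operations refuse systems with unassigned radii.
    """

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str = "A"
    radius: float | None = None

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOM_NAMES

    def __post_init__(self):
        if self.index < 0 or self.residue_index < 0:
            raise ValueError("atom and residue indices must be >= 0")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be > 0")


@dataclass(frozen=True)
class ResidueEntry:
    """Row of a residue table: internal index, identity, atom span.

    ``auth_seq_id`` retains the author numbering of the source file so
    user-facing tables can report both.
    """

    index: int
    name: str
    chain_id: str
    start: int          # first atom index (inclusive)
    stop: int           # past-the-end atom index
    auth_seq_id: int | None = None

    @property
    def atom_indices(self) -> range:
        return range(self.start, self.stop)


class MolecularSystem:
    """Atoms + positions (+ optional box), the substrate of all geometry.

    Parameters
    ----------
    atoms:
        Ordered atom list.  Residue indices must be grouped (all atoms of
        a residue contiguous) and non-decreasing within a chain.
    positions:
        (n_atoms, 3) array, nm.
    box:
        Optional orthorhombic box lengths (3,), nm.
    """

    def __init__(self, atoms: Sequence[Atom], positions: np.ndarray,
                 box: Sequence[float] | None = None):
        self.atoms = list(atoms)
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError(
                f"positions shape {positions.shape} does not match "
                f"{len(self.atoms)} atoms")
        self.positions = positions
        self.box = None if box is None else np.asarray(box, dtype=float)
        if self.box is not None and self.box.shape != (3,):
            raise ValueError("box must be three lengths")
        self.residue_table = self._build_residue_table()

    def _build_residue_table(self) -> list[ResidueEntry]:
        table: list[ResidueEntry] = []
        prev_key = None
        seen: set[tuple[str, int]] = set()
        prev_index_by_chain: dict[str, int] = {}
        for i, atom in enumerate(self.atoms):
            key = (atom.chain_id, atom.residue_index)
            if key != prev_key:
                if key in seen:
                    raise ValueError(
                        f"residue {atom.residue_index} of chain "
                        f"{atom.chain_id} is not contiguous in the atom list")
                last = prev_index_by_chain.get(atom.chain_id)
                if last is not None and atom.residue_index < last:
                    raise ValueError(
                        "residue indices must be non-decreasing within "
                        f"chain {atom.chain_id}")
                prev_index_by_chain[atom.chain_id] = atom.residue_index
                seen.add(key)
                table.append(ResidueEntry(
                    index=atom.residue_index, name=atom.residue_name,
                    chain_id=atom.chain_id, start=i, stop=i + 1))
                prev_key = key
            else:
                entry = table[-1]
                if atom.residue_name != entry.name:
                    raise ValueError(
                        f"conflicting names for residue {atom.residue_index}")
                table[-1] = replace(entry, stop=i + 1)
        return table

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_table)

    @property
    def radii(self) -> np.ndarray:
        """Per-atom radii (nm); NaN where unassigned."""
        return np.array([math.nan if a.radius is None else a.radius
                         for a in self.atoms])

    @property
    def sidechain_mask(self) -> np.ndarray:
        return np.array([a.is_sidechain for a in self.atoms], dtype=bool)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(a.element.upper(), 12.011)
                         for a in self.atoms])

    def residue_of_atom(self) -> np.ndarray:
        """Map atom index -> row of ``residue_table``."""
        out = np.empty(self.n_atoms, dtype=int)
        for row, entry in enumerate(self.residue_table):
            out[entry.start:entry.stop] = row
        return out

    def with_positions(self, positions: np.ndarray,
                       box: Sequence[float] | None = None) -> "MolecularSystem":
        return MolecularSystem(self.atoms, positions,
                               self.box if box is None else box)

    def translated(self, shift: Sequence[float]) -> "MolecularSystem":
        return self.with_positions(self.positions + np.asarray(shift, float))


@dataclass
class Frame:
    time_ns: float
    positions: np.ndarray
    box: np.ndarray | None = None


class Trajectory:
    """Ordered frames over a fixed atom table."""

    def __init__(self, system: MolecularSystem, frames: Iterable[Frame]):
        self.system = system
        self.frames = list(frames)
        n = system.n_atoms
        times = []
        for k, fr in enumerate(self.frames):
            fr.positions = np.asarray(fr.positions, dtype=float)
            if fr.positions.shape != (n, 3):
                raise ValueError(f"frame {k}: expected {n} atoms, "
                                 f"got {fr.positions.shape[0]}")
            if fr.box is not None:
                fr.box = np.asarray(fr.box, dtype=float)
            times.append(fr.time_ns)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time_ns for fr in self.frames])

    def system_at(self, k: int) -> MolecularSystem:
        fr = self.frames[k]
        return self.system.with_positions(fr.positions, fr.box)


# ---------------------------------------------------------------------------
# lookup tables

def _read_table(name: str) -> tuple[dict[str, float], str]:
    provenance = []
    mapping: dict[str, float] = {}
    text = (resources.files("surfads.data") / name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance.append(line.lstrip("# "))
            continue
        key, value = line.split()[:2]
        mapping[key.upper()] = float(value)
    return mapping, " ".join(p for p in provenance if p)


@dataclass(frozen=True)
class HydrophobicityScale:
    """Residue code -> dimensionless hydrophobicity R_h.

    The default is the Black & Mould scale shifted so R_h(GLY) = 0; with
    that shift positive values mark hydrophobic residues and glycine-only
    stretches contribute nothing to SAP or sequence hydrophobicity.
    """

    values: dict[str, float]
    scale_name: str = "custom"

    def __post_init__(self):
        missing = set(STANDARD_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"scale missing residues: {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue.upper()]
        except KeyError:
            raise UnknownResidueError(
                f"residue {residue!r} not in scale {self.scale_name!r}")

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self.values


@dataclass(frozen=True)
class ReferenceExposedSASA:
    """Residue code -> fully exposed side-chain SASA (nm²)."""

    values: dict[str, float]
    provenance: str = "custom"

    def __post_init__(self):
        missing = set(STANDARD_RESIDUES) - set(self.values)
        if missing:
            raise ValueError(f"reference table missing: {sorted(missing)}")
        bad = [r for r, v in self.values.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive reference areas: {bad}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue.upper()]
        except KeyError:
            raise UnknownResidueError(
                f"residue {residue!r} has no reference exposed SASA "
                f"({self.provenance})")


@dataclass(frozen=True)
class RadiiSet:
    """Element -> vdW radius (nm); lookup falls back to the leading
    alphabetic characters of the atom name."""

    values: dict[str, float]
    set_name: str = "custom"

    def __post_init__(self):
        required = {"H", "C", "N", "O", "S", "P"}
        missing = required - set(self.values)
        if missing:
            raise ValueError(f"radii set must cover {sorted(missing)}")

    def lookup(self, element: str, atom_name: str = "",
               residue_name: str = "") -> float:
        el = element.strip().upper()
        if el in self.values:
            return self.values[el]
        # fall back: leading element symbol of the atom name
        name = atom_name.strip().upper()
        if name:
            if name[:2] in self.values:
                return self.values[name[:2]]
            if name[0] in self.values:
                return self.values[name[0]]
        raise UnknownElementError(
            f"element {element!r} (atom {atom_name!r}, residue "
            f"{residue_name!r}) not in radii set {self.set_name!r}")


def load_default_radii() -> RadiiSet:
    values, prov = _read_table("bondi_radii.txt")
    return RadiiSet(values=values, set_name=f"Bondi ({prov.split('provenance:')[-1].strip() or 'packaged'})")


def load_default_scale() -> HydrophobicityScale:
    values, _ = _read_table("black_mould_shifted.txt")
    return HydrophobicityScale(values=values,
                               scale_name="Black-Mould shifted (GLY=0)")


def load_default_reference_sasa() -> ReferenceExposedSASA:
    values, _ = _read_table("reference_exposed_sasa.txt")
    return ReferenceExposedSASA(
        values=values,
        provenance="Miller et al. 1987 Gly-X-Gly side-chain areas; "
                   "GLY assigned 0.50 nm^2")


# ---------------------------------------------------------------------------
# operations

def assign_radii(system: MolecularSystem,
                 radii: RadiiSet | None = None) -> MolecularSystem:
    """Return a copy of ``system`` with every atom's vdW radius set.

    Deterministic, order-independent and idempotent: the radius depends
    only on the atom's element (with atom-name fallback).

    Raises
    ------
    UnknownElementError
        Naming the offending atom and residue.
    """
    radii = radii or load_default_radii()
    new_atoms = [
        replace(a, radius=radii.lookup(a.element, a.name, a.residue_name))
        for a in system.atoms
    ]
    return MolecularSystem(new_atoms, system.positions, system.box)


def classify_hydrophobic(residue_name: str,
                         scale: HydrophobicityScale | None = None,
                         hydrophobic_set: frozenset[str] | set[str] | None = None,
                         ) -> bool:
    """True iff ``residue_name`` belongs to the hydrophobic residue set.

    The residue must be known to ``scale`` (default: shifted Black &
    Mould); membership is decided by ``hydrophobic_set`` (default:
    ALA/VAL/LEU/ILE/PRO/PHE/MET/TRP/TYR).
    """
    scale = scale or load_default_scale()
    code = residue_name.upper()
    if code not in scale:
        raise UnknownResidueError(f"residue {residue_name!r} not in scale")
    members = DEFAULT_HYDROPHOBIC_SET if hydrophobic_set is None \
        else frozenset(c.upper() for c in hydrophobic_set)
    return code in members
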