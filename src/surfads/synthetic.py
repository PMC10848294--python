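"""Synthetic fixtures with known ground truth.

Every generator returns its ground truth alongside the data so tests
never have to reverse-engineer it from the data itself:

* single pseudo-atoms at a planar interface, with the analytic
  spherical-cap area as the vapor-exposure oracle;
* solvent slabs sampled from a tanh-bounded density with two planted
  interface planes;
* bead-model toy peptides (one backbone + one side-chain pseudo-atom
  per residue, side-chain radius growing with residue size) for SAP,
  SASA and sequence-mining fixtures;
* rigid peptides translated across a planted interface following a
  prescribed protrusion schedule, with a high-resolution quadrature
  oracle for the per-frame vapor-exposed area;
* Ala–X–Ala trimer fixtures for reference-exposure calculations.

The geometries are deliberately crude — ordering and contiguity of
exposure are what matters for the fixtures, not realistic peptide
stereochemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (Atom, Frame, MolecularSystem, ONE_TO_THREE,
                   STANDARD_RESIDUES, Trajectory, UnknownResidueError,
                   load_default_radii)
from .interface import InterfacePair

__all__ = [
    "ProtrusionSchedule", "SIDECHAIN_BEAD_RADII",
    "make_sphere_system", "spherical_cap_area", "make_solvent_slab",
    "make_toy_peptide", "make_adsorption_trajectory",
    "make_protrusion_schedule", "make_trimer_fixture",
    "make_random_cluster", "parse_sequence",
]

# fixture-only side-chain bead radii (nm): ordered by heavy-atom count,
# not physical
SIDECHAIN_BEAD_RADII = {
    "GLY": 0.10, "ALA": 0.15,
    "SER": 0.20, "THR": 0.20, "CYS": 0.20, "PRO": 0.20, "VAL": 0.20,
    "LEU": 0.25, "ILE": 0.25, "ASN": 0.25, "ASP": 0.25,
    "GLN": 0.30, "GLU": 0.30, "HIS": 0.30, "LYS": 0.30, "MET": 0.30,
    "PHE": 0.30, "ARG": 0.30, "TRP": 0.30, "TYR": 0.30,
}

_BACKBONE_BEAD_RADIUS = 0.17
_BOND_LENGTH = 0.38


@dataclass(frozen=True)
class ProtrusionSchedule:
    """Per-frame z-offset of the peptide's reference atom relative to the
    upper interface plane (nm)."""

    offsets: tuple[float, ...]
    seed: int = 0

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.offsets):
            raise ValueError("schedule offsets must be finite")

    def __len__(self) -> int:
        return len(self.offsets)


def spherical_cap_area(sphere_radius: float, plane_offset: float) -> float:
    """Area of the part of a sphere lying above a horizontal plane.

    ``plane_offset`` is the sphere center's height above the plane; the
    cap height is clipped to [0, 2R] (fully submerged / fully exposed).
    """
    h = np.clip(plane_offset + sphere_radius, 0.0, 2.0 * sphere_radius)
    return float(2.0 * math.pi * sphere_radius * h)


def make_sphere_system(radius: float, z_offset: float, interface_z: float,
                       probe_radius: float = 0.2,
                       ) -> tuple[MolecularSystem, float]:
    """One pseudo-atom at (0, 0, interface_z + z_offset) plus the analytic
    vapor-exposed-area oracle for the probe-expanded sphere."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    atom = Atom(index=0, name="C1", element="C", residue_index=0,
                residue_name="SPH", chain_id="A", radius=radius)
    system = MolecularSystem(
        [atom], np.array([[0.0, 0.0, interface_z + z_offset]]))
    oracle = spherical_cap_area(radius + probe_radius, z_offset)
    return system, oracle


def make_solvent_slab(n_particles: int = 20_000,
                      box: tuple[float, float, float] = (5.0, 5.0, 10.0),
                      z_center: float = 5.0, half_width: float = 2.0,
                      interface_width: float = 0.1, seed: int = 0,
                      n_frames: int = 1, dt_ns: float = 0.1,
                      ) -> tuple[Trajectory, tuple[float, float]]:
    """Solvent slab sampled from a tanh-bounded density profile.

    The planted interface planes sit at ``z_center ± half_width``; the
    density falls from its bulk value to zero over ``interface_width``.
    Returns the trajectory and the planted ``(z_lower, z_upper)``.
    """
    if not half_width > interface_width > 0:
        raise ValueError("need half_width > interface_width > 0")
    box = np.asarray(box, dtype=float)
    z_lower = z_center - half_width
    z_upper = z_center + half_width
    margin = 3.0 * interface_width
    if z_lower - margin < 0 or z_upper + margin > box[2]:
        raise ValueError("box too small for the requested slab")
    rng = np.random.default_rng(seed)
    # one shared residue: solvent particles need no per-residue identity,
    # and PDB residue ids wrap beyond 9999
    atoms = [Atom(index=i, name="OW", element="O", residue_index=0,
                  residue_name="HOH", chain_id="W", radius=0.152)
             for i in range(n_particles)]

    def sample_frame() -> np.ndarray:
        zs = np.empty(0)
        while len(zs) < n_particles:
            cand = rng.uniform(0.0, box[2], size=2 * n_particles)
            p = 0.5 * (np.tanh((cand - z_lower) / interface_width)
                       - np.tanh((cand - z_upper) / interface_width))
            keep = rng.uniform(size=len(cand)) < p
            zs = np.concatenate([zs, cand[keep]])
        zs = zs[:n_particles]
        xy = rng.uniform(0.0, box[:2], size=(n_particles, 2))
        return np.column_stack([xy, zs])

    frames = [Frame(time_ns=k * dt_ns, positions=sample_frame(), box=box)
              for k in range(n_frames)]
    system = MolecularSystem(atoms, frames[0].positions, box)
    return Trajectory(system, frames), (z_lower, z_upper)


def parse_sequence(sequence) -> list[str]:
    """Accept a list of 3-letter codes, a whitespace-separated 3-letter
    string, or a bare one-letter string ("GGG")."""
    if isinstance(sequence, str):
        tokens = sequence.split()
        if len(tokens) == 1 and len(tokens[0]) > 3 or (
                len(tokens) == 1 and tokens[0].upper() not in STANDARD_RESIDUES):
            tokens = list(tokens[0])
        codes = []
        for t in tokens:
            t = t.upper()
            if len(t) == 1:
                if t not in ONE_TO_THREE:
                    raise UnknownResidueError(f"unknown one-letter code {t!r}")
                codes.append(ONE_TO_THREE[t])
            else:
                codes.append(t)
    else:
        codes = [c.upper() for c in sequence]
    for c in codes:
        if c not in STANDARD_RESIDUES:
            raise UnknownResidueError(f"unknown residue code {c!r}")
    return codes


def make_toy_peptide(sequence, geometry: str = "extended", seed: int = 0,
                     bond_length: float = _BOND_LENGTH,
                     ) -> MolecularSystem:
    """Bead-model peptide: one backbone (CA) and one side-chain (CB)
    pseudo-atom per residue.

    Extended geometry places backbone beads along x with exact
    ``bond_length`` spacing and side-chain beads touching their backbone
    bead along +y; helixlike winds the backbone on a coarse helix with
    side chains pointing radially outward.  Deterministic for fixed
    inputs.
    """
    codes = parse_sequence(sequence)
    if not codes:
        raise ValueError("sequence must have length >= 1")
    if geometry not in ("extended", "helixlike"):
        raise ValueError(f"unknown geometry {geometry!r}")
    atoms: list[Atom] = []
    positions: list[np.ndarray] = []
    for i, code in enumerate(codes):
        r_sc = SIDECHAIN_BEAD_RADII[code]
        if geometry == "extended":
            ca = np.array([i * bond_length, 0.0, 0.0])
            cb = ca + np.array([0.0, _BACKBONE_BEAD_RADIUS + r_sc, 0.0])
        else:
            theta = math.radians(100.0) * i
            helix_r, rise = 0.23, 0.15
            ca = np.array([helix_r * math.cos(theta),
                           helix_r * math.sin(theta), rise * i])
            out_r = helix_r + _BACKBONE_BEAD_RADIUS + r_sc
            cb = np.array([out_r * math.cos(theta),
                           out_r * math.sin(theta), rise * i])
        atoms.append(Atom(index=2 * i, name="CA", element="C",
                          residue_index=i, residue_name=code,
                          radius=_BACKBONE_BEAD_RADIUS))
        atoms.append(Atom(index=2 * i + 1, name="CB", element="C",
                          residue_index=i, residue_name=code,
                          radius=r_sc))
        positions.extend([ca, cb])
    return MolecularSystem(atoms, np.array(positions))


def make_trimer_fixture(center_residue: str) -> MolecularSystem:
    """Ala–X–Ala extended trimer for reference-exposure calculations."""
    code = parse_sequence([center_residue])[0]
    return make_toy_peptide(["ALA", code, "ALA"])


def make_protrusion_schedule(n_frames: int, kind: str = "mixed",
                             z_min: float = -1.0, z_max: float = 0.5,
                             seed: int = 0) -> ProtrusionSchedule:
    """Prescribed reference-atom offsets: "submerged" (all below),
    "rising" (monotone ramp), or "mixed" (seeded random walk)."""
    if kind == "submerged":
        offs = np.full(n_frames, min(z_min, -1.0))
    elif kind == "rising":
        offs = np.linspace(z_min, z_max, n_frames)
    elif kind == "mixed":
        rng = np.random.default_rng(seed)
        steps = rng.uniform(-0.15, 0.2, size=n_frames)
        offs = np.clip(z_min + np.cumsum(steps), z_min, z_max)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return ProtrusionSchedule(offsets=tuple(float(v) for v in offs),
                              seed=seed)


def make_adsorption_trajectory(peptide: MolecularSystem,
                               schedule: ProtrusionSchedule,
                               interface_z: float = 5.0,
                               probe_radius: float = 0.2,
                               oracle_n_points: int = 9600,
                               dt_ns: float = 0.1,
                               ) -> tuple[Trajectory, np.ndarray,
                                          InterfacePair]:
    """Rigidly translate a peptide across a planted interface.

    The peptide's reference atom (its highest atom in the input
    geometry) is placed at ``interface_z + offset`` each frame.  The
    per-frame vapor-exposed-area oracle is computed by high-density
    quadrature (``oracle_n_points``, at least 10× a typical production
    point count).  Returns (trajectory, oracle A_ads per frame, the
    interface pair used).
    """
    from .adsorption import vapor_exposed_area  # deferred: avoids cycle
    ref_atom = int(np.argmax(peptide.positions[:, 2]))
    z_ref = peptide.positions[ref_atom, 2]
    z_span = peptide.positions[:, 2].max() - peptide.positions[:, 2].min()
    z_floor = (interface_z + min(schedule.offsets)
               - z_span - max(r for r in peptide.radii) - probe_radius - 5.0)
    pair = InterfacePair(z_lower=z_floor, z_upper=interface_z,
                         bulk_density=33.0,
                         method="planted (synthetic)")
    frames = []
    oracle = np.empty(len(schedule))
    for k, off in enumerate(schedule.offsets):
        shift = (interface_z + off) - z_ref
        pos = peptide.positions + np.array([0.0, 0.0, shift])
        frames.append(Frame(time_ns=k * dt_ns, positions=pos))
        oracle[k] = vapor_exposed_area(
            peptide.with_positions(pos), pair, probe_radius,
            oracle_n_points).total
    return Trajectory(peptide, frames), oracle, pair


def make_random_cluster(n_atoms: int, seed: int, spread: float = 0.55,
                        elements: tuple[str, ...] = ("C", "N", "O", "S"),
                        ) -> MolecularSystem:
    """Seeded random atomic cluster with Bondi radii (for oracle tests).

    ``spread`` (the Gaussian position scale) defaults to 0.55 nm, which
    makes neighbors genuinely occlude each other while leaving every
    atom an appreciable exposed fraction.
    """
    rng = np.random.default_rng(seed)
    radii = load_default_radii()
    atoms = []
    for i in range(n_atoms):
        el = elements[rng.integers(len(elements))]
        atoms.append(Atom(index=i, name=f"{el}{i}", element=el,
                          residue_index=0, residue_name="CLU",
                          radius=radii.lookup(el)))
    positions = rng.normal(scale=spread, size=(n_atoms, 3))
    return MolecularSystem(atoms, positions)
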