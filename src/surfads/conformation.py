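"""Conformation metrics: radius of gyration, RMSD, per-domain RMSD.

RMSD uses the standard least-squares rigid superposition (optimal proper
rotation via SVD, reflections excluded), unweighted over the selected
atoms.  Per-domain RMSD superposes each domain independently on its
reference counterpart, which removes interdomain translation/rotation by
construction and isolates intradomain deformation — useful when large
whole-molecule RMSD is dominated by rigid-body motion of the domains
(e.g. Fab arms swinging about the hinge of an antibody).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import MolecularSystem

__all__ = ["DomainDefinition", "radius_of_gyration", "rmsd", "domain_rmsd",
           "superpose"]


@dataclass(frozen=True)
class DomainDefinition:
    """Named set of residue-index ranges (inclusive bounds)."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.ranges:
            raise ValueError(f"domain {self.name}: no ranges")
        spans = sorted(self.ranges)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"domain {self.name}: overlapping ranges")
        for lo, hi in spans:
            if hi < lo:
                raise ValueError(f"domain {self.name}: empty range {lo}-{hi}")

    def atom_indices(self, system: MolecularSystem) -> np.ndarray:
        rows = [
            i for entry in system.residue_table
            for i in entry.atom_indices
            if any(lo <= entry.index <= hi for lo, hi in self.ranges)
        ]
        if not rows:
            raise ValueError(
                f"domain {self.name} selects no atoms in this system")
        return np.asarray(rows, dtype=int)


def _select(system: MolecularSystem, selection) -> np.ndarray:
    if selection is None:
        idx = np.arange(system.n_atoms)
    else:
        idx = np.asarray(list(selection), dtype=int)
    if len(idx) == 0:
        raise ValueError("empty atom selection")
    return idx


def radius_of_gyration(system: MolecularSystem, selection=None,
                       mass_weighted: bool = True) -> float:
    """Rg = sqrt(Σ mᵢ|rᵢ−r̄|² / Σ mᵢ), nm (default mass-weighted)."""
    idx = _select(system, selection)
    x = system.positions[idx]
    m = system.masses[idx] if mass_weighted else np.ones(len(idx))
    com = np.average(x, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((x - com) ** 2, axis=1),
                                    weights=m)))


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the residual RMSD (nm).
    The rotation is the optimal proper rotation (SVD, reflection
    excluded); coordinates are centered before rotation.
    """
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets differ in size")
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    moved = rot.apply(mob_c) + reference.mean(axis=0)
    value = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, value


def rmsd(system: MolecularSystem, reference: MolecularSystem,
         selection=None, superpose_first: bool = True) -> float:
    """RMSD between two structures over a selection, nm.

    With ``superpose_first`` (default) the minimal RMSD over rigid
    transforms; otherwise the raw coordinate RMSD.
    """
    idx = _select(system, selection)
    a = system.positions[idx]
    b = reference.positions[idx] if reference.n_atoms == system.n_atoms \
        else reference.positions
    if a.shape != b.shape:
        raise ValueError("selection sizes differ between structures")
    if superpose_first:
        _, value = superpose(a, b)
        return value
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def domain_rmsd(system: MolecularSystem, reference: MolecularSystem,
                domains: list[DomainDefinition]) -> dict[str, float]:
    """Per-domain RMSD with each domain independently superposed."""
    out: dict[str, float] = {}
    for dom in domains:
        idx = dom.atom_indices(system)
        ref_idx = dom.atom_indices(reference)
        if len(idx) != len(ref_idx):
            raise ValueError(f"domain {dom.name}: atom counts differ")
        _, value = superpose(system.positions[idx],
                             reference.positions[ref_idx])
        out[dom.name] = value
    return out
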