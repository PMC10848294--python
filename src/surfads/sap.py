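"""Spatial aggregation propensity (SAP).

SAP quantifies the solvent-exposed hydrophobicity around each atom: for
atom j it sums, over every residue with at least one side-chain atom
within a cutoff distance r of j (0.5 nm by default), the SASA of that
residue's side-chain atoms inside the cutoff divided by the residue's
fully exposed side-chain reference SASA, weighted by the residue's
(shifted Black & Mould) hydrophobicity.  Positive per-atom SAP marks an
exposed hydrophobic patch.  The residue SAP is the mean over its atoms,
and the SAP score of a protein is the sum of the positive residue SAPs.

Distances are center-to-center between atom j and candidate side-chain
atoms; the time average runs over the requested frame range (a single
structure is a one-frame average).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import (HydrophobicityScale, MolecularSystem,
                   ReferenceExposedSASA, Trajectory, UnknownResidueError,
                   load_default_reference_sasa, load_default_scale)
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, compute_sasa

__all__ = ["SapResult", "sap_per_atom", "sap_per_residue", "sap_score",
           "compute_sap", "DEFAULT_SAP_CUTOFF"]

#: neighborhood radius r for the SAP sum (nm)
DEFAULT_SAP_CUTOFF = 0.5


@dataclass
class SapResult:
    per_atom: np.ndarray
    per_residue: np.ndarray
    sap_score: float
    r_cutoff: float
    probe_radius: float
    frames_averaged: int
    residue_names: list[str]
    residue_indices: list[int]


def _sap_single_frame(system: MolecularSystem,
                      per_atom_sasa: np.ndarray,
                      scale: HydrophobicityScale,
                      ref: ReferenceExposedSASA,
                      r_cutoff: float) -> np.ndarray:
    res_of_atom = system.residue_of_atom()
    sc_mask = system.sidechain_mask
    sc_idx = np.flatnonzero(sc_mask)
    rh = np.empty(system.n_residues)
    ref_area = np.empty(system.n_residues)
    for row, entry in enumerate(system.residue_table):
        if entry.name not in scale:
            raise UnknownResidueError(
                f"residue {entry.name} missing from hydrophobicity scale")
        rh[row] = scale[entry.name]
        ref_area[row] = ref[entry.name]

    out = np.zeros(system.n_atoms)
    if len(sc_idx) == 0:
        return out
    sc_tree = cKDTree(system.positions[sc_idx])
    for j in range(system.n_atoms):
        # side-chain atoms within r of atom j (center-to-center, <= r)
        hits = sc_tree.query_ball_point(system.positions[j], r_cutoff)
        if not hits:
            continue
        atoms_in = sc_idx[np.asarray(hits)]
        sasa_sum = np.bincount(res_of_atom[atoms_in],
                               weights=per_atom_sasa[atoms_in],
                               minlength=system.n_residues)
        qualifying = np.flatnonzero(
            np.bincount(res_of_atom[atoms_in],
                        minlength=system.n_residues) > 0)
        out[j] = float(np.sum(sasa_sum[qualifying] / ref_area[qualifying]
                              * rh[qualifying]))
    return out


def sap_per_atom(source: MolecularSystem | Trajectory,
                 scale: HydrophobicityScale | None = None,
                 ref: ReferenceExposedSASA | None = None,
                 r_cutoff: float = DEFAULT_SAP_CUTOFF,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = DEFAULT_N_POINTS,
                 frame_range: tuple[int, int] | None = None,
                 ) -> np.ndarray:
    """Time-averaged per-atom SAP.

    ``source`` may be a single structure (one-frame average) or a
    trajectory, in which case the SAP of every frame in ``frame_range``
    is averaged.
    """
    if r_cutoff <= 0:
        raise ValueError("r_cutoff must be > 0")
    scale = scale or load_default_scale()
    ref = ref or load_default_reference_sasa()
    if isinstance(source, Trajectory):
        lo, hi = (0, len(source)) if frame_range is None else frame_range
        frames = [source.system_at(k) for k in range(lo, hi)]
    else:
        frames = [source]
    if not frames:
        raise ValueError("no frames to average")
    acc = np.zeros(frames[0].n_atoms)
    for system in frames:
        sasa = compute_sasa(system, probe_radius, n_points)
        acc += _sap_single_frame(system, sasa.per_atom_area, scale, ref,
                                 r_cutoff)
    return acc / len(frames)


def sap_per_residue(per_atom_sap: np.ndarray,
                    system: MolecularSystem) -> np.ndarray:
    """Residue SAP: arithmetic mean over the residue's member atoms."""
    out = np.empty(system.n_residues)
    for row, entry in enumerate(system.residue_table):
        out[row] = per_atom_sap[entry.start:entry.stop].mean()
    return out


def sap_score(per_residue_sap: np.ndarray) -> float:
    """Sum of strictly positive residue SAP values (0 if none)."""
    v = np.asarray(per_residue_sap, dtype=float)
    return float(v[v > 0].sum())


def compute_sap(source: MolecularSystem | Trajectory,
                scale: HydrophobicityScale | None = None,
                ref: ReferenceExposedSASA | None = None,
                r_cutoff: float = DEFAULT_SAP_CUTOFF,
                probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_points: int = DEFAULT_N_POINTS,
                frame_range: tuple[int, int] | None = None) -> SapResult:
    """Convenience wrapper: per-atom SAP, residue SAP and SAP score."""
    system = source.system if isinstance(source, Trajectory) else source
    per_atom = sap_per_atom(source, scale, ref, r_cutoff, probe_radius,
                            n_points, frame_range)
    per_res = sap_per_residue(per_atom, system)
    if isinstance(source, Trajectory):
        lo, hi = (0, len(source)) if frame_range is None else frame_range
        n_frames = hi - lo
    else:
        n_frames = 1
    return SapResult(per_atom=per_atom, per_residue=per_res,
                     sap_score=sap_score(per_res), r_cutoff=r_cutoff,
                     probe_radius=probe_radius, frames_averaged=n_frames,
                     residue_names=[e.name for e in system.residue_table],
                     residue_indices=[e.index for e in system.residue_table])
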