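"""Readers, writers and run configuration.

PDB structures are read and written through biotite; coordinates are
converted Å → nm on read and back on write.  Trajectories use a plain
multi-frame XYZ dialect: per frame an atom-count line, a comment line
``time=<ns> box=<lx> <ly> <lz>``, then ``element x y z`` in nm.

The run configuration is a flat ``key: value`` text file mirroring
:class:`RunConfig`; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .core import (Atom, Frame, MolecularSystem, RadiiSet, Trajectory,
                   assign_radii, load_default_radii)

__all__ = ["RunConfig", "read_pdb", "write_pdb", "read_xyz_trajectory",
           "write_xyz_trajectory", "read_config", "write_json"]

logger = logging.getLogger("surfads")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    The defaults are the working values of the analysis: probe 0.14 nm
    for generic SASA, 0.2 nm for vapor-area work, neighborhood radius
    0.5 nm for SAP, contribution cutoff 0.5 nm² for the adsorption
    score, 0.1 nm² for sequence mining, and a trailing averaging window
    of 0.75 (the last 150 ns of a 200 ns trajectory).
    """

    structure: str = ""
    trajectory: str = ""
    output_dir: str = "surfads_out"
    probe_sasa: float = 0.14
    probe_vapor: float = 0.2
    n_points: int = 960
    score_cutoff: float = 0.5
    sequence_threshold: float = 0.1
    aads_floor: float = 0.1
    window_fraction: float = 0.75
    sap_r_cutoff: float = 0.5
    axis: str = "z"
    bin_width: float = 0.05
    seed: int = 0
    score_denominator: str = "contributing"   # or "total"
    running_window: int = 10

    def __post_init__(self):
        positive = ["probe_vapor", "n_points", "window_fraction",
                    "sap_r_cutoff", "bin_width", "running_window"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be > 0")
        for name in ["probe_sasa", "score_cutoff", "sequence_threshold",
                     "aads_floor"]:
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name} must be >= 0")
        if self.axis not in ("x", "y", "z"):
            raise ValueError("axis must be x, y or z")
        if self.score_denominator not in ("contributing", "total"):
            raise ValueError("score_denominator must be 'contributing' "
                             "or 'total'")

    def metadata(self) -> dict:
        return dataclasses.asdict(self)


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key: value`` config file; unknown keys error."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value'")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = fields[key].type
        if ftype in ("float", float):
            kwargs[key] = float(value)
        elif ftype in ("int", int):
            kwargs[key] = int(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


_ELEMENT_GUESSES = ("CL", "BR", "C", "N", "O", "S", "P", "H", "F", "I")


def _infer_element(atom_name: str) -> str:
    name = "".join(c for c in atom_name.upper() if c.isalpha())
    for guess in _ELEMENT_GUESSES:
        if name.startswith(guess):
            return guess
    return name[:1] or "C"


def read_pdb(path: str | Path, radii: RadiiSet | None = None,
             assign: bool = True,
             radii_from_bfactor: bool = False) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem` (coordinates nm).

    Residue numbering of the file is retained as ``auth_seq_id`` on the
    residue table; internal residue indices are 0-based and contiguous
    in order of appearance.  Blank element columns fall back to
    inference from the atom name (logged as a warning).  With ``assign``
    (default) vdW radii are assigned from ``radii`` (default Bondi).

    ``radii_from_bfactor`` reads per-atom radii (nm) from the B-factor
    column instead — the convention :func:`write_pdb` uses to round-trip
    the bead radii of synthetic fixtures, which have no physical
    element radii.
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    arr = pdb_file.get_structure(
        model=1, extra_fields=["b_factor"] if radii_from_bfactor else [])
    atoms: list[Atom] = []
    res_key_to_index: dict[tuple, int] = {}
    auth_ids: list[int] = []
    for i in range(arr.array_length()):
        element = arr.element[i].strip()
        if not element:
            element = _infer_element(arr.atom_name[i])
            logger.warning("atom %s/%s: element column blank, inferred %r",
                           arr.res_name[i], arr.atom_name[i], element)
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.ins_code[i])
        if key not in res_key_to_index:
            res_key_to_index[key] = len(res_key_to_index)
            auth_ids.append(int(arr.res_id[i]))
        radius = None
        if radii_from_bfactor:
            radius = float(arr.b_factor[i])
            if radius <= 0:
                raise ValueError(
                    f"atom {arr.atom_name[i]}: non-positive B-factor "
                    "radius; file was not written with bfactor_radii")
        atoms.append(Atom(
            index=i, name=arr.atom_name[i].strip(), element=element,
            residue_index=res_key_to_index[key],
            residue_name=arr.res_name[i].strip(),
            chain_id=str(arr.chain_id[i]).strip() or "A",
            radius=radius))
    system = MolecularSystem(atoms, arr.coord / 10.0)   # Å -> nm
    for entry_i, entry in enumerate(system.residue_table):
        system.residue_table[entry_i] = dataclasses.replace(
            entry, auth_seq_id=auth_ids[entry.index])
    if assign and not radii_from_bfactor:
        system = assign_radii(system, radii or load_default_radii())
    return system


def write_pdb(system: MolecularSystem, path: str | Path,
              bfactor_radii: bool = False) -> None:
    """Write a :class:`MolecularSystem` as PDB (nm → Å).

    With ``bfactor_radii`` the per-atom radii (nm) are stored in the
    B-factor column so synthetic bead models survive a round trip.
    """
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = system.positions * 10.0
    if bfactor_radii:
        arr.set_annotation("b_factor", system.radii)
    for i, atom in enumerate(system.atoms):
        arr.chain_id[i] = atom.chain_id[:4]
        arr.res_id[i] = atom.residue_index + 1
        arr.res_name[i] = atom.residue_name[:5]
        arr.atom_name[i] = atom.name[:6]
        arr.element[i] = atom.element[:2]
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_xyz_trajectory(traj: Trajectory, path: str | Path,
                         precision: int = 6) -> None:
    """Write the multi-frame XYZ dialect (positions in nm)."""
    lines: list[str] = []
    for fr in traj.frames:
        lines.append(str(traj.system.n_atoms))
        box = fr.box if fr.box is not None else (0.0, 0.0, 0.0)
        lines.append(f"time={fr.time_ns:.6f} "
                     f"box={box[0]:.6f} {box[1]:.6f} {box[2]:.6f}")
        for atom, pos in zip(traj.system.atoms, fr.positions):
            lines.append(f"{atom.element} "
                         + " ".join(f"{v:.{precision}f}" for v in pos))
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_trajectory(path: str | Path,
                        topology: MolecularSystem) -> Trajectory:
    """Read the multi-frame XYZ dialect against a fixed topology."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i, frame_idx = 0, 0
    n_expect = topology.n_atoms
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"frame {frame_idx}: bad atom-count line "
                             f"at line {i + 1}")
        if count != n_expect:
            raise ValueError(f"frame {frame_idx}: {count} atoms, topology "
                             f"has {n_expect}")
        if i + 1 >= len(lines):
            raise ValueError(f"frame {frame_idx}: missing comment line")
        header = lines[i + 1].split()
        time_ns = box = None
        for tok in header:
            if tok.startswith("time="):
                time_ns = float(tok[5:])
            elif tok.startswith("box="):
                box = [float(tok[4:])]
            elif box is not None and len(box) < 3:
                box.append(float(tok))
        if time_ns is None:
            raise ValueError(f"frame {frame_idx}: comment line lacks time=")
        body = lines[i + 2: i + 2 + count]
        if len(body) < count:
            raise ValueError(f"frame {frame_idx}: truncated "
                             f"({len(body)}/{count} atom lines)")
        pos = np.empty((count, 3))
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"frame {frame_idx}: malformed atom line {k}")
            pos[k] = [float(v) for v in parts[1:4]]
        box_arr = None
        if box is not None and len(box) == 3 and any(v > 0 for v in box):
            box_arr = np.asarray(box)
        frames.append(Frame(time_ns=time_ns, positions=pos, box=box_arr))
        i += 2 + count
        frame_idx += 1
    if not frames:
        raise ValueError("no frames found")
    return Trajectory(topology, frames)


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o).__name__)
    Path(path).write_text(json.dumps(payload, indent=2, default=default)
                          + "\n")
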