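"""Locate the liquid/vapor planes of a solvent slab.

The slab's number-density profile along the interface normal is
histogrammed and the two interface planes are placed where the density
crosses half its bulk value — the Gibbs-dividing-surface convention.
Everything outside the two planes (higher and lower along the normal)
is the vapor region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory

__all__ = ["DensityProfile", "InterfacePair", "density_profile",
           "locate_interfaces", "interfaces_per_frame"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class DensityProfile:
    """Time-averaged number density along one box axis."""

    axis: str
    bin_edges: np.ndarray      # (n_bins+1,) nm
    density: np.ndarray        # (n_bins,) nm^-3
    frames_averaged: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class InterfacePair:
    """The two liquid/vapor planes of a slab along the profile axis."""

    z_lower: float
    z_upper: float
    bulk_density: float
    method: str = "half-bulk-density crossing (Gibbs dividing surface)"
    axis: str = "z"

    def __post_init__(self):
        if not self.z_lower < self.z_upper:
            raise ValueError("z_lower must be < z_upper")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be > 0")

    def in_vapor(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask: which points lie on the vapor side of the nearer
        plane (strictly outside the slab)."""
        w = coords[:, _AXES[self.axis]]
        return (w > self.z_upper) | (w < self.z_lower)


def density_profile(traj: Trajectory, solvent_atom_indices,
                    axis: str = "z", bin_width: float = 0.05,
                    frame_range: tuple[int, int] | None = None,
                    ) -> DensityProfile:
    """Time-averaged solvent number density in uniform bins along ``axis``.

    The normalization is per frame: counts divided by the bin volume
    (bin width × the box cross-section perpendicular to ``axis``), then
    averaged over frames, so integrating the profile recovers the mean
    solvent atom count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ax = _AXES[axis]
    idx = np.asarray(solvent_atom_indices, dtype=int)
    frames = traj.frames if frame_range is None \
        else traj.frames[frame_range[0]:frame_range[1]]
    if not frames:
        raise ValueError("no frames in range")
    for k, fr in enumerate(frames):
        if fr.box is None:
            raise ValueError(f"frame {k} has no box; density needs a volume")
    length = max(fr.box[ax] for fr in frames)
    n_bins = max(1, int(round(length / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    acc = np.zeros(n_bins)
    for fr in frames:
        coords = fr.positions[idx, ax] if len(idx) else np.empty(0)
        counts, _ = np.histogram(coords, bins=edges)
        cross_section = np.prod([fr.box[a] for a in range(3) if a != ax])
        acc += counts / (bin_width * cross_section)
    return DensityProfile(axis=axis, bin_edges=edges,
                          density=acc / len(frames),
                          frames_averaged=len(frames))


def locate_interfaces(profile: DensityProfile) -> InterfacePair:
    """Place the two planes at the outermost half-bulk density crossings.

    The bulk density is the mean over the central 50% of the occupied
    region (bins above half the profile maximum); each plane is found by
    linear interpolation between the bin centers that bracket the
    half-bulk level, scanning inward from either end.

    Raises
    ------
    ValueError
        "no interface detectable" for uniform or empty profiles.
    """
    rho = profile.density
    centers = profile.bin_centers
    if rho.max() <= 0:
        raise ValueError("no interface detectable: empty profile")
    occupied = np.flatnonzero(rho > 0.5 * rho.max())
    lo, hi = occupied[0], occupied[-1]
    span = hi - lo + 1
    c0 = lo + span // 4
    c1 = hi - span // 4
    bulk = float(rho[c0:c1 + 1].mean())
    half = 0.5 * bulk

    below = rho < half
    if not below.any():
        raise ValueError("no interface detectable: profile never falls "
                         "below half of the bulk density (uniform slab?)")

    def crossing(i_out: int, step: int) -> float:
        # walk inward from bin i_out until density rises through `half`
        i = i_out
        while 0 <= i + step < len(rho):
            if rho[i] < half <= rho[i + step]:
                z0, z1 = centers[i], centers[i + step]
                r0, r1 = rho[i], rho[i + step]
                return float(z0 + (half - r0) / (r1 - r0) * (z1 - z0))
            i += step
        raise ValueError("no interface detectable")

    z_lower = crossing(0, +1)
    z_upper = crossing(len(rho) - 1, -1)
    return InterfacePair(z_lower=z_lower, z_upper=z_upper,
                         bulk_density=bulk, axis=profile.axis)


def interfaces_per_frame(traj: Trajectory, solvent_atom_indices,
                         axis: str = "z", bin_width: float = 0.05,
                         averaged: bool = False,
                         ) -> list[InterfacePair]:
    """Interface planes per frame (default) or one trajectory-averaged
    pair replicated across frames (``averaged=True``)."""
    if averaged:
        prof = density_profile(traj, solvent_atom_indices, axis, bin_width)
        pair = locate_interfaces(prof)
        return [pair] * len(traj)
    out = []
    for k in range(len(traj)):
        prof = density_profile(traj, solvent_atom_indices, axis, bin_width,
                               frame_range=(k, k + 1))
        out.append(locate_interfaces(prof))
    return out
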