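"""Interfacial adsorption statistics.

The central quantity is the vapor-exposed area A_ads: the part of a
protein's solvent-accessible surface that lies on the vapor side of the
water/vapor interface plane(s).  Each accessible surface point is
classified by its own position (not its owner atom's center) against the
nearer plane, so A_ads is genuinely a property of the accessible
surface, and the per-atom / per-residue / total values partition
exactly.

On top of A_ads this module builds the residue-level adsorption score
(mean of per-simulation A_ads values above a 0.5 nm² cutoff),
adsorbing-sequence mining (maximal runs of residues with A_ads above
0.1 nm²), the per-residue normalized sequence area, hydrophobicity
correlations, residue-species composition, the cumulative hydrophobic
SASA time series, and the γ·A_ads interfacial free-energy estimate.

All cutoffs are strict (>, not ≥): a value exactly at a cutoff does not
adsorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .core import (DEFAULT_HYDROPHOBIC_SET, HydrophobicityScale,
                   MolecularSystem, Trajectory, load_default_scale)
from .interface import InterfacePair
from .sasa import (DEFAULT_N_POINTS, VAPOR_PROBE_RADIUS, SasaResult,
                   sasa_from_points, surface_points)

__all__ = [
    "VaporAreaResult", "ResidueAreaSeries",
    "AdsorbingSequence", "HydrophobicityAreaStats", "SurfaceFreeEnergy",
    "vapor_exposed_area", "aads_timeseries", "time_average", "delta_sasa",
    "adsorption_score", "mine_adsorbing_sequences",
    "normalized_sequence_area", "sequence_hydrophobicity",
    "hydrophobicity_area_stats", "species_composition",
    "cumulative_hydrophobic_sasa", "surface_free_energy",
    "SCORE_CUTOFF", "SEQUENCE_THRESHOLD",
]

#: per-simulation contribution cutoff for the adsorption score (nm²)
SCORE_CUTOFF = 0.5
#: per-residue threshold for adsorbing-sequence mining (nm²)
SEQUENCE_THRESHOLD = 0.1

_KB = 1.380649e-23          # J/K
_NA = 6.02214076e23         # 1/mol


@dataclass
class VaporAreaResult:
    """A_ads split of one configuration, alongside its full SASA."""

    per_atom: np.ndarray          # (n_atoms,) nm²
    per_residue: np.ndarray       # (n_residues,) nm²
    total: float                  # nm²
    sasa: SasaResult
    interfaces: InterfacePair


@dataclass
class ResidueAreaSeries:
    """Per-frame A_ads and SASA of one residue."""

    residue_index: int
    residue_name: str
    chain_id: str
    times_ns: np.ndarray
    aads: np.ndarray              # nm²
    sasa: np.ndarray              # nm²
    probe_radius: float


@dataclass
class AdsorbingSequence:
    """A maximal contiguous run of adsorbing residues in one chain."""

    chain_id: str
    start: int                    # residue index, inclusive
    end: int                      # residue index, inclusive
    residue_names: list[str]
    mean_aads: list[float]        # nm², one per member
    threshold: float

    def __len__(self) -> int:
        return len(self.residue_names)


@dataclass
class HydrophobicityAreaStats:
    """A_ads vs residue hydrophobicity for surface-active residues."""

    pairs: np.ndarray             # (n, 2): R_h, A_ads
    group_rh: np.ndarray          # unique R_h values
    group_mean: np.ndarray
    group_sd: np.ndarray
    pearson_r: float
    slope: float
    slope_stderr: float
    intercept: float
    floor: float


@dataclass
class SurfaceFreeEnergy:
    joules: float
    kBT: float
    kJ_per_mol: float


def vapor_exposed_area(system: MolecularSystem,
                       interfaces: InterfacePair,
                       probe_radius: float = VAPOR_PROBE_RADIUS,
                       n_points: int = DEFAULT_N_POINTS) -> VaporAreaResult:
    """Area of the accessible surface protruding into the vapor phase.

    Sums the weights of accessible surface points whose position lies in
    the vapor region (above the upper plane or below the lower one).
    """
    cloud = surface_points(system, probe_radius, n_points)
    sasa = sasa_from_points(system, cloud)
    vapor = interfaces.in_vapor(cloud.positions) if len(cloud) else \
        np.empty(0, dtype=bool)
    per_atom = np.bincount(cloud.owner[vapor],
                           weights=cloud.weights[vapor],
                           minlength=system.n_atoms)
    per_res = np.zeros(system.n_residues)
    for row, entry in enumerate(system.residue_table):
        per_res[row] = per_atom[entry.start:entry.stop].sum()
    return VaporAreaResult(per_atom=per_atom, per_residue=per_res,
                           total=float(per_atom.sum()), sasa=sasa,
                           interfaces=interfaces)


def aads_timeseries(traj: Trajectory,
                    interfaces: InterfacePair | list[InterfacePair],
                    probe_radius: float = VAPOR_PROBE_RADIUS,
                    n_points: int = DEFAULT_N_POINTS,
                    frame_range: tuple[int, int] | None = None,
                    ) -> tuple[list[ResidueAreaSeries], np.ndarray]:
    """Per-residue A_ads(t) and SASA(t) plus the total A_ads series."""
    lo, hi = (0, len(traj)) if frame_range is None else frame_range
    frames = range(lo, hi)
    if isinstance(interfaces, InterfacePair):
        planes = [interfaces] * len(frames)
    else:
        planes = list(interfaces)
        if len(planes) != len(frames):
            raise ValueError(
                f"{len(planes)} interface pairs for {len(frames)} frames")
    n_res = traj.system.n_residues
    aads = np.zeros((len(frames), n_res))
    sasa = np.zeros((len(frames), n_res))
    for k, f in enumerate(frames):
        res = vapor_exposed_area(traj.system_at(f), planes[k],
                                 probe_radius, n_points)
        aads[k] = res.per_residue
        sasa[k] = res.sasa.per_residue_area
    times = traj.times[lo:hi]
    series = [
        ResidueAreaSeries(
            residue_index=entry.index, residue_name=entry.name,
            chain_id=entry.chain_id, times_ns=times,
            aads=aads[:, row], sasa=sasa[:, row],
            probe_radius=probe_radius)
        for row, entry in enumerate(traj.system.residue_table)
    ]
    return series, aads.sum(axis=1)


def time_average(values: np.ndarray,
                 window_fraction: float = 0.75) -> float | np.ndarray:
    """Arithmetic mean over the trailing fraction of a series.

    The default 0.75 mirrors averaging the last 150 ns of a 200 ns
    trajectory.  Works on 1-D series and on (n_frames, n_residues)
    arrays (axis 0 is time).
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    n_win = int(round(window_fraction * n))
    if n_win < 1:
        raise ValueError("empty trailing window")
    tail = values[n - n_win:]
    out = tail.mean(axis=0)
    return float(out) if np.ndim(out) == 0 else out


def delta_sasa(native: SasaResult, other: SasaResult) -> np.ndarray:
    """Per-residue ΔSASA = SASA(other) − SASA(native).

    Positive values mark residues more exposed in ``other`` (e.g. a
    locally unfolded conformer) than in the native reference.
    Antisymmetric under argument swap.
    """
    if (native.residue_indices != other.residue_indices
            or native.residue_names != other.residue_names):
        raise ValueError("residue tables differ between the two results")
    return other.per_residue_area - native.per_residue_area


def adsorption_score(per_sim_aads: np.ndarray,
                     cutoff: float = SCORE_CUTOFF,
                     residue_names: list[str] | None = None,
                     residue_indices: list[int] | None = None,
                     denominator: str = "contributing") -> pd.DataFrame:
    """Residue adsorption score S across repeat simulations.

    ``per_sim_aads`` is (n_simulations, n_residues): the time-averaged
    A_ads of each residue in each simulation.  A value contributes only
    if strictly above ``cutoff`` (default 0.5 nm²).  Under the default
    convention S is the mean of the contributing values (0 if none);
    ``denominator="total"`` divides the sum by the total number of
    simulations instead.  The convention used is recorded in
    ``DataFrame.attrs``.
    """
    if denominator not in ("contributing", "total"):
        raise ValueError("denominator must be 'contributing' or 'total'")
    vals = np.atleast_2d(np.asarray(per_sim_aads, dtype=float))
    n_sims, n_res = vals.shape
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    mask = vals > cutoff
    n_contrib = mask.sum(axis=0)
    total = np.where(mask, vals, 0.0).sum(axis=0)
    if denominator == "contributing":
        with np.errstate(invalid="ignore"):
            score = np.where(n_contrib > 0, total / np.maximum(n_contrib, 1),
                             0.0)
    else:
        score = total / n_sims
    df = pd.DataFrame({
        "residue_index": residue_indices if residue_indices is not None
        else np.arange(n_res),
        "residue_name": residue_names if residue_names is not None
        else [""] * n_res,
        "score_nm2": score,
        "n_contributing": n_contrib,
        "n_simulations": n_sims,
    })
    df.attrs["cutoff_nm2"] = cutoff
    df.attrs["denominator"] = denominator
    return df


def mine_adsorbing_sequences(mean_aads: np.ndarray,
                             system: MolecularSystem,
                             threshold: float = SEQUENCE_THRESHOLD,
                             min_length: int = 2,
                             ) -> tuple[list[AdsorbingSequence],
                                        list[AdsorbingSequence]]:
    """Maximal contiguous runs of residues with mean A_ads > threshold.

    Every member of a run must individually exceed the threshold; runs
    shorter than ``min_length`` are returned separately as singletons
    rather than silently dropped.  Ordering is by chain then start
    index.  Returns ``(sequences, singletons)``.
    """
    mean_aads = np.asarray(mean_aads, dtype=float)
    table = system.residue_table
    if len(mean_aads) != len(table):
        raise ValueError("mean_aads length does not match residue table")
    runs: list[list[int]] = []
    current: list[int] = []
    for row, entry in enumerate(table):
        above = mean_aads[row] > threshold
        contiguous = bool(current) and (
            entry.chain_id == table[current[-1]].chain_id
            and entry.index == table[current[-1]].index + 1)
        if above and (not current or contiguous):
            current.append(row)
        else:
            if current:
                runs.append(current)
            current = [row] if above else []
    if current:
        runs.append(current)

    def build(rows: list[int]) -> AdsorbingSequence:
        return AdsorbingSequence(
            chain_id=table[rows[0]].chain_id,
            start=table[rows[0]].index, end=table[rows[-1]].index,
            residue_names=[table[r].name for r in rows],
            mean_aads=[float(mean_aads[r]) for r in rows],
            threshold=threshold)

    runs.sort(key=lambda rows: (table[rows[0]].chain_id,
                                table[rows[0]].index))
    sequences = [build(r) for r in runs if len(r) >= min_length]
    singletons = [build(r) for r in runs if len(r) < min_length]
    return sequences, singletons


def normalized_sequence_area(seq: AdsorbingSequence) -> float:
    """Normalized adsorption area: mean member A_ads, nm² per residue."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return float(np.mean(seq.mean_aads))


def sequence_hydrophobicity(seq: AdsorbingSequence,
                            scale: HydrophobicityScale | None = None,
                            ) -> float:
    """Cumulative hydrophobicity: sum of member R_h values."""
    scale = scale or load_default_scale()
    return float(sum(scale[name] for name in seq.residue_names))


def hydrophobicity_area_stats(residue_names, mean_aads,
                              scale: HydrophobicityScale | None = None,
                              floor: float = SEQUENCE_THRESHOLD,
                              ) -> HydrophobicityAreaStats:
    """Correlate per-residue A_ads with residue hydrophobicity.

    Residues with A_ads > ``floor`` (default 0.1 nm²) enter as scatter
    points; residues sharing an R_h value are additionally summarized by
    their group mean and standard deviation.  Pearson correlation and an
    ordinary least-squares slope describe the trend.
    """
    scale = scale or load_default_scale()
    mean_aads = np.asarray(mean_aads, dtype=float)
    keep = mean_aads > floor
    if keep.sum() < 2:
        raise ValueError("need at least 2 residues above the floor")
    rh = np.array([scale[n] for n, k in zip(residue_names, keep) if k])
    area = mean_aads[keep]
    group_rh = np.unique(rh)
    gmean = np.array([area[rh == g].mean() for g in group_rh])
    gsd = np.array([area[rh == g].std(ddof=0) for g in group_rh])
    if np.ptp(rh) == 0:
        r_val, slope, stderr, intercept = math.nan, math.nan, math.nan, math.nan
    else:
        r_val = float(_stats.pearsonr(rh, area).statistic)
        fit = _stats.linregress(rh, area)
        slope, stderr, intercept = fit.slope, fit.stderr, fit.intercept
    return HydrophobicityAreaStats(
        pairs=np.column_stack([rh, area]), group_rh=group_rh,
        group_mean=gmean, group_sd=gsd, pearson_r=r_val,
        slope=float(slope), slope_stderr=float(stderr),
        intercept=float(intercept), floor=floor)


def species_composition(mean_aads, system: MolecularSystem,
                        cutoff: float = SCORE_CUTOFF,
                        restrict_to_hydrophobic: bool = False,
                        hydrophobic_set=DEFAULT_HYDROPHOBIC_SET,
                        ) -> tuple[dict[str, float], float]:
    """Percentage contribution of each residue species among adsorbers.

    Counts residues with mean A_ads > ``cutoff``; with
    ``restrict_to_hydrophobic`` only species in ``hydrophobic_set``
    enter the percentages.  Returns ``(percentages, hydrophobic_fraction)``
    where the fraction is hydrophobic adsorbers / all adsorbers.
    """
    mean_aads = np.asarray(mean_aads, dtype=float)
    names = [e.name for e in system.residue_table]
    adsorbing = [n for n, a in zip(names, mean_aads) if a > cutoff]
    if not adsorbing:
        raise ValueError("no residues adsorb above the cutoff")
    hydro = [n for n in adsorbing if n in hydrophobic_set]
    pool = hydro if restrict_to_hydrophobic else adsorbing
    if not pool:
        raise ValueError("restricted adsorbing set is empty")
    pct: dict[str, float] = {}
    for n in pool:
        pct[n] = pct.get(n, 0.0) + 100.0 / len(pool)
    return pct, len(hydro) / len(adsorbing)


def cumulative_hydrophobic_sasa(traj: Trajectory,
                                residue_rows,
                                probe_radius: float = 0.14,
                                n_points: int = DEFAULT_N_POINTS,
                                stride: int = 1,
                                running_window: int = 10,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative SASA of a residue set over time, with a running mean.

    ``residue_rows`` are rows of the residue table (the surface-active
    hydrophobic residues).  Frames are sampled every ``stride``; the raw
    per-sample sum is smoothed by a centered running average of
    ``running_window`` points, so the output has
    ``n_samples − window + 1`` values.  Returns ``(times, smoothed)``.
    """
    rows = list(residue_rows)
    if not rows:
        raise ValueError("residue set is empty")
    if running_window < 1:
        raise ValueError("running_window must be >= 1")
    from .sasa import compute_sasa
    samples, times = [], []
    for k in range(0, len(traj), stride):
        res = compute_sasa(traj.system_at(k), probe_radius, n_points)
        samples.append(res.per_residue_area[rows].sum())
        times.append(traj.frames[k].time_ns)
    raw = np.asarray(samples)
    if running_window > len(raw):
        raise ValueError("running window longer than the series")
    kernel = np.full(running_window, 1.0 / running_window)
    smoothed = np.convolve(raw, kernel, mode="valid")
    t = np.asarray(times)
    half = (running_window - 1) / 2.0
    t_centered = t[:len(smoothed)] + half * (t[1] - t[0] if len(t) > 1 else 0)
    return t_centered, smoothed


def surface_free_energy(aads_nm2: float, gamma_mN_per_m: float = 62.0,
                        temperature_K: float = 300.0) -> SurfaceFreeEnergy:
    """Interfacial free-energy gain γ·A_ads of an adsorbed protein.

    1 mN/m × 1 nm² = 10⁻²¹ J.  Reported in J, k_BT at the given
    temperature, and kJ/mol.  The default γ corresponds to a simulated
    water surface tension of 62 mN/m.
    """
    if gamma_mN_per_m <= 0 or temperature_K <= 0 or aads_nm2 < 0:
        raise ValueError("gamma and temperature must be > 0, A_ads >= 0")
    joules = gamma_mN_per_m * aads_nm2 * 1e-21
    return SurfaceFreeEnergy(
        joules=joules,
        kBT=joules / (_KB * temperature_K),
        kJ_per_mol=joules * _NA / 1000.0)
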