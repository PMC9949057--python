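"""Geometry statistics over labelled coordinate ensembles.

Operators for the standard questions asked of membrane-protein
trajectories: how many waters sit inside a transmembrane cylinder (and in
its extracellular/intracellular halves), where ions sit along the membrane
normal, which residues contact a probe and how often, how far an ion drifts
from its starting position, and how close pairs of helices approach.

Conventions (documented because they decide boundary cases):

* the membrane normal is +z toward the extracellular side; the cylinder is
  split at the anchor-midpoint plane, and points exactly on that plane
  belong to the extracellular half;
* cylinder containment is closed (axial offset ≤ length/2, radial ≤ radius);
* contact cutoffs are open at the boundary (distance < cutoff), matching
  the reading of "within X nm";
* the minimum-image convention applies only when a box is present.

Distances in nm, times in ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEnsemble",
    "CylinderSpec",
    "ContactTable",
    "select",
    "cylinder_count",
    "z_trace",
    "contact_occupancy",
    "top_k_residues",
    "ion_rmsd",
    "min_helix_distance",
    "water_density_grid",
    "DensityGrid",
]


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of labelled 3D coordinates.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; label arrays are
    per-atom and constant across frames.  ``box`` is optional orthorhombic
    box lengths (3,) in nm.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n = self.coords.shape[1]
        for attr in ("names", "resnames", "resids", "chains"):
            arr = np.asarray(getattr(self, attr))
            setattr(self, attr, arr)
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have one entry per atom")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_slice(self, window: float | None) -> np.ndarray:
        """Indices of the trailing ``window`` ps (all frames when None)."""
        if window is None:
            return np.arange(self.n_frames)
        span = self.times[-1] - self.times[0]
        if window > span:
            raise ValueError(
                f"window of {window} ps exceeds trajectory span of {span} ps"
            )
        cut = self.times[-1] - window
        return np.flatnonzero(self.times >= cut)


def select(
    traj: TrajectoryEnsemble,
    name: str | Sequence[str] | None = None,
    resname: str | Sequence[str] | None = None,
    resid: int | Sequence[int] | None = None,
    chain: str | Sequence[str] | None = None,
) -> np.ndarray:
    """Boolean atom mask from simple label criteria (AND-combined)."""
    mask = np.ones(traj.n_atoms, dtype=bool)

    def crit(values, wanted):
        wanted = [wanted] if np.isscalar(wanted) or isinstance(wanted, str) else list(wanted)
        return np.isin(values, wanted)

    if name is not None:
        mask &= crit(traj.names, name)
    if resname is not None:
        mask &= crit(traj.resnames, resname)
    if resid is not None:
        mask &= crit(traj.resids, resid)
    if chain is not None:
        mask &= crit(traj.chains, chain)
    return mask


def _as_mask(traj: TrajectoryEnsemble, selector) -> np.ndarray:
    """Accept a boolean mask, an index array, or a selector kwargs dict."""
    if isinstance(selector, dict):
        return select(traj, **selector)
    arr = np.asarray(selector)
    if arr.dtype == bool:
        if arr.shape != (traj.n_atoms,):
            raise ValueError("boolean selector must cover every atom")
        return arr
    mask = np.zeros(traj.n_atoms, dtype=bool)
    mask[arr] = True
    return mask


def _min_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


@dataclass(frozen=True)
class CylinderSpec:
    """A cylinder centred on the midpoint of two anchor atoms.

    ``anchor_a``/``anchor_b`` are selectors that must resolve to exactly one
    atom each per frame.  The axis is the membrane normal (z).  ``half``
    restricts containment to the extracellular (axial offset >= 0) or
    intracellular (< 0) side of the midpoint plane.
    """

    anchor_a: dict
    anchor_b: dict
    length: float = 4.0
    radius: float = 1.3
    half: str = "whole"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.radius <= 0:
            raise ValueError("cylinder length and radius must be positive")
        if self.half not in ("whole", "extracellular", "intracellular"):
            raise ValueError(
                "half must be 'whole', 'extracellular' or 'intracellular'"
            )

    def centers(self, traj: TrajectoryEnsemble) -> np.ndarray:
        """Per-frame cylinder centre (midpoint of the two anchors)."""
        ia = np.flatnonzero(_as_mask(traj, self.anchor_a))
        ib = np.flatnonzero(_as_mask(traj, self.anchor_b))
        if ia.size != 1 or ib.size != 1:
            raise ValueError(
                f"cylinder anchors must each resolve to exactly one atom "
                f"(got {ia.size} and {ib.size})"
            )
        return 0.5 * (traj.coords[:, ia[0], :] + traj.coords[:, ib[0], :])

    def contains(
        self, traj: TrajectoryEnsemble, points: np.ndarray, centers: np.ndarray
    ) -> np.ndarray:
        """Containment mask for points of shape (n_frames, n, 3)."""
        delta = _min_image(points - centers[:, None, :], traj.box)
        axial = delta[..., 2]
        radial = np.hypot(delta[..., 0], delta[..., 1])
        inside = (np.abs(axial) <= self.length / 2) & (radial <= self.radius)
        if self.half == "extracellular":
            inside &= axial >= 0.0  # midplane points belong to the EC half
        elif self.half == "intracellular":
            inside &= axial < 0.0
        return inside


@dataclass
class CountResult:
    per_frame: np.ndarray
    mean: float
    sd: float
    times: np.ndarray


def cylinder_count(
    traj: TrajectoryEnsemble,
    spec: CylinderSpec,
    species,
    window: float | None = None,
) -> CountResult:
    """Per-frame count of ``species`` atoms inside the cylinder.

    ``window`` restricts the statistics to the trailing window in ps (e.g.
    a final-10-ns analysis).  Mean and standard deviation are over the
    selected frames; across repeats, combine per-repeat means as
    mean ± sd between repeats.
    """
    mask = _as_mask(traj, species)
    if not mask.any():
        raise ValueError("species selector matches no atoms")
    frames = traj.frame_slice(window)
    centers = spec.centers(traj)[frames]
    pts = traj.coords[frames][:, mask, :]
    inside = spec.contains(traj, pts, centers)
    counts = inside.sum(axis=1).astype(float)
    return CountResult(
        per_frame=counts,
        mean=float(np.mean(counts)),
        sd=float(np.std(counts, ddof=0)),
        times=traj.times[frames],
    )


def z_trace(
    traj: TrajectoryEnsemble,
    spec: CylinderSpec,
    species: dict[str, dict],
) -> pd.DataFrame:
    """Tidy (time, species, particle, z) rows for particles inside the cylinder.

    ``species`` maps a species label (e.g. "water", "NA") to a selector;
    only atoms inside the cylinder in a given frame appear for that frame.
    """
    centers = spec.centers(traj)
    rows = []
    for label, sel in species.items():
        mask = _as_mask(traj, sel)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        pts = traj.coords[:, idx, :]
        inside = spec.contains(traj, pts, centers)
        f_idx, a_idx = np.nonzero(inside)
        for f, a in zip(f_idx, a_idx):
            rows.append(
                {
                    "time_ps": traj.times[f],
                    "species": label,
                    "particle": int(idx[a]),
                    "z_nm": pts[f, a, 2],
                }
            )
    return pd.DataFrame(rows, columns=["time_ps", "species", "particle", "z_nm"])


@dataclass
class ContactTable:
    """Residue contact occupancies, sorted by occupancy (desc)."""

    table: pd.DataFrame
    cutoff: float
    min_report: float

    def __post_init__(self) -> None:
        occ = self.table["occupancy_pct"]
        if ((occ < 0) | (occ > 100)).any():
            raise ValueError("occupancies must lie in [0, 100]")


def contact_occupancy(
    traj: TrajectoryEnsemble,
    probe,
    targets,
    cutoff: float = 0.3,
    min_report: float = 1.0,
) -> ContactTable:
    """Percent of frames each target residue is within ``cutoff`` of the probe.

    A residue is in contact in a frame iff any of its atoms lies strictly
    within ``cutoff`` nm of any probe atom (minimum image when a box is
    present).  Residues below ``min_report`` percent are dropped.  Typical
    cutoffs: 0.3 nm for ion coordination, 0.6 nm for sterol contacts.
    """
    probe_mask = _as_mask(traj, probe)
    if not probe_mask.any():
        raise ValueError("probe selector matches no atoms")
    target_mask = _as_mask(traj, targets)
    if not target_mask.any():
        raise ValueError("target selector matches no atoms")
    probe_xyz = traj.coords[:, probe_mask, :]

    keys = list(
        zip(
            traj.chains[target_mask],
            traj.resids[target_mask],
            traj.resnames[target_mask],
        )
    )
    target_idx = np.flatnonzero(target_mask)
    residues: dict[tuple, list[int]] = {}
    for key, ai in zip(keys, target_idx):
        residues.setdefault(key, []).append(ai)

    rows = []
    n_frames = traj.n_frames
    for (chain, resid, resname), atom_ids in residues.items():
        res_xyz = traj.coords[:, atom_ids, :]
        delta = _min_image(
            res_xyz[:, :, None, :] - probe_xyz[:, None, :, :], traj.box
        )
        d = np.linalg.norm(delta, axis=-1)
        in_contact = (d < cutoff).any(axis=(1, 2))
        pct = 100.0 * in_contact.sum() / n_frames
        if pct >= min_report:
            label = f"{resname}{resid}" + (f":{chain}" if str(chain) else "")
            rows.append(
                {
                    "residue": label,
                    "resname": resname,
                    "resid": int(resid),
                    "chain": chain,
                    "occupancy_pct": pct,
                }
            )
    df = pd.DataFrame(
        rows, columns=["residue", "resname", "resid", "chain", "occupancy_pct"]
    )
    if len(df):
        df = df.sort_values(
            ["occupancy_pct", "resid"], ascending=[False, True]
        ).reset_index(drop=True)
    return ContactTable(table=df, cutoff=cutoff, min_report=min_report)


def top_k_residues(table: ContactTable, k: int) -> list[str]:
    """The k highest-occupancy residues (ties broken by residue number)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.table.sort_values(
        ["occupancy_pct", "resid"], ascending=[False, True]
    )
    return df["residue"].head(k).tolist()


def _kabsch(mobile: np.ndarray, ref: np.ndarray):
    """Optimal rotation+translation mapping mobile onto ref (least squares)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, rc - R @ mc


@dataclass
class RmsdResult:
    per_frame: np.ndarray  # (n_frames, n_ions) displacement from reference
    mean: np.ndarray  # per ion
    sd: np.ndarray  # per ion


def ion_rmsd(
    traj: TrajectoryEnsemble,
    ion,
    reference: str | np.ndarray = "first",
    align: dict | None = None,
) -> RmsdResult:
    """Displacement of each selected ion from its reference position.

    Per frame, |r(t) − r_ref| for each ion; reported per ion as mean ± sd
    over frames.  ``reference`` is the first frame or a supplied (n_ions, 3)
    array.  With ``align`` (a selector, typically protein Cα), every frame
    is first superimposed onto the first frame by a rigid Kabsch fit of the
    alignment atoms, making the measure invariant to rigid whole-system
    motion.
    """
    mask = _as_mask(traj, ion)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("ion selector matches no atoms")
    coords = traj.coords.copy()
    if align is not None:
        amask = _as_mask(traj, align)
        if amask.sum() < 3:
            raise ValueError("alignment selector needs at least 3 atoms")
        ref_sub = coords[0, amask, :]
        for f in range(1, traj.n_frames):
            R, t = _kabsch(coords[f, amask, :], ref_sub)
            coords[f] = coords[f] @ R.T + t
    ion_xyz = coords[:, idx, :]
    if isinstance(reference, str):
        if reference != "first":
            raise ValueError("reference must be 'first' or an (n_ions, 3) array")
        ref = ion_xyz[0]
    else:
        ref = np.asarray(reference, dtype=float).reshape(idx.size, 3)
    disp = np.linalg.norm(ion_xyz - ref[None, :, :], axis=-1)
    return RmsdResult(
        per_frame=disp,
        mean=disp.mean(axis=0),
        sd=disp.std(axis=0, ddof=0),
    )


@dataclass
class MinDistanceResult:
    per_frame: np.ndarray
    times: np.ndarray
    mean: float
    sd: float


def min_helix_distance(
    traj: TrajectoryEnsemble,
    selector_a,
    selector_b,
    window: float | None = None,
) -> MinDistanceResult:
    """Per-frame minimum over all cross pairs of distances between two selections.

    Intended for Cα selections on two helices; reports the time series plus
    its mean ± sd over the (optionally trailing-``window``) frames.
    """
    ma = _as_mask(traj, selector_a)
    mb = _as_mask(traj, selector_b)
    if not ma.any() or not mb.any():
        raise ValueError("each selector must resolve to at least one atom")
    frames = traj.frame_slice(window)
    a = traj.coords[frames][:, ma, :]
    b = traj.coords[frames][:, mb, :]
    delta = _min_image(a[:, :, None, :] - b[:, None, :, :], traj.box)
    d = np.linalg.norm(delta, axis=-1)
    per_frame = d.min(axis=(1, 2))
    return MinDistanceResult(
        per_frame=per_frame,
        times=traj.times[frames],
        mean=float(per_frame.mean()),
        sd=float(per_frame.std(ddof=0)),
    )


@dataclass
class DensityGrid:
    """Time-averaged particle density on a regular grid (counts per nm³)."""

    origin: np.ndarray
    voxel: float
    values: np.ndarray  # (nx, ny, nz)

    def integrated_count(self) -> float:
        """Total density × voxel volume = mean particle count in the region."""
        return float(self.values.sum() * self.voxel**3)


def water_density_grid(
    traj: TrajectoryEnsemble,
    species,
    voxel: float = 0.1,
    region: np.ndarray | None = None,
    align: dict | None = None,
) -> DensityGrid:
    """Time-averaged density of ``species`` atoms on a cubic-voxel grid.

    ``region`` is a (3, 2) array of (lo, hi) bounds in nm (defaults to the
    bounding box of the selected atoms over all frames, padded by one
    voxel).  With ``align``, frames are rigid-body superimposed onto the
    first frame using the alignment selection before binning.  Density is
    mean count per voxel divided by voxel volume, so the grid integrates to
    the mean in-region particle count.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    mask = _as_mask(traj, species)
    if not mask.any():
        raise ValueError("species selector matches no atoms")
    coords = traj.coords.copy()
    if align is not None:
        amask = _as_mask(traj, align)
        ref_sub = coords[0, amask, :]
        for f in range(1, traj.n_frames):
            R, t = _kabsch(coords[f, amask, :], ref_sub)
            coords[f] = coords[f] @ R.T + t
    pts = coords[:, mask, :].reshape(-1, 3)
    if region is None:
        lo = pts.min(axis=0) - voxel
        hi = pts.max(axis=0) + voxel
    else:
        region = np.asarray(region, dtype=float)
        lo, hi = region[:, 0], region[:, 1]
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    edges = [lo[d] + voxel * np.arange(shape[d] + 1) for d in range(3)]
    hist, _ = np.histogramdd(pts, bins=edges)
    density = hist / traj.n_frames / voxel**3
    return DensityGrid(origin=lo, voxel=voxel, values=density)
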