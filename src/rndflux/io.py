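"""Readers, writers, configuration and run manifests.

File dialects:

* xvg-style whitespace-separated numeric columns, ``#``/``@`` comment lines
  ignored (the native dialect of umbrella pull and energy outputs);
* a tab-separated window metadata table (filename, center, force constant)
  mirroring the pullx convention of gmx-wham;
* multi-model PDB for coordinate ensembles (Å on disk, nm in memory — the
  conversion lives only here);
* OpenDX volumetric text for density grids;
* JSON sidecars and run manifests.

Every CLI run writes a :class:`RunManifest` next to its outputs recording
the package version, config hash, master seed and input checksums, so any
two runs with identical config and seed are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rndflux.pmf import UmbrellaWindow
from rndflux.trajectory import TrajectoryEnsemble, DensityGrid

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_window_set",
    "write_window_set",
    "read_pdb_frames",
    "write_pdb_frames",
    "write_dx",
    "RunManifest",
    "RunConfig",
]

NM_PER_ANGSTROM = 0.1


def read_xvg(path) -> np.ndarray:
    """Parse whitespace-separated numeric columns, ignoring #/@ lines.

    Returns an (n_rows, n_cols) array; a file containing only comments (or
    nothing) returns an empty (0, 0) array rather than raising.  Ragged or
    non-numeric rows raise with the offending line number.
    """
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "@")):
                continue
            parts = stripped.split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value on line {lineno}: {stripped!r}"
                ) from exc
            if n_cols is None:
                n_cols = len(values)
            elif len(values) != n_cols:
                raise ValueError(
                    f"{path}: ragged row on line {lineno}: expected {n_cols} "
                    f"columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        return np.empty((0, 0))
    return np.asarray(rows, dtype=float)


def write_xvg(path, data: np.ndarray, comments: list[str] | None = None) -> None:
    """Write columns at 12 significant digits with # comment headers."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        for row in data:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def write_window_set(
    directory,
    windows: list[UmbrellaWindow],
    prefix: str = "window",
) -> Path:
    """Write windows as two-column xvg files plus a metadata table.

    Returns the path of the metadata TSV (filename, center_nm,
    force_constant_kJ_mol_nm2), the entry point :func:`read_window_set`
    consumes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, w in enumerate(windows):
        fname = f"{prefix}_{i:03d}.xvg"
        write_xvg(
            directory / fname,
            np.column_stack([w.times, w.xi]),
            comments=[
                "umbrella window pull coordinate",
                "time_ps xi_nm",
                f"center_nm = {w.center:.6g}",
                f"force_constant_kJ_mol_nm2 = {w.force_constant:.6g}",
            ],
        )
        meta.append(
            {
                "filename": fname,
                "center_nm": w.center,
                "force_constant_kJ_mol_nm2": w.force_constant,
            }
        )
    meta_path = directory / f"{prefix}_meta.tsv"
    with open(meta_path, "w") as fh:
        fh.write("# umbrella window metadata; xi in nm, k in kJ/mol/nm^2\n")
        pd.DataFrame(meta).to_csv(fh, sep="\t", index=False)
    return meta_path


def read_window_set(meta_path, discard: float = 0.0) -> list[UmbrellaWindow]:
    """Read umbrella windows listed in a metadata TSV (see write_window_set)."""
    meta_path = Path(meta_path)
    df = pd.read_csv(meta_path, sep="\t", comment="#")
    required = {"filename", "center_nm", "force_constant_kJ_mol_nm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{meta_path}: metadata missing columns {sorted(missing)}")
    windows = []
    for _, row in df.iterrows():
        data = read_xvg(meta_path.parent / row["filename"])
        if data.size == 0 or data.shape[1] < 2:
            raise ValueError(f"{row['filename']}: expected two numeric columns")
        windows.append(
            UmbrellaWindow(
                center=float(row["center_nm"]),
                force_constant=float(row["force_constant_kJ_mol_nm2"]),
                times=data[:, 0],
                xi=data[:, 1],
                discard=discard,
            )
        )
    return windows


def write_pdb_frames(path, traj: TrajectoryEnsemble) -> None:
    """Write an ensemble as a multi-model PDB (coordinates nm → Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.coords / NM_PER_ANGSTROM
    stack.atom_name = traj.names.astype(str)
    stack.res_name = traj.resnames.astype(str)
    stack.res_id = traj.resids.astype(int)
    stack.chain_id = traj.chains.astype(str)
    stack.element = np.array(
        [str(n)[:1] if str(n) else "X" for n in traj.names]
    )
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_frames(path, box: np.ndarray | None = None) -> TrajectoryEnsemble:
    """Read a (possibly multi-model) PDB into an ensemble (Å → nm).

    Frame order follows MODEL order; atom labelling must be constant across
    models (biotite enforces consistent atom counts).  Frame times default
    to the frame index in ps.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack, coord (m, n, 3) in Å
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    return TrajectoryEnsemble(
        names=np.asarray(stack.atom_name),
        resnames=np.asarray(stack.res_name),
        resids=np.asarray(stack.res_id, dtype=int),
        chains=np.asarray(stack.chain_id),
        coords=coords * NM_PER_ANGSTROM,
        times=np.arange(coords.shape[0], dtype=float),
        box=box,
    )


def write_dx(path, grid: DensityGrid) -> None:
    """Write a density grid in OpenDX text format (units nm, nm^-3)."""
    nx, ny, nz = grid.values.shape
    with open(path, "w") as fh:
        fh.write("# time-averaged particle density; lengths nm, density nm^-3\n")
        fh.write(
            f"object 1 class gridpositions counts {nx} {ny} {nz}\n"
            f"origin {grid.origin[0]:.6g} {grid.origin[1]:.6g} {grid.origin[2]:.6g}\n"
            f"delta {grid.voxel:.6g} 0 0\n"
            f"delta 0 {grid.voxel:.6g} 0\n"
            f"delta 0 0 {grid.voxel:.6g}\n"
            f"object 2 class gridconnections counts {nx} {ny} {nz}\n"
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written atomically alongside every CLI output."""

    version: str
    command: str
    seed: int | None
    config_hash: str | None = None
    stream_seeds: list = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)
    timestamp: str = ""

    def write(self, path) -> None:
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)


class RunConfig:
    """A validated YAML configuration mapping.

    Keys carry their units in the key name (``spacing_nm``,
    ``kT_kJ_per_mol``, ``dV_mV`` ...).  Unknown keys are rejected against a
    per-stage schema so typos fail loudly.
    """

    def __init__(self, data: dict, allowed: set[str] | None = None):
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
        if allowed is not None:
            unknown = set(data) - allowed
            if unknown:
                raise ValueError(
                    f"unknown config keys: {sorted(unknown)}; allowed: "
                    f"{sorted(allowed)}"
                )
        self.data = data

    @classmethod
    def from_yaml(cls, path, allowed: set[str] | None = None) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data, allowed)

    def get(self, key, default=None):
        return self.data.get(key, default)

    def __getitem__(self, key):
        return self.data[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
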