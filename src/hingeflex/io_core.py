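"""Core containers and on-disk formats for the hinge-mobility pipeline.

Internal units are fixed throughout the package: nanometres, picoseconds,
kJ/mol and kelvin.  PDB files are the only ångström-unit surface; they are
converted on read and write.  Angles are stored in radians internally; the
opening angle is reported in degrees, dihedrals in radians, matching the
conventions used for hinge peptides in the literature.

On-disk formats are deliberately plain text: PDB for structures, multi-frame
XYZ (time carried on the comment line) for trajectories, TSV for collective
variable series, a PLUMED-HILLS-style column file for the metadynamics bias
log, and a gridded text file for free-energy surfaces.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083144621

# Three-letter residue codes for the amino acids used by the presets.
AA3 = {
    "A": "ALA", "C": "CYS", "E": "GLU", "G": "GLY", "H": "HIS", "L": "LEU",
    "P": "PRO", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL", "W": "TRP",
    "Y": "TYR",
}


class FormatError(ValueError):
    """Raised for malformed on-disk artifacts (carries the offending line)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A coarse two-chain peptide structure of Cα and Sγ beads.

    Atom metadata is held in parallel arrays; ``coords`` is an (N, 3) float
    array in nm.  ``roles`` entries are ``"CA"`` or ``"SG"``.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    roles: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = len(self.chain_ids)
        if not all(len(a) == n for a in (self.res_ids, self.res_names, self.roles)) \
                or self.coords.shape[0] != n:
            raise ValueError("atom attribute arrays must share one length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def index_of(self, chain: str, res_id: int, role: str) -> int:
        """Index of a single atom identified by (chain, residue, role)."""
        hit = np.flatnonzero(
            (self.chain_ids == chain) & (self.res_ids == res_id) & (self.roles == role)
        )
        if hit.size != 1:
            raise KeyError(
                f"expected exactly one atom {chain}/{res_id}/{role}, found {hit.size}"
            )
        return int(hit[0])

    def select(self, role: str | None = None, chain: str | None = None) -> np.ndarray:
        """Indices of atoms matching a role and/or chain."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if chain is not None:
            mask &= self.chain_ids == chain
        return np.flatnonzero(mask)

    def validate(self) -> None:
        """Enforce container invariants (per-chain ordering, SG on Cys)."""
        for chain in dict.fromkeys(self.chain_ids):
            idx = self.select(chain=chain)
            rid = self.res_ids[idx]
            # strictly increasing over residue boundaries (CA then SG share a residue)
            uniq = rid[np.concatenate(([True], np.diff(rid.astype(int)) != 0))]
            if np.any(np.diff(uniq.astype(int)) <= 0):
                raise ValueError(f"residue indices not increasing in chain {chain}")
            for r in dict.fromkeys(rid.tolist()):
                in_res = idx[rid == r]
                names = set(self.res_names[in_res])
                n_sg = int(np.sum(self.roles[in_res] == "SG"))
                if "CYS" in names and n_sg != 1:
                    raise ValueError(
                        f"Cys {chain}/{r} must carry exactly one SG atom, found {n_sg}"
                    )
                if "CYS" not in names and n_sg > 0:
                    raise ValueError(f"non-Cys residue {chain}/{r} carries an SG atom")

    def copy(self) -> "Structure":
        return Structure(
            self.chain_ids.copy(), self.res_ids.copy(), self.res_names.copy(),
            self.roles.copy(), self.coords.copy(),
        )


@dataclass
class Trajectory:
    """An ordered stack of frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; ``times`` in ps.
    """

    topology: Structure
    times: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and frames differ in length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        s = self.topology.copy()
        s.coords = self.coords[i].copy()
        return s


@dataclass
class CVSeries:
    """A named time series of one collective variable."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RunConfig:
    """Run-level configuration: preset, seed and stage parameters."""

    preset: str = "hinge_peptide"
    seed: int = 0
    temperature: float = 300.0
    integrator: dict = field(default_factory=dict)
    metad: dict = field(default_factory=dict)
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def to_dict(self) -> dict:
        return {
            "preset": self.preset, "seed": self.seed,
            "temperature": self.temperature, "integrator": dict(self.integrator),
            "metad": dict(self.metad), "out_dir": self.out_dir,
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def header_comment(config: RunConfig | None, prefix: str = "#") -> list[str]:
    """Comment lines embedding seed and config hash in every pipeline output."""
    if config is None:
        return []
    return [f"{prefix} seed={config.seed} config_hash={config.config_hash()}"]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file, keeping only CA and SG atoms, converting Å → nm.

    The coarse model carries Cα beads plus one Sγ bead per cysteine; all
    other atoms in the file are dropped (a documented filter).  A cysteine
    without an SG atom is a hard error.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise FormatError(f"unparseable PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    keep = np.isin(atoms.atom_name, ("CA", "SG"))
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no CA/SG atoms found")
    struct = Structure(
        chain_ids=atoms.chain_id.astype(object),
        res_ids=atoms.res_id.astype(int),
        res_names=atoms.res_name.astype(object),
        roles=atoms.atom_name.astype(object),
        coords=atoms.coord.astype(float) / 10.0,  # Å → nm
    )
    struct.validate()
    return struct


def write_pdb(structure: Structure, path: str | Path,
              config: RunConfig | None = None) -> None:
    """Write the coarse structure as PDB (nm → Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = (structure.coords * 10.0).astype(np.float32)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_ids
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.roles.astype("U6")
    arr.element = np.where(structure.roles == "SG", "S", "C").astype("U2")
    pdb = PDBFile()
    pdb.set_structure(arr)
    lines = header_comment(config, prefix="REMARK  ") + pdb.lines
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Multi-frame XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz(trajectory: Trajectory, path: str | Path,
              config: RunConfig | None = None) -> None:
    """Write a multi-frame XYZ file with the frame time on the comment line."""
    top = trajectory.topology
    labels = [f"{c}{r}{a}" for c, r, a in
              zip(top.chain_ids, top.res_ids, top.roles)]
    with open(path, "w") as fh:
        for t, frame in zip(trajectory.times, trajectory.coords):
            fh.write(f"{top.n_atoms}\n")
            extra = header_comment(config, prefix="")[0] if config else ""
            fh.write(f"t= {t:.6f} {extra}".rstrip() + "\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.9f} {y:.9f} {z:.9f}\n")


def read_xyz(path: str | Path, topology: Structure) -> Trajectory:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`."""
    times, frames = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"line {i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = 0.0
        if comment.startswith("t="):
            t = float(comment.split()[1])
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise FormatError(f"line {i + 1}: truncated frame")
        coords = np.empty((n, 3))
        for j, line in enumerate(block):
            parts = line.split()
            try:
                coords[j] = [float(v) for v in parts[1:4]]
            except (ValueError, IndexError) as exc:
                raise FormatError(f"line {i + 3 + j}: bad XYZ record") from exc
        times.append(t)
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: empty trajectory")
    return Trajectory(topology, np.array(times), np.stack(frames))


# ---------------------------------------------------------------------------
# CV tables
# ---------------------------------------------------------------------------

def write_cv_table(series: Sequence[CVSeries], path: str | Path,
                   config: RunConfig | None = None) -> None:
    """Write CV series to a TSV: time column plus one column per series."""
    series = list(series)
    if not series:
        raise ValueError("no CV series to write")
    n = len(series[0])
    for s in series[1:]:
        if len(s) != n or not np.allclose(s.times, series[0].times):
            raise ValueError("all CV series must share one time base")
    df = pd.DataFrame({"time_ps": series[0].times})
    for s in series:
        df[s.name] = s.values
    with open(path, "w") as fh:
        for line in header_comment(config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_cv_table(path: str | Path) -> list[CVSeries]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time_ps" not in df.columns:
        raise FormatError(f"{path}: missing time_ps column")
    t = df["time_ps"].to_numpy()
    return [CVSeries(c, t, df[c].to_numpy()) for c in df.columns if c != "time_ps"]


# ---------------------------------------------------------------------------
# HILLS-style bias log
# ---------------------------------------------------------------------------

def write_hills(bias, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a metadynamics bias log in a PLUMED-HILLS-style column layout.

    Columns: time, one center per CV, one sigma per CV, deposited height,
    bias factor.  Full float precision so the round trip is lossless.
    """
    if len(bias.hills) == 0:
        raise ValueError("refusing to write an empty bias log")
    ncv = bias.params.n_cv
    names = [f"cv{i + 1}" for i in range(ncv)]
    with open(path, "w") as fh:
        for line in header_comment(config):
            fh.write(line + "\n")
        fh.write("#! FIELDS time " + " ".join(names) + " "
                 + " ".join(f"sigma_{n}" for n in names) + " height biasf\n")
        for t, center, h in bias.hills:
            cs = " ".join(f"{c:.17g}" for c in np.atleast_1d(center))
            ss = " ".join(f"{s:.17g}" for s in bias.params.sigma)
            fh.write(f"{t:.17g} {cs} {ss} {h:.17g} {bias.params.bias_factor:.17g}\n")


def read_hills(path: str | Path, temperature: float = 300.0,
               stride: float | None = None, initial_height: float | None = None,
               periods: Sequence[float | None] | None = None):
    """Read a HILLS-style file back into a :class:`~hingeflex.dynamics_metad.MetaDBias`.

    The HILLS layout does not store temperature or deposition stride, so
    they are supplied by the caller (defaults: 300 K; stride inferred from
    consecutive hill times).
    """
    from .dynamics_metad import MetaDBias, MetaDParams

    rows = []
    sigma = None
    biasf = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            # layout: time, ncv centers, ncv sigmas, height, biasf -> odd count >= 5
            if len(parts) < 5 or len(parts) % 2 == 0:
                raise FormatError(f"line {lineno}: malformed HILLS record")
            ncv = (len(parts) - 3) // 2
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field") from exc
            t = vals[0]
            center = np.array(vals[1:1 + ncv])
            sig = np.array(vals[1 + ncv:1 + 2 * ncv])
            height, bf = vals[-2], vals[-1]
            if height <= 0:
                raise FormatError(f"line {lineno}: non-positive hill height")
            sigma, biasf = sig, bf
            rows.append((t, center, height))
    if not rows:
        raise FormatError(f"{path}: no hills")
    times = [r[0] for r in rows]
    if stride is None:
        stride = times[1] - times[0] if len(times) > 1 else 1.0
    if initial_height is None:
        initial_height = max(r[2] for r in rows)
    params = MetaDParams(
        initial_height=initial_height, bias_factor=biasf, stride=stride,
        sigma=sigma, temperature=temperature,
        periods=periods if periods is not None else [None] * len(sigma),
    )
    bias = MetaDBias(params)
    for t, center, h in rows:
        bias.add_hill(t, center, h)
    return bias


# ---------------------------------------------------------------------------
# FES grid text
# ---------------------------------------------------------------------------

def write_fes(grid, path: str | Path, config: RunConfig | None = None) -> None:
    """Write an FES grid as text: bin centers per axis, free energy, masked=nan."""
    centers = [0.5 * (e[1:] + e[:-1]) for e in grid.edges]
    with open(path, "w") as fh:
        for line in header_comment(config):
            fh.write(line + "\n")
        names = " ".join(f"cv{i + 1}" for i in range(len(centers)))
        fh.write(f"# {names} free_energy_kJ_mol (nan = never visited)\n")
        if len(centers) == 1:
            for x, f, v in zip(centers[0], grid.free_energy, grid.visited):
                fh.write(f"{x:.10g} {f if v else float('nan'):.10g}\n")
        else:
            for i, x in enumerate(centers[0]):
                for j, y in enumerate(centers[1]):
                    f = grid.free_energy[i, j] if grid.visited[i, j] else float("nan")
                    fh.write(f"{x:.10g} {y:.10g} {f:.10g}\n")
                fh.write("\n")


def read_fes(path: str | Path):
    """Read a 1-D or 2-D FES text file written by :func:`write_fes`."""
    from .fes_reweight import FESGrid

    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    ncol = data.shape[1]
    if ncol == 2:
        x, f = data[:, 0], data[:, 1]
        edges = [_centers_to_edges(x)]
        visited = np.isfinite(f)
        return FESGrid(edges=edges, free_energy=np.nan_to_num(f), visited=visited)
    x = np.unique(data[:, 0])
    y = np.unique(data[:, 1])
    f = data[:, 2].reshape(len(x), len(y))
    edges = [_centers_to_edges(x), _centers_to_edges(y)]
    return FESGrid(edges=edges, free_energy=np.nan_to_num(f), visited=np.isfinite(f))


def _centers_to_edges(centers: np.ndarray) -> np.ndarray:
    d = np.diff(centers)
    step = d[0] if len(d) else 1.0
    return np.concatenate(([centers[0] - step / 2],
                           centers[:-1] + d / 2,
                           [centers[-1] + step / 2]))
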