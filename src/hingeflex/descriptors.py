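"""Per-frame hinge descriptors.

Four quantities characterize hinge mobility in this package:

* **opening angle** — the angle at the centroid of the terminal-cysteine
  Sγ cluster (the physical hinge pin) subtended by the per-chain centroids
  of the mid-strand apex Cα atoms (residues 5/8 of the designed hinge,
  whether cysteine or its serine replacement).  Reported in degrees.
* **core dihedral** — the torsion over four cysteine Cα atoms spanning the
  two chains (first Cys of chain A, last of chain B, first of B, last of A
  for the antiparallel hinge), IUPAC sign convention (cis = 0, right-handed
  about the 2→3 axis), range (−π, π].  Reported in radians.
* **Trp–Trp distance** — Euclidean distance between the tryptophan Cα atoms
  of the two chains, a proxy for the β-hairpin twist.  In nm.
* **RMSD** after optimal Kabsch superposition onto a reference, Cα-only and
  mass-unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import CVSeries, Structure, Trajectory
from .synthetic_hinge import HingeTopology


class DegenerateGeometryError(ValueError):
    """Raised when an angle or dihedral is undefined for the given atoms."""


@dataclass
class DescriptorSpec:
    """Symbolic atom selections for the descriptor set.

    Atom labels are (chain, residue, role) triples; set a field to None to
    skip that descriptor.
    """

    apex_atoms: list          # SG labels whose centroid is the hinge apex
    arm_atoms: dict           # chain id -> CA labels whose centroid is that arm
    dihedral: list | None     # four CA labels
    distance_pair: list | None  # two labels
    rmsd_selection: str = "CA"

    def validate(self, topology_structure: Structure) -> None:
        labels = list(self.apex_atoms)
        for arm in self.arm_atoms.values():
            labels += list(arm)
        if self.dihedral:
            if len(self.dihedral) != 4 or len(set(self.dihedral)) != 4:
                raise ValueError("dihedral needs 4 distinct atom labels")
            labels += list(self.dihedral)
        if self.distance_pair:
            labels += list(self.distance_pair)
        for lab in labels:
            topology_structure.index_of(*lab)


def default_descriptor_spec(topology: HingeTopology) -> DescriptorSpec:
    """Build the standard descriptor selections for a preset topology."""
    apex = []
    for chain, cys in topology.cys_positions.items():
        for r in (min(cys), max(cys)):
            apex.append((chain, r, "SG"))
    arms = {chain: [(chain, r, "CA") for r in res]
            for chain, res in topology.apex_residues.items()}
    dihedral = [(c, r, "CA") for c, r in topology.dihedral_quadruple]
    pair = None
    if topology.trp_positions and all(topology.trp_positions.values()):
        pair = [(c, topology.trp_positions[c][0], "CA") for c in sorted(topology.trp_positions)]
    return DescriptorSpec(apex_atoms=apex, arm_atoms=arms,
                          dihedral=dihedral, distance_pair=pair)


def _resolve(structure: Structure, labels) -> np.ndarray:
    idx = [structure.index_of(*lab) for lab in labels]
    return structure.coords[idx]


def opening_angle(frame: Structure, spec: DescriptorSpec) -> float:
    """Opening angle in degrees at the sulfur-cluster apex.

    Uses atan2(|u×v|, u·v) of the apex→arm vectors, which is numerically
    stable near 0° and 180°.
    """
    apex = _resolve(frame, spec.apex_atoms).mean(axis=0)
    arms = [_resolve(frame, labs).mean(axis=0) for labs in spec.arm_atoms.values()]
    if len(arms) != 2:
        raise ValueError("opening angle needs exactly two arm selections")
    u, v = arms[0] - apex, arms[1] - apex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise DegenerateGeometryError("arm center coincides with apex")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def dihedral_from_points(p: np.ndarray) -> float:
    """Signed torsion of four points, IUPAC convention, range (−π, π]."""
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise DegenerateGeometryError("collinear triple: dihedral undefined")
    # IUPAC convention: cis (eclipsed) = 0, sign right-handed about b2
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = float(np.arctan2(y, x))
    return np.pi if ang == -np.pi else ang


def core_dihedral(frame: Structure, quadruple) -> float:
    """Disulfide-core torsion (radians) over four Cα labels."""
    return dihedral_from_points(_resolve(frame, quadruple))


def trp_trp_distance(frame: Structure, pair) -> float:
    """Euclidean distance (nm) between the two labelled atoms."""
    p = _resolve(frame, pair)
    return float(np.linalg.norm(p[1] - p[0]))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t, rmsd) with R proper (det +1) and
    ``mobile @ R.T + t`` the aligned coordinates.  Coordinates are (N, 3)
    with N ≥ 3 non-collinear points; mass-unweighted.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("selection atom counts differ")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    if np.linalg.matrix_rank(a, tol=1e-10) < 2 or np.linalg.matrix_rank(b, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) selection")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    aligned = a @ r.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - b) ** 2, axis=1))))
    t = rc - r @ mc
    return r, t, rmsd


def superpose_structure(mobile: Structure, reference: Structure,
                        selection: str = "CA") -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition on a role selection of two structures."""
    idx_m = mobile.select(role=selection)
    idx_r = reference.select(role=selection)
    return kabsch_superpose(mobile.coords[idx_m], reference.coords[idx_r])


def descriptor_series(trajectory: Trajectory, spec: DescriptorSpec,
                      reference: Structure | None = None) -> list[CVSeries]:
    """Evaluate every configured descriptor on each frame.

    RMSD is computed after per-frame superposition onto ``reference``
    (defaults to the trajectory topology).  Errors in individual frames are
    re-raised with the frame index attached.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    ref = reference if reference is not None else trajectory.topology
    top = trajectory.topology
    idx_sel = top.select(role=spec.rmsd_selection)
    ref_sel = ref.coords[ref.select(role=spec.rmsd_selection)]

    names = ["opening_angle_deg"]
    if spec.dihedral:
        names.append("core_dihedral_rad")
    if spec.distance_pair:
        names.append("trp_trp_distance_nm")
    names.append("rmsd_nm")

    values = {n: np.empty(trajectory.n_frames) for n in names}
    frame = top.copy()
    for i in range(trajectory.n_frames):
        frame.coords = trajectory.coords[i]
        try:
            values["opening_angle_deg"][i] = opening_angle(frame, spec)
            if spec.dihedral:
                values["core_dihedral_rad"][i] = core_dihedral(frame, spec.dihedral)
            if spec.distance_pair:
                values["trp_trp_distance_nm"][i] = trp_trp_distance(frame, spec.distance_pair)
            _, _, rmsd = kabsch_superpose(frame.coords[idx_sel], ref_sel)
            values["rmsd_nm"][i] = rmsd
        except Exception as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return [CVSeries(n, trajectory.times.copy(), values[n]) for n in names]
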