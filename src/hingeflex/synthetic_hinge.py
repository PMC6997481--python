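"""Synthetic coarse-grained hinge models with known ground truth.

Two families of bi-disulfide-linked peptide dimers are covered:

* the designed antiparallel hinge peptide (CHWECRGCRLVC)\\ :sub:`2` with four
  disulfides (two intermolecular at the termini, one intramolecular C5–C8
  per chain) and its Ser- and Tyr-modified derivatives, and
* the parallel IgG1 hinge (TCPPCPAP)\\ :sub:`2` with two intermolecular
  disulfides, plus its Ala/Gly core mutants.

The reference geometries are idealized (straight Cα strands at 0.35 nm
spacing, 0.5 nm between chains, Sγ beads placed on the disulfide axis so
every declared S–S pair sits at 0.205 nm): they exist so descriptor and PCA
code can be exercised against closed-form expectations, not to be realistic
β-sheet geometry.

The module also generates Cartesian trajectories with a prescribed normal-
mode structure (so PCA variance fractions are known analytically) and
analytic collective-variable potentials whose basin layout mirrors the free
energy landscape of the hinge peptide: an open/twisted basin near a 110°
opening angle and 2.5 nm Trp–Trp distance and a compact basin near 43° and
0.3 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io_core import AA3, Structure, Trajectory

PRESETS = ("hinge_peptide", "ser_hinge", "tyr_hinge", "pro_igg", "ala_igg", "gly_igg")

CA_SPACING = 0.35   # nm between consecutive Cα along a strand
CHAIN_SEP = 0.5     # nm between the two strands
SS_DIST = 0.205     # nm target S–S distance for every disulfide


@dataclass
class HingeTopology:
    """Residue layout and disulfide pairing for one peptide variant."""

    preset: str
    sequences: dict            # chain id -> one-letter sequence
    cys_positions: dict        # chain id -> list of residue indices (1-based)
    disulfide_pairs: list      # [((chain, res), (chain, res)), ...]
    orientation: str           # "antiparallel" | "parallel"
    apex_residues: dict        # chain id -> residue indices defining the arm centers
    dihedral_quadruple: list   # four (chain, res) Cα labels for the core dihedral
    trp_positions: dict = field(default_factory=dict)

    @property
    def n_disulfides(self) -> int:
        return len(self.disulfide_pairs)


def _hinge_family(preset: str, tyr_terminus: str) -> HingeTopology:
    seq = "CHWECRGCRLVC"
    if preset == "ser_hinge":
        seq = "CHWESRGSRLVC"
    offset = 0
    if preset == "tyr_hinge":
        if tyr_terminus == "N":
            seq = "Y" + seq
            offset = 1
        else:
            seq = seq + "Y"
    n = len(seq)
    cys = [i + 1 for i, a in enumerate(seq) if a == "C"]
    first, last = min(cys), max(cys)
    pairs = [(("A", first), ("B", last)), (("B", first), ("A", last))]
    if preset != "ser_hinge":
        mid = [c for c in cys if c not in (first, last)]
        pairs += [(("A", mid[0]), ("A", mid[1])), (("B", mid[0]), ("B", mid[1]))]
    # apex residues: core positions 5 and 8 regardless of Cys/Ser identity
    apex = [5 + offset, 8 + offset]
    quad = [("A", first), ("B", last), ("B", first), ("A", last)]
    trp = {c: [i + 1 for i, a in enumerate(seq) if a == "W"] for c in "AB"}
    return HingeTopology(
        preset=preset, sequences={"A": seq, "B": seq},
        cys_positions={"A": cys, "B": cys}, disulfide_pairs=pairs,
        orientation="antiparallel", apex_residues={"A": apex, "B": apex},
        dihedral_quadruple=quad, trp_positions=trp,
    )


def _igg_family(preset: str) -> HingeTopology:
    core = {"pro_igg": "PP", "ala_igg": "AA", "gly_igg": "GG"}[preset]
    seq = "TC" + core + "CPAP"
    cys = [2, 5]
    pairs = [(("A", 2), ("B", 2)), (("A", 5), ("B", 5))]
    quad = [("A", 2), ("B", 2), ("B", 5), ("A", 5)]
    return HingeTopology(
        preset=preset, sequences={"A": seq, "B": seq},
        cys_positions={"A": cys, "B": cys}, disulfide_pairs=pairs,
        orientation="parallel", apex_residues={"A": [3, 4], "B": [3, 4]},
        dihedral_quadruple=quad, trp_positions={},
    )


def build_topology(preset: str, tyr_terminus: str = "N") -> tuple[HingeTopology, Structure]:
    """Build a preset topology and its idealized reference structure.

    ``tyr_terminus`` picks where the Tyr elongation of ``tyr_hinge`` is
    attached ("N" default or "C"); the source study does not state it.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {', '.join(PRESETS)}")
    if preset in ("hinge_peptide", "ser_hinge", "tyr_hinge"):
        topo = _hinge_family(preset, tyr_terminus)
    else:
        topo = _igg_family(preset)

    chains, res_ids, res_names, roles, coords = [], [], [], [], []
    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    for ci, chain in enumerate(("A", "B")):
        seq = topo.sequences[chain]
        n = len(seq)
        y = ci * CHAIN_SEP
        for r, aa in enumerate(seq, start=1):
            if chain == "B" and topo.orientation == "antiparallel":
                x = (n - r) * CA_SPACING
            else:
                x = (r - 1) * CA_SPACING
            p = np.array([x, y, 0.0])
            ca_pos[(chain, r)] = p
            chains.append(chain)
            res_ids.append(r)
            res_names.append(AA3[aa])
            roles.append("CA")
            coords.append(p)

    # Sγ beads on each disulfide axis, symmetric about the Cα midpoint,
    # lifted out of the backbone plane (a different height per disulfide so
    # sulfur clusters stay distinct).
    sg_pos: dict[tuple[str, int], np.ndarray] = {}
    for k, ((ca_a, ra), (cb, rb)) in enumerate(topo.disulfide_pairs):
        pa, pb = ca_pos[(ca_a, ra)], ca_pos[(cb, rb)]
        mid = 0.5 * (pa + pb)
        u = pb - pa
        u = u / np.linalg.norm(u)
        lift = np.array([0.0, 0.0, 0.15 + 0.08 * k])
        sg_pos[(ca_a, ra)] = mid - 0.5 * SS_DIST * u + lift
        sg_pos[(cb, rb)] = mid + 0.5 * SS_DIST * u + lift

    for chain in ("A", "B"):
        for r in topo.cys_positions[chain]:
            chains.append(chain)
            res_ids.append(r)
            res_names.append("CYS")
            roles.append("SG")
            coords.append(sg_pos[(chain, r)])

    # order atoms chain-major, residue-minor (CA before SG within a residue)
    order = sorted(range(len(chains)),
                   key=lambda i: (chains[i], res_ids[i], roles[i]))
    struct = Structure(
        chain_ids=np.array(chains, dtype=object)[order],
        res_ids=np.array(res_ids)[order],
        res_names=np.array(res_names, dtype=object)[order],
        roles=np.array(roles, dtype=object)[order],
        coords=np.array(coords)[order],
    )
    struct.validate()
    return topo, struct


# ---------------------------------------------------------------------------
# Mode-structured trajectories
# ---------------------------------------------------------------------------

@dataclass
class Sinusoid:
    """a(t) = amplitude * sin(2*pi*t/period + phase)."""
    amplitude: float
    period: float
    phase: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(2 * np.pi * t / self.period + self.phase)

    @property
    def variance(self) -> float:
        return self.amplitude ** 2 / 2.0


@dataclass
class GaussianAmplitude:
    """a(t) ~ i.i.d. Normal(0, std^2)."""
    std: float

    @property
    def variance(self) -> float:
        return self.std ** 2


@dataclass
class ModeSpec:
    """One collective mode: a unit 3N displacement vector and its amplitude law."""
    vector: np.ndarray
    process: Sinusoid | GaussianAmplitude
    label: str = "other"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()


def rigid_body_subspace(reference: Structure) -> np.ndarray:
    """Orthonormal basis (6, 3N) of rigid translations and rotations
    about the centroid of the reference."""
    x = reference.coords - reference.coords.mean(axis=0)
    n = len(x)
    basis = []
    for i in range(3):
        v = np.zeros((n, 3))
        v[:, i] = 1.0
        basis.append(v.ravel())
    for axis in np.eye(3):
        basis.append(np.cross(np.broadcast_to(axis, x.shape), x).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T


def internal_mode_vectors(reference: Structure, k: int, seed: int) -> np.ndarray:
    """k random orthonormal 3N mode vectors orthogonal to the rigid-body
    subspace, so modal displacements carry no net translation or torque and
    survive trajectory superposition unchanged."""
    rng = np.random.default_rng(seed)
    n3 = 3 * reference.n_atoms
    rigid = rigid_body_subspace(reference)
    raw = rng.standard_normal((n3, k))
    raw -= rigid.T @ (rigid @ raw)
    q, _ = np.linalg.qr(raw)
    return q.T[:k]


def generate_mode_trajectory(reference: Structure, modes: Sequence[ModeSpec],
                             noise_std: float, n_frames: int, seed: int,
                             dt: float = 1.0) -> Trajectory:
    """Trajectory frames = reference + sum_k a_k(t) v_k + isotropic noise.

    With sinusoidal amplitudes and zero noise the population covariance is
    exactly sum_k (A_k^2/2) v_k v_k^T, so PCA variance fractions equal
    A_k^2 / sum A_k^2.  Reproducible for a fixed seed.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    vecs = np.array([m.vector for m in modes])
    n3 = 3 * reference.n_atoms
    if vecs.shape[1] != n3:
        raise ValueError("mode vector length does not match 3N")
    gram = vecs @ vecs.T
    if np.max(np.abs(gram - np.eye(len(modes)))) > 1e-8:
        raise ValueError("mode vectors must be mutually orthonormal")

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt
    disp = np.zeros((n_frames, n3))
    for m in modes:
        if isinstance(m.process, Sinusoid):
            a = m.process(times)
        else:
            a = rng.normal(0.0, m.process.std, size=n_frames)
        disp += np.outer(a, m.vector)
    coords = reference.coords.ravel()[None, :] + disp
    if noise_std > 0:
        coords = coords + rng.normal(0.0, noise_std, size=coords.shape)
    return Trajectory(reference, times, coords.reshape(n_frames, -1, 3))


# ---------------------------------------------------------------------------
# Analytic CV-space potentials
# ---------------------------------------------------------------------------

@dataclass
class AnalyticPotential:
    """Energy (kJ/mol) and gradient over a 1- or 2-D collective-variable space.

    ``energy`` and ``gradient`` accept arrays of shape (..., dim) (or bare
    scalars for 1-D) and broadcast over leading axes.
    """

    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def _prep(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.dim == 1 and (s.ndim == 0 or s.shape[-1] != 1):
            s = s[..., None]
        return s

    def U(self, s) -> np.ndarray:
        return self.energy(self._prep(s))

    def dU(self, s) -> np.ndarray:
        return self.gradient(self._prep(s))


def make_double_well(barrier: float) -> AnalyticPotential:
    """Symmetric quartic double well U(s) = barrier * (s^2 - 1)^2.

    Minima at s = ±1 with U = 0; the barrier top sits at s = 0 with
    U = ``barrier`` kJ/mol.  This is the exact free-energy profile of the
    1-D Langevin benchmark, so bias-based FES estimates can be scored
    against it pointwise.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")

    def energy(s):
        x = s[..., 0]
        return barrier * (x ** 2 - 1.0) ** 2

    def gradient(s):
        x = s[..., 0]
        return (4.0 * barrier * x * (x ** 2 - 1.0))[..., None]

    return AnalyticPotential(1, energy, gradient, {"barrier": barrier})


def make_hinge_potential_2d(open_basin: tuple[float, float] = (110.0, 2.5),
                            compact_basin: tuple[float, float] = (43.0, 0.3),
                            depths: tuple[float, float] = (8.0, 5.0),
                            barrier: float = 3.0,
                            open_widths: tuple[float, float] = (18.0, 0.5),
                            compact_widths: tuple[float, float] = (6.0, 0.08),
                            theta_walls: tuple[float, float] = (30.0, 150.0),
                            d_walls: tuple[float, float] = (0.05, 3.5),
                            ) -> AnalyticPotential:
    """Two-basin surface over (opening angle theta in degrees, Trp–Trp
    distance d in nm) emulating the hinge peptide's landscape.

    Defaults place the open/twisted basin at (110°, 2.5 nm) and the compact
    basin at (43°, 0.3 nm) with the open basin deeper, a Gaussian saddle bump
    of height ``barrier`` at the midpoint, and steep quartic confining walls
    outside theta in [30°, 150°] and d in [0.05, 3.5] nm.
    """
    ob = np.asarray(open_basin, dtype=float)
    cb = np.asarray(compact_basin, dtype=float)
    if np.allclose(ob, cb):
        raise ValueError("basins must be distinct")
    if min(depths) <= 0 or barrier <= 0:
        raise ValueError("depths and barrier must be positive")
    centers = np.array([ob, cb])
    widths = np.array([open_widths, compact_widths], dtype=float)
    depth = np.asarray(depths, dtype=float)
    # solve for effective well depths so U at each basin center is exactly
    # -depth (the tiny cross-well tails would otherwise offset the basins)
    cross = np.ones((2, 2))
    for i in range(2):
        for j in range(2):
            if i != j:
                cross[i, j] = np.exp(
                    -((centers[i, 0] - centers[j, 0]) ** 2 / (2 * widths[j, 0] ** 2)
                      + (centers[i, 1] - centers[j, 1]) ** 2 / (2 * widths[j, 1] ** 2)))
    depth = np.linalg.solve(cross, depth)
    bump_c = 0.5 * (ob + cb)
    # narrow enough that the bump does not measurably shift the basin minima
    bump_w = np.abs(ob - cb) / 6.0
    wall_k = 50.0
    wall_scale = np.array([10.0, 0.25])  # deg, nm

    def energy(s):
        th, d = s[..., 0], s[..., 1]
        u = np.zeros(np.broadcast(th, d).shape)
        for i in range(2):
            u = u - depth[i] * np.exp(
                -((th - centers[i, 0]) ** 2 / (2 * widths[i, 0] ** 2)
                  + (d - centers[i, 1]) ** 2 / (2 * widths[i, 1] ** 2)))
        u = u + barrier * np.exp(
            -((th - bump_c[0]) ** 2 / (2 * bump_w[0] ** 2)
              + (d - bump_c[1]) ** 2 / (2 * bump_w[1] ** 2)))
        lo = np.clip(theta_walls[0] - th, 0.0, None) / wall_scale[0]
        hi = np.clip(th - theta_walls[1], 0.0, None) / wall_scale[0]
        dlo = np.clip(d_walls[0] - d, 0.0, None) / wall_scale[1]
        dhi = np.clip(d - d_walls[1], 0.0, None) / wall_scale[1]
        return u + wall_k * (lo ** 4 + hi ** 4 + dlo ** 4 + dhi ** 4)

    def gradient(s):
        th, d = s[..., 0], s[..., 1]
        gth = np.zeros(np.broadcast(th, d).shape)
        gd = np.zeros_like(gth)
        for i in range(2):
            e = np.exp(-((th - centers[i, 0]) ** 2 / (2 * widths[i, 0] ** 2)
                         + (d - centers[i, 1]) ** 2 / (2 * widths[i, 1] ** 2)))
            gth = gth + depth[i] * e * (th - centers[i, 0]) / widths[i, 0] ** 2
            gd = gd + depth[i] * e * (d - centers[i, 1]) / widths[i, 1] ** 2
        e = np.exp(-((th - bump_c[0]) ** 2 / (2 * bump_w[0] ** 2)
                     + (d - bump_c[1]) ** 2 / (2 * bump_w[1] ** 2)))
        gth = gth - barrier * e * (th - bump_c[0]) / bump_w[0] ** 2
        gd = gd - barrier * e * (d - bump_c[1]) / bump_w[1] ** 2
        lo = np.clip(theta_walls[0] - th, 0.0, None) / wall_scale[0]
        hi = np.clip(th - theta_walls[1], 0.0, None) / wall_scale[0]
        gth = gth + wall_k * 4 * (hi ** 3 - lo ** 3) / wall_scale[0]
        dlo = np.clip(d_walls[0] - d, 0.0, None) / wall_scale[1]
        dhi = np.clip(d - d_walls[1], 0.0, None) / wall_scale[1]
        gd = gd + wall_k * 4 * (dhi ** 3 - dlo ** 3) / wall_scale[1]
        return np.stack([gth, gd], axis=-1)

    return AnalyticPotential(2, energy, gradient, {
        "open_basin": tuple(ob), "compact_basin": tuple(cb),
        "depths": tuple(depth), "barrier": barrier,
    })
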