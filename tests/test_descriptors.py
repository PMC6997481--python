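"""Descriptor geometry against independent oracles and invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from hingeflex import (
    CVSeries, ModeSpec, Sinusoid, Trajectory, build_topology,
    default_descriptor_spec, descriptor_series, internal_mode_vectors,
    generate_mode_trajectory, kabsch_superpose, opening_angle,
    trp_trp_distance,
)
from hingeflex.descriptors import (
    DegenerateGeometryError, core_dihedral, dihedral_from_points,
    superpose_structure,
)
from .conftest import random_rigid_transform


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def arccos_angle_oracle(apex, a, b):
    """Plain arccos-of-normalized-dot-product opening angle, degrees."""
    u, v = a - apex, b - apex
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def projection_dihedral_oracle(p):
    """Dihedral via in-plane projections perpendicular to the central bond."""
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    m = b2 / np.linalg.norm(b2)
    u = -(b1 - np.dot(b1, m) * m)   # toward atom 1, projected
    w = b3 - np.dot(b3, m) * m      # toward atom 4, projected
    return np.arctan2(np.dot(np.cross(u, w), m), np.dot(u, w))


def grid_search_rmsd_oracle(mobile, reference, coarse_deg=15.0):
    """Minimum RMSD over rotations by Euler-grid search plus local refinement."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)

    def rmsd_of(angles):
        r = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ r.T - b) ** 2, axis=1)))

    grid = np.arange(-180.0, 180.0, coarse_deg)
    best, best_angles = np.inf, None
    for az in grid:
        for ay in np.arange(-90.0, 90.1, coarse_deg):
            for ax in grid:
                v = rmsd_of((az, ay, ax))
                if v < best:
                    best, best_angles = v, (az, ay, ax)
    res = minimize(rmsd_of, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 4000})
    return min(best, res.fun)


# --------------------------------------------------------------------------
# opening angle
# --------------------------------------------------------------------------

def _angle_from_points(apex, a, b):
    """opening_angle on a minimal synthetic frame with the given centers."""
    from hingeflex.io_core import Structure
    from hingeflex.descriptors import DescriptorSpec

    coords = np.array([apex, a, b])
    s = Structure(
        chain_ids=np.array(["A", "A", "B"], dtype=object),
        res_ids=np.array([1, 2, 1]),
        res_names=np.array(["CYS", "ALA", "ALA"], dtype=object),
        roles=np.array(["SG", "CA", "CA"], dtype=object),
        coords=coords,
    )
    spec = DescriptorSpec(apex_atoms=[("A", 1, "SG")],
                          arm_atoms={"A": [("A", 2, "CA")], "B": [("B", 1, "CA")]},
                          dihedral=None, distance_pair=None)
    return opening_angle(s, spec)


def test_opening_angle_collinear_and_orthogonal():
    assert _angle_from_points([0, 0, 0], [1, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)
    assert _angle_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)


def test_opening_angle_matches_arccos_oracle(rng):
    for _ in range(200):
        apex, a, b = rng.uniform(-2, 2, size=(3, 3))
        if min(np.linalg.norm(a - apex), np.linalg.norm(b - apex)) < 1e-3:
            continue
        assert _angle_from_points(apex, a, b) == pytest.approx(
            arccos_angle_oracle(apex, a, b), abs=1e-9)


def test_opening_angle_degenerate_apex():
    with pytest.raises(DegenerateGeometryError):
        _angle_from_points([0, 0, 0], [0, 0, 0], [1, 0, 0])


def test_opening_angle_symmetric_under_chain_swap(hinge_ref):
    topo, ref = hinge_ref
    spec = default_descriptor_spec(topo)
    swapped = default_descriptor_spec(topo)
    keys = list(spec.arm_atoms)
    swapped.arm_atoms = {keys[0]: spec.arm_atoms[keys[1]],
                         keys[1]: spec.arm_atoms[keys[0]]}
    assert opening_angle(ref, spec) == pytest.approx(opening_angle(ref, swapped), abs=1e-12)


# --------------------------------------------------------------------------
# core dihedral
# --------------------------------------------------------------------------

def test_dihedral_planar_conventions():
    trans = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], dtype=float)
    cis = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    quarter = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=float)
    assert dihedral_from_points(trans) == pytest.approx(np.pi)
    assert dihedral_from_points(cis) == pytest.approx(0.0)
    assert dihedral_from_points(quarter) == pytest.approx(np.pi / 2)


def test_dihedral_matches_projection_oracle(rng):
    """1000 random quadruples agree with the projection oracle to 1e-9 rad."""
    n = 0
    while n < 1000:
        p = rng.uniform(-2, 2, size=(4, 3))
        try:
            val = dihedral_from_points(p)
        except DegenerateGeometryError:
            continue
        assert val == pytest.approx(projection_dihedral_oracle(p), abs=1e-9)
        n += 1


def test_dihedral_rotation_construction(rng):
    """Rotating atom 4 about the 2→3 axis by −φ lands in the cis plane."""
    for _ in range(50):
        p = rng.uniform(-2, 2, size=(4, 3))
        try:
            phi = dihedral_from_points(p)
        except DegenerateGeometryError:
            continue
        axis = p[2] - p[1]
        rot = Rotation.from_rotvec(-phi * axis / np.linalg.norm(axis))
        q = p.copy()
        q[3] = p[2] + rot.apply(p[3] - p[2])
        assert dihedral_from_points(q) == pytest.approx(0.0, abs=1e-8)


def test_dihedral_reversal_and_mirror_symmetries(rng):
    for _ in range(100):
        p = rng.uniform(-2, 2, size=(4, 3))
        try:
            fwd = dihedral_from_points(p)
        except DegenerateGeometryError:
            continue
        # classic identity: the torsion is invariant under order reversal
        rev = dihedral_from_points(p[::-1])
        assert np.angle(np.exp(1j * (fwd - rev))) == pytest.approx(0.0, abs=1e-9)
        # mirror reflection negates the signed torsion
        mirrored = p * np.array([1.0, 1.0, -1.0])
        mir = dihedral_from_points(mirrored)
        assert np.angle(np.exp(1j * (fwd + mir))) == pytest.approx(0.0, abs=1e-9)


def test_dihedral_collinear_triple_rejected():
    p = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]], dtype=float)
    with pytest.raises(DegenerateGeometryError):
        dihedral_from_points(p)


# --------------------------------------------------------------------------
# distance, Kabsch, series
# --------------------------------------------------------------------------

def test_trp_trp_distance(hinge_ref, rng):
    topo, ref = hinge_ref
    spec = default_descriptor_spec(topo)
    assert spec.distance_pair is not None
    s = ref.copy()
    i = s.index_of(*spec.distance_pair[0])
    j = s.index_of(*spec.distance_pair[1])
    s.coords[i] = [0, 0, 0]
    s.coords[j] = [0, 0, 2.5]
    assert trp_trp_distance(s, spec.distance_pair) == pytest.approx(2.5)
    s.coords[j] = s.coords[i]
    assert trp_trp_distance(s, spec.distance_pair) == 0.0
    for _ in range(20):
        a, b = rng.uniform(-3, 3, size=(2, 3))
        s.coords[i], s.coords[j] = a, b
        assert trp_trp_distance(s, spec.distance_pair) == pytest.approx(
            float(np.sqrt(((a - b) ** 2).sum())), abs=1e-12)


def test_kabsch_self_and_rigid_copy(hinge_ref, rng):
    _, ref = hinge_ref
    r0, t0, rmsd0 = superpose_structure(ref, ref)
    assert rmsd0 == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(r0, np.eye(3), atol=1e-9)
    rot, trans = random_rigid_transform(rng)
    moved = ref.copy()
    moved.coords = ref.coords @ rot.T + trans
    _, _, rmsd = superpose_structure(moved, ref)
    assert rmsd < 1e-9


def test_kabsch_rotation_is_proper(rng):
    # a reflection-prone configuration: nearly planar point sets
    for _ in range(20):
        a = rng.uniform(-1, 1, size=(5, 3)) * np.array([1, 1, 1e-3])
        b = rng.uniform(-1, 1, size=(5, 3)) * np.array([1, 1, 1e-3])
        r, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_matches_grid_search_oracle(rng):
    """5-atom random pairs: SVD RMSD equals exhaustive rotation search."""
    from .test_descriptors import grid_search_rmsd_oracle
    for _ in range(8):
        a = rng.uniform(-1, 1, size=(5, 3))
        b = rng.uniform(-1, 1, size=(5, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(grid_search_rmsd_oracle(a, b), abs=1e-4)


def test_kabsch_contract_errors(rng):
    a = rng.uniform(-1, 1, size=(5, 3))
    with pytest.raises(ValueError, match="differ"):
        kabsch_superpose(a, a[:4])
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line)


def test_rigid_invariance_of_all_descriptors(hinge_ref, rng):
    """Global rotation+translation leaves every descriptor unchanged (1e-9)."""
    topo, ref = hinge_ref
    spec = default_descriptor_spec(topo)
    base = (opening_angle(ref, spec), core_dihedral(ref, spec.dihedral),
            trp_trp_distance(ref, spec.distance_pair))
    for _ in range(10):
        rot, trans = random_rigid_transform(rng)
        moved = ref.copy()
        moved.coords = ref.coords @ rot.T + trans
        assert opening_angle(moved, spec) == pytest.approx(base[0], abs=1e-9)
        assert core_dihedral(moved, spec.dihedral) == pytest.approx(base[1], abs=1e-9)
        assert trp_trp_distance(moved, spec.distance_pair) == pytest.approx(base[2], abs=1e-9)


def test_descriptor_series_constant_trajectory(hinge_ref):
    topo, ref = hinge_ref
    spec = default_descriptor_spec(topo)
    traj = Trajectory(ref, np.arange(4.0), np.repeat(ref.coords[None], 4, axis=0))
    series = {s.name: s for s in descriptor_series(traj, spec)}
    assert np.allclose(series["rmsd_nm"].values, 0.0, atol=1e-12)
    for s in series.values():
        assert len(s) == 4
        assert np.ptp(s.values) < 1e-12


def test_pure_twist_mode_leaves_opening_angle_flat(hinge_ref):
    """A mode built from in-plane chain counter-rotation changes the core
    dihedral but not the opening angle."""
    topo, ref = hinge_ref
    spec = default_descriptor_spec(topo)
    # displace chains in ±z proportional to x-offset from center: a twist
    v = np.zeros((ref.n_atoms, 3))
    xc = ref.coords[:, 0].mean()
    for i in range(ref.n_atoms):
        sgn = 1.0 if ref.chain_ids[i] == "A" else -1.0
        v[i, 2] = sgn * (ref.coords[i, 0] - xc)
    v = v.ravel()
    v /= np.linalg.norm(v)
    traj = generate_mode_trajectory(ref, [ModeSpec(v, Sinusoid(0.05, 25.0))],
                                    0.0, 100, seed=0)
    series = {s.name: s for s in descriptor_series(traj, spec)}
    assert np.ptp(series["core_dihedral_rad"].values) > 0.05
    assert np.ptp(series["opening_angle_deg"].values) < 1.0
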