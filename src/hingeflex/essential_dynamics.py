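"""Essential dynamics: PCA of superposed Cα trajectories.

Frames are iteratively superposed onto a self-consistent mean structure
(align to frame 1, recompute the mean, re-align to it, and repeat until the
mean stops moving), then the full 3N x 3N positional covariance is
eigendecomposed.  Leading eigenvectors are the dominant collective motions;
eigenvalue fractions are their share of the total variance — the quantity
reported as "percentage of the dominating modes" for hinge peptides.

Covariance uses the population normalization (1/n_frames) so that
noise-free sinusoidal mode trajectories reproduce their analytic
eigenvalues A_k^2/2 exactly; variance *fractions* are independent of this
choice.  Mass-unweighted, Cα-only by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import CVSeries, Structure, Trajectory
from .descriptors import kabsch_superpose


@dataclass
class PCAModel:
    """Fitted essential-dynamics model over one atom selection."""

    selection: str
    template: Structure          # selection-only topology, coords = mean
    mean: np.ndarray             # (3M,) nm
    eigenvalues: np.ndarray      # (n_modes,) nm^2, descending
    components: np.ndarray       # (n_modes, 3M), orthonormal rows
    n_frames: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def variance_fraction(self, k: int) -> float:
        """Fraction of total variance carried by mode k (1-based)."""
        if not 1 <= k <= self.n_modes:
            raise ValueError(f"mode index {k} out of range 1..{self.n_modes}")
        total = self.eigenvalues.sum()
        return float(self.eigenvalues[k - 1] / total)


def _aligned_selection(trajectory: Trajectory, selection: str,
                       align: bool, tol: float = 1e-12,
                       max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame's selection onto the converged mean.

    Returns (aligned coords (n, M, 3), mean (M, 3)).
    """
    idx = trajectory.topology.select(role=selection)  # role=None selects all
    if len(idx) < 3:
        raise ValueError("selection must contain at least 3 atoms")
    frames = trajectory.coords[:, idx, :]
    if not align:
        return frames.copy(), frames.mean(axis=0)
    mean = frames[0]
    aligned = frames
    for _ in range(max_iter):
        aligned = np.empty_like(frames)
        for i, f in enumerate(frames):
            r, t, _ = kabsch_superpose(f, mean)
            aligned[i] = f @ r.T + t
        new_mean = aligned.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return aligned, mean


def fit_pca(trajectory: Trajectory, selection: str | None = "CA",
            align: bool = True) -> PCAModel:
    """Fit essential-dynamics PCA on a trajectory.

    ``selection`` is an atom role ("CA" default, mass-unweighted) or None
    for all atoms.

    Eigenvector sign is fixed (largest-magnitude component positive) so the
    decomposition is deterministic; eigenvalues are clipped at zero.
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    aligned, mean = _aligned_selection(trajectory, selection, align)
    n = aligned.shape[0]
    y = aligned.reshape(n, -1) - mean.ravel()[None, :]
    cov = (y.T @ y) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    idx = trajectory.topology.select(role=selection)
    top = trajectory.topology
    template = Structure(top.chain_ids[idx], top.res_ids[idx],
                         top.res_names[idx], top.roles[idx], mean.copy())
    return PCAModel(selection=selection, template=template, mean=mean.ravel(),
                    eigenvalues=evals, components=comps, n_frames=n)


def variance_fraction(model: PCAModel, k: int) -> float:
    """λ_k / Σλ for 1-based mode index k."""
    return model.variance_fraction(k)


def project(trajectory: Trajectory, model: PCAModel, k: int) -> CVSeries:
    """Projection of each (aligned, mean-centered) frame onto mode k."""
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"mode index {k} out of range 1..{model.n_modes}")
    idx = trajectory.topology.select(role=model.selection)
    if len(idx) * 3 != model.mean.size:
        raise ValueError("trajectory selection does not match the model")
    mean3 = model.mean.reshape(-1, 3)
    vals = np.empty(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        f = trajectory.coords[i, idx, :]
        r, t, _ = kabsch_superpose(f, mean3)
        y = (f @ r.T + t).ravel() - model.mean
        vals[i] = y @ model.components[k - 1]
    return CVSeries(f"pc{k}", trajectory.times.copy(), vals)


def mode_endpoints(model: PCAModel, k: int, amplitude: float = 2.0
                   ) -> tuple[Structure, Structure, np.ndarray]:
    """Extreme conformations of mode k at ±amplitude·√λ_k.

    Returns the two endpoint structures and the per-atom displacement
    vectors between them (the arrows of a porcupine-style mode plot).
    """
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"mode index {k} out of range 1..{model.n_modes}")
    lam = model.eigenvalues[k - 1]
    if lam <= 0:
        raise ValueError(f"mode {k} has zero variance; endpoints undefined")
    disp = amplitude * np.sqrt(lam) * model.components[k - 1]
    lo, hi = model.template.copy(), model.template.copy()
    lo.coords = (model.mean - disp).reshape(-1, 3)
    hi.coords = (model.mean + disp).reshape(-1, 3)
    arrows = hi.coords - lo.coords
    return lo, hi, arrows


def label_modes(model: PCAModel, trajectory: Trajectory,
                descriptor_series: list[CVSeries], n_modes: int = 3,
                threshold: float = 0.7) -> dict[int, str]:
    """Assign twist / open_close labels by correlating PC projections with
    descriptor series (|Pearson r| above the threshold)."""
    by_name = {s.name: s.values for s in descriptor_series}
    labels: dict[int, str] = {}
    for k in range(1, min(n_modes, model.n_modes) + 1):
        proj = project(trajectory, model, k).values
        best, best_r = "other", threshold
        for name, label in (("core_dihedral_rad", "twist"),
                            ("trp_trp_distance_nm", "twist"),
                            ("opening_angle_deg", "open_close")):
            if name not in by_name:
                continue
            v = by_name[name]
            if np.std(v) < 1e-12 or np.std(proj) < 1e-12:
                continue
            r = abs(np.corrcoef(proj, v)[0, 1])
            if r > best_r:
                best, best_r = label, r
        labels[k] = best
    return labels
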