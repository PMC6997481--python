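"""Langevin dynamics on collective-variable potentials and a from-scratch
well-tempered metadynamics engine.

The sampler is a BAOAB-discretized Langevin integrator acting directly in
a 1- or 2-dimensional collective-variable space (a desk-scale surrogate for
thermostatted all-atom dynamics).  Well-tempered metadynamics deposits a
Gaussian energy penalty on previously visited CV values every ``stride``
picoseconds; hill heights decay as

    h = w0 * exp(-V(s)/(kB * dT)),      dT = (gamma - 1) * T,

so the accumulated bias converges to -(1 - 1/gamma) * F(s) and the free
energy is recovered as F(s) = -(gamma/(gamma-1)) * V(s), shifted to zero at
its minimum.

Default deposition parameters follow the hinge-peptide protocol: initial
height 0.175 kJ/mol, bias factor 8, one hill per ps, Gaussian width 0.05 in
the twist-like CV (0.35 for distance-like CVs).

Hills are kept as an exact append-only log; `bias_value`/`bias_gradient`
are straight sums over all hills.  For long runs the integrator's inner
loop reads the bias force from an incrementally updated fine grid (linear
interpolation) instead of the O(n_hills) sum — deposited heights and any
post-hoc free-energy reconstruction always use the exact sum.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import KB, CVSeries
from .synthetic_hinge import AnalyticPotential


@dataclass
class MetaDParams:
    """Well-tempered deposition parameters (one sigma/period entry per CV)."""

    initial_height: float = 0.175      # w0, kJ/mol
    bias_factor: float = 8.0           # gamma, dimensionless
    stride: float = 1.0                # ps between deposits
    sigma: Sequence[float] = (0.05,)   # Gaussian width per CV, CV units
    temperature: float = 300.0         # K
    periods: Sequence[float | None] = (None,)  # e.g. 2*pi for dihedral CVs

    def __post_init__(self) -> None:
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.periods = list(self.periods)
        if len(self.periods) != len(self.sigma):
            raise ValueError("periods and sigma must have one entry per CV")
        if self.initial_height <= 0:
            raise ValueError("initial height must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if np.any(self.sigma <= 0) or self.stride <= 0:
            raise ValueError("sigma and stride must be positive")

    @property
    def n_cv(self) -> int:
        return len(self.sigma)

    @property
    def kb_delta_t(self) -> float:
        """kB * dT = kB * (gamma - 1) * T, the well-tempered energy scale."""
        return KB * (self.bias_factor - 1.0) * self.temperature


class MetaDBias:
    """Ordered log of deposited Gaussians plus exact bias evaluation."""

    def __init__(self, params: MetaDParams):
        self.params = params
        self._n = 0
        cap = 1024
        self._times = np.empty(cap)
        self._centers = np.empty((cap, params.n_cv))
        self._heights = np.empty(cap)

    # -- log management -----------------------------------------------------

    def __len__(self) -> int:
        return self._n

    @property
    def hills(self) -> list[tuple[float, np.ndarray, float]]:
        return [(float(self._times[i]), self._centers[i].copy(),
                 float(self._heights[i])) for i in range(self._n)]

    def add_hill(self, t: float, center, height: float) -> None:
        center = np.atleast_1d(np.asarray(center, dtype=float))
        if center.shape != (self.params.n_cv,):
            raise ValueError("hill center dimension mismatch")
        if self._n and t <= self._times[self._n - 1]:
            raise ValueError("hill times must be strictly increasing")
        if not 0 < height <= self.params.initial_height + 1e-12:
            raise ValueError("hill height must lie in (0, w0]")
        if self._n == len(self._times):
            grow = len(self._times) * 2
            self._times = np.resize(self._times, grow)
            self._heights = np.resize(self._heights, grow)
            self._centers = np.resize(self._centers, (grow, self.params.n_cv))
        self._times[self._n] = t
        self._centers[self._n] = center
        self._heights[self._n] = height
        self._n += 1

    # -- evaluation ---------------------------------------------------------

    def _wrapped_delta(self, s: np.ndarray) -> np.ndarray:
        """(..., H, d) displacements from every hill center, periodic-wrapped."""
        delta = s[..., None, :] - self._centers[:self._n]
        for i, p in enumerate(self.params.periods):
            if p is not None:
                delta[..., i] -= p * np.round(delta[..., i] / p)
        return delta

    def bias_value(self, s) -> np.ndarray | float:
        """V(s) = sum over hills of h * prod_i exp(-delta_i^2 / (2 sigma_i^2))."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        scalar = s.ndim == 1
        if s.shape[-1] != self.params.n_cv:
            raise ValueError("CV dimension mismatch")
        if self._n == 0:
            out = np.zeros(s.shape[:-1])
            return float(out) if scalar else out
        delta = self._wrapped_delta(s)
        expo = np.sum(delta ** 2 / (2.0 * self.params.sigma ** 2), axis=-1)
        v = np.exp(-expo) @ self._heights[:self._n]
        return float(v) if scalar else v

    def bias_gradient(self, s) -> np.ndarray:
        """Analytic gradient of the bias, same shape as s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        scalar = s.ndim == 1
        if self._n == 0:
            g = np.zeros(s.shape)
            return g if not scalar else g
        delta = self._wrapped_delta(s)
        expo = np.sum(delta ** 2 / (2.0 * self.params.sigma ** 2), axis=-1)
        w = np.exp(-expo) * self._heights[:self._n]
        g = -np.einsum("...h,...hd->...d", w, delta / self.params.sigma ** 2)
        return g[0] if scalar and g.ndim == 2 and s.ndim == 1 else g


def deposit(bias: MetaDBias, s_now, t: float) -> float:
    """Deposit one well-tempered hill at the current CV position.

    Returns the deposited height h = w0 * exp(-V(s_now)/(kB*dT)).
    """
    p = bias.params
    v = bias.bias_value(s_now)
    h = p.initial_height * math.exp(-float(v) / p.kb_delta_t)
    bias.add_hill(t, s_now, h)
    return h


def fes_from_bias(bias: MetaDBias, edges: Sequence[np.ndarray]):
    """Free-energy estimate F = -(gamma/(gamma-1)) V_final on a grid,
    shifted so the minimum is zero.  ``edges`` is one bin-edge array per CV.
    """
    from .fes_reweight import FESGrid

    if len(bias) == 0:
        raise ValueError("empty bias: no free energy to reconstruct")
    edges = [np.asarray(e, dtype=float) for e in edges]
    if len(edges) != bias.params.n_cv:
        raise ValueError("grid dimension must match the CV count")
    centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
    mesh = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1)
    g = bias.params.bias_factor
    f = -(g / (g - 1.0)) * bias.bias_value(mesh)
    f = f - f.min()
    return FESGrid(edges=edges, free_energy=f,
                   visited=np.ones(f.shape, dtype=bool),
                   metadata={"temperature": bias.params.temperature,
                             "estimator": "well-tempered final bias"})


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------

@dataclass
class LangevinParams:
    """BAOAB integrator parameters for CV-space dynamics."""

    dt: float = 0.01               # ps
    friction: float = 1.0          # 1/ps
    temperature: float = 300.0     # K
    mass: Sequence[float] | float = 1.0  # (kJ/mol) ps^2 per CV-unit^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction <= 0 or self.temperature <= 0:
            raise ValueError("dt, friction and temperature must be positive")

    def masses(self, dim: int) -> np.ndarray:
        m = np.atleast_1d(np.asarray(self.mass, dtype=float))
        if m.size == 1:
            m = np.full(dim, m[0])
        if m.size != dim or np.any(m <= 0):
            raise ValueError("need one positive mass per CV")
        return m


class _TabulatedForce:
    """Force of an analytic potential sampled on a fine regular grid.

    Linear/bilinear interpolation between grid nodes; positions outside the
    grid fall back to the exact callable.  Also serves as the incremental
    accumulator for the metadynamics bias force.
    """

    def __init__(self, dim: int, lows, highs, n_points: int = 801):
        self.dim = dim
        self.lows = np.atleast_1d(np.asarray(lows, dtype=float))
        self.highs = np.atleast_1d(np.asarray(highs, dtype=float))
        self.n = n_points
        axes = [np.linspace(self.lows[i], self.highs[i], n_points)
                for i in range(dim)]
        self.axes = axes
        self.step = np.array([a[1] - a[0] for a in axes])
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        self.mesh = mesh
        self.force = np.zeros(mesh.shape)
        self.refresh_cache()

    def add_potential(self, potential: AnalyticPotential) -> None:
        self.force -= potential.dU(self.mesh)
        self.refresh_cache()

    def add_hill(self, center: np.ndarray, height: float,
                 sigma: np.ndarray, periods) -> None:
        delta = self.mesh - center
        for i, p in enumerate(periods):
            if p is not None:
                delta[..., i] -= p * np.round(delta[..., i] / p)
        expo = np.sum(delta ** 2 / (2.0 * sigma ** 2), axis=-1)
        w = height * np.exp(-expo)
        self.force += w[..., None] * delta / sigma ** 2
        self.refresh_cache()

    def in_range(self, s) -> bool:
        for i in range(self.dim):
            if not self.lows[i] <= s[i] <= self.highs[i]:
                return False
        return True

    def __call__(self, s) -> list[float]:
        """Interpolated force at a position given as a sequence of floats."""
        if self.dim == 1:
            ix = (s[0] - self._lo0) / self._st0
            i0 = int(ix)
            i0 = 0 if i0 < 0 else (self.n - 2 if i0 > self.n - 2 else i0)
            fr = ix - i0
            col = self._f1d
            return [col[i0] + fr * (col[i0 + 1] - col[i0])]
        ix = (s[0] - self._lo0) / self._st0
        jx = (s[1] - self._lo1) / self._st1
        i0, j0 = int(ix), int(jx)
        i0 = 0 if i0 < 0 else (self.n - 2 if i0 > self.n - 2 else i0)
        j0 = 0 if j0 < 0 else (self.n - 2 if j0 > self.n - 2 else j0)
        fi, fj = ix - i0, jx - j0
        f = self.force
        out = []
        for d in range(2):
            f00 = f[i0, j0, d]
            f10 = f[i0 + 1, j0, d]
            f01 = f[i0, j0 + 1, d]
            f11 = f[i0 + 1, j0 + 1, d]
            out.append((f00 + fi * (f10 - f00)) * (1 - fj)
                       + (f01 + fi * (f11 - f01)) * fj)
        return out

    def refresh_cache(self) -> None:
        """Rebind scalar-loop lookup attributes after force updates."""
        self._lo0 = float(self.lows[0])
        self._st0 = float(self.step[0])
        if self.dim == 1:
            self._f1d = self.force[:, 0].tolist()
        else:
            self._lo1 = float(self.lows[1])
            self._st1 = float(self.step[1])


def _baoab(potential: AnalyticPotential, params: LangevinParams, n_steps: int,
           start, bias: MetaDBias | None, metad: MetaDParams | None,
           sample_stride: int, grid) -> tuple[np.ndarray, np.ndarray, MetaDBias | None]:
    dim = potential.dim
    m = params.masses(dim).tolist()
    dt, kbt = params.dt, KB * params.temperature
    c1 = math.exp(-params.friction * dt)
    c2 = [math.sqrt(kbt * (1.0 - c1 * c1) / mi) for mi in m]
    hdt = 0.5 * dt
    hdt_m = [hdt / mi for mi in m]
    rng = random.Random(params.seed)
    gauss = rng.gauss

    if start is None:
        x = [0.0] * dim
    else:
        x = [float(s) for s in np.atleast_1d(start)]
    v = [gauss(0.0, math.sqrt(kbt / m[i])) for i in range(dim)]

    tab: _TabulatedForce | None = None
    if grid is not None:
        lows, highs = grid[0], grid[1]
        n_points = grid[2] if len(grid) > 2 else 801
        tab = _TabulatedForce(dim, lows, highs, n_points)
        tab.add_potential(potential)
        if bias is not None and len(bias):
            # fold a pre-existing (fixed) bias into the tabulated force
            for row in range(tab.mesh.shape[0]):
                tab.force[row] -= bias.bias_gradient(tab.mesh[row])
            tab.refresh_cache()

    deposit_every = None
    if metad is not None:
        if bias is None:
            bias = MetaDBias(metad)
        deposit_every = max(1, round(metad.stride / dt))
        if abs(deposit_every * dt - metad.stride) > 1e-9:
            raise ValueError("deposition stride must be an integer multiple of dt")

    def exact_force(pos) -> list[float]:
        f = -np.atleast_1d(potential.dU(np.asarray(pos)))
        if bias is not None and len(bias):
            f = f - bias.bias_gradient(np.asarray(pos))
        return [float(fi) for fi in f]

    def total_force(pos) -> list[float]:
        if tab is not None and tab.in_range(pos):
            return tab(pos)
        return exact_force(pos)

    f = total_force(x)
    n_samples = n_steps // sample_stride
    out_t = np.empty(n_samples)
    out_x = np.empty((n_samples, dim))
    k = 0
    for step in range(1, n_steps + 1):
        for i in range(dim):
            vi = v[i] + hdt_m[i] * f[i]
            xi = x[i] + hdt * vi
            vi = c1 * vi + c2[i] * gauss(0.0, 1.0)
            x[i] = xi + hdt * vi
            v[i] = vi
        if deposit_every is not None and step % deposit_every == 0:
            t = step * dt
            h = deposit(bias, list(x), t)
            if tab is not None:
                tab.add_hill(np.asarray(x, dtype=float), h,
                             bias.params.sigma, bias.params.periods)
        f = total_force(x)
        for i in range(dim):
            fi = f[i]
            if not (math.isfinite(fi) and math.isfinite(x[i])):
                raise FloatingPointError(f"non-finite state at step {step}")
            v[i] += hdt_m[i] * fi
        if step % sample_stride == 0:
            out_t[k] = step * dt
            out_x[k] = x
            k += 1
    return out_t, out_x, bias


def run_langevin(potential: AnalyticPotential, params: LangevinParams,
                 n_steps: int, bias: MetaDBias | None = None,
                 start=None, sample_stride: int = 10,
                 grid=None) -> list[CVSeries]:
    """Unbiased (or fixed-bias) BAOAB Langevin trajectory on a potential.

    Returns one CVSeries per CV dimension, sampled every ``sample_stride``
    steps.  ``grid=(lows, highs[, n_points])`` enables the tabulated-force
    fast path for long runs.
    """
    t, x, _ = _baoab(potential, params, n_steps, start, bias, None,
                     sample_stride, grid)
    return [CVSeries(f"cv{i + 1}", t, x[:, i]) for i in range(potential.dim)]


def run_wtmetad(potential: AnalyticPotential, langevin: LangevinParams,
                metad: MetaDParams, n_steps: int, start=None,
                sample_stride: int = 10, grid=None
                ) -> tuple[list[CVSeries], MetaDBias]:
    """Well-tempered metadynamics: Langevin dynamics under U + V(s, t).

    Deposits one hill every ``metad.stride`` ps; the returned bias log is
    complete and the run is reproducible for a fixed ``langevin.seed``.
    """
    if metad.n_cv != potential.dim:
        raise ValueError("metadynamics CV count must match potential dimension")
    t, x, bias = _baoab(potential, langevin, n_steps, start, None, metad,
                        sample_stride, grid)
    series = [CVSeries(f"cv{i + 1}", t, x[:, i]) for i in range(potential.dim)]
    return series, bias


def count_crossings(values: np.ndarray, lo: float = -0.5, hi: float = 0.5) -> int:
    """Number of lo→hi / hi→lo transitions with hysteresis (basin switches)."""
    state = 0
    n = 0
    for v in np.asarray(values, dtype=float):
        if v <= lo:
            if state == 1:
                n += 1
            state = -1
        elif v >= hi:
            if state == -1:
                n += 1
            state = 1
    return n
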