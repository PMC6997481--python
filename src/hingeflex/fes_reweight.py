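"""Weighted-histogram free-energy surfaces from biased trajectories.

Each frame of a biased run enters the histogram with weight
exp(+V_bias/kB T), where V_bias is the (final) metadynamics bias evaluated
at that frame's CV position — the static last-bias estimator, appropriate
for converged well-tempered runs.  The free energy of a bin is

    F = -kB T ln(w / w_max),

shifted so the minimum over visited bins is zero.  Never-visited bins are
masked, not imputed.  The default 2-D surface over (opening angle,
Trp–Trp distance) uses 425 bins per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_core import KB, CVSeries


@dataclass
class FESGrid:
    """Binned free energy over 1 or 2 CVs, minimum shifted to zero."""

    edges: list                  # one bin-edge array per axis
    free_energy: np.ndarray      # kJ/mol; values on masked bins meaningless
    visited: np.ndarray          # bool mask of bins that received weight
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        shape = tuple(len(e) - 1 for e in self.edges)
        if self.free_energy.shape != shape or self.visited.shape != shape:
            raise ValueError("grid shape does not match bin edges")

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def reweighted_histogram(cv_series: Sequence[CVSeries], bias_at_frame: CVSeries,
                         temperature: float, bins) -> tuple[np.ndarray, list[np.ndarray]]:
    """Weighted counts over 1 or 2 CVs; weight = exp(+V_bias / kB T).

    ``bins`` is passed through to numpy.histogramdd (int, per-axis ints, or
    explicit edge arrays).  Returns (weights grid, bin edges).
    """
    cv_series = list(cv_series)
    if not 1 <= len(cv_series) <= 2:
        raise ValueError("need 1 or 2 CV series")
    n = len(cv_series[0])
    for s in list(cv_series) + [bias_at_frame]:
        if len(s) != n:
            raise ValueError("CV and bias series lengths differ")
    v = bias_at_frame.values
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite bias values")
    weights = np.exp(v / (KB * temperature))
    sample = np.column_stack([s.values for s in cv_series])
    hist, edges = np.histogramdd(sample, bins=bins, weights=weights)
    return hist, [np.asarray(e) for e in edges]


def fes_from_histogram(weights: np.ndarray, edges: Sequence[np.ndarray],
                       temperature: float, **metadata) -> FESGrid:
    """F = -kB T ln(w / w_max) over visited bins, masked elsewhere."""
    weights = np.asarray(weights, dtype=float)
    if not np.any(weights > 0):
        raise ValueError("histogram holds no weight; cannot build an FES")
    visited = weights > 0
    f = np.full(weights.shape, np.nan)
    f[visited] = -KB * temperature * np.log(weights[visited] / weights[visited].max())
    f = np.nan_to_num(f, nan=0.0)
    return FESGrid(edges=list(edges), free_energy=f, visited=visited,
                   metadata={"temperature": temperature,
                             "estimator": "final-bias reweighted histogram",
                             **metadata})


def locate_minima(grid: FESGrid, depth_threshold: float = 6.0,
                  smooth_sigma: float = 4.0, level: float | None = None
                  ) -> list[dict]:
    """Locate free-energy minima on a (possibly noisy) FES grid.

    The neighborhood search runs on a Gaussian-smoothed copy of the
    Boltzmann weights (8-neighborhood strict local minima over visited
    bins, at most ``depth_threshold`` kJ/mol above the global minimum).
    Each minimum is then refined to sub-bin precision by the Boltzmann-
    weighted centroid of the *unsmoothed* weights over the contiguous
    basin region lying within ``level`` kJ/mol (default kB·T) of the
    minimum — for a symmetric basin this averages histogram noise down
    without biasing the location.  Masked bins are never reported.
    """
    t = grid.metadata.get("temperature", 300.0)
    kbt = KB * t
    if level is None:
        level = kbt
    w = np.where(grid.visited, np.exp(-grid.free_energy / kbt), 0.0)
    ws = gaussian_filter(w, smooth_sigma, mode="nearest") if smooth_sigma > 0 else w
    with np.errstate(divide="ignore"):
        fs = np.where(ws > 0, -kbt * np.log(np.maximum(ws, 1e-300)), np.inf)
    fs = fs - fs.min()

    if grid.ndim == 1:
        fs2 = fs[:, None]
        vis2 = grid.visited[:, None]
        w2 = w[:, None]
    else:
        fs2, vis2, w2 = fs, grid.visited, w
    ni, nj = fs2.shape
    centers = grid.centers
    minima = []
    pad = np.pad(fs2, 1, constant_values=np.inf)
    for i in range(ni):
        for j in range(nj):
            if not vis2[i, j] or fs2[i, j] > depth_threshold:
                continue
            neigh = pad[i:i + 3, j:j + 3].copy()
            neigh[1, 1] = np.inf
            if fs2[i, j] < neigh.min():
                minima.append((fs2[i, j], i, j))
    minima.sort()

    out = []
    claimed = np.zeros(fs2.shape, dtype=bool)
    for f, i, j in minima:
        if claimed[i, j]:
            continue
        # flood fill the basin: contiguous bins within `level` of the seed
        cutoff = f + level
        stack = [(i, j)]
        region = np.zeros(fs2.shape, dtype=bool)
        region[i, j] = True
        distinct = True
        while stack:
            ci, cj = stack.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni_, nj_ = ci + di, cj + dj
                    if (0 <= ni_ < ni and 0 <= nj_ < nj and not region[ni_, nj_]
                            and fs2[ni_, nj_] <= cutoff):
                        region[ni_, nj_] = True
                        stack.append((ni_, nj_))
                        if fs2[ni_, nj_] < f - 1e-12:
                            # reaches a deeper point without climbing `level`:
                            # a noise dip on a larger basin's shoulder
                            distinct = False
        claimed |= region
        if not distinct:
            continue
        block = np.where(region, w2, 0.0)
        tot = block.sum()
        if tot <= 0:
            continue
        ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
        ci = float((block * ii).sum() / tot)
        coord = [float(np.interp(ci, np.arange(len(centers[0])), centers[0]))]
        if grid.ndim == 2:
            cj = float((block * jj).sum() / tot)
            coord.append(float(np.interp(cj, np.arange(len(centers[1])), centers[1])))
        out.append({"position": tuple(coord), "free_energy": float(f),
                    "bin": (i,) if grid.ndim == 1 else (i, j)})
    return out


def fes_2d_pipeline(angle_series: CVSeries, distance_series: CVSeries,
                    bias_at_frame: CVSeries | None = None,
                    temperature: float = 300.0, bins: int = 425,
                    depth_threshold: float = 6.0,
                    range_=None) -> tuple[FESGrid, list[dict]]:
    """2-D FES over (opening angle, Trp–Trp distance) plus located minima.

    ``bias_at_frame`` holds the final metadynamics bias evaluated at each
    frame (kJ/mol); omit it for unbiased sampling.  425 bins per axis by
    default.
    """
    if bias_at_frame is None:
        bias_at_frame = CVSeries("bias", angle_series.times,
                                 np.zeros(len(angle_series)))
    if range_ is not None:
        edges = [np.linspace(range_[0][0], range_[0][1], bins + 1),
                 np.linspace(range_[1][0], range_[1][1], bins + 1)]
        hist, edges = reweighted_histogram(
            [angle_series, distance_series], bias_at_frame, temperature, edges)
    else:
        hist, edges = reweighted_histogram(
            [angle_series, distance_series], bias_at_frame, temperature, bins)
    grid = fes_from_histogram(hist, edges, temperature,
                              cv_names=(angle_series.name, distance_series.name))
    minima = locate_minima(grid, depth_threshold=depth_threshold)
    return grid, minima
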