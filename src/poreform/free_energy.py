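"""2D free-energy landscape over (SASA, Rg) by Boltzmann inversion.

The joint distribution of two reaction coordinates, binned on a regular
grid, is converted to a free-energy surface W = -RT ln P (shifted so the
global minimum is zero).  Local minima of W are the metastable aggregate
states — here typically a compact pore-like basin and an extended
fiber-like basin — and the barrier between two basins is the minimax
saddle: the path through occupied bins whose highest point is lowest.

Empty bins are undefined (conceptually infinite W), never zero-filled, and
minimax paths cannot cross them.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet
from scipy.ndimage import gaussian_filter

from .core_io import R_KCAL
from .conformation import ConformationSeries


@dataclass
class Landscape2D:
    """Binned free-energy surface W(X, Y) in kcal/mol.

    ``p`` holds normalized bin probabilities (summing to 1 over occupied
    bins); ``w`` is -RT ln p shifted so its occupied minimum is 0; empty
    bins carry ``w = +inf`` and ``occupied = False``.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    p: np.ndarray
    w: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.p > 0

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    def bin_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (0.5 * (self.x_edges[ix] + self.x_edges[ix + 1]),
                0.5 * (self.y_edges[iy] + self.y_edges[iy + 1]))

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({
            "x_center": xx.ravel(), "y_center": yy.ravel(),
            "p": self.p.ravel(), "w_kcal_mol": self.w.ravel(),
        })


@dataclass
class Basin:
    """A local free-energy minimum (metastable aggregate state)."""

    ix: int
    iy: int
    w: float
    x: float
    y: float
    label: str = ""


@dataclass
class BarrierResult:
    """Minimax barrier between two basins."""

    forward: float                    # dG++ a -> b, kcal/mol
    backward: float                   # dG++ b -> a
    saddle_w: float
    saddle_bin: tuple[int, int] | None
    path: list[tuple[int, int]] = field(default_factory=list)
    connected: bool = True
    diagnostic: str = ""


def histogram2d(series, bins: tuple[int, int] = (50, 50),
                ranges: tuple | None = None):
    """Normalized 2D histogram of (X, Y) samples.

    ``series`` is a :class:`ConformationSeries` or a pair of arrays.  The
    default range is the observed min/max of each coordinate padded by half
    a bin, so extreme samples do not sit on the outermost edge.
    Returns ``(p, x_edges, y_edges)`` with p summing to 1.
    """
    if isinstance(series, ConformationSeries):
        x, y = np.asarray(series.sasa, float), np.asarray(series.rg, float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in series)
    if x.size == 0:
        raise ValueError("empty series")
    nx, ny = bins
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 bins per axis")
    if ranges is None:
        ranges = []
        for arr, n in ((x, nx), (y, ny)):
            lo, hi = float(arr.min()), float(arr.max())
            if hi == lo:
                hi = lo + 1e-9
            pad = 0.5 * (hi - lo) / n
            ranges.append((lo - pad, hi + pad))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=ranges)
    return counts / counts.sum(), x_edges, y_edges


def boltzmann_invert(p: np.ndarray, temperature: float,
                     x_edges: np.ndarray | None = None,
                     y_edges: np.ndarray | None = None,
                     smooth_sigma: float = 0.0) -> Landscape2D:
    """Invert a normalized probability grid into a free-energy surface.

    W = -RT ln P on occupied bins, shifted so min W = 0; the pairwise
    relation dG = -RT ln(P2/P1) then holds exactly for every occupied pair.
    ``smooth_sigma`` optionally blurs P (in bin units) before inversion.
    """
    p = np.asarray(p, dtype=float)
    if smooth_sigma > 0:
        p = gaussian_filter(p, smooth_sigma)
        p = p / p.sum()
    occupied = p > 0
    if not occupied.any():
        raise ValueError("all-empty probability grid")
    total = p[occupied].sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        p = p / total
    rt = R_KCAL * temperature
    w = np.full_like(p, np.inf)
    w[occupied] = -rt * np.log(p[occupied])
    w[occupied] -= w[occupied].min()
    nx, ny = p.shape
    if x_edges is None:
        x_edges = np.arange(nx + 1, dtype=float)
    if y_edges is None:
        y_edges = np.arange(ny + 1, dtype=float)
    return Landscape2D(x_edges=np.asarray(x_edges, float),
                       y_edges=np.asarray(y_edges, float),
                       p=p, w=w, temperature=temperature)


def _neighbours(ix: int, iy: int, shape: tuple[int, int],
                connectivity: int = 8):
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dx, dy in offsets:
        jx, jy = ix + dx, iy + dy
        if 0 <= jx < shape[0] and 0 <= jy < shape[1]:
            yield jx, jy


def find_basins(landscape: Landscape2D, min_separation: int = 3,
                max_w: float = np.inf, connectivity: int = 8) -> list[Basin]:
    """Local minima of the landscape, plateau-merged and deduplicated.

    A bin is a minimum when no 8-connected occupied neighbour is lower.
    Connected plateaus of equal-W minima collapse to one basin (so a flat
    landscape yields a single basin).  Among remaining candidates within
    ``min_separation`` bins (Chebyshev) of a deeper one, only the deeper is
    kept.  Basins above ``max_w`` are dropped; the result is sorted by W.
    """
    w, occ = landscape.w, landscape.occupied
    shape = w.shape
    is_min = np.zeros(shape, dtype=bool)
    for ix, iy in zip(*np.nonzero(occ)):
        wij = w[ix, iy]
        if all(w[jx, jy] >= wij for jx, jy in _neighbours(ix, iy, shape, connectivity)
               if occ[jx, jy]):
            is_min[ix, iy] = True

    # merge equal-W plateau components into one candidate each
    ds = DisjointSet([(int(ix), int(iy)) for ix, iy in zip(*np.nonzero(is_min))])
    for ix, iy in zip(*np.nonzero(is_min)):
        for jx, jy in _neighbours(ix, iy, shape, connectivity):
            if is_min[jx, jy] and w[jx, jy] == w[ix, iy]:
                ds.merge((int(ix), int(iy)), (int(jx), int(jy)))
    candidates = [min(comp) for comp in ds.subsets()]
    candidates.sort(key=lambda b: (w[b], b))

    kept: list[tuple[int, int]] = []
    for cand in candidates:
        if w[cand] > max_w:
            continue
        if any(max(abs(cand[0] - k[0]), abs(cand[1] - k[1])) <= min_separation
               for k in kept):
            continue
        kept.append(cand)

    basins = []
    for ix, iy in kept:
        x, y = landscape.bin_center(ix, iy)
        basins.append(Basin(ix=ix, iy=iy, w=float(w[ix, iy]), x=x, y=y))
    return basins


def barrier_height(landscape: Landscape2D, a: Basin, b: Basin,
                   connectivity: int = 8) -> BarrierResult:
    """Minimax (saddle) barrier between two basins.

    The saddle value is the minimum over occupied-bin paths from a to b of
    the path's maximum W; forward dG++ = saddle - W(a), backward =
    saddle - W(b).  Disconnected basins report an infinite barrier.
    """
    w, occ = landscape.w, landscape.occupied
    start, goal = (a.ix, a.iy), (b.ix, b.iy)
    if not (occ[start] and occ[goal]):
        raise ValueError("basins must sit on occupied bins")
    if start == goal:
        return BarrierResult(forward=0.0, backward=0.0, saddle_w=float(w[start]),
                             saddle_bin=start, path=[start])

    # widest-path Dijkstra: minimise the maximum W along the path
    best = {start: float(w[start])}
    parent: dict = {start: None}
    heap = [(float(w[start]), start)]
    saddle_bin = None
    while heap:
        cost, node = heapq.heappop(heap)
        if cost > best.get(node, np.inf):
            continue
        if node == goal:
            break
        for nb in _neighbours(*node, w.shape, connectivity):
            if not occ[nb]:
                continue
            new_cost = max(cost, float(w[nb]))
            if new_cost < best.get(nb, np.inf):
                best[nb] = new_cost
                parent[nb] = node
                heapq.heappush(heap, (new_cost, nb))
    if goal not in best:
        return BarrierResult(forward=np.inf, backward=np.inf, saddle_w=np.inf,
                             saddle_bin=None, connected=False,
                             diagnostic="basins not connected through occupied bins")
    saddle = best[goal]
    path = [goal]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    for node in path:
        if float(w[node]) == saddle:
            saddle_bin = node
            break
    return BarrierResult(forward=float(saddle - w[start]),
                         backward=float(saddle - w[goal]),
                         saddle_w=float(saddle), saddle_bin=saddle_bin,
                         path=path)


def landscape_from_series(series, temperature: float = 310.0,
                          bins: tuple[int, int] = (50, 50),
                          ranges=None, smooth_sigma: float = 0.0) -> Landscape2D:
    """Histogram + Boltzmann inversion in one call."""
    p, xe, ye = histogram2d(series, bins=bins, ranges=ranges)
    return boltzmann_invert(p, temperature, xe, ye, smooth_sigma=smooth_sigma)


def plot_landscape(landscape: Landscape2D, path=None, levels: int = 20):
    """Filled-contour plot of W; returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xc = 0.5 * (landscape.x_edges[:-1] + landscape.x_edges[1:])
    yc = 0.5 * (landscape.y_edges[:-1] + landscape.y_edges[1:])
    w = np.where(np.isfinite(landscape.w), landscape.w, np.nan)
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contourf(xc, yc, w.T, levels=levels, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="W (kcal/mol)")
    ax.set_xlabel("SASA (nm$^2$)")
    ax.set_ylabel("R$_g$ (nm)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
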