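"""Least-energy functional paths on dual landscapes, frame sets and toy reconstruction.

The functional route of ligand binding starts at the minimum-energy cell of the
-ligand landscape (START), follows the conduit of lowest energy to a cell with
high interlandscape transition probability (HOT), hops iso-conformationally to
the +ligand landscape, and descends to its minimum-energy cell (FINISH).

Paths live on the 8-connected graph of occupied grid cells.  The default
"integral" action is the discrete line integral of energy along the route
(step length times the trapezoidal mean of the endpoint energies); the
"minimax" mode minimizes the highest energy crossed, with ties resolved by the
integral cost.  Unobserved cells are impassable by default; a flag admits them
at the observability-limit cost.
"""

from __future__ import annotations

import dataclasses
import heapq
import warnings

import numpy as np

from .landscape import EnergyLandscape
from .transitions import TransitionMap, find_hotspots
from .synthetic import project_volume  # noqa: F401  (rendering counterpart)

__all__ = [
    "FunctionalPath",
    "FrameSet",
    "least_action_path",
    "bresenham_path",
    "path_action",
    "dual_landscape_path",
    "path_frames",
    "backproject_frame",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _step_len(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _energies_for_path(landscape: EnergyLandscape, allow_unobserved: bool) -> np.ndarray:
    e = landscape.energies.copy()
    e -= np.nanmin(e)  # offset so min energy is 0 (it already is by construction)
    if allow_unobserved:
        e[landscape.mask] = landscape.delta_g_max
    return e


def path_action(cells, energies: np.ndarray, mode: str = "integral") -> float:
    """Action of a given cell sequence: energy line integral, or max energy."""
    cells = list(cells)
    if mode == "minimax":
        return float(max(energies[c] for c in cells))
    total = 0.0
    for a, b in zip(cells[:-1], cells[1:]):
        total += _step_len(a, b) * 0.5 * (energies[a] + energies[b])
    return total


def least_action_path(
    landscape: EnergyLandscape,
    start: tuple[int, int],
    end: tuple[int, int],
    mode: str = "integral",
    allow_unobserved: bool = False,
) -> tuple[list[tuple[int, int]], float]:
    """Optimal path between two occupied cells on the 8-connected cell graph.

    ``mode="integral"`` minimizes the trapezoidal energy line integral;
    ``mode="minimax"`` minimizes the maximum energy along the path, ties
    resolved by integral cost.  Deterministic tie-breaking by row-major
    neighbor order.  Returns ``(cells, action)`` where the action is the
    integral cost of the chosen path.
    """
    if mode not in ("integral", "minimax"):
        raise ValueError("mode must be 'integral' or 'minimax'")
    grid = landscape.grid
    e = _energies_for_path(landscape, allow_unobserved)
    passable = ~np.isnan(e)
    for name, cell in (("start", start), ("end", end)):
        if not (0 <= cell[0] < grid.n1 and 0 <= cell[1] < grid.n2):
            raise ValueError(f"{name} cell {cell} outside the grid")
        if not passable[cell]:
            raise ValueError(f"{name} cell {cell} is unobserved (masked)")
    start = tuple(start)
    end = tuple(end)

    if mode == "minimax":
        # phase 1: the optimal bottleneck (lowest achievable maximum energy);
        # phase 2: cheapest integral route using only cells at or below it.
        m_star = _bottleneck(e, passable, start, end)
        if m_star is None:
            raise ValueError(
                f"no route from {start} to {end}: the unobserved-cell mask "
                "disconnects them"
            )
        passable = passable & (e <= m_star)
    path = _integral_dijkstra(e, passable, start, end)
    if path is None:
        raise ValueError(
            f"no route from {start} to {end}: the unobserved-cell mask disconnects them"
        )
    return path, path_action(path, e, "integral")


def _neighbors_of(cell, shape):
    for di, dj in _NEIGHBORS:  # row-major order: deterministic ties
        nb = (cell[0] + di, cell[1] + dj)
        if 0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]:
            yield nb


def _bottleneck(e, passable, start, end):
    """Lowest achievable maximum energy along any route (Dijkstra with max)."""
    n2 = e.shape[1]
    best = {start: e[start]}
    heap = [(e[start], start[0] * n2 + start[1], start)]
    seen = set()
    while heap:
        maxe, _, cell = heapq.heappop(heap)
        if cell in seen:
            continue
        seen.add(cell)
        if cell == end:
            return maxe
        for nb in _neighbors_of(cell, e.shape):
            if nb in seen or not passable[nb]:
                continue
            cand = max(maxe, e[nb])
            if nb not in best or cand < best[nb]:
                best[nb] = cand
                heapq.heappush(heap, (cand, nb[0] * n2 + nb[1], nb))
    return None


def _integral_dijkstra(e, passable, start, end):
    """Cheapest trapezoidal energy line-integral route on passable cells."""
    n2 = e.shape[1]
    best = {start: 0.0}
    heap = [(0.0, start[0] * n2 + start[1], start, None)]
    parent: dict = {}
    seen = set()
    while heap:
        integ, _, cell, prev = heapq.heappop(heap)
        if cell in seen:
            continue
        seen.add(cell)
        parent[cell] = prev
        if cell == end:
            path = []
            c = cell
            while c is not None:
                path.append(c)
                c = parent[c]
            path.reverse()
            return path
        for nb in _neighbors_of(cell, e.shape):
            if nb in seen or not passable[nb]:
                continue
            cand = integ + _step_len(cell, nb) * 0.5 * (e[cell] + e[nb])
            if nb not in best or cand < best[nb]:
                best[nb] = cand
                heapq.heappush(heap, (cand, nb[0] * n2 + nb[1], nb, cell))
    return None


def bresenham_path(start, end) -> list[tuple[int, int]]:
    """8-connected straight-line (Bresenham) cell interpolation between two cells."""
    x0, y0 = start
    x1, y1 = end
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x1 > x0 else -1
    sy = 1 if y1 > y0 else -1
    err = dx - dy
    path = [(x0, y0)]
    while (x0, y0) != (x1, y1):
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x0 += sx
        if e2 < dx:
            err += dx
            y0 += sy
        path.append((x0, y0))
    return path


@dataclasses.dataclass
class FunctionalPath:
    """Ordered cell route START -> HOT -> FINISH spanning both landscapes."""

    cells: list[tuple[int, int]]
    side: list[str]  # 'minus' / 'plus' per cell
    switch_index: int  # position of the hotspot cell (first cell on '+')
    energies: np.ndarray  # per-cell energy on the cell's own landscape
    action: float
    hotspot: tuple[int, int]
    summaries: dict = dataclasses.field(default_factory=dict)

    def __len__(self):
        return len(self.cells)


def dual_landscape_path(
    e_minus: EnergyLandscape,
    e_plus: EnergyLandscape,
    tmap: TransitionMap,
    hotspot: tuple[int, int] | None = None,
    mode: str = "integral",
    allow_unobserved: bool = False,
    hot_window_halfwidth: int = 1,
) -> FunctionalPath:
    """Concatenated least-action route across the two landscapes.

    The route runs from argmin(E-) to the hotspot on the -ligand landscape and
    from the hotspot to argmin(E+) on the +ligand landscape; the single
    - -> + switch is iso-conformational at the hotspot cell.  The hotspot
    defaults to the top-ranked local maximum of the transition map.

    ``summaries`` reports the fraction of the -ligand ensemble within a
    ``hot_window_halfwidth``-cell window of the hotspot (the probability of
    finding the hotspot region occupied before binding) and the normalized
    interlandscape transition probability at the hotspot cell.
    """
    if hotspot is None:
        spots = find_hotspots(tmap)
        if not spots:
            raise ValueError("transition map has no hotspot")
        hotspot = spots[0]
    hotspot = tuple(hotspot)
    if e_minus.mask[hotspot] or e_plus.mask[hotspot]:
        raise ValueError(f"hotspot cell {hotspot} unoccupied on one of the landscapes")
    start = e_minus.argmin_cell
    finish = e_plus.argmin_cell
    leg1, act1 = least_action_path(e_minus, start, hotspot, mode, allow_unobserved)
    leg2, act2 = least_action_path(e_plus, hotspot, finish, mode, allow_unobserved)
    cells = leg1 + leg2[1:] if len(leg2) > 1 else leg1
    side = ["minus"] * len(leg1) + ["plus"] * (len(cells) - len(leg1))
    energies = np.array(
        [
            (e_minus if s == "minus" else e_plus).energies[c]
            for c, s in zip(cells, side)
        ]
    )
    # occupancy fraction of the hotspot window on the -ligand grid
    hw = hot_window_halfwidth
    counts_minus = np.exp(-np.where(e_minus.mask, np.inf, e_minus.energies) / e_minus.kT)
    window = np.zeros(e_minus.grid.shape, dtype=bool)
    window[
        max(0, hotspot[0] - hw): hotspot[0] + hw + 1,
        max(0, hotspot[1] - hw): hotspot[1] + hw + 1,
    ] = True
    hot_occ = float(counts_minus[window & ~e_minus.mask].sum() / counts_minus[~e_minus.mask].sum())
    return FunctionalPath(
        cells=cells,
        side=side,
        switch_index=len(leg1) - 1,
        energies=energies,
        action=act1 + act2,
        hotspot=hotspot,
        summaries={
            "hot_region_occupancy_minus": hot_occ,
            "hotspot_transition_probability": float(tmap.t[hotspot]),
        },
    )


@dataclasses.dataclass
class FrameSet:
    """Per-frame snapshot membership along a resampled functional path."""

    frame_cells: list[tuple[int, int]]
    frame_side: list[str]
    members: list[np.ndarray]  # snapshot indices per frame
    window_halfwidth: int

    def __len__(self):
        return len(self.frame_cells)


def path_frames(
    path: FunctionalPath,
    cc: np.ndarray,
    condition: np.ndarray,
    grid,
    n_frames: int = 50,
    window_halfwidth: int = 1,
    cc1_excursion: int = 0,
) -> FrameSet:
    """Resample the path into equidistant frames and select members per frame.

    The cell sequence is resampled by arc length into ``n_frames`` frame
    centers (nearest cell).  Each frame's members are the snapshots of the
    frame's landscape side whose (cc1, cc2) fall inside a rectangular window
    of ``window_halfwidth`` cells around the frame cell.  ``cc1_excursion``
    optionally extends the route by that many cells beyond the two energy
    minima along CC1: increasing CC1 on the -ligand side, decreasing CC1 on
    the +ligand side (to cover motions just beyond the minima).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    cells = list(path.cells)
    side = list(path.side)
    if cc1_excursion > 0:
        n1 = grid.n1
        pre = [
            (min(n1 - 1, cells[0][0] + d), cells[0][1])
            for d in range(cc1_excursion, 0, -1)
        ]
        post = [
            (max(0, cells[-1][0] - d), cells[-1][1])
            for d in range(1, cc1_excursion + 1)
        ]
        cells = pre + cells + post
        side = ["minus"] * len(pre) + side + ["plus"] * len(post)
    pts = np.array(cells, dtype=float)
    seg = np.hypot(*(pts[1:] - pts[:-1]).T) if len(pts) > 1 else np.array([])
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_frames) if arc[-1] > 0 else np.zeros(n_frames)
    idx = np.searchsorted(arc, targets, side="left")
    idx = np.clip(idx, 0, len(cells) - 1)
    # snap each target to the nearer of the bracketing cells
    frame_cells, frame_side = [], []
    for t, i in zip(targets, idx):
        if i > 0 and abs(arc[i - 1] - t) < abs(arc[i] - t):
            i = i - 1
        frame_cells.append(cells[i])
        frame_side.append(side[i])

    w1 = (grid.edges1[1] - grid.edges1[0]) * window_halfwidth
    w2 = (grid.edges2[1] - grid.edges2[0]) * window_halfwidth
    cc = np.asarray(cc, dtype=float)
    condition = np.asarray(condition)
    members = []
    for cell, s in zip(frame_cells, frame_side):
        lo1, hi1 = grid.edges1[cell[0]] - w1, grid.edges1[cell[0] + 1] + w1
        lo2, hi2 = grid.edges2[cell[1]] - w2, grid.edges2[cell[1] + 1] + w2
        inside = (
            (condition == s)
            & (cc[:, 0] >= lo1)
            & (cc[:, 0] < hi1)
            & (cc[:, 1] >= lo2)
            & (cc[:, 1] < hi2)
        )
        sel = np.flatnonzero(inside)
        if sel.size == 0:
            warnings.warn(f"frame at cell {cell} ({s}) has no member snapshots")
        members.append(sel)
    return FrameSet(
        frame_cells=frame_cells,
        frame_side=frame_side,
        members=members,
        window_halfwidth=window_halfwidth,
    )


def backproject_frame(
    images: np.ndarray, euler_deg: np.ndarray, volume_size: int | None = None
) -> np.ndarray:
    """Simple real-space back-projection of a snapshot subset into a 3D volume.

    Each image is smeared along its projection lines (nearest-voxel resampling
    of the z-replicated image under the inverse orientation), accumulated over
    images, and normalized by per-voxel hit counts.  Intended for toy phantoms,
    not quantitative reconstruction.
    """
    from scipy.ndimage import affine_transform
    from scipy.spatial.transform import Rotation

    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
        euler_deg = np.atleast_2d(euler_deg)
    if len(images) == 0:
        raise ValueError("cannot back-project an empty snapshot subset")
    size = volume_size or images.shape[1]
    if size != images.shape[1]:
        raise ValueError("volume size must match image size")
    acc = np.zeros((size, size, size))
    hits = np.zeros_like(acc)
    c = (size - 1) / 2.0
    center = np.array([c, c, c])
    ones = np.ones((size, size, size))
    for img, eul in zip(images, euler_deg):
        rep = np.broadcast_to(img, (size, size, size))
        R = Rotation.from_euler("ZYZ", eul, degrees=True).as_matrix()
        Rt = R.T  # inverse rotation: adjoint of the projection resampling
        if np.allclose(R, np.eye(3), atol=1e-14):
            acc += rep
            hits += ones
        else:
            acc += affine_transform(
                rep, Rt, offset=center - Rt @ center, order=0, mode="constant"
            )
            hits += affine_transform(
                ones, Rt, offset=center - Rt @ center, order=0, mode="constant"
            )
    out = np.zeros_like(acc)
    nz = hits > 0
    out[nz] = acc[nz] / hits[nz]
    return out
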