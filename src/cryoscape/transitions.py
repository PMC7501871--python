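"""Interlandscape transition maps and master-equation kinetics of ligand binding.

The dynamics of transitions between conformational states, with and without a
bound ligand, follow coupled master equations

    dp_c+/dt = sum_c' W++_cc' p_c'+ + sum_c' W-+_cc' p_c'-
               - p_c+ sum_c' (W++_c'c + W+-_c'c)

(and symmetrically for p_c-).  Ligand association is modeled as connecting
iso-conformational states only (the interlandscape hop is too fast for
conformational adjustment), with a mass-action rate ``k_c L`` whose
conformation dependence follows an Arrhenius form with activation energy
``E_c+ - E_c0+`` read off the +ligand landscape.  Since
``exp(-(E_c+ - E_c0+)/kT) = P_c+ / P_c0+``, the initial flux into the bound
state c is proportional to ``P_c+ P_c-``: the transition-probability map is
the normalized product of the two conformational spectra, and ligand
association concentrates at the cells ("hotspots") where that product peaks.

Intra-landscape rates are not constrained by the data; Metropolis rates
``A min(1, exp(-(E_j - E_i)/kT))`` between nearest-neighbor cells are used so
the stationary state of each landscape is exactly the Boltzmann density the
landscape asserts.  Dissociation rates default to zero, matching the
initial-time analysis in which no receptors are bound yet.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .landscape import EnergyLandscape, GridSpec, OccupancyGrid

__all__ = [
    "ConformationalSpectrum",
    "TransitionMap",
    "RateModel",
    "transition_map",
    "find_hotspots",
    "build_rate_model",
    "integrate_master_equation",
    "initial_flux",
    "stationary_distribution",
]


@dataclasses.dataclass
class ConformationalSpectrum:
    """Per-cell occupancy probability P_c = n_c / N for one condition."""

    condition: str
    grid: GridSpec
    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.grid.shape:
            raise ValueError("spectrum shape does not match grid")
        if (self.p < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("spectrum must sum to 1 within 1e-12")

    @classmethod
    def from_occupancy(cls, occ: OccupancyGrid) -> "ConformationalSpectrum":
        return cls(condition=occ.condition, grid=occ.grid, p=occ.probabilities)


@dataclasses.dataclass
class TransitionMap:
    """Normalized interlandscape transition probability per conformational cell."""

    grid: GridSpec
    t: np.ndarray  # sums to 1; zero where either condition is unoccupied

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if (self.t < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        if abs(self.t.sum() - 1.0) > 1e-12:
            raise ValueError("transition map must sum to 1 within 1e-12")

    @property
    def argmax_cell(self) -> tuple[int, int]:
        i, j = np.unravel_index(np.argmax(self.t), self.t.shape)
        return (int(i), int(j))


def transition_map(occ_minus: OccupancyGrid, occ_plus: OccupancyGrid) -> TransitionMap:
    """T_c = P_c+ P_c- / sum_c P_c+ P_c- from the two occupancy grids."""
    if occ_minus.grid != occ_plus.grid:
        raise ValueError("occupancy grids must share the same grid spec")
    prod = occ_minus.probabilities * occ_plus.probabilities
    z = prod.sum()
    if z == 0:
        raise ValueError(
            "no iso-conformational overlap: the two conditions occupy disjoint cells"
        )
    return TransitionMap(grid=occ_minus.grid, t=prod / z)


def find_hotspots(tmap: TransitionMap, rel_threshold: float = 0.5) -> list[tuple[int, int]]:
    """Local maxima of the transition map, ordered by probability.

    A cell is a local maximum if its value is >= all of its 8-neighbors and
    ``>= rel_threshold * max(T)``.  Ties are broken by row-major cell index.
    """
    t = tmap.t
    n1, n2 = t.shape
    tmax = t.max()
    hits = []
    for i in range(n1):
        for j in range(n2):
            v = t[i, j]
            if v <= 0 or v < rel_threshold * tmax:
                continue
            neigh = t[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if v >= neigh.max():
                hits.append((i, j))
    hits.sort(key=lambda c: (-t[c], c[0] * n2 + c[1]))
    return hits


@dataclasses.dataclass
class RateModel:
    """Sparse rate matrices of the dual-landscape master equation.

    States are grid cells in row-major order; ``w_mm``/``w_pp`` hold
    intra-landscape nearest-neighbor rates (entry [j, i] is the rate i -> j),
    ``w_assoc`` the per-cell iso-conformational association rates (diagonal in
    conformation space) and ``w_dissoc`` the optional dissociation rates.
    """

    grid: GridSpec
    w_mm: sp.csr_matrix
    w_pp: sp.csr_matrix
    w_assoc: np.ndarray  # (ncells,) -> + from -
    w_dissoc: np.ndarray  # (ncells,) -> - from +
    ligand_conc: float
    prefactor: float
    kT: float

    @property
    def n_cells(self) -> int:
        return self.grid.n1 * self.grid.n2

    def generator(self) -> sp.csr_matrix:
        """Full (2 ncells x 2 ncells) generator Q with dp/dt = Q p.

        State ordering: the first ``n_cells`` entries are the -ligand cells,
        the rest the +ligand cells.  Columns of Q sum to zero.
        """
        n = self.n_cells
        a = sp.diags(self.w_assoc)
        d = sp.diags(self.w_dissoc)
        q = sp.bmat([[self.w_mm, d], [a, self.w_pp]], format="lil")
        q = q.tocsr()
        q = q - sp.diags(np.asarray(q.sum(axis=0)).ravel())
        return q.tocsr()


def _neighbor_rates(energies: np.ndarray, mask: np.ndarray, A: float, kT: float) -> sp.csr_matrix:
    """Metropolis rates A min(1, exp(-dE/kT)) between 4-adjacent occupied cells."""
    n1, n2 = energies.shape
    n = n1 * n2
    rows, cols, vals = [], [], []
    for i in range(n1):
        for j in range(n2):
            if mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if not (0 <= ii < n1 and 0 <= jj < n2) or mask[ii, jj]:
                    continue
                rate = A * min(1.0, float(np.exp(-(energies[ii, jj] - energies[i, j]) / kT)))
                rows.append(ii * n2 + jj)  # destination
                cols.append(i * n2 + j)  # source
                vals.append(rate)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_rate_model(
    e_minus: EnergyLandscape,
    e_plus: EnergyLandscape,
    ligand_conc: float = 1.0,
    prefactor: float = 1.0,
    kT: float | None = None,
    dissociation: str = "none",
) -> RateModel:
    """Assemble the dual-landscape rate model.

    Association rates are ``L A exp(-(E_c+ - E_c0+)/kT)`` on cells occupied in
    both landscapes and zero elsewhere (masked-cell adjacency carries zero
    rate).  ``dissociation="none"`` (default) matches the initial-time
    analysis; ``"detailed_balance"`` adds the reverse rates that balance the
    association flux against the two equilibrium spectra (an optional,
    admittedly incomplete description of the unbinding pathway).
    """
    if e_minus.grid != e_plus.grid:
        raise ValueError("landscapes must share the same grid spec")
    if ligand_conc < 0 or prefactor <= 0:
        raise ValueError("require ligand concentration >= 0 and prefactor > 0")
    if kT is None:
        kT = e_minus.kT
    grid = e_minus.grid
    em = np.where(e_minus.mask, np.inf, e_minus.energies)
    ep = np.where(e_plus.mask, np.inf, e_plus.energies)
    w_mm = _neighbor_rates(em, e_minus.mask, prefactor, kT)
    w_pp = _neighbor_rates(ep, e_plus.mask, prefactor, kT)
    both = ~(e_minus.mask | e_plus.mask)
    ep0 = np.nanmin(e_plus.energies)
    w_assoc = np.zeros(grid.n1 * grid.n2)
    w_assoc[both.ravel()] = (
        ligand_conc * prefactor * np.exp(-(ep[both] - ep0) / kT)
    )
    w_dissoc = np.zeros_like(w_assoc)
    if dissociation == "detailed_balance":
        pm = np.exp(-em[both] / kT)
        pp = np.exp(-ep[both] / kT)
        w_dissoc[both.ravel()] = w_assoc[both.ravel()] * (pm / pm.sum()) / (pp / pp.sum())
    elif dissociation != "none":
        raise ValueError("dissociation must be 'none' or 'detailed_balance'")
    return RateModel(
        grid=grid,
        w_mm=w_mm,
        w_pp=w_pp,
        w_assoc=w_assoc,
        w_dissoc=w_dissoc,
        ligand_conc=ligand_conc,
        prefactor=prefactor,
        kT=kT,
    )


def integrate_master_equation(
    model: RateModel, p0: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """Propagate the coupled master equation over ``t_grid``.

    ``p0`` is a probability vector over (cell, condition) states, ordered as
    all -ligand cells then all +ligand cells (length ``2 * n_cells``).  The
    system is linear and autonomous, so the solution is the matrix exponential
    ``p(t) = exp(t Q) p0``, evaluated by stepping a dense propagator between
    the requested times (the state space here is small enough that the dense
    exponential is both fast and free of estimation heuristics).  Total
    probability is conserved to 1e-8 along the trajectory (checked).
    """
    from scipy.linalg import expm

    p0 = np.asarray(p0, dtype=float)
    n = 2 * model.n_cells
    if p0.shape != (n,):
        raise ValueError(f"p0 must have length {n}")
    if (p0 < 0).any() or abs(p0.sum() - 1.0) > 1e-10:
        raise ValueError("p0 must be a probability vector")
    t_grid = np.asarray(t_grid, dtype=float)
    if (np.diff(t_grid) < 0).any() or (t_grid < 0).any():
        raise ValueError("t grid must be nonnegative and nondecreasing")
    if n > 4000:
        raise ValueError("state space too large for the dense propagator")
    q = model.generator().toarray()
    traj = np.empty((len(t_grid), n))
    props: dict[float, np.ndarray] = {}
    p = p0
    t_prev = 0.0
    for k, t in enumerate(t_grid):
        dt = t - t_prev
        if dt > 0:
            if dt not in props:
                props[dt] = expm(q * dt)
            p = props[dt] @ p
        traj[k] = p
        t_prev = t
    drift = np.abs(traj.sum(axis=1) - 1.0)
    if (drift > 1e-8).any():
        raise RuntimeError(
            f"probability conservation violated (max drift {drift.max():.2e})"
        )
    if (traj < -1e-8).any():
        raise RuntimeError("negative probabilities beyond tolerance during integration")
    return traj


def initial_flux(model: RateModel, p_minus_eq: np.ndarray) -> np.ndarray:
    """Initial gain of each bound state: dp_c+/dt at t=0 = W-+(c) p_c,eq-.

    ``p_minus_eq`` may be a grid-shaped or flat spectrum.  After normalization
    this equals the transition map exactly.
    """
    p = np.asarray(p_minus_eq, dtype=float).ravel()
    if p.shape != model.w_assoc.shape:
        raise ValueError("p_minus_eq does not match the model grid")
    return model.w_assoc * p


def stationary_distribution(w: sp.csr_matrix) -> np.ndarray:
    """Stationary density of a single-landscape rate matrix (null-space of Q).

    Restricted to the states that carry any rate; returns a probability vector
    over all cells (zeros on isolated/masked cells).
    """
    n = w.shape[0]
    active = np.asarray((w.sum(axis=0) + w.sum(axis=1).T)).ravel() > 0
    idx = np.flatnonzero(active)
    q = w[np.ix_(idx, idx)].toarray()
    q -= np.diag(q.sum(axis=0))
    evals, evecs = np.linalg.eig(q)
    k = int(np.argmin(np.abs(evals)))
    v = np.real(evecs[:, k])
    v = np.abs(v)
    out = np.zeros(n)
    out[idx] = v / v.sum()
    return out
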