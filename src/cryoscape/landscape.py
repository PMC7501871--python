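"""Occupancy grids and inverse-Boltzmann free-energy landscapes.

In equilibrium a conformational state c is occupied with statistical weight
``exp(-E_c / kT)``, so the number of sightings ``n_c`` of each conformational
bin determines its relative free energy:

    E_c = -kT ln(n_c / n_max)

with ``n_max`` the count of the most populated cell, making the minimum energy
exactly 0.  Unobserved cells (``n_c = 0``) carry no energy value and are
masked.  The highest observable energy in an ensemble of N snapshots is the
state sighted once, at

    dG_max = kT ln N.

This conversion assumes the variance of the coarse-graining entropy across
cells is negligible compared to the variance of the energies; the assumption
is recorded in each landscape's metadata.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "GridSpec",
    "OccupancyGrid",
    "EnergyLandscape",
    "KT_ROOM_KCAL",
    "kt_kcal_per_mol",
    "occupancy_grid",
    "energy_from_occupancy",
    "delta_g_max",
    "region_fraction",
    "ligand_contamination_fraction",
    "poisson_energy_error",
    "plot_landscape",
]

#: Gas constant in kcal / (mol K)
R_KCAL = 1.9872042586e-3

#: Default kT at 298.15 K in kcal/mol (rounded convention used throughout)
KT_ROOM_KCAL = 0.593


def kt_kcal_per_mol(temperature_K: float = 298.15) -> float:
    """kT in kcal/mol at the given absolute temperature."""
    if temperature_K <= 0:
        raise ValueError("temperature must be > 0 K")
    return R_KCAL * temperature_K


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Regular n1 x n2 cell grid over the unit square of (cc1, cc2)."""

    n1: int = 50
    n2: int = 50

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("grid must have at least 2 cells per axis")

    @property
    def shape(self):
        return (self.n1, self.n2)

    @property
    def edges1(self):
        return np.linspace(0.0, 1.0, self.n1 + 1)

    @property
    def edges2(self):
        return np.linspace(0.0, 1.0, self.n2 + 1)

    @property
    def centers1(self):
        e = self.edges1
        return 0.5 * (e[:-1] + e[1:])

    @property
    def centers2(self):
        e = self.edges2
        return 0.5 * (e[:-1] + e[1:])

    def cell_center(self, cell: tuple[int, int]) -> tuple[float, float]:
        return (float(self.centers1[cell[0]]), float(self.centers2[cell[1]]))


@dataclasses.dataclass
class OccupancyGrid:
    """Sighting counts per conformational cell for one ligand condition."""

    condition: str
    grid: GridSpec
    counts: np.ndarray  # (n1, n2) nonnegative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid spec")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Conformational spectrum P_c = n_c / N."""
        return self.counts / self.total


@dataclasses.dataclass
class EnergyLandscape:
    """Relative free energies per occupied cell, in units of kT (or as configured)."""

    condition: str
    grid: GridSpec
    energies: np.ndarray  # (n1, n2); NaN on unobserved cells
    mask: np.ndarray  # True where unobserved
    kT: float
    n_total: int
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def delta_g_max(self) -> float:
        return delta_g_max(self.n_total, self.kT)

    @property
    def argmin_cell(self) -> tuple[int, int]:
        e = np.where(self.mask, np.inf, self.energies)
        i, j = np.unravel_index(np.argmin(e), e.shape)
        return (int(i), int(j))


def occupancy_grid(
    cc: np.ndarray,
    condition: str = "minus",
    grid: GridSpec | None = None,
    condition_labels: np.ndarray | None = None,
) -> OccupancyGrid:
    """Histogram (cc1, cc2) coordinates into grid cells.

    Cells are half-open ``[lo, hi)`` with the top edge closed (a point exactly
    on an interior edge goes to the higher cell).  If ``condition_labels`` is
    given, only rows matching ``condition`` are counted; rows with undefined
    (NaN) coordinates are dropped.
    """
    grid = grid or GridSpec()
    cc = np.asarray(cc, dtype=float)
    if condition_labels is not None:
        cc = cc[np.asarray(condition_labels) == condition]
    cc = cc[~np.isnan(cc).any(axis=1)]
    if ((cc < 0) | (cc > 1)).any():
        raise ValueError("coordinates outside [0, 1]")
    counts, _, _ = np.histogram2d(cc[:, 0], cc[:, 1], bins=[grid.edges1, grid.edges2])
    return OccupancyGrid(condition=condition, grid=grid, counts=counts.astype(np.int64))


def energy_from_occupancy(occ: OccupancyGrid, kT: float = 1.0) -> EnergyLandscape:
    """Inverse-Boltzmann conversion E_c = -kT ln(n_c / n_max) on occupied cells."""
    if occ.total == 0:
        raise ValueError("occupancy grid is empty; cannot build a landscape")
    counts = occ.counts
    mask = counts == 0
    n_max = counts.max()
    energies = np.full(counts.shape, np.nan)
    occupied = ~mask
    energies[occupied] = -kT * np.log(counts[occupied] / n_max)
    return EnergyLandscape(
        condition=occ.condition,
        grid=occ.grid,
        energies=energies,
        mask=mask,
        kT=kT,
        n_total=occ.total,
        metadata={
            "assumption": (
                "coarse-graining degeneracy variance assumed negligible "
                "relative to energy variance"
            ),
            "reference": "most-populated cell (min energy 0)",
        },
    )


def delta_g_max(n: int, kT: float = 1.0) -> float:
    """Observability limit kT ln N: the energy of a state sighted once among N."""
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    return float(kT * np.log(n))


def region_fraction(occ: OccupancyGrid, region) -> float:
    """Fraction of the ensemble sighted inside a set of cells.

    ``region`` is an iterable of (i, j) cell indices or a boolean mask of the
    grid shape.
    """
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.shape != occ.grid.shape:
            raise ValueError("region mask shape does not match grid")
        sel = region
    else:
        region = list(region)
        if not region:
            raise ValueError("region must be nonempty")
        sel = np.zeros(occ.grid.shape, dtype=bool)
        for i, j in region:
            if not (0 <= i < occ.grid.n1 and 0 <= j < occ.grid.n2):
                raise ValueError(f"cell {(i, j)} outside grid {occ.grid.shape}")
            sel[i, j] = True
    return float(occ.counts[sel].sum() / occ.total)


def ligand_contamination_fraction(
    contaminant_molar: float,
    receptor_molar: float,
    region_occupancy_fraction: float,
) -> float:
    """Contaminating-ligand molecules per receptor in an occupancy region.

    Worked example: with 2e-10 M residual free ligand, 2e-6 M receptor, and a
    functionally relevant region holding 2% of the ensemble, the receptor
    concentration in that region is 4e-8 M, so the ratio is
    2e-10 / 4e-8 = 0.005 (0.5%) -- assuming every contaminant ion is bound.
    """
    if contaminant_molar < 0 or receptor_molar <= 0:
        raise ValueError("concentrations must be positive")
    if not (0 < region_occupancy_fraction <= 1):
        raise ValueError("region occupancy fraction must be in (0, 1]")
    return contaminant_molar / (receptor_molar * region_occupancy_fraction)


def poisson_energy_error(occ: OccupancyGrid, kT: float = 1.0) -> np.ndarray:
    """Counting-statistics energy uncertainty kT/sqrt(n_c) per occupied cell.

    A first-order Poisson propagation of the count fluctuation through
    -kT ln(n_c); NaN on unobserved cells.  A rough diagnostic only - it
    ignores the shared reference-cell fluctuation.
    """
    err = np.full(occ.counts.shape, np.nan)
    occupied = occ.counts > 0
    err[occupied] = kT / np.sqrt(occ.counts[occupied])
    return err


def plot_landscape(landscape: EnergyLandscape, ax=None, levels: int = 12,
                   title: str | None = None):
    """Filled contour rendering of a landscape (masked cells blank).

    Returns the matplotlib axes; import is deferred so headless use of the
    numerical API never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    g1, g2 = np.meshgrid(landscape.grid.centers1, landscape.grid.centers2,
                         indexing="ij")
    z = np.ma.masked_invalid(landscape.energies)
    cs = ax.contourf(g1, g2, z, levels=levels, cmap="viridis")
    ax.figure.colorbar(cs, ax=ax, label=f"free energy (kT = {landscape.kT:g})")
    ax.set_xlabel("CC1")
    ax.set_ylabel("CC2")
    ax.set_title(title or f"{landscape.condition} ligand landscape")
    return ax
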