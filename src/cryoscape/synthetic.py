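"""Ground-truthed synthetic snapshot ensembles with two conformational degrees of freedom.

This module builds the validation system for the landscape pipeline: a voxel
phantom whose shape is controlled by two conformational coordinates
``(cc1, cc2)`` on the unit square, a pair of analytic free-energy surfaces
(one per ligand condition) from which conformations are Boltzmann-sampled,
and a projection renderer that turns sampled states into aligned, centered
2D snapshots over many viewing directions, with or without additive Gaussian
noise.

Conventions
-----------
* The conformational domain is fixed to ``[0, 1]^2``.
* Energies are in units of kT unless stated otherwise.
* Orientations follow the RELION ZYZ intrinsic Euler convention
  ``(rot, tilt, psi)`` in degrees; the projection integrates the rotated
  volume along its z axis, so the viewing direction in the volume frame is
  ``(sin(tilt) cos(rot), sin(tilt) sin(rot), cos(tilt))`` and ``psi`` is an
  in-plane rotation that does not move the viewing direction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

__all__ = [
    "AnalyticLandscapePair",
    "Phantom",
    "GroundTruth",
    "define_dual_landscape",
    "sample_conformations",
    "fibonacci_directions",
    "euler_from_direction",
    "direction_from_euler",
    "render_snapshots",
    "sigma_for_snr",
    "make_default_phantom",
    "simulate_ensemble",
]


# ---------------------------------------------------------------------------
# Analytic dual landscapes
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AnalyticLandscapePair:
    """Two scalar free-energy surfaces over [0,1]^2, one per ligand condition.

    ``energy_minus`` / ``energy_plus`` are vectorized callables of
    ``(cc1, cc2)`` returning energies in kT with minimum value 0 at
    ``minimum_minus`` / ``minimum_plus`` respectively.
    """

    name: str
    energy_minus: Callable[[np.ndarray, np.ndarray], np.ndarray]
    energy_plus: Callable[[np.ndarray, np.ndarray], np.ndarray]
    minimum_minus: tuple[float, float]
    minimum_plus: tuple[float, float]
    params: dict = dataclasses.field(default_factory=dict)

    def energy(self, condition: str):
        if condition == "minus":
            return self.energy_minus
        if condition == "plus":
            return self.energy_plus
        raise ValueError(f"condition must be 'minus' or 'plus', got {condition!r}")


def _bowl(center: tuple[float, float], curvature: float):
    cx, cy = center

    def energy(cc1, cc2):
        cc1 = np.asarray(cc1, dtype=float)
        cc2 = np.asarray(cc2, dtype=float)
        return curvature * ((cc1 - cx) ** 2 + (cc2 - cy) ** 2)

    return energy


def _double_well_1d(m1, m2, w1, w2, sigma, conf_curv, conf_center):
    """Separable surface: two-well profile along cc1 + harmonic confinement in cc2.

    The cc1 profile is the negative log of a two-Gaussian mixture (well depths
    set by the weights w1, w2); cc2 is harmonically confined about
    ``conf_center``.  The surface is shifted so its exact global minimum
    (located numerically along cc1) is 0.
    """
    from scipy.optimize import minimize_scalar

    def profile(cc1):
        mix = w1 * np.exp(-((cc1 - m1) ** 2) / (2 * sigma**2)) + w2 * np.exp(
            -((cc1 - m2) ** 2) / (2 * sigma**2)
        )
        return -np.log(mix)

    deep = m1 if w1 >= w2 else m2
    opt = minimize_scalar(
        profile, bounds=(max(0.0, deep - sigma), min(1.0, deep + sigma)), method="bounded"
    )
    x_min, e_min = float(opt.x), float(opt.fun)

    def energy(cc1, cc2):
        cc1 = np.asarray(cc1, dtype=float)
        cc2 = np.asarray(cc2, dtype=float)
        return profile(cc1) - e_min + conf_curv * (cc2 - conf_center) ** 2

    return energy, (x_min, conf_center)


def define_dual_landscape(spec: str = "shifted_double_well", **params) -> AnalyticLandscapePair:
    """Build a named analytic landscape pair.

    Presets
    -------
    ``"bowl"``
        Identical quadratic bowls for both conditions.
        Parameters: ``center=(0.5, 0.5)``, ``curvature=8.0`` (kT per unit^2).
    ``"shifted_bowls"``
        Quadratic bowls with different minima per condition.
        Parameters: ``center_minus``, ``center_plus``, ``curvature``.
    ``"shifted_double_well"``
        Separable dual surfaces exercising both degrees of freedom: a two-well
        profile along cc1 (negative log of a two-Gaussian mixture) whose
        deeper well swaps between conditions, plus a harmonic confinement
        along cc2 whose center shifts with condition.  The global minima
        (START and FINISH) therefore differ in both coordinates, and the
        populated barrier region between the wells provides interlandscape
        overlap where transitions concentrate.
        Parameters: ``wells=(0.30, 0.70)``, ``well_sigma=0.10``, ``bias=3.0``
        (weight ratio of deep to shallow well), ``conf_curvature=10.0`` (kT
        per unit^2 along cc2), ``conf_centers=(0.40, 0.60)`` (minus, plus).

    Raises
    ------
    ValueError
        If the requested surfaces are non-finite anywhere on a 101x101
        evaluation grid (the offending location is reported).
    """
    if spec == "bowl":
        center = tuple(params.pop("center", (0.5, 0.5)))
        curvature = float(params.pop("curvature", 8.0))
        pair = AnalyticLandscapePair(
            name=spec,
            energy_minus=_bowl(center, curvature),
            energy_plus=_bowl(center, curvature),
            minimum_minus=center,
            minimum_plus=center,
            params={"center": center, "curvature": curvature},
        )
    elif spec == "shifted_bowls":
        cm = tuple(params.pop("center_minus", (0.3, 0.4)))
        cp = tuple(params.pop("center_plus", (0.7, 0.6)))
        curvature = float(params.pop("curvature", 10.0))
        pair = AnalyticLandscapePair(
            name=spec,
            energy_minus=_bowl(cm, curvature),
            energy_plus=_bowl(cp, curvature),
            minimum_minus=cm,
            minimum_plus=cp,
            params={"center_minus": cm, "center_plus": cp, "curvature": curvature},
        )
    elif spec == "shifted_double_well":
        wells = tuple(params.pop("wells", (0.30, 0.70)))
        well_sigma = float(params.pop("well_sigma", 0.10))
        bias = float(params.pop("bias", 3.0))
        conf_curv = float(params.pop("conf_curvature", 10.0))
        conf_centers = tuple(params.pop("conf_centers", (0.40, 0.60)))
        e_minus, min_minus = _double_well_1d(
            wells[0], wells[1], bias, 1.0, well_sigma, conf_curv, conf_centers[0]
        )
        e_plus, min_plus = _double_well_1d(
            wells[0], wells[1], 1.0, bias, well_sigma, conf_curv, conf_centers[1]
        )
        pair = AnalyticLandscapePair(
            name=spec,
            energy_minus=e_minus,
            energy_plus=e_plus,
            minimum_minus=min_minus,
            minimum_plus=min_plus,
            params={
                "wells": wells,
                "well_sigma": well_sigma,
                "bias": bias,
                "conf_curvature": conf_curv,
                "conf_centers": conf_centers,
            },
        )
    else:
        raise ValueError(f"unknown landscape preset {spec!r}")
    if params:
        raise TypeError(f"unexpected parameters for preset {spec!r}: {sorted(params)}")

    xs = np.linspace(0.0, 1.0, 101)
    g1, g2 = np.meshgrid(xs, xs, indexing="ij")
    for cond in ("minus", "plus"):
        vals = np.asarray(pair.energy(cond)(g1, g2), dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"landscape {spec!r} ({cond}) is non-finite at "
                f"(cc1={xs[i]:.2f}, cc2={xs[j]:.2f})"
            )
    return pair


# ---------------------------------------------------------------------------
# Boltzmann sampling of conformations
# ---------------------------------------------------------------------------

def sample_conformations(
    pair: AnalyticLandscapePair,
    condition: str,
    n: int,
    kT: float = 1.0,
    seed: int | np.random.Generator = 0,
    method: str = "grid",
    grid_points: int = 200,
) -> np.ndarray:
    """Draw ``n`` conformations from density proportional to exp(-E/kT) on [0,1]^2.

    ``method="grid"`` (default) evaluates the Boltzmann weight at the centers
    of a ``grid_points`` x ``grid_points`` lattice, draws cells multinomially
    and jitters uniformly within each cell.  ``method="rejection"`` performs
    plain rejection sampling against the global minimum (0 kT) envelope and
    aborts if the acceptance rate falls below 1e-4.

    Returns an ``(n, 2)`` array of (cc1, cc2); reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    energy = pair.energy(condition)

    if method == "grid":
        edges = np.linspace(0.0, 1.0, grid_points + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        g1, g2 = np.meshgrid(centers, centers, indexing="ij")
        w = np.exp(-np.asarray(energy(g1, g2), dtype=float) / kT).ravel()
        p = w / w.sum()
        counts = rng.multinomial(n, p)
        idx = np.repeat(np.arange(p.size), counts)
        i1, i2 = np.unravel_index(idx, (grid_points, grid_points))
        width = 1.0 / grid_points
        cc1 = edges[i1] + rng.random(n) * width
        cc2 = edges[i2] + rng.random(n) * width
        out = np.column_stack([cc1, cc2])
        # multinomial repeats are ordered by cell; shuffle for exchangeability
        rng.shuffle(out, axis=0)
        return out

    if method == "rejection":
        samples = []
        n_drawn = 0
        n_kept = 0
        while n_kept < n:
            m = max(4 * (n - n_kept), 1000)
            cand = rng.random((m, 2))
            e = np.asarray(energy(cand[:, 0], cand[:, 1]), dtype=float)
            keep = rng.random(m) < np.exp(-e / kT)
            samples.append(cand[keep])
            n_drawn += m
            n_kept += int(keep.sum())
            if n_drawn >= 10_000 and n_kept / n_drawn < 1e-4:
                raise RuntimeError(
                    "rejection sampling acceptance rate below 1e-4; "
                    "use method='grid' (grid-multinomial) instead"
                )
        return np.concatenate(samples)[:n]

    raise ValueError(f"unknown sampling method {method!r}")


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Phantom:
    """Cubic voxel phantom with two continuous deformation generators.

    The density is a sum of isotropic Gaussian blobs.  ``cc1`` translates the
    mobile blob along ``blob1_shift`` voxels; ``cc2`` scales the width of the
    breathing blob from ``blob2_sigma`` to ``blob2_sigma * (1 + blob2_grow)``.
    ``density(0, 0)`` equals ``base_map`` exactly.
    """

    size: int = 32
    body_sigma: float = 6.0
    body_amp: float = 1.0
    blob1_center: tuple[float, float, float] = (-7.0, -7.0, 5.0)
    blob1_shift: tuple[float, float, float] = (4.5, 4.5, -3.2)
    blob1_sigma: float = 3.0
    blob1_amp: float = 2.0
    blob2_center: tuple[float, float, float] = (7.0, 7.0, -7.0)
    blob2_sigma: float = 2.2
    blob2_grow: float = 0.5
    blob2_amp: float = 1.8

    def _grid(self):
        c = (self.size - 1) / 2.0
        ax = np.arange(self.size, dtype=float) - c
        return np.meshgrid(ax, ax, ax, indexing="ij")

    def density(self, cc1: float, cc2: float) -> np.ndarray:
        """Voxel density map at conformation (cc1, cc2); nonnegative."""
        x, y, z = self._grid()

        def blob(center, sigma, amp):
            d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
            return amp * np.exp(-d2 / (2.0 * sigma**2))

        c1 = tuple(
            c0 + cc1 * dc for c0, dc in zip(self.blob1_center, self.blob1_shift)
        )
        s2 = self.blob2_sigma * (1.0 + self.blob2_grow * cc2)
        vol = (
            blob((0.0, 0.0, 0.0), self.body_sigma, self.body_amp)
            + blob(c1, self.blob1_sigma, self.blob1_amp)
            + blob(self.blob2_center, s2, self.blob2_amp)
        )
        return vol

    @property
    def base_map(self) -> np.ndarray:
        return self.density(0.0, 0.0)


def make_default_phantom(size: int = 32) -> Phantom:
    """The default two-degree-of-freedom validation phantom."""
    return Phantom(size=size)


# ---------------------------------------------------------------------------
# Orientations
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def euler_from_direction(direction: np.ndarray, psi: float = 0.0) -> np.ndarray:
    """ZYZ Euler angles (rot, tilt, psi) in degrees whose viewing direction is given."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tilt = np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0)))
    rot = np.degrees(np.arctan2(d[1], d[0]))
    return np.array([rot, tilt, psi])


def direction_from_euler(euler_deg: np.ndarray) -> np.ndarray:
    """Unit viewing direction(s) from ZYZ Euler angles in degrees; psi is ignored."""
    e = np.atleast_2d(np.asarray(euler_deg, dtype=float))
    rot = np.radians(e[:, 0])
    tilt = np.radians(e[:, 1])
    d = np.column_stack(
        [np.sin(tilt) * np.cos(rot), np.sin(tilt) * np.sin(rot), np.cos(tilt)]
    )
    return d[0] if np.asarray(euler_deg).ndim == 1 else d


def _rotation_matrix(euler_deg) -> np.ndarray:
    return Rotation.from_euler("ZYZ", euler_deg, degrees=True).as_matrix()


# ---------------------------------------------------------------------------
# Ground truth and rendering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroundTruth:
    """Per-snapshot generating state: condition, (cc1, cc2), Euler orientation."""

    condition: np.ndarray  # (n,) str array of 'minus'/'plus'
    cc: np.ndarray  # (n, 2) in [0,1]
    euler_deg: np.ndarray  # (n, 3) ZYZ degrees
    seed: int | None = None

    def __post_init__(self):
        self.condition = np.asarray(self.condition)
        self.cc = np.asarray(self.cc, dtype=float)
        self.euler_deg = np.asarray(self.euler_deg, dtype=float)
        n = len(self.condition)
        if self.cc.shape != (n, 2) or self.euler_deg.shape != (n, 3):
            raise ValueError("inconsistent ground-truth record lengths")
        if ((self.cc < 0) | (self.cc > 1)).any():
            raise ValueError("cc values must lie in [0, 1]")

    def __len__(self):
        return len(self.condition)


def project_volume(volume: np.ndarray, euler_deg, image_size: int | None = None) -> np.ndarray:
    """Line-integral projection of ``volume`` along the viewing direction.

    The volume is resampled on the rotated frame (trilinear interpolation) and
    summed along z.  An identity orientation reproduces ``volume.sum(axis=0)``
    exactly.  ``image_size`` >= volume side pads the image symmetrically.
    """
    n = volume.shape[0]
    if volume.shape != (n, n, n):
        raise ValueError("volume must be cubic")
    if image_size is None:
        image_size = n
    if image_size < n:
        raise ValueError(
            f"image size {image_size} smaller than phantom silhouette; need >= {n}"
        )
    R = _rotation_matrix(euler_deg)
    if np.allclose(R, np.eye(3), atol=1e-14):
        img = volume.sum(axis=0)
    else:
        c = (n - 1) / 2.0
        center = np.array([c, c, c])
        rotated = affine_transform(
            volume, R, offset=center - R @ center, order=1, mode="constant", cval=0.0
        )
        img = rotated.sum(axis=0)
    if image_size > n:
        pad0 = (image_size - n) // 2
        pad1 = image_size - n - pad0
        img = np.pad(img, ((pad0, pad1), (pad0, pad1)))
    return img


def render_snapshots(
    phantom: Phantom,
    states: GroundTruth,
    image_size: int | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
):
    """Render one projection image per ground-truth record.

    Each image is the line-integral projection of ``phantom.density(cc1, cc2)``
    along the record's orientation plus i.i.d. Gaussian noise of standard
    deviation ``noise_sigma`` (0 gives exact projections).  Deterministic
    given ``seed``.  Returns an :class:`cryoscape.io_em.SnapshotStack`.
    """
    from .io_em import SnapshotStack  # deferred: io_em imports nothing from here

    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    size = image_size if image_size is not None else phantom.size
    n = len(states)
    images = np.empty((n, size, size), dtype=np.float32)
    for i in range(n):
        vol = phantom.density(states.cc[i, 0], states.cc[i, 1])
        images[i] = project_volume(vol, states.euler_deg[i], size)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        images += rng.normal(0.0, noise_sigma, images.shape).astype(np.float32)
    return SnapshotStack(
        images=images,
        pixel_size=pixel_size,
        euler_deg=states.euler_deg.copy(),
        condition=states.condition.copy(),
        ground_truth_cc=states.cc.copy(),
    )


def sigma_for_snr(images: np.ndarray, snr: float) -> float:
    """Noise sigma giving the requested SNR = mean per-image pixel variance / sigma^2."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    signal_power = float(np.mean(np.var(images, axis=(1, 2))))
    return float(np.sqrt(signal_power / snr))


# ---------------------------------------------------------------------------
# Full ensemble generation (the study conditions of the validation system)
# ---------------------------------------------------------------------------

def simulate_ensemble(
    landscape: AnalyticLandscapePair | None = None,
    phantom: Phantom | None = None,
    n_directions: int = 100,
    snapshots_per_direction: int = 75,
    snr: float | None = None,
    kT: float = 1.0,
    image_size: int | None = None,
    seed: int = 0,
):
    """Generate the default two-degree-of-freedom validation ensemble.

    For each condition, ``n_directions * snapshots_per_direction`` conformations
    are Boltzmann-sampled from the condition's analytic surface and assigned
    round-robin to the Fibonacci-lattice viewing directions, so every
    projection-direction bin holds ``2 * snapshots_per_direction`` snapshots
    when conditions are pooled.  ``snr=None`` renders noise-free images;
    otherwise additive Gaussian noise at the requested SNR is applied, with the
    sigma calibrated on the noise-free images.

    Returns ``(stack, ground_truth)``.
    """
    if landscape is None:
        landscape = define_dual_landscape("shifted_double_well")
    if phantom is None:
        phantom = make_default_phantom()
    rng = np.random.default_rng(seed)
    n_per_cond = n_directions * snapshots_per_direction
    dirs = fibonacci_directions(n_directions)
    eulers = np.array([euler_from_direction(d) for d in dirs])

    cc_list, cond_list, eul_list = [], [], []
    for condition in ("minus", "plus"):
        cc = sample_conformations(landscape, condition, n_per_cond, kT=kT, seed=rng)
        idx = np.arange(n_per_cond) % n_directions
        cc_list.append(cc)
        cond_list.append(np.full(n_per_cond, condition))
        eul_list.append(eulers[idx])
    truth = GroundTruth(
        condition=np.concatenate(cond_list),
        cc=np.concatenate(cc_list),
        euler_deg=np.concatenate(eul_list),
        seed=seed,
    )
    stack = render_snapshots(phantom, truth, image_size=image_size, noise_sigma=0.0)
    if snr is not None:
        sigma = sigma_for_snr(stack.images, snr)
        noise_rng = np.random.default_rng(rng.integers(2**31))
        stack.images = (
            stack.images + noise_rng.normal(0.0, sigma, stack.images.shape)
        ).astype(np.float32)
    return stack, truth


def stack_checksum(images: np.ndarray) -> str:
    """SHA-256 of the float32 image payload (pipeline determinism checks)."""
    return hashlib.sha256(np.ascontiguousarray(images, dtype=np.float32).tobytes()).hexdigest()


def config_sidecar(path, config: dict) -> None:
    """Write the generator configuration and seed as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
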