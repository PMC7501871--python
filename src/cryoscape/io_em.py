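"""MRC/MRCS + STAR I/O and projection-direction binning.

Snapshot stacks are stored as MRC2014 mode-2 (float32) image stacks with a
RELION-dialect STAR table carrying per-particle ZYZ Euler angles in degrees
(``_rlnAngleRot``/``_rlnAngleTilt``/``_rlnAnglePsi``), the ligand condition and
optional ground-truth conformational coordinates in namespaced custom columns
(``_cryoscapeCondition``, ``_cryoscapeCC1``, ``_cryoscapeCC2``).

Snapshots are grouped into projection directions by nearest-center assignment
against a quasi-uniform spherical tessellation (Fibonacci lattice) whose
angular spacing is about twice the chosen semi-cone aperture; the aperture
itself comes from the Shannon angle (spatial resolution / particle diameter)
times a multiplier, two by default.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import gemmi
import numpy as np

from .synthetic import direction_from_euler, fibonacci_directions

__all__ = [
    "SnapshotStack",
    "ProjectionBin",
    "read_mrc",
    "write_mrc",
    "read_stack",
    "write_stack",
    "shannon_aperture",
    "bin_orientations",
    "append_coordinates_star",
]

CONDITIONS = ("minus", "plus")

_EULER_COLS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
_COND_COL = "_cryoscapeCondition"
_CC_COLS = ("_cryoscapeCC1", "_cryoscapeCC2")


@dataclasses.dataclass
class SnapshotStack:
    """Aligned, centered particle images with orientations and condition labels."""

    images: np.ndarray  # (n, H, W) float32
    pixel_size: float  # Angstrom / pixel
    euler_deg: np.ndarray  # (n, 3) ZYZ degrees (rot, tilt, psi)
    condition: np.ndarray  # (n,) 'minus' / 'plus'
    ground_truth_cc: np.ndarray | None = None  # (n, 2) in [0,1]

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.euler_deg = np.asarray(self.euler_deg, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        n = self.images.shape[0]
        if n < 1 or self.images.ndim != 3:
            raise ValueError("images must be a non-empty (n, H, W) array")
        if self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be square")
        if self.euler_deg.shape != (n, 3):
            raise ValueError("euler_deg must have shape (n, 3)")
        if not np.isfinite(self.euler_deg).all():
            raise ValueError("Euler angles must be finite")
        if len(self.condition) != n:
            raise ValueError("condition labels must match image count")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"condition labels must be in {CONDITIONS}, got {bad}")
        if self.ground_truth_cc is not None:
            self.ground_truth_cc = np.asarray(self.ground_truth_cc, dtype=float)
            if self.ground_truth_cc.shape != (n, 2):
                raise ValueError("ground_truth_cc must have shape (n, 2)")

    def __len__(self):
        return self.images.shape[0]

    @property
    def directions(self) -> np.ndarray:
        """(n, 3) unit viewing directions (psi ignored)."""
        return direction_from_euler(self.euler_deg)


# ---------------------------------------------------------------------------
# MRC2014 mode-2 stacks
# ---------------------------------------------------------------------------
# Fixed 1024-byte header, little-endian, float32 payload; nz = image count.

def write_mrc(path, images: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a (n, H, W) or (H, W) float32 array as an MRC2014 mode-2 stack."""
    data = np.asarray(images, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("images must be 2D or 3D")
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, 2)  # MODE 2 = float32
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0)  # ISPG 0 = image stack
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 mode-2 stack; returns ``(images (n,H,W), pixel_size)``."""
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if header[208:212] != b"MAP ":
            raise ValueError(f"{path}: missing 'MAP ' signature; not an MRC2014 file")
        if mode != 2:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
        (xlen,) = struct.unpack_from("<f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(1024 + nsymbt)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    pixel = xlen / nx if nx else 1.0
    return data.reshape(nz, ny, nx).copy(), float(pixel)


# ---------------------------------------------------------------------------
# STAR tables (RELION dialect via gemmi)
# ---------------------------------------------------------------------------

def _write_star(path, stack: SnapshotStack, mrcs_name: str) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    tags = ["_rlnImageName", *_EULER_COLS, _COND_COL]
    has_cc = stack.ground_truth_cc is not None
    if has_cc:
        tags += list(_CC_COLS)
    loop = block.init_loop("", tags)
    for i in range(len(stack)):
        row = [
            f"{i + 1:06d}@{mrcs_name}",
            *(f"{v:.6f}" for v in stack.euler_deg[i]),
            str(stack.condition[i]),
        ]
        if has_cc:
            row += [f"{v:.8f}" for v in stack.ground_truth_cc[i]]
        loop.add_row(row)
    doc.write_file(str(path))


def _read_star(path):
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    n = None
    cols = {}
    for tag in ("_rlnImageName", *_EULER_COLS, _COND_COL):
        col = block.find_loop(tag)
        values = list(col)
        if not values:
            raise ValueError(f"{path}: missing STAR column {tag}")
        if n is None:
            n = len(values)
        cols[tag] = values
    euler = np.column_stack([
        np.array(cols[tag], dtype=float) for tag in _EULER_COLS
    ])
    condition = np.array(cols[_COND_COL], dtype=object)
    cc_cols = [list(block.find_loop(tag)) for tag in _CC_COLS]
    cc = (
        np.column_stack([np.array(c, dtype=float) for c in cc_cols])
        if all(cc_cols)
        else None
    )
    image_names = cols["_rlnImageName"]
    mrcs_name = image_names[0].split("@", 1)[1] if "@" in image_names[0] else None
    return euler, condition, cc, mrcs_name


def write_stack(stack: SnapshotStack, prefix) -> dict:
    """Write ``<prefix>.mrcs`` + ``<prefix>.star`` + ``<prefix>.json`` sidecar.

    Returns the paths written.  Round-trip through :func:`read_stack`
    preserves image values at float32 precision and all table columns.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mrcs = prefix.with_suffix(".mrcs")
    star = prefix.with_suffix(".star")
    sidecar = prefix.with_suffix(".json")
    write_mrc(mrcs, stack.images, stack.pixel_size)
    _write_star(star, stack, mrcs.name)
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "n_images": len(stack),
                "image_size": int(stack.images.shape[1]),
                "pixel_size": stack.pixel_size,
                "has_ground_truth": stack.ground_truth_cc is not None,
            },
            fh,
            indent=2,
        )
    return {"mrcs": mrcs, "star": star, "json": sidecar}


def read_stack(prefix) -> SnapshotStack:
    """Read a stack written by :func:`write_stack` (pass the prefix or the .star path)."""
    prefix = Path(prefix)
    star = prefix if prefix.suffix == ".star" else prefix.with_suffix(".star")
    if not star.exists():
        raise FileNotFoundError(f"STAR table not found: {star}")
    euler, condition, cc, mrcs_name = _read_star(star)
    mrcs = star.with_name(mrcs_name) if mrcs_name else star.with_suffix(".mrcs")
    if not mrcs.exists():
        raise FileNotFoundError(f"image stack not found: {mrcs}")
    images, pixel = read_mrc(mrcs)
    if images.shape[0] != len(condition):
        raise ValueError(
            f"{mrcs}: {images.shape[0]} images but {len(condition)} STAR rows"
        )
    return SnapshotStack(
        images=images,
        pixel_size=pixel,
        euler_deg=euler,
        condition=condition,
        ground_truth_cc=cc,
    )


# ---------------------------------------------------------------------------
# Projection-direction binning
# ---------------------------------------------------------------------------

def shannon_aperture(resolution: float, particle_diameter: float, multiplier: float = 2) -> float:
    """Semi-cone aperture in radians: multiplier x (resolution / particle diameter).

    With the conventional values of 0.4 nm resolution, 32 nm particle diameter
    and a multiplier of two Shannon angles this gives 0.025 rad.
    """
    if resolution <= 0 or particle_diameter <= 0 or multiplier <= 0:
        raise ValueError("resolution, diameter and multiplier must all be > 0")
    return multiplier * (resolution / particle_diameter)


@dataclasses.dataclass
class ProjectionBin:
    """A tessellation cell on the orientation sphere and its member snapshots."""

    bin_id: int
    center: np.ndarray  # unit vector
    aperture: float  # semi-cone angle, radians
    members: np.ndarray  # snapshot indices
    flagged: bool = False  # below minimum occupancy -> excluded from embedding

    def __len__(self):
        return len(self.members)


def n_tessellation_centers(aperture: float) -> int:
    """Number of quasi-uniform centers with angular spacing ~= 2 x aperture."""
    # area per center (2a)^2 ~ sphere area 4*pi / N
    return max(1, round(np.pi / aperture**2))


def bin_orientations(
    stack: SnapshotStack,
    aperture: float,
    min_occupancy: int = 20,
    n_centers: int | None = None,
) -> list[ProjectionBin]:
    """Assign snapshots to projection-direction bins by nearest tessellation center.

    Centers come from a deterministic Fibonacci lattice over the full sphere
    with angular spacing about ``2 * aperture`` (override with ``n_centers``).
    Each snapshot joins the center with the largest dot product against its
    viewing direction (ties broken by lowest bin id).  Bins with fewer than
    ``min_occupancy`` members are flagged; empty bins are not emitted, so the
    returned bins partition the snapshot set.
    """
    if not (0 < aperture <= np.pi):
        raise ValueError(f"aperture must be in (0, pi], got {aperture}")
    if n_centers is None:
        n_centers = n_tessellation_centers(aperture)
    centers = fibonacci_directions(n_centers)
    dirs = stack.directions
    if dirs.ndim == 1:
        dirs = dirs[None]
    dots = dirs @ centers.T
    # argmax returns the first (lowest-id) maximum: the stated tie rule
    assignment = np.argmax(np.round(dots, 12), axis=1)
    bins = []
    for b in np.unique(assignment):
        members = np.flatnonzero(assignment == b)
        bins.append(
            ProjectionBin(
                bin_id=int(b),
                center=centers[b],
                aperture=aperture,
                members=members,
                flagged=len(members) < min_occupancy,
            )
        )
    return bins


def bin_adjacency(bins: list[ProjectionBin], k: int = 6):
    """Adjacency between bins: each bin linked to its k nearest centers.

    Returns a symmetric edge set over positions in ``bins``; the graph is made
    connected by joining nearest centers across components.
    """
    import networkx as nx

    m = len(bins)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    if m == 1:
        return g
    centers = np.array([b.center for b in bins])
    dots = centers @ centers.T
    np.fill_diagonal(dots, -np.inf)
    kk = min(k, m - 1)
    for i in range(m):
        for j in np.argsort(-dots[i])[:kk]:
            g.add_edge(i, int(j))
    # bridge disconnected components via the closest center pair
    comps = list(nx.connected_components(g))
    while len(comps) > 1:
        a = comps[0]
        best = None
        for i in a:
            for j in range(m):
                if j in a:
                    continue
                if best is None or dots[i, j] > best[2]:
                    best = (i, j, dots[i, j])
        g.add_edge(best[0], best[1])
        comps = list(nx.connected_components(g))
    return g


def append_coordinates_star(star_path, cc: np.ndarray, out_path=None) -> None:
    """Append pooled conformational coordinates as custom STAR columns.

    Adds ``_cryoscapePooledCC1`` / ``_cryoscapePooledCC2`` to every row of the
    particle table (NaN where a snapshot's coordinates are undefined).
    """
    star_path = Path(star_path)
    doc = gemmi.cif.read_file(str(star_path))
    block = doc.sole_block()
    names = list(block.find_loop("_rlnImageName"))
    cc = np.asarray(cc, dtype=float)
    if len(names) != len(cc):
        raise ValueError(f"{star_path}: {len(names)} rows but {len(cc)} coordinates")
    existing_tags = [
        "_rlnImageName", *_EULER_COLS, _COND_COL,
        *(t for t in _CC_COLS if list(block.find_loop(t))),
    ]
    columns = {t: list(block.find_loop(t)) for t in existing_tags}
    out = gemmi.cif.Document()
    blk = out.add_new_block(block.name)
    tags = existing_tags + ["_cryoscapePooledCC1", "_cryoscapePooledCC2"]
    loop = blk.init_loop("", tags)
    for i in range(len(names)):
        row = [columns[t][i] for t in existing_tags]
        row += [f"{cc[i, 0]:.8f}", f"{cc[i, 1]:.8f}"]
        loop.add_row(row)
    out.write_file(str(out_path or star_path))
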