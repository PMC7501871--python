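"""Per-bin diffusion-map embedding and global conformational coordinates.

Each projection-direction bin is embedded independently: pairwise squared
Euclidean distances between the (optionally low-pass-filtered) raw pixel
intensities of the aligned images, a Gaussian kernel ``exp(-d^2 / 2 eps)``, and
the eigen-decomposition of the symmetric normalization of the row-stochastic
Markov operator.  The leading non-trivial eigenvectors are the bin-local
conformational coordinates.

Because each bin is embedded separately, the identity, ordering and sign of the
coordinates are arbitrary per bin.  A spanning-tree propagation across
neighboring bins on the orientation sphere fixes a consistent pairing and sign,
scored by the correlation of coordinate-ordered windowed image-mean
trajectories.  A rank transform ("metric homogenization") then maps each bin's
coordinates onto [0, 1] so they can be pooled into global (cc1, cc2) values
per snapshot.

The full time-lagged spectral machinery used in the original formulation of
this analysis is intentionally replaced here by the simpler, fully specified
procedure above (windowed image means for propagation, empirical-CDF rank
homogenization); see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

__all__ = [
    "BinEmbedding",
    "GlobalCoordinates",
    "estimate_bandwidth",
    "diffusion_embed",
    "coordinates_above_noise",
    "select_independent_coordinates",
    "propagate_coordinates",
    "homogenize_and_pool",
    "embed_bins",
    "save_embeddings",
    "load_embeddings",
]


@dataclasses.dataclass
class BinEmbedding:
    """Diffusion-map spectrum and coordinate values for one projection bin."""

    bin_id: int
    bandwidth: float
    eigenvalues: np.ndarray  # descending, eigenvalues[0] == 1
    eigenvectors: np.ndarray  # (n_members, k), column j pairs with eigenvalues[j]
    members: np.ndarray  # snapshot indices, aligned with eigenvector rows
    n_retained: int | None = None
    selected: tuple[int, ...] | None = None  # non-harmonic coordinate columns

    @property
    def coordinates(self) -> np.ndarray:
        """Non-trivial coordinates (psi_1, psi_2, ...), one column each."""
        return self.eigenvectors[:, 1:]

    @property
    def independent_coordinates(self) -> np.ndarray:
        """The selected non-harmonic coordinates (falls back to the leading ones)."""
        if self.selected is None:
            return self.coordinates
        return self.coordinates[:, list(self.selected)]


@dataclasses.dataclass
class GlobalCoordinates:
    """Pooled per-snapshot conformational coordinates in [0, 1]."""

    cc: np.ndarray  # (n_snapshots, 2), NaN where undefined (flagged bins)
    sign_order_map: dict  # per-bin (permutation, signs) applied
    provenance: dict

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.cc).any(axis=1)


def estimate_bandwidth(sq_distances: np.ndarray) -> float:
    """Default kernel bandwidth: median of the nonzero pairwise squared distances."""
    d = np.asarray(sq_distances, dtype=float)
    if d.ndim == 2:
        iu = np.triu_indices(d.shape[0], k=1)
        d = d[iu]
    if d.size == 0:
        raise ValueError("need at least 2 points to estimate a bandwidth")
    nz = d[d > 0]
    if nz.size == 0:
        raise ValueError("all pairwise distances are zero; cannot set a bandwidth")
    return float(np.median(nz))


def _pairwise_sq(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=float).reshape(len(images), -1)
    return squareform(pdist(x, metric="sqeuclidean"))


def diffusion_embed(
    images: np.ndarray,
    epsilon: float | None = None,
    k: int = 10,
    bin_id: int = 0,
    members: np.ndarray | None = None,
    lowpass_sigma: float | None = None,
    bandwidth_scale: float = 1.0,
) -> BinEmbedding:
    """Diffusion-map embedding of one bin's images.

    Builds the Gaussian kernel ``exp(-d^2 / 2 eps)`` on pairwise squared
    Euclidean image distances, symmetrically normalizes the row-stochastic
    Markov operator and returns the top-``k`` eigenpairs (descending; the
    trivial pair has eigenvalue 1).  Eigenvector sign is fixed so each
    vector's first nonzero component is positive.  ``lowpass_sigma`` applies a
    Gaussian low-pass filter (in pixels) to the images before the distance
    computation.  When ``epsilon`` is not given, the bandwidth is
    ``bandwidth_scale`` times the median nonzero pairwise squared distance
    (scales above 1 smooth the eigenfunctions, which is useful when nearby
    eigenvalues would otherwise mix).
    """
    images = np.asarray(images, dtype=float)
    n = len(images)
    if n < k + 1:
        raise ValueError(f"bin of size {n} too small for {k} eigenpairs (need >= k+1)")
    if lowpass_sigma:
        from scipy.ndimage import gaussian_filter

        images = np.stack([gaussian_filter(im, lowpass_sigma) for im in images])
    d2 = _pairwise_sq(images)
    if epsilon is None:
        epsilon = bandwidth_scale * estimate_bandwidth(d2)
    if epsilon <= 0:
        raise ValueError("bandwidth must be > 0")
    kernel = np.exp(-d2 / (2.0 * epsilon))
    off = kernel[~np.eye(n, dtype=bool)]
    if off.max() < 1e-300:
        raise ValueError(
            "degenerate kernel: all off-diagonal weights ~0; increase the bandwidth"
        )
    deg = kernel.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    sym = kernel * inv_sqrt[:, None] * inv_sqrt[None, :]
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    # Markov-operator eigenvectors: psi = D^{-1/2} phi, unit-normalized
    psi = evecs[:, order] * inv_sqrt[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    for j in range(psi.shape[1]):
        col = psi[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            psi[:, j] = -col
    if members is None:
        members = np.arange(n)
    return BinEmbedding(
        bin_id=bin_id,
        bandwidth=float(epsilon),
        eigenvalues=evals,
        eigenvectors=psi,
        members=np.asarray(members),
    )


def select_independent_coordinates(
    embedding: BinEmbedding,
    n: int = 2,
    r2_threshold: float = 0.85,
    n_neighbors: int = 10,
) -> tuple[int, ...]:
    """Pick the leading non-harmonic eigenvectors of one bin.

    Higher diffusion-map eigenvectors can be harmonics (functions) of earlier
    ones rather than new manifold directions.  Following the parsimonious
    eigendirection-selection idea, candidates are scanned in eigenvalue order;
    a candidate is skipped if a k-nearest-neighbor regression on the already
    selected coordinates explains it with R^2 above ``r2_threshold``.  Returns
    column indices into ``embedding.coordinates`` (at most ``n``; padded with
    the next unselected columns if fewer survive, so the count is always
    ``min(n, available)``).
    """
    cols = embedding.coordinates
    m, total = cols.shape
    k = min(n_neighbors, m - 1)
    selected: list[int] = [0]
    for j in range(1, total):
        if len(selected) >= n:
            break
        base = cols[:, selected]
        # kNN prediction of column j from the selected coordinates
        scale = base.std(axis=0)
        scale[scale == 0] = 1.0
        b = base / scale
        d2 = ((b[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k]
        pred = cols[nn, j].mean(axis=1)
        resid = cols[:, j] - pred
        ss_tot = float(np.var(cols[:, j])) * m
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        if r2 <= r2_threshold:
            selected.append(j)
    j = 1
    while len(selected) < min(n, total):  # pad deterministically if all were harmonics
        if j not in selected:
            selected.append(j)
        j += 1
    return tuple(selected)


def coordinates_above_noise(
    spectra: list[np.ndarray] | np.ndarray,
    tau: float = 0.5,
    cap: int = 2,
) -> tuple[int, list[int]]:
    """Count coordinates above the noise plateau of the eigenvalue spectra.

    Per bin, the plateau level is the median of the trailing half of the
    non-trivial eigenvalues ``lambda_1..lambda_K``; coordinate ``k`` is
    retained if ``lambda_k > plateau * (1 + tau)``.  The global retained count
    is the median across bins, capped at ``cap`` (landscapes are built from
    the two strongest coordinates).

    Returns ``(global_count, per_bin_counts)``.
    """
    per_bin = []
    for spec in spectra:
        spec = np.asarray(spec, dtype=float)
        lam = spec[1:]  # drop the trivial lambda_0 = 1
        if lam.size < 8:
            raise ValueError("need at least 8 eigenvalues beyond lambda_0 per spectrum")
        plateau = float(np.median(lam[lam.size // 2:]))
        per_bin.append(int(np.sum(lam > plateau * (1.0 + tau))))
    global_count = int(min(cap, round(float(np.median(per_bin)))))
    return global_count, per_bin


# ---------------------------------------------------------------------------
# Coordinate propagation across projection directions
# ---------------------------------------------------------------------------

def _radial_profile(image: np.ndarray) -> np.ndarray:
    """Rotational average of a square image about its center (ring sums)."""
    h = image.shape[0]
    c = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:h]
    rbin = np.clip(np.hypot(yy - c, xx - c).astype(int), 0, h // 2)
    return np.bincount(rbin.ravel(), weights=image.ravel(), minlength=h // 2 + 1)


def _profiles(images: np.ndarray) -> np.ndarray:
    """Per-image radial profiles (n, n_rings)."""
    return np.stack([_radial_profile(np.asarray(im, dtype=float)) for im in images])


def _ordered_trajectory(profiles: np.ndarray, coord: np.ndarray, n_windows: int = 8) -> np.ndarray:
    """Windowed means of per-image radial profiles along a coordinate ordering.

    Members are sorted by the coordinate and split into ``n_windows``
    contiguous windows; each window's images are averaged and reduced to the
    rotational average about the image center (the radial profile is linear,
    so the profile of the mean equals the mean of the profiles).  The
    rotational average is invariant to in-plane rotation and varies slowly
    with viewing direction, so trajectories of neighboring
    projection-direction bins remain comparable.  The trajectory is centered
    by subtracting its mean over windows so that correlations compare
    patterns of change rather than the static view.
    """
    order = np.argsort(coord, kind="stable")
    x = profiles[order]
    splits = np.array_split(np.arange(len(x)), n_windows)
    traj = np.stack([x[sel].mean(axis=0) for sel in splits if len(sel)])
    if traj.shape[0] != n_windows:  # resample to the common length
        t_old = np.linspace(0, 1, traj.shape[0])
        t_new = np.linspace(0, 1, n_windows)
        traj = np.stack(
            [np.interp(t_new, t_old, traj[:, j]) for j in range(traj.shape[1])], axis=1
        )
    return traj - traj.mean(axis=0, keepdims=True)


def _traj_correlation(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float((a.ravel() @ b.ravel()) / (na * nb))


_MIX_ANGLES = np.radians(np.arange(-75.0, 76.0, 15.0))


def propagate_coordinates(
    embeddings: dict[int, BinEmbedding],
    adjacency,
    images: np.ndarray,
    n_coords: int = 2,
    n_windows: int = 8,
    ambiguity_threshold: float = 0.2,
    n_candidates: int = 4,
    degeneracy_ratio: float = 0.6,
    n_sweeps: int = 2,
) -> tuple[dict[int, np.ndarray], dict]:
    """Fix coordinate identity and orientation consistently across bins.

    ``embeddings`` maps graph-node ids (as used by ``adjacency``, a networkx
    graph) to bin embeddings; ``images`` is the full snapshot array indexed by
    each embedding's ``members``.  A greedy spanning tree grows from the
    most-populated bin, always resolving the frontier bin whose best
    assignment is the most confident, so low-quality attachments cannot
    corrupt bins reachable through better ones.

    Each bin's global coordinates are chosen from its ``n_candidates`` leading
    eigenvectors by maximizing the correlation of coordinate-ordered windowed
    image-mean trajectories against the consensus of all already-resolved
    neighboring bins (their normalized trajectories concatenated): first the
    best single column per coordinate (covering permutations and sign flips),
    then a refinement over in-plane rotations with each remaining candidate
    whose eigenvalue is within ``degeneracy_ratio`` of the base column's
    (un-mixing quasi-degenerate eigenvector pairs only).  After the initial
    growth, ``n_sweeps`` consensus sweeps re-fit every non-root bin against
    all its neighbors, correcting isolated misassignments.  Bins whose best
    per-coordinate |correlation| falls below ``ambiguity_threshold`` are
    flagged (processing continues).

    Returns ``(mixing_map, diagnostics)``: ``mixing_map[node]`` is an
    ``(n_coords, n_candidates)`` weight matrix ``W`` such that global
    coordinate ``g`` of the bin is ``coordinates[:, :n_candidates] @ W[g]``.
    A pure permutation/sign-flip assignment appears as signed one-hot rows.
    """
    nodes = list(embeddings)

    def one_hot(emb):
        sel = emb.selected or tuple(range(n_coords))
        m = min(n_candidates, emb.coordinates.shape[1])
        w = np.zeros((n_coords, m))
        for g in range(n_coords):
            w[g, min(sel[g], m - 1) if g < len(sel) else g] = 1.0
        return w

    if len(nodes) <= 1:
        return {n: one_hot(embeddings[n]) for n in nodes}, {
            "edges": [],
            "flagged_edges": [],
        }

    # The root's coordinate identity seeds the whole propagation; its own
    # harmonic-filtered selection defines the global (cc1, cc2).
    root = max(nodes, key=lambda n: len(embeddings[n].members))
    mixing: dict = {root: one_hot(embeddings[root])}
    edge_log, flagged = [], []

    prof_cache: dict = {}

    def node_data(node):
        if node not in prof_cache:
            emb = embeddings[node]
            m = min(n_candidates, emb.coordinates.shape[1])
            prof_cache[node] = (
                _profiles(images[emb.members]),
                emb.coordinates[:, :m],
                emb.eigenvalues[1 : m + 1],
            )
        return prof_cache[node]

    traj_cache: dict = {}

    def resolved_trajs(node):
        key = (node, mixing[node].tobytes())
        if key not in traj_cache:
            profiles, cols, _ = node_data(node)
            w = mixing[node]
            traj_cache[key] = [
                _ordered_trajectory(profiles, cols @ w[g], n_windows)
                for g in range(n_coords)
            ]
        return traj_cache[key]

    def reference_trajs(parents):
        """Consensus reference: normalized parent trajectories concatenated."""
        refs = []
        for g in range(n_coords):
            parts = []
            for p in parents:
                t = resolved_trajs(p)[g]
                norm = np.linalg.norm(t)
                parts.append(t.ravel() / norm if norm else t.ravel())
            refs.append(np.concatenate(parts))
        return refs

    def fit_node(child, parents):
        """Best mixing weights for ``child`` against the parents' consensus."""
        refs = reference_trajs(parents)
        profiles, cols, lam = node_data(child)
        m = cols.shape[1]
        singles = [
            _ordered_trajectory(profiles, cols[:, j], n_windows) for j in range(m)
        ]

        def ref_corr(g, traj):
            norm = np.linalg.norm(traj)
            if norm == 0:
                return 0.0
            flat = np.tile(traj.ravel() / norm, len(parents))
            return float(refs[g] @ flat) / len(parents)

        weights = np.zeros((n_coords, m))
        per_coord = []
        taken: list[int] = []
        for g in range(n_coords):
            corr = [
                ref_corr(g, singles[j]) if j not in taken else 0.0 for j in range(m)
            ]
            j0 = int(np.argmax(np.abs(corr)))
            best_w = np.zeros(m)
            best_w[j0] = np.sign(corr[j0]) or 1.0
            best_c = abs(corr[j0])
            # refine: rotate within the plane spanned by j0 and each other
            # candidate; a rotation is physically meaningful only when the
            # two eigenvalues are nearly degenerate (otherwise the
            # eigenvectors are well determined and mixing just overfits the
            # trajectory proxy)
            for j in range(m):
                if j == j0:
                    continue
                lo, hi = sorted((abs(lam[j0]), abs(lam[j])))
                if hi == 0 or lo / hi < degeneracy_ratio:
                    continue
                for th in _MIX_ANGLES:
                    if th == 0.0:
                        continue
                    v = np.cos(th) * cols[:, j0] + np.sin(th) * cols[:, j]
                    c = ref_corr(g, _ordered_trajectory(profiles, v, n_windows))
                    if abs(c) > best_c:
                        best_c = abs(c)
                        best_w = np.zeros(m)
                        best_w[j0] = np.cos(th) * (np.sign(c) or 1.0)
                        best_w[j] = np.sin(th) * (np.sign(c) or 1.0)
            weights[g] = best_w
            per_coord.append(best_c)
            taken.append(j0)
        return weights, per_coord

    fit_cache: dict = {}

    def fit_cached(child):
        parents = tuple(sorted(p for p in adjacency.neighbors(child) if p in mixing))
        if not parents:
            return None
        key = (child, parents)
        if key not in fit_cache:
            fit_cache[key] = fit_node(child, parents)
        return (key[1],) + fit_cache[key]

    unresolved = set(nodes) - {root}
    while unresolved:
        best = None
        for child in unresolved:
            fit = fit_cached(child)
            if fit is None:
                continue
            parents, weights, per_coord = fit
            key = min(per_coord)
            if best is None or key > best[0]:
                best = (key, child, parents, weights, per_coord)
        if best is None:  # disconnected remainder: fall back to local selection
            child = min(unresolved)
            mixing[child] = one_hot(embeddings[child])
            unresolved.discard(child)
            flagged.append((None, child))
            continue
        _, child, parents, weights, per_coord = best
        mixing[child] = weights
        unresolved.discard(child)
        edge_log.append(
            {"edge": (parents, child), "weights": weights, "scores": per_coord,
             "ambiguous": min(per_coord) < ambiguity_threshold}
        )

    # consensus sweeps: re-fit every bin (root included) against its neighbors
    for _ in range(n_sweeps):
        updated = dict(mixing)
        for child in nodes:
            parents = tuple(sorted(p for p in adjacency.neighbors(child) if p in mixing))
            if not parents:
                continue
            weights, per_coord = fit_node(child, parents)
            updated[child] = weights
        mixing = updated

    # final ambiguity audit against the (now stable) neighbor consensus
    final_scores = {}
    for child in nodes:
        if child == root:
            continue
        parents = tuple(sorted(p for p in adjacency.neighbors(child) if p in mixing))
        if not parents:
            flagged.append((None, child))
            continue
        _, per_coord = fit_node(child, parents)
        final_scores[child] = per_coord
        if min(per_coord) < ambiguity_threshold:
            flagged.append((parents, child))
    return mixing, {
        "edges": edge_log,
        "flagged_edges": flagged,
        "final_scores": final_scores,
    }


# ---------------------------------------------------------------------------
# Metric homogenization and pooling
# ---------------------------------------------------------------------------

def _rank_unit(values: np.ndarray) -> np.ndarray:
    """Empirical-CDF rank transform to [0, 1] (average ranks for ties)."""
    r = rankdata(values, method="average")
    lo, hi = r.min(), r.max()
    if hi == lo:
        return np.full_like(r, 0.5, dtype=float)
    return (r - lo) / (hi - lo)


def homogenize_and_pool(
    embeddings: dict[int, BinEmbedding],
    sign_order_map: dict,
    n_snapshots: int,
    n_coords: int = 2,
    exclude: set | None = None,
    provenance: dict | None = None,
) -> GlobalCoordinates:
    """Rank-transform each bin's coordinates to [0,1] and pool over bins.

    Every snapshot in a non-excluded bin receives (cc1, cc2); snapshots in
    excluded (flagged) bins carry NaN.  ``sign_order_map`` holds the per-bin
    mixing weights from :func:`propagate_coordinates`.
    """
    exclude = exclude or set()
    cc = np.full((n_snapshots, n_coords), np.nan)
    for node, emb in embeddings.items():
        if node in exclude:
            continue
        w = np.asarray(sign_order_map[node])
        cols = emb.coordinates[:, : w.shape[1]]
        for g in range(n_coords):
            vals = cols @ w[g]
            cc[emb.members, g] = _rank_unit(vals)
    return GlobalCoordinates(
        cc=cc, sign_order_map=sign_order_map, provenance=provenance or {}
    )


def embed_bins(
    stack_images: np.ndarray,
    bins,
    k: int = 10,
    lowpass_sigma: float | None = None,
    min_occupancy: int | None = None,
    n_coords: int = 2,
    bandwidth_scale: float = 1.0,
) -> dict[int, BinEmbedding]:
    """Embed every non-flagged projection bin; returns {bin position: embedding}.

    Bins smaller than ``max(min_occupancy, k+1)`` are skipped (they stay
    counted in occupancy reports upstream but contribute no coordinates).
    Each embedding's ``selected`` columns are set to its leading
    ``n_coords`` non-harmonic coordinates.
    """
    floor = max(min_occupancy or 20, k + 1)
    out = {}
    for pos, b in enumerate(bins):
        if b.flagged or len(b.members) < floor:
            continue
        emb = diffusion_embed(
            stack_images[b.members],
            k=k,
            bin_id=b.bin_id,
            members=b.members,
            lowpass_sigma=lowpass_sigma,
            bandwidth_scale=bandwidth_scale,
        )
        emb.selected = select_independent_coordinates(emb, n=n_coords)
        out[pos] = emb
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_embeddings(path, embeddings: dict[int, BinEmbedding]) -> None:
    """Persist per-bin embeddings to an HDF5 container keyed by bin id."""
    import h5py

    with h5py.File(path, "w") as fh:
        for node, emb in embeddings.items():
            grp = fh.create_group(str(node))
            grp.attrs["bin_id"] = emb.bin_id
            grp.attrs["bandwidth"] = emb.bandwidth
            if emb.selected is not None:
                grp.attrs["selected"] = list(emb.selected)
            grp.create_dataset("eigenvalues", data=emb.eigenvalues)
            grp.create_dataset("eigenvectors", data=emb.eigenvectors)
            grp.create_dataset("members", data=emb.members)


def load_embeddings(path) -> dict[int, BinEmbedding]:
    """Load embeddings written by :func:`save_embeddings`."""
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for key in fh:
            grp = fh[key]
            out[int(key)] = BinEmbedding(
                bin_id=int(grp.attrs["bin_id"]),
                bandwidth=float(grp.attrs["bandwidth"]),
                eigenvalues=grp["eigenvalues"][...],
                eigenvectors=grp["eigenvectors"][...],
                members=grp["members"][...],
                selected=(
                    tuple(int(v) for v in grp.attrs["selected"])
                    if "selected" in grp.attrs
                    else None
                ),
            )
    return out
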