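# Methods

`cryoscape` turns an ensemble of aligned, centered single-particle projection
images — each carrying an orientation assignment and a ligand-condition label
(−ligand / +ligand) — into free-energy landscapes over two data-derived
conformational coordinates, an interlandscape ligand-association transition
map, and a least-energy functional path with per-frame snapshot sets. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic validation does and does not establish.

## Model overview

**Inverse-Boltzmann landscapes.** In equilibrium a conformational state `c`
is occupied with statistical weight `exp(-E_c/kT)`. Histogramming the pooled
conformational coordinates of one condition into an `n1 × n2` grid gives
sighting counts `n_c`, and relative free energies

    E_c = -kT ln(n_c / n_max),

referenced to the most-populated cell (only relative energies are defined;
the partition function is unknown). Unobserved cells carry no energy and are
masked. The highest observable energy in `N` snapshots is the state sighted
once, at `ΔG_max = kT ln N` (natural logarithm); every reported energy is
bounded by it. The conversion assumes the variance of the coarse-graining
degeneracy (entropy) across cells is negligible relative to the energy
variance; the package does not estimate the degeneracy and records the
assumption in each landscape's metadata.

**Transition map.** Ligand association is modeled as a master equation over
(cell, condition) states. Binding connects iso-conformational cells only (the
hop is fast relative to conformational motion), with mass-action rate `k_c L`
and an Arrhenius association constant whose activation energy is read off the
+ligand landscape: `k_c = A exp(-(E_c⁺ - E_c0⁺)/kT) ∝ P_c⁺`. At initial time
(no bound receptors, the −ligand ensemble at equilibrium) the gain of bound
state `c` is therefore proportional to `P_c⁺ P_c⁻`: the transition map is the
normalized product of the two conformational spectra, its local maxima are
the association hotspots, and the prefactor `A` and ligand concentration `L`
cancel in the normalization. Intra-landscape kinetics are not constrained by
the data; Metropolis rates `A·min(1, exp(-ΔE/kT))` between 4-adjacent
occupied cells are used because they make the stationary state of each
landscape exactly the Boltzmann density the landscape asserts. Dissociation
rates default to zero, matching the initial-time analysis; a
detailed-balance-consistent reverse rate is available behind a flag and is an
admittedly incomplete description of unbinding.

**Functional path.** The route of binding starts at the −ligand energy
minimum (START), runs through a transition hotspot (HOT, the top local
maximum of the transition map by default), hops iso-conformationally, and
descends to the +ligand minimum (FINISH). Paths live on the 8-connected
graph of occupied cells. The default action is the discrete energy line
integral (step length × trapezoidal mean of endpoint energies, energies
offset to minimum 0); `minimax` mode instead minimizes the highest energy
crossed, ties resolved by the integral — solved in two phases (bottleneck
Dijkstra for the optimal maximum, then integral Dijkstra restricted to cells
at or below it), because a single lexicographic Dijkstra does not have
optimal substructure for the tie-break. Unobserved cells are impassable by
default; a flag admits them at cost `ΔG_max`. The path is arc-length
resampled into frames (50 by default); each frame's snapshot set is the
frame-side snapshots within a rectangular window (default half-width 1 cell),
and a flag extends the route beyond the two minima along CC1 to cover motions
just past them.

## The manifold pipeline

Snapshots are grouped into projection directions by nearest-center assignment
against a Fibonacci-lattice tessellation of the sphere whose spacing is about
twice the semi-cone aperture; the aperture is `multiplier ×
resolution/diameter` (two Shannon angles by default). In-plane rotation is
ignored for binning. Each bin is embedded by a diffusion map: pairwise
squared Euclidean distances between raw pixel intensities (optionally
low-pass filtered), Gaussian kernel `exp(-d²/2ε)`, symmetric normalization of
the row-stochastic operator, top-k eigenpairs. Eigenvector sign is fixed
(first nonzero component positive) and ordering is by eigenvalue, so the
embedding is deterministic.

The original formulation of this analysis applies a time-lagged spectral
decomposition along the embedding eigenfunctions; this package substitutes a
simpler, fully specified procedure and documents every piece:

* **Bandwidth.** `ε = bandwidth_scale × median` nonzero pairwise squared
  distance. The bare estimator defaults to the median itself; the pipeline
  uses `bandwidth_scale = 3`. The wider kernel smooths the eigenfunctions and
  reduces mixing between nearly degenerate eigenpairs (the weaker coordinate
  and harmonics of the stronger one), which is the dominant error mode at
  a few hundred images per bin.
* **Coordinate identity across bins.** Each bin's eigenvector order and sign
  are arbitrary, and a harmonic of the strong coordinate can outrank the weak
  one. A greedy spanning tree grows from the most-populated bin, always
  resolving the frontier bin whose assignment is most confident. A bin's two
  global coordinates are chosen from its four leading eigenvectors by
  maximizing the correlation of *coordinate-ordered windowed image-mean
  trajectories* against the consensus of all already-resolved neighbors: the
  bin's members are sorted by a candidate coordinate, split into 8 windows,
  and each window's mean image is reduced to its rotational average (radial
  profile). Radial profiles are invariant to in-plane rotation and vary
  slowly with viewing direction, so neighboring bins' trajectories remain
  comparable where raw-pixel trajectories decorrelate. A rotation search
  within quasi-degenerate eigenvalue pairs (ratio ≥ 0.6) un-mixes coordinates
  the eigensolver cannot separate; rotations between well-separated
  eigenvalues are not attempted, since those eigenvectors are well determined
  and rotating them only overfits the trajectory proxy. Two consensus sweeps
  re-fit every bin against its neighbors, correcting isolated errors. Bins
  whose best per-coordinate |correlation| falls below 0.2 are flagged and
  excluded from pooling (they remain in occupancy reports).
* **Harmonic filter.** The root bin (which seeds the global coordinate
  identity) selects its two leading *non-harmonic* eigenvectors: a candidate
  is skipped when a k-nearest-neighbor regression on already-selected
  coordinates explains it with R² > 0.85 (parsimonious eigendirection
  selection).
* **Metric homogenization.** Within each bin, each global coordinate is
  rank-transformed to [0, 1] (empirical CDF; average ranks for ties; all-tied
  bins map to 0.5) and pooled. The pooled coordinates therefore live in
  quantile space: each marginal is uniformized, and landscape structure is
  carried by the joint density. All downstream quantities (energies, maps,
  paths) are defined on this rank scale; agreement with ground truth is
  accordingly measured by Spearman correlation, i.e., up to monotone
  reparameterization.
* **Coordinate count.** Per bin, the noise-plateau level is the median of the
  trailing half of the non-trivial eigenvalues; coordinate `k` is retained if
  `λ_k > plateau × 1.5` (τ = 0.5). The global count is the median across
  bins, capped at 2 for landscape construction. The plateau criterion is
  meaningful only when a noise plateau exists: on noise-free data the
  trailing spectrum is residual signal structure and the rule retains more
  coordinates, which is expected and harmless (the cap applies).

## The synthetic validation system

The generator emulates the end-to-end study design on a system where the
answer is known: a 32³-voxel phantom whose shape is controlled by two
conformational degrees of freedom on the unit square, dual analytic energy
surfaces (one per ligand condition), Boltzmann sampling, and line-integral
projection over many directions with optional additive Gaussian noise.

* **Landscape pair (`shifted_double_well`).** A separable design: a two-well
  profile along CC1 (negative log of a two-Gaussian mixture; wells at 0.30
  and 0.70, width 0.10, depth ratio 3) whose deeper well swaps between
  conditions, plus a harmonic confinement along CC2 (10 kT/unit²) whose
  center shifts from 0.40 (−ligand) to 0.60 (+ligand). The minima (START and
  FINISH) therefore differ in both coordinates, the ~1.7 kT barrier region
  between the wells stays populated enough to carry a path and interlandscape
  overlap, and — decisive for a two-coordinate validation — the two degrees
  of freedom are excited independently. A non-separable two-well pair puts
  nearly all variance on the well-to-well diagonal, and no embedding can
  recover two coordinates from effectively one-dimensional data.
* **Phantom.** A static central body blob plus two deformation sites placed
  at opposite corners of the box: a blob that translates radially toward the
  box center with CC1, and a blob whose width grows isotropically with CC2.
  The placement keeps the two sites' projections from overlapping in most
  viewing directions (overlap introduces image-metric cross-terms that curve
  the embedding), and the radial motion direction keeps CC1 visible to the
  rotational-average trajectory descriptor from every view. Deformation
  amplitudes are balanced so CC1 is consistently the stronger image-space
  mode (ratio ≈ 2) — enough anisotropy to keep the eigenvalue order stable,
  not so much that CC2 drowns.
* **Sampling and rendering.** Conformations are sampled per condition by
  grid-multinomial draws from `exp(-E/kT)` on a 200×200 lattice with uniform
  within-cell jitter (plain rejection sampling is available and aborts below
  an acceptance rate of 1e-4). Orientations are a Fibonacci lattice of 100
  directions, assigned round-robin (75 snapshots per direction per condition,
  so a pooled bin holds 150). Projections are trilinear resamplings of the
  deformed volume summed along the viewing axis; identity orientations
  reproduce exact axis sums, and projection is linear in the volume to
  machine precision. Noise is i.i.d. Gaussian with sigma set from the target
  SNR (mean per-image signal variance / noise variance); the noisy validation
  condition is SNR 1, analyzed with a 1.5-pixel Gaussian low-pass before the
  distance computation. No CTF, dose, or motion effects are simulated.

**What passing validation shows — and what it does not.** The validation
demonstrates that the full chain (binning → per-bin embedding → propagation →
homogenization → landscapes → transition map → path → frames) recovers two
independently excited, monotone, well-separated deformation modes from ideal
and SNR-1 images with known orientations. Real particle images add CTF,
orientation errors, alignment-induced signal damping, conformational motion
that is neither separable nor two-dimensional, and artifact classes; none of
these are emulated, so the validation bounds correctness of the
implementation, not performance on experimental data.

## Numerical choices and degenerate inputs

* Grid cells are half-open `[lo, hi)` with the top edge closed; a point on an
  interior edge belongs to the higher cell. Default landscape grid 50 × 50.
* `kT` defaults to 1 (energies in kT); conversions use 0.593 kcal/mol at
  298.15 K (configurable temperature).
* Nearest-center binning ties break to the lowest bin id; path-search ties
  break by row-major neighbor order; hotspot ties by row-major cell index.
* Identical images in a bin produce a rank-one kernel (λ₀ = 1, rest 0);
  all-zero pairwise distances make the median bandwidth undefined and raise.
  A kernel whose off-diagonal entries underflow raises with advice to widen
  the bandwidth.
* The master-equation propagator is a dense matrix exponential stepped
  between requested times (state spaces here are ≤ a few thousand); total
  probability is checked to 1e-8. Stationary distributions come from the
  null-space eigenvector of the generator restricted to active cells.
* Back-projection is the adjoint of the projection resampling with
  nearest-voxel interpolation, normalized by per-voxel hit counts — a toy
  reconstruction for phantom-scale sanity checks, not a quantitative method.
* Simulation, embedding and pooling are deterministic given the config seed;
  reruns are bit-identical (landscape checksums are part of the report).

## Problem sizes used in the shipped validation runs

Noise-free and SNR-1 runs: 100 directions × 150 snapshots per pooled bin
(15,000 images per run, 32×32 pixels), 50×50 landscape grid. The
inverse-Boltzmann recovery check uses 3×10⁵ sampled conformations. The path
oracle enumerates 1000 random grids up to 5×5; the stationarity check uses a
20×20 grid; the reconstruction check uses 200 noise-free views.

## Known limitations

* The pooled coordinates are quantile-scale: absolute units of the original
  collective variables are not recovered (and are not identifiable from
  rank homogenization). Energies are relative, capped by `kT ln N`.
* Rank uniformization of each marginal means one-dimensional structure along
  a single coordinate axis is flattened; landscape features are carried by
  the joint density only.
* Propagation assumes the coordinate identity varies smoothly between
  neighboring viewing directions; directions where a deformation mode is
  nearly invisible rely on the neighbor consensus and may be flagged.
* The transition model ignores dissociation and conformation-dependent
  prefactors; it estimates where association concentrates, not absolute
  rates.
* The degeneracy/entropy correction to the inverse-Boltzmann conversion is
  assumed negligible, exactly as stated in each landscape's metadata.
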