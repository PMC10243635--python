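# Methods

## Model

The package models exploration of an unweighted, undirected, simple graph
by a discrete-time random walk: at each step the walker moves to a
uniformly chosen neighbour, so the transition matrix is `T = D⁻¹A` with
`D = diag(dᵢ)`. Spatial coordinates and edge lengths do not enter the
dynamics; they are carried along only for reporting and external
plotting. Continuous-time, lazy and teleporting walks, and weighted or
directed graphs, are out of scope.

All analysis assumes a connected graph with no isolated nodes — both the
relaxation time and the stationary distribution are otherwise undefined —
so the pipeline always extracts the largest connected component first and
logs the retained node fraction. Generators and thinning can disconnect a
graph; thinning is applied before component extraction.

## Spectral decomposition and normalisation

`T` is conjugate to the symmetric `M = D⁻¹ᐟ²AD⁻¹ᐟ²`; its orthonormal
eigenvectors `v_k` give the biorthogonal system

    psi_k = sqrt(2E) D^-1/2 v_k,   phi_k = D^1/2 v_k / sqrt(2E),

the unique scaling for which `Φᵀ Ψ = I`, `ψ₀ ≡ 1` and `φ₀ = d/2E`
simultaneously. Eigenpairs are kept in order of decreasing |λ| (ties:
positive eigenvalue first), because the magnitude-ordered truncation
minimises the spectral-norm error of `T_K^t` and keeps near-(−1) modes
representable; `λ₀ = 1` is always retained. The stationary pair is known
in closed form and is pinned to it exactly after the solve (`λ₀ := 1`,
`ψ₀ := 1`, `φ₀ := d/2E`); this removes a ~1e−13 solver residual that
would otherwise be amplified to ~1e−7 at walk times of order 10⁶.
Eigenvalues are clipped to [−1, 1].

Small problems (N ≤ `dense_cutoff`, default 2000) or near-full ranks use
LAPACK `eigh`; larger ones use Lanczos (`eigsh`, largest magnitude) with
a start vector drawn from the seeded `random_state`, so repeated fits
agree. Each eigenvector's sign is fixed by making its largest-magnitude
entry positive. `λᵗ` for large t is evaluated as
`sign(λ)ᵗ·exp(t·log|λ|)` and underflows gracefully to 0.

The relaxation time is `τ = 1/(1 − |λ₁|)`. If `|λ₁| ≥ 1 − 1e−9` the
graph is bipartite (λ = −1) or disconnected (repeated λ = 1) and a
dedicated error names the cause; τ is reported as a real number and
floored only where a step count is required (the embedding time).

Because `Σⱼ φ_k(j) = δ_{k0}` (biorthogonality against `ψ₀ = 1`),
truncated presence fields conserve probability mass exactly at every K;
truncation instead shows up as pointwise error, which
`truncation_error` quantifies as `‖Tᵗ − T_Kᵗ‖₂/‖Tᵗ‖₂` against an exact
dense power (guarded to N ≤ 2000).

## Communities

Diffusion communities are k-means clusters of the rows of `X_K(t)` with
the constant column 0 dropped. `t` defaults to `floor(τ)`; at that time
most coordinates have underflowed to zero and clustering acts on the few
surviving slow modes, which is the intended long-time resolution.
k-means uses k-means++ initialisation, 10 restarts and relative inertia
tolerance 1e−6 (the method itself does not prescribe these), seeded from
a single integer; empty clusters are repaired by re-seeding from the
point farthest from the donor centroid (sklearn's Lloyd iterations make
this a degenerate-case safeguard only). Coordinates are not rescaled
before clustering. Nearest-centroid ties resolve to the lowest community
id. All downstream features are invariant to community relabelling.

## Features

* `h(C)` uses the full cut and the *smaller* of the two volumes, so
  `0 < h ≤ 1` for any proper community of a connected graph; `h̄` is the
  unweighted mean over communities (k ≥ 2 required).
* `⟨p_in⟩`/`⟨p_out⟩` are evaluated from per-community sums
  `S_ψ(C,k) = Σ_{m∈C} ψ_k(m)`, `S_φ(C,k) = Σ_{l∈C} φ_k(l)`: cost
  O(KN + Kk) per time point, never a dense `Tᵗ`. The k = 0 stationary
  term is included — without it the long-time limits
  `⟨p_in⟩_C(∞) = ⟨d⟩_C/2E` and `⟨p_out⟩_C(∞) = ⟨d⟩_{C̄}/2E` could not
  hold. On regular graphs `ψ_k(m)φ_k(l)` is symmetric in (l, m), so
  entry and exit probabilities coincide at any truncation.
* The heterogeneity statistic takes the *population* SD (k divisor)
  across communities — the choice is immaterial at k = 100 but is fixed
  for reproducibility — and maximises it over the time grid.
* The default time grid is ~12 log-spaced integers from 1 to
  `2·floor(τ)` with `floor(τ)` always included and flagged; it is a
  documented default, not a canonical sampling.
* The step-time conversion rounds the per-step duration
  (`edge_length/speed`) to 2 decimal places *before* dividing the
  residence time, then floors: 10 µm / 13 µm·min⁻¹ → 0.77 min,
  720 min / 0.77 → 935 steps. Exact division would give 936; the
  rounded form is the only arithmetic consistent with both printed
  intermediate values of the worked T-cell example.

## Null-network generators

The generators' default parameters are the full-scale study conditions;
desk-scale fixtures pass smaller sizes through the same code paths.

* **HVor** — 31³ integer lattice centred at the origin; the 5185 points
  closest to the centre are kept (rank-based ball clipping, because the
  recipe fixes the count, not the radius; boundary ties break
  lexicographically on coordinates); each coordinate is jittered with
  seeded uniform noise in [−0.2, 0.2] lattice units — enough to make the
  tessellation generic (degree-4 Voronoi vertices) without erasing the
  grid character; 3D Voronoi tessellation; nodes = finite Voronoi
  vertices, edges = consecutive-vertex segments of each finite ridge
  polygon, deduplicated, with ridges touching the vertex at infinity
  discarded; thin to mean degree 2.8; largest component. A zero-noise
  lattice yields the degenerate degree-6 limit.
* **PVor** — identical from the tessellation step onward, with seeds
  drawn from two isotropic Gaussians: 10,000 points, sd 5, at the
  origin; 18,752 points, sd 1, at (5,5,5).
* **Random** — stub-matching configuration model on a constant degree-3
  sequence, simplified (self-loops and parallel edges removed), thinned,
  largest component.
* **rewire** — `ceil(fraction·E/2)` successful double-edge swaps
  ("fraction of edges touched": each swap rewires two edges — the
  phrase is ambiguous between swaps and edges, and this reading is
  documented as the package's convention), rejecting self-loops and
  duplicates, with a 100× attempt cap. Degree sequence, |V| and |E| are
  preserved exactly.

Thinning removes a seeded uniform-random permutation prefix of edges —
exactly the count that first brings `2E/N` to or below the target —
which is equivalent to one-at-a-time removal with a deterministic
stopping rule.

What the synthetic networks emulate: the quasi-regular degree profile
(mean degree 2.8, mode 3–4), the spatial coherence of a tessellation,
and (PVor) a polarised node density. What they do not: the biological
network's anisotropy along a long axis, its boundary effects, its exact
degree histogram, and any geometry-dependent walk biases — so passing
the ordering checks shows the *method* discriminates coherence and
polarity, not that any particular biological claim holds.

## Problem sizes and numerical choices

Desk-scale analyses use HVor at grid 13³/700 kept points and PVor at
250 + 470 seeds (≈4.2–4.5k nodes after thinning, preserving the full
recipes' clipping rule and 1:1.9 count ratio), a rank-64 embedding and
50 communities — large enough for stable seed-averaged orderings
(rewiring monotonicity of h̄; PVor > HVor SD maxima in ≥10 matched
seeds) while keeping a full workflow run at ~2 s. Dense-oracle
equivalence checks run at N ≤ 200 with K = N, where presence fields,
diffusion distances and entry/exit probabilities agree with dense `Tᵗ`
computations to 1e−8 for t ≤ 50. Full-scale defaults (K = 2000,
k = 100) are the intended production settings for ~200k-node networks;
the spectral model is serialised to `.npz` so the expensive
decomposition is computed once.

## Known limitations

* The Cheeger mixing index is reported per community against the rest of
  the graph; it is not the graph's Cheeger constant (no minimisation
  over node subsets).
* Heterogeneity comparisons between networks are ordinal (seed-averaged
  orderings), not hypothesis tests.
* k-means in a high-dimensional underflowed embedding can depend on the
  seed near symmetric optima; determinism is guaranteed per seed, and
  cross-network comparisons average over seeds.
* `truncation_error` needs a dense reference power and is deliberately
  capped at N ≤ 2000.
* The configuration model may be disconnected before extraction; the
  reported network is its giant component, whose mean degree can sit
  slightly above the thinning target.
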