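# diffwalk

Random-walk heterogeneity detection on large undirected networks.

`diffwalk` asks whether the connectivity pattern of a network biases the
collective exploration behaviour of random walkers — the motivating case
being naive T cells scanning a lymph-node conduit network (a ~200k-node,
quasi-regular 3D network of lymph pipes) for dendritic cells. Rather than
per-node statistics such as the global mean first-passage time, which do
not scale and do not delimit regions, the package compares walk-derived
features *between regions* of the network:

1. **Embed** the nodes in diffusion space. The transition matrix of the
   simple walk, `T = D⁻¹A`, has the biorthogonal eigensystem
   `T = Ψ Λ Φᵀ` with `ψ₀ = 1` and `φ₀ = d/2E`. The diffusion coordinates
   at time t are `X(t) = Ψ Λᵗ`; Euclidean distances between rows are
   diffusion distances (small when many short paths connect two nodes).
   For large N only the K largest-magnitude eigenpairs are kept, computed
   from the symmetrised operator `D⁻¹ᐟ²AD⁻¹ᐟ²`, giving the truncated
   operator `T_K^t = Ψ_K Λ_Kᵗ Φ_Kᵀ` with O(KN) evaluations.
2. **Cluster** the node point-cloud with k-means at the relaxation time
   `τ = 1/(1 − |λ₁|)` into k diffusion communities — groups of nodes
   whose walkers have correlated presence fields.
3. **Score** each community C with
   - the **Cheeger mixing index**
     `h(C) = cut(C, C̄) / min(vol C, vol C̄)` (low mean h̄ ⇒ the network
     is spatially coherent: diffusion-close nodes are also path-close);
   - the **mean entry/exit probabilities**
     `⟨p_in⟩_C(t) = (1/n_C n_C̄) Σ_{l∈C} Σ_{m∈C̄} Σ_k ψ_k(m) λ_kᵗ φ_k(l)`
     (and the transposed `⟨p_out⟩`), evaluated from per-community
     eigenvector sums without any dense matrix power.
4. **Compare**: the heterogeneity statistic is `max_t SD_C(⟨p_in⟩_C(t))`
   (and likewise for `⟨p_out⟩`), the across-community spread maximised
   over a time grid; communities with jointly low entry and exit
   probability at the biological scan time (935 steps for a 12 h T-cell
   residence at 13 µm/min over 10 µm edges) are "remote regions".

Because judging "high" or "low" needs a reference, the package ships
seeded null-network generators: a homogeneous Voronoi tessellation
(HVor), a polarised two-Gaussian Voronoi (PVor), a degree-3
configuration-model graph, and degree-preserving double-edge rewiring of
any graph — all thinned to a target mean degree (2.8 by default, the
conduit-network value).

## Worked example

```python
import diffwalk as dw

g = dw.homogeneous_voronoi(grid_side=13, noise=0.2, sphere_keep=700,
                           target_mean_degree=2.8, seed=1)
model = dw.DiffusionMap(n_components=64, random_state=1).fit(g)
tau = model.relaxation_time()
part = dw.detect_communities(model, k=50, seed=1)
grid = dw.make_time_grid(tau)
het = dw.heterogeneity(model, part, grid)
print(g.n_nodes, g.n_edges, round(g.mean_degree, 3))
print(round(tau, 1), round(dw.mean_cheeger(g, part), 4), f"{het.max_sd_pin:.2e}")
```

prints

```
4216 5959 2.827
388.1 0.1214 3.27e-05
```

i.e. a 4216-node homogeneous Voronoi network with mean degree 2.83 whose
walk relaxes in ≈388 steps; its 50 diffusion communities have a mean
Cheeger mixing index of 0.12 (spatially coherent — only ~12% of the
smaller side's edge volume crosses a community boundary) and a maximal
across-community SD of the entry probability of 3.3·10⁻⁵ per
source–target pair. Rewiring 20% of its edges roughly quadruples h̄, and
the polarised PVor network of the same size shows ~40% larger SD maxima —
the orderings that make "spatially coherent" and "heterogeneous"
quantitative.

The same pipeline runs from the shell:

```sh
diffwalk generate --model hvor --param grid_side=13 --param sphere_keep=700 \
    --param target_mean_degree=2.8 --seed 1 --out net/
diffwalk run --edges net/edges.tsv -K 64 --k 50 --seed 1 --out out/
```

writing `partition.csv`, `features.csv`, `heterogeneity.json`,
`summary.json`, a provenance log and the reusable spectral model
(`spectral_model.npz`). `diffwalk compare --config networks.yaml` runs
several networks and tabulates N, E, τ, h̄ and the SD maxima per row.

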