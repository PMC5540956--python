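# perconet

Percolation-based optimal sparsification for community detection in
weighted brain connectivity networks.

## The problem

Resting-state fMRI connectivity is usually analyzed as a weighted graph:
nodes are brain regions, edge weights are Pearson correlations between
regional BOLD time series. Before community detection the graph is
*sparsified* — the weakest edges, the ones most contaminated by noise, are
removed. Cutting too little leaves spurious edges that blur the modular
structure; cutting too much destroys genuine weak connections. `perconet`
implements a data-driven answer: **percolation analysis**. Sweeping the
edge-weight threshold t upward, the size of the giant connected component is
a non-increasing step function; the *percolation threshold*

> t\* = the highest threshold at which the giant component is still intact

marks the point where the network starts to fragment, and sits at a
quasi-optimal trade-off between noise removal and information loss.

The package ships the full synthetic validation chain needed to test this
claim against a known ground truth, aimed at methods researchers in network
neuroscience:

- **`lfr`** — weighted LFR benchmarks: power-law degrees (exponent τ_d) and
  community sizes (τ_c), with planted communities, topological mixing μ_t
  (per-node fraction of edges leaving the community) and weight mixing μ_w
  (same for strength), node strength s_i = k_i^β.
- **`simulate`** — planted adjacency → positive-definite target C (Higham
  projection) → Cholesky factor C = LL^T → per-subject node time series
  Y = LX + baseline with cov(Y) = C exactly → Rician noise at
  SNR = S̄/σ_N.
- **`connectivity`** — subject-level Pearson matrices, Fisher z-averaged
  (z = atanh r) into a group matrix, negative edges dropped.
- **`percolation`** — threshold sweeps, giant components, t\*.
- **`community`** — weighted Newman modularity
  Q = (1/2W) Σ_ij [w_ij − s_i s_j/2W] δ(c_i, c_j) maximized by Louvain;
  Asymptotical Surprise AS = W·D(q ‖ ⟨q⟩) (binomial divergence of the
  observed vs expected intracluster weight fraction under an Erdős–Rényi
  null) maximized by a PACO-style Kruskal-order agglomerator; InfoMap via
  the igraph backend.
- **`evaluation`** — NMI from the contingency table
  (−2 Σ N_ij ln(N_ij N / N_i·N_·j) normalized by the marginal entropies),
  plus sensitivity TP/(TP+FN) and specificity TN/(TN+FP) after
  biggest-overlap matching.
- **`pipeline` / CLI** — the two end-to-end protocols with replicates,
  threshold sweeps and tidy CSV reports.

## Worked example

```python
import perconet as pc

params = pc.LFRParams(n_nodes=150, avg_degree=12, max_degree=50,
                      min_community=5, max_community=50,
                      mixing_topology=0.2, mixing_weight=0.2, seed=11)
network, planted = pc.generate_lfr(params)
mu_t, mu_w = pc.empirical_mixing(network, planted)
print(f"benchmark: {network.n_nodes} nodes, {network.n_edges} edges, "
      f"{planted.n_communities} planted communities")
print(f"empirical mixing: mu_t={mu_t:.3f}, mu_w={mu_w:.3f}")

panel = pc.generate_cohort(network, n_subjects=10, n_timepoints=150,
                           snr=35.0, baseline=100.0, seed=1)
gnet = pc.group_to_network(pc.panel_to_group(panel))
print(f"group network: {gnet.n_edges} positive edges")

t_star = pc.percolation_threshold(gnet)
print(f"percolation threshold t* = {t_star:.4f}")

for t in (0.0, t_star):
    part = pc.louvain(pc.sparsify(gnet, t), seed=0)
    m = pc.evaluate(planted, part)
    print(f"louvain at t={t:.4f}: NMI={m.nmi:.3f}, "
          f"sensitivity={m.sensitivity:.3f}, specificity={m.specificity:.3f}")
```

Output:

```
benchmark: 150 nodes, 886 edges, 7 planted communities
empirical mixing: mu_t=0.197, mu_w=0.197
group network: 6890 positive edges
percolation threshold t* = 0.1284
louvain at t=0.0000: NMI=0.979, sensitivity=1.000, specificity=0.984
louvain at t=0.1284: NMI=1.000, sensitivity=1.000, specificity=1.000
```

The benchmark hits its nominal mixing (0.197 vs the requested 0.2). After
the noisy observational chain the unthresholded group network has ~6900
positive edges — mostly weak spurious correlations (the planted graph has
886). Thresholding at t\* = 0.128 removes them, and modularity maximization
recovers the planted 7-community structure exactly (NMI = 1), slightly
better than with no thresholding at all.

The same experiment from the shell:

```bash
perconet sim2 --preset scaled --out results/sim2      # N=150, 10 subjects
perconet sim2 --preset full --out results/sim2-full    # N=600, full protocol
```

which writes a tidy per-threshold CSV (replicate, method, threshold, nmi,
sensitivity, specificity, t_star) and a per-method summary (t\* band across
replicates, peak NMI, NMI at t\*). Per-stage subcommands (`generate-lfr`,
`simulate-cohort`, `build-connectivity`, `percolate`, `detect`, `evaluate`)
expose each step separately.

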