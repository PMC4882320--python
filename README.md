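# metabnet

Inter-subject **metabolic covariance brain-network analysis** for regional
FDG-PET data.

In resting FDG-PET, regions whose glucose metabolism rises and falls
together across subjects are functionally related.  `metabnet` turns a
subjects × regions table of mean regional metabolism into one network per
subject group and asks two questions: *is the network small-world?* and
*do two groups (e.g. patients vs. controls) differ in topology or in which
regions act as hubs?*  It is aimed at nuclear-medicine and neuroimaging
researchers who have ROI-level uptake tables (or NIfTI volumes plus a label
atlas) for two cohorts.

## Method

Nodes are the 90 cerebral regions of the AAL atlas (45 per hemisphere,
cerebellum excluded).  Per group:

1. **Normalize** — each subject's regional values are divided by that
   subject's whole-brain mean, removing global uptake scaling.
2. **Residualize** — per region, OLS residuals on age, sex and fasting
   glucose replace the values.
3. **Correlate** — the across-subject Pearson matrix R (90 × 90) is the
   group's covariance network.
4. **Binarize** — |r| is thresholded at a connection density *d* (the
   fraction of the N(N−1)/2 pairs kept as edges), swept over 10–40% in 1%
   steps since no single threshold is canonical.

Each binary graph is characterized by the mean clustering coefficient
C = (1/N) Σ Cᵢ with Cᵢ = 2eᵢ/(kᵢ(kᵢ−1)), the characteristic path length
L = (1/(N(N−1))) Σ Lᵢⱼ, and Freeman betweenness B(i) = Σ n_jk(i)/n_jk.
C and L are normalized by the means of 100 degree-preserving random
references (double edge swap): γ = C/C_random, λ = L/L_random, and the
small-world index **σ = γ/λ** (σ > 1 indicates small-world organization).
Normalized betweenness bᵢ = B(i)/mean(B) defines **hubs** as regions with
bᵢ > 1.5, summarized by their functional class (association / paralimbic /
subcortical / primary).

Group differences are assessed with a **group-relabeling permutation
test**: subjects are reassigned to pseudo-groups of the original sizes
1000 times, the entire pipeline is re-run each time, and the observed
difference is compared with the null distribution (95th-percentile
one-tailed critical values per direction; the primary flag uses the
doubled-min-tail empirical p, which holds the nominal level).

Because ROI-level PET cohorts are rarely shareable, the package ships a
synthetic cohort generator: a ring-rewired latent graph induces a
distance-decay correlation matrix, from which positive, globally scaled,
covariate-confounded "metabolism-like" panels are drawn — with the ground
truth returned for recovery tests.

## Worked example

```python
from metabnet import (CohortSpec, generate_cohort, pearson_matrix, density_threshold,
                      small_world, nodal_centrality, identify_hubs, load_region_table)
from metabnet.preprocess import preprocess

spec = CohortSpec(n_group_a=73, n_group_b=91, group_b_perturbation=0.2, seed=7)
panel_a, panel_b, truth = generate_cohort(spec, region_labels=load_region_table().labels)
table = load_region_table()
for tag, panel in (("A", panel_a), ("B", panel_b)):
    net = density_threshold(pearson_matrix(preprocess(panel)), 0.10)
    gm = small_world(net, n_random=100, seed=1, on_disconnected="connected_pairs")
    hubs = identify_hubs(nodal_centrality(net), table)
    print(f"group {tag}: sigma={gm.sigma:.2f} gamma={gm.gamma:.2f} lambda={gm.lambda_:.2f} "
          f"hubs={len(hubs)} top={hubs.entries[0][0].label} (b={hubs.entries[0][1]:.2f})")
```

prints

```
group A: sigma=3.57 gamma=3.97 lambda=1.11 hubs=21 top=DCG_L (b=4.57)
group B: sigma=2.42 gamma=2.52 lambda=1.04 hubs=14 top=IFGoperc_L (b=2.64)
```

Both simulated groups are clearly small-world (σ ≫ 1, driven by γ ≫ 1 with
λ ≈ 1, as expected for a ring-rewired latent topology), and group B — whose
latent graph had 20% of its edges rewired — shows lower clustering, a lower
small-world index and fewer betweenness hubs at the same 10% density.

The same stages are available from the shell (`metabnet simulate`,
`preprocess`, `network`, `metrics`, `permtest`, `run`); `metabnet run
--config config.json` executes everything and writes TSV/JSON artifacts
plus a deterministic `summary.json`.

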