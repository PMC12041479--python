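# mea-netpharm

Machine-learning analysis of drug-induced changes in neuronal network
activity recorded on microelectrode-array (MEA) biosensors.

Cultured neuronal networks on MEA chips fire spontaneously; neuroactive
compounds such as the GABA_A antagonist bicuculline reshape that activity
toward hypersynchronous, epileptiform firing.  This package implements a
complete workflow that detects such effects from paired pre/post-drug spike
recordings and characterizes them in interpretable, network-theoretic terms:

1. **Windowing** — each 600 s recording is cut into sliding windows
   (60/120/240 s, 0–75 % overlap) to augment the small number of chips.
2. **Functional connectivity** — spike trains are binary-binned (1/10/100 ms)
   and correlated pairwise (Pearson/Spearman/sparse canonical); the
   correlation matrix is thresholded at 0.5 into an undirected graph.
3. **Features** — 17 complex-network measures (density, transitivity, average
   shortest path length, betweenness, eigenvector centrality, degree-
   distribution entropy ED, second moment of the degree distribution
   SMD = ⟨k²⟩, complexity ⟨k²⟩/⟨k⟩, k-core, …), 8 community-structure
   measures (average path length of the largest community under eight
   community-detection algorithms), and the Spike-Contrast multivariate
   synchrony measure, giving 26 features per window.
4. **Classification** — features are standardized per chip against the
   pre-drug windows, then seven model families (SVM, RF, XGBoost, kNN,
   logistic regression, Gaussian naive Bayes, MLP) are evaluated by grouped
   leave-one-chip-out cross-validation; the model score is the lower bound of
   the bootstrap 95 % CI of the per-split AUCs.
5. **Interpretation** — Shapley-value feature attributions (exact subset
   enumeration or permutation sampling) rank features per model; a linear
   mixed model (`feature ~ condition + (1 | chip)`) validates each feature's
   drug effect while accounting for the repeated-measures window structure.

Because real drug-response MEA datasets are rarely public, the package ships
a first-class synthetic generator (`mea_netpharm.synthetic`) producing paired
pre/post-drug recordings — Poisson background firing plus jittered network
bursts, with per-chip random effects — whose "drug" condition has more,
tighter, better-attended bursts.  Every stage is tested against it.

## Worked example

```python
from mea_netpharm import (SynthConfig, generate_chip_pair, WindowSpec, segment,
                          bin_binary, build_graph, graph_features, spike_contrast)

pre, post = generate_chip_pair(SynthConfig(seed=1), chip_index=0)
window = segment(post, WindowSpec(window_s=240.0, overlap_pct=75.0))[0]
print(len(segment(post, WindowSpec(240.0, 75.0))))   # 7 windows per recording

s_max, _ = spike_contrast(window)
print(round(s_max, 3))                               # 0.636

graph = build_graph(bin_binary(window, 0.01), "pearson", threshold=0.5)
feats = graph_features(graph.adjacency, seed=0)
print(round(feats["density"], 4), round(feats["mean_degree"], 3))  # 0.0017 0.1
```

The post-drug window scores a Spike-Contrast synchrony of 0.636 (pre-drug
windows of the same chip sit near 0.32): the synthetic drug sharpens network
bursts.  At the 0.5 correlation threshold the 10 ms-binned graph is sparse
(density 0.0017), so for this generator most of the discriminative signal is
carried by synchrony rather than by graph topology — the classification
stage discovers exactly that via SHAP.

Full pipeline from the shell:

```bash
mea-netpharm synth --chips 9 --seed 42 --out data/
mea-netpharm run --input data/ --seed 42 --out report/
```

`report/` then contains `features.csv` (one row per chip × condition ×
window), per-model AUC tables, SHAP rankings, the model-similarity matrix,
and the mixed-model significance table (`lmm_table.csv`) with star codes
(`ns`, `*`, `**`, `***`, `****`).

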