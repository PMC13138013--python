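# nnet-csn — cell-specific coexpression networks from single-cell expression

Standard coexpression analysis of scRNA-seq averages over predefined cell
clusters and hides how gene-gene relationships change across cell states.
This package infers one weighted coexpression network **per cell** and
provides the downstream machinery to summarize, test, and annotate the
resulting network ensemble. It is aimed at computational biologists studying
gene-regulatory rewiring along differentiation, perturbation responses, and
receptor signaling in single-cell data.

## The model

Given a log-normalized cell × gene matrix **X**, a set of *response* genes
(typically TFs) and a set of *predictor* genes (typically known targets):

1. **Embedding.** PCA (centered, scaled) on the predictors gives scores
   **S** = X_std **V** with loadings **V**; the number of components comes
   from a scree-elbow rule (capped at 50). A low-rank reconstruction
   **X̂** of each response serves as the regression response.
2. **Neighborhoods.** A weighted KNN graph **W** of cells is built from
   geodesic (graph shortest-path) distances in PC space, k = 30 by default;
   weights shrink with distance via a Gaussian kernel with per-cell median
   bandwidth.
3. **Local PC regression.** Within each cell *n*'s neighborhood, each
   response *p* is fit by weighted ridge regression (penalty λ = 0.5)
   of X̂_·p on **S**, giving coefficients β̂_np·.
4. **Coexpression = analytic permutation feature importance.** The
   coexpression of predictor *q* with response *p* in cell *n* is

   CSN_npq = 2 · Var(X_·q) · ( Σ_r β̂_npr V_qr / ‖V_q·‖ )²

   with Var(X_·q) the weighted local variance of *q* in the neighborhood.
   Stacking all cells yields the cells × responses × predictors ensemble.
5. **Smoothing and significance.** The ensemble is smoothed with a random
   walk operator from **W**; a neighborhood-shuffle null yields per-edge
   Wald-type z statistics mapped to scores in [0, 1].
6. **Downstream.** Nonnegative-PCA factorization of the ensemble gives soft
   cell clusters and meta-networks (Meta-Network_i = Σ_n CSN_n·· H_ni) or
   gene modules; personalized PageRank on a signaling prior network scores
   receptor activity over pruned networks and reconstructs upstream
   signaling paths; TF activity is scored from expression or coexpression
   profiles by rank-AUC or univariate-regression t-values.

## Worked example

```python
import numpy as np
import nnet

# 300 cells, 3 populations, one planted TF-target module per population
expr, truth = nnet.simulate_modules(n_cells=300, n_genes=120, n_populations=3, seed=0)

est = nnet.NeighbourNet(
    responses=truth.tf_genes, predictors=truth.predictor_genes, random_state=0
)
est.fit(expr)
smoothed = est.smooth()
print("ensemble shape:", smoothed.shape)

tf, target = truth.modules[0]["tf"], truth.modules[0]["targets"][0]
i = smoothed.response_ids.index(tf)
j = smoothed.predictor_ids.index(target)
active = truth.labels == truth.modules[0]["population"]
print(f"mean coexpression {tf}->{target}: "
      f"active {smoothed.coexpression[active, i, j].mean():.4f}, "
      f"elsewhere {smoothed.coexpression[~active, i, j].mean():.4f}")

clusters = nnet.soft_clusters(smoothed, n_components=3, seed=0)
nets = nnet.meta_networks(smoothed, clusters)
```

This prints:

```
ensemble shape: (300, 3, 117)
mean coexpression TF01->M01_T01: active 0.0116, elsewhere 0.0030
```

The planted edge carries ~4× more coexpression inside its population than
elsewhere. Ranking cells by the soft-cluster weights shows each meta-network
concentrating on one population, and the SVD centrality of each meta-network
recovers that population's module TF as its most central response:

```
meta-network 1: top-50 cells 66% from population 2, central TF TF03
meta-network 2: top-50 cells 100% from population 1, central TF TF02
meta-network 3: top-50 cells 100% from population 0, central TF TF01
```

A command-line interface mirrors the library
(`nnet simulate | preprocess | regress | significance | factorize | annotate |
activity`); every subcommand writes a JSON provenance block next to its
output.

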