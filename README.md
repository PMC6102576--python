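# rmvspc

Regularized multi-view sparse subspace clustering for discovering **common
gene modules** across cancer stages.

Gene-expression studies of cancer progression produce one expression matrix
per clinical stage.  Genes that stay co-expressed in *every* stage — common
modules — are candidate progression machinery and useful classification
features, but stage-by-stage clustering fragments them and expression alone
ignores what is known about physical gene interactions.  This package
addresses both problems for computational biologists working with staged
expression data plus a protein–protein interaction (PPI) network.

## Model

Each stage's matrix `X_s` (samples × genes) gets a sparse
self-representation `X_s ≈ X_s C_s`, `diag(C_s) = 0`; the per-stage
matrices are pulled toward one consensus `C`, which is smoothed over the
PPI network through its graph Laplacian `L = D − A`:

```
min  Σ_s [ ‖C_s‖₁ + (λ_z/2)‖X_s − X_s C_s‖_F² + (λ_c/2)‖C_s − C‖_F² ]
     + λ_G tr(C′ L C)        s.t. diag(C_s) = 0
```

The jointly convex problem is solved by exact alternating minimization
(column-wise lasso for each `C_s`, a Cholesky solve for `C`).  Modules come
from normalized spectral clustering of the affinity
`W = |C_norm| + |C_norm|′`.  Evaluation tools include normalized mutual
information (NMI) against a reference partition, a permutation test of
module co-expression with Benjamini–Hochberg correction, and per-sample
module-activity features for downstream classifiers.  A built-in generator
reproduces the classical 128-node / 4-community planted-partition benchmark
(three coupled graphs: two data views plus one regularization network).

## Worked example

Generate a benchmark instance (view mixing `z_out = 3`, regularization
network at `z_out = 6`), fit, cluster, and score:

```sh
rmvspc benchmark --zout-views 3 --zout-reg 6 --seed 7 --out bench
rmvspc fit --views bench/view1.tsv --views bench/view2.tsv \
           --network bench/network.tsv --lam 1.0 --k 4 --out fit_out
rmvspc modules --consensus fit_out/consensus.tsv --k 4 --seed 0 --out modules.tsv
rmvspc evaluate --modules modules.tsv --truth bench/truth.tsv
```

prints

```
NMI	1.000000
```

i.e. the four planted 32-gene communities are recovered exactly; the fit
converged in 3 outer iterations (see `fit_out/manifest.json` and
`fit_out/objective_trace.tsv`).  A sweep over harder mixing levels:

```sh
rmvspc sweep --zout 5 --zout 6 --lam 1.0 --n-seeds 3 --out sweep.tsv
```

```
 z_out  lambda  mean  std
     5     1.0   1.0  0.0
     6     1.0   1.0  0.0
```

where `mean`/`std` summarize NMI against the planted partition over seeds;
the per-run table lands in `sweep.tsv`.  For real data, supply per-stage
expression TSVs (header = gene ids, one row per sample) and a two-column
edge list, e.g.
`rmvspc run --config study.cfg` with a flat `key = value` config naming
`views`, `network`, `k`, `out` (optional `lam`, `seed`, `significance`,
`features`).

Library use mirrors the CLI:

```python
from rmvspc import build_benchmark, fit, detect_modules, nmi, HyperParams

bench = build_benchmark(z_out_views=3, z_out_reg=6, seed=7)
rep = fit(bench.views, bench.reg_network, HyperParams.equal(1.0, k=4))
part = detect_modules(rep.consensus, k=4, seed=0)
print(nmi(part, bench.truth))   # 1.0
```

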