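# ancut — assisted normalized-cut clustering of gene expression

Clustering gene expression profiles is a staple of transcriptomics, but with
few samples and many genes the similarity structure in expression alone is
often too weak to cluster well.  Modern profiling studies measure expression
*and* its DNA-level regulators — copy-number alterations, methylation,
microRNA — on the same samples.  This package implements **assisted
normalized-cut clustering (ANCut)**: it borrows the regulators' information
to sharpen the clustering of the genes.

The method has two stages:

1. **Regulation model.** Expression is regressed on the regulators with a
   per-gene elastic net,

   β̂ = argmin ‖Y − Xβᵀ‖² + λ(α‖β‖₁ + (1−α)‖β‖²),

   with (λ, α) chosen by V-fold cross-validation over a geometric λ path.
   The fitted, regulator-predicted component Ŷ = Xβ̂ᵀ isolates the part of
   expression explained by the measured regulators; Y − Ŷ keeps everything
   else (unmeasured regulation, noise).

2. **Assisted graph cut.** With inverse-Euclidean-distance gene similarities
   W (from observed Y) and Ŵ (from predicted Ŷ), the partition A₁…A_K of
   genes minimizes

   ANCut(A₁…A_K) = Σₖ cut(A_k, A_kᶜ; W) / cutvol(A_k; Ŵ),

   i.e. cross-cluster similarity in observed expression normalized by
   within-cluster similarity in the regulated component.  The minimization
   runs by simulated annealing with logarithmic cooling, followed by a local
   descent polish.  NCut (the unassisted special case Ŵ = W), K-means,
   spectral clustering, augmented K-means, accuracy/stability metrics, a
   gap-statistic chooser for K, and a synthetic-data generator with a
   planted two-cluster structure round out the toolkit.

The estimators follow scikit-learn conventions (`fit`, `fit_predict`,
`get_params`, trailing-underscore attributes).

## Worked example

```python
import numpy as np
from ancut import ANCut, accuracy_measure, make_toy_example

data = make_toy_example(seed=3)          # 10 genes, 10 regulators, 2 clusters
est = ANCut(n_clusters=2, random_state=1).fit(data.Y, regulators=data.X)
print("selected lambda = %.3f, alpha = %.2f" % (est.lambda_, est.alpha_))
print("best assisted objective = %.4f" % est.best_objective_)
print("labels:", est.labels_)
print("accuracy vs truth = %.2f" % accuracy_measure(data.true_labels, est.labels_))
```

prints

```
selected lambda = 2.001, alpha = 0.50
best assisted objective = 1.9102
labels: [0 0 0 0 0 1 1 1 1 1]
accuracy vs truth = 0.00
```

The cross-validated elastic net kept a moderate penalty (λ ≈ 2 at the fixed
software-default mixing α = 0.5), the annealer drove the assisted objective
to 1.91, and the recovered labels split the ten genes exactly into the two
planted clusters — an accuracy measure (normalized co-clustering
disagreement) of 0, i.e. perfect recovery.

The same pipeline is available from the shell:

```bash
ancut simulate --n 100 --p 100 --q 50 --q0 50 --rho 0.1 --h 0.1 -o data/
ancut cluster -y data/expression.csv -x data/regulators.csv -k 2 -o run/
ancut select-k -y data/expression.csv --k-max 8
ancut experiment --config cell.txt --methods ancut,ncut,kmeans --n-reps 10 -o exp/
```

Matrices are delimited text with a header row of feature ids and a leading
sample-id column; every run writes a key=value config echo sufficient to
reproduce it exactly.

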