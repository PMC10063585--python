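# wsdmgc — weakly supervised deep-metric graph clustering

`wsdmgc` discovers subtypes among small grayscale image patches (for
example 32×32 CT nodule crops) when only a small fraction of the samples
— typically 0.5–10% — carry class labels. It combines three ingredients:

1. **A metric-embedding network.** A small convolutional network f(·)
   maps each patch onto the unit sphere in R^d, trained with a hinged
   triplet loss under online *batch-hard* mining — within each
   mini-batch, every anchor x_a is paired with its farthest same-class
   sample x_p and its nearest other-class sample x_n:

       L_M = mean over triplets of  max( ‖f(x_a)−f(x_p)‖² − ‖f(x_a)−f(x_n)‖² + α, 0 )

   A linear softmax head q(f(x)) on the embedding is trained jointly,
   giving the total objective

       L = L_M + λ₁·L_C + λ₂·‖W‖²_F ,

   with L_C the cross-entropy of the head and ‖W‖²_F the squared
   Frobenius norm of all weight tensors. Defaults: λ₁ = 0.6, λ₂ = 0.04.

2. **Supervision-constrained spectral clustering.** A similarity graph
   over all samples combines a Gaussian kernel on embedding distances
   with hard constraints:

       w_ij = 1                          both labeled, same class
       w_ij = 0                          both labeled, different class
       w_ij = exp(−‖x_i−x_j‖²/2σ²)       otherwise

   Samples are embedded in the k eigenvectors of the unnormalised
   Laplacian L = D − W with smallest eigenvalues and partitioned with
   seeded k-means.

3. **Iterative label propagation.** Each unlabeled sample gets a weak
   classifier label L¹ and a cluster label L² (clusters aligned to
   classes on the labeled samples). Samples where the two agree are
   promoted to strong labels (ΔS = {u : L¹_u = L²_u}); additionally the
   S unlabeled samples nearest each cluster's labeled centroid are
   promoted with the cluster's class. The embedder is then retrained on
   the grown labeled set, and the loop repeats until no unlabeled
   samples remain.

Everything runs on plain NumPy/SciPy/scikit-learn — no GPU or deep
learning framework required — and every source of randomness flows from
one integer seed.

## Worked example

A fully synthetic experiment: render 5 clusters of 200 nodule-like
phantom patches, hide 90% of the labels, and run the pipeline.

```python
from wsdmgc import PhantomSpec, WSDMGC, generate_phantom_dataset, mask_labels

dataset = generate_phantom_dataset(
    PhantomSpec(n_clusters=5, per_cluster=200, separation=3.0, seed=0))
weak = mask_labels(dataset, fraction=0.10, seed=0)   # 20 labels per class

results = WSDMGC(weak, seed=0).fit()
print(results.summary())
```

which prints:

```
WS-DMGC results
==============================================
samples                                   1000
classes / clusters                  5        5
initially labeled                          100
outer iterations                             2
converged                                 True
lambda1 / lambda2                 0.6     0.04
triplet margin alpha                         1
seed                                         0
----------------------------------------------
labels from agreement                      896
labels from initial                        100
labels from knn                              4
----------------------------------------------
purity                                  0.9780
best-map accuracy                       0.9780
NMI                                     0.9316
mean silhouette                         0.6688
```

Reading the output: starting from 100 labeled samples the loop promoted
896 samples because their classifier and spectral-cluster labels agreed,
and 4 more through the nearest-to-centroid update; against the
generator's hidden truth the final partition matches 97.8% of samples
(after the optimal cluster-to-class assignment) with normalised mutual
information 0.93. `results.to_frame()` gives per-sample labels with
their provenance, `results.history` the per-iteration growth of the
labeled set, and `results.save(out_dir)` writes `labels.csv` and
`report.json`.

The same pipeline is available from the shell:

```bash
wsdmgc synth --spec spec.yaml --out data/ --labeled-fraction 0.1
wsdmgc run --data data/ --table data/samples.csv --out results/ --seed 0
wsdmgc evaluate --pred results/labels.csv --truth data/samples.csv
```

with `train`, `cluster` and `sweep-k` subcommands for the individual
stages, and `--loss contrastive` / `--no-propagation` / `--no-hinge`
flags for the ablation variants.

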