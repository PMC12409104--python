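# fedipca

A seeded, in-process simulator of **adaptive federated learning for
multi-site 3D medical-image classification**, built around three components:

1. **Federated incremental PCA (FIPCA).** Each site flattens its masked 3D
   volumes into voxel-intensity vectors and sends only its sample count
   `N_i`, mean `μ_i` and scatter matrix `S_i` to the server. The server
   aggregates

   `μ = Σ N_i μ_i / Σ N_i`,  `S = Σ S_i + Σ N_i (μ_i − μ)(μ_i − μ)ᵀ`,

   normalizes `Cov = S / N_total`, and eigendecomposes it into the top-`k`
   orthonormal basis `W ∈ R^{d×k}`. Every site — including held-out
   inference-only sites that contributed no statistics — projects its data
   as `(X − μ) W`. No per-case data ever crosses sites, and the federated
   result equals a centralized PCA of the pooled data exactly.

2. **Imbalance-aware client training.** A small dense network
   (128→BN→ReLU, 64→BN→ReLU, dropout 0.5, 2-unit softmax) trained with
   Adam on

   `L = L_CE + λ_FN·y(1−p) + λ_FP·(1−y)p + λ_AUC·(p−y)²`,  λ = (2, 1, 0.1),

   with balanced inverse-frequency class weights, a round-indexed staircase
   learning-rate decay (every 25 rounds), and per-round early stopping on
   validation loss (patience 5 epochs).

3. **Adaptive server control.** Accuracy-weighted aggregation
   `w = Σ n_k a_k w_k / Σ n_k a_k`, aggregated validation loss
   `L_t = Σ n_val,k L_k / Σ n_val,k`, and an early-stopping controller with
   patience/tolerance/delta/minimum-rounds that halts the federation once
   improvements plateau. Disabling the controller and forcing sample
   weighting yields standard FedAvg.

A synthetic-data module generates multi-site cohorts with the non-IID
structure this method targets — site-specific gray-value baselines (scanner
shift), site-specific positive-class prevalence, and lesion blobs in
positive cases — written as NIfTI volumes plus CSV manifests, so the same
pipeline can be pointed at real data.

Who is this for: researchers prototyping federated pipelines for
cross-institution imaging studies who need a fully deterministic, desk-scale
testbed for scatter-matrix aggregation, heterogeneity diagnostics and
adaptive federation control, without a networking stack.

## Worked example

```python
import numpy as np
from fedipca import (FederatedPCA, FederatedClient, FLConfig, ClientConfig,
                     run_federated_training, roc_auc)
from fedipca.pipeline import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(arms=("adaptive", "fedavg_fixed")))

for arm, res in report["arms"].items():
    ev = res["evaluation"]
    print(f"{arm}: rounds={res['rounds_used']} AUC={ev['auc']:.3f} "
          f"CI=({ev['auc_ci95'][0]:.3f}, {ev['auc_ci95'][1]:.3f})")
for pair in report["site_distances"]:
    print(pair["pair"], f"distance cut {pair['percent_reduction']:.1f}%")
print(f"variance retained: {report['fipca']['variance_retained']:.3f}")
```

prints (one platform, default seed 12345):

```
adaptive: rounds=20 AUC=0.945 CI=(0.902, 0.979)
fedavg_fixed: rounds=200 AUC=0.631 CI=(0.552, 0.707)
['site_a', 'site_b'] distance cut 87.9%
['site_a', 'site_c'] distance cut 87.8%
['site_b', 'site_c'] distance cut 87.7%
variance retained: 0.695
```

Reading: the adaptive arm (FIPCA features, accuracy-weighted aggregation,
server early stopping) converged in 20 rounds and generalizes to the
held-out site far better than the fixed 200-round FedAvg baseline trained on
raw voxel features; projecting onto the 10-component global basis cut the
between-site centroid separation (relative to within-site variability) by
~88% while keeping ~70% of the total variance.

The same pipeline is scriptable from the shell:

```bash
fedipca simulate --out-dir scratch/data             # write NIfTI cohorts
fedipca train --out-dir scratch/run --seed 12345    # adaptive arm
fedipca ablate --out-dir scratch/ablation           # all five arms
fedipca pc-sweep --k-values 1,2,5,10,20,50 --out-dir scratch/sweep
```

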