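# trustomics

Trustworthy multi-omics classification for diagnostic prediction: build a
co-expression graph per omics type, encode each subject with a multi-level
graph-attention network, turn each omics' output into Dirichlet evidence
with an explicit uncertainty mass, and fuse omics at the decision level by
Dempster–Shafer combination. The result is a classifier that reports not
just a label but *how much* each modality — and the fused decision —
actually knows, plus a feature-ablation biomarker ranking.

## Who this is for

Computational biologists integrating matched omics blocks (e.g. mRNA
expression, DNA methylation, miRNA) over the same subjects for disease
classification, who need (1) fusion that discounts unreliable modalities
instead of averaging them in, (2) per-subject uncertainty that responds to
data quality, and (3) ranked candidate biomarkers from the fitted model.

## The model

For each omics, features become nodes of a signed weighted co-expression
network, `A_ij = ((1 + r_ij)/2)^β` with `r_ij` the Pearson correlation over
training subjects, binarized at a threshold (default 0.08) into a shared
edge matrix; each subject's graph puts their scaled feature values on the
nodes. Two multi-head graph-attention layers (attention
`softmax_j LeakyReLU(a^T[W h_i ‖ W h_j])`) build representations G1 and G2
from the raw values G0; the concatenated levels feed an evidence head
emitting `e_k ≥ 0` per class. Subjective logic turns evidence into an
opinion — beliefs `b_k = e_k/S` and uncertainty `u = K/S` with
`S = Σ(e_k + 1)` — and opinions fuse across omics by

    b_k^F = (b_k^1 b_k^2 + b_k^1 u^2 + b_k^2 u^1)/(1 − C),
    u^F = u^1 u^2/(1 − C),   C = Σ_{i≠j} b_i^1 b_j^2.

Training minimizes the evidential cross-entropy
`Σ_k y_k (ψ(S) − ψ(α_k))` plus an annealed KL regularizer toward the
uniform Dirichlet on the fused and per-omics opinions, plus per-omics
softmax cross-entropies (γ = 1). Details and design decisions:
[docs/methods.md](docs/methods.md).

The package includes a synthetic multi-omics generator with planted
correlated modules and class signal, so every stage is testable without
external cohort downloads.

## Worked example

```bash
python examples/train_and_evaluate.py
```

trains on a synthetic cohort (3 omics × 50 features, 300 subjects, 3
classes, 5 informative features per omics at effect size 1.5) and prints:

```
held-out metrics: {'acc': 1.0, 'f1_weighted': 1.0, 'f1_macro': 1.0}
single-omics accuracy: {'mrna': 0.778, 'methylation': 0.8, 'mirna': 0.822}
stopped at epoch 105, best validation epoch 75
```

The fused accuracy (1.0 on this seed's 45 held-out subjects) exceeds every
single modality: the combination rule concentrates belief where modalities
agree and discounts the uncertain ones. The other example scripts follow
the same pattern: `fuse_opinions.py` (the opinion algebra on one subject),
`simulate_cohort.py` (the generator's planted structure),
`robustness.py` (accuracy and uncertainty under progressive masking of one
modality), `biomarkers.py` (ablation-ranked features vs the planted
truth).

A thin CLI wraps the same library calls:

```bash
trustomics simulate --seed 7 --out data/
trustomics run --config run.yaml
trustomics explain --checkpoint out/run.pkl --data data/
```

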