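"""Train the full multi-omics evidential classifier on a synthetic cohort.

Runs the complete pipeline: stratified split, per-omics preprocessing
([0,1] scaling fitted on training subjects), co-expression network
construction, multi-level GAT training under the global evidential
objective, and held-out evaluation — then compares the fused accuracy with
what each omics achieves alone.
"""

from trustomics import pipeline, simdata
from trustomics.encoder import EncoderConfig

spec = simdata.SimSpec(seed=0)
blocks, labels = simdata.generate_cohort(spec)

config = pipeline.RunConfig(
    seed=0, n_classes=3, epochs=200, patience=30, weight_decay=0.0,
    encoder=EncoderConfig(n_heads=2, hidden=4, head_hidden=32, dropout=0.0))
run = pipeline.train(blocks, labels, config)

report = pipeline.evaluate_run(run, blocks, labels)
single = pipeline.single_omics_metrics(run, blocks, labels)
print(f"held-out metrics: {report.as_dict()}")
print(f"single-omics accuracy: { {k: round(v, 3) for k, v in single.items()} }")
print(f"stopped at epoch {run.training_log.epoch.iloc[-1]}, "
      f"best validation epoch {run.training_log.attrs['best_epoch']}")

# Expected: fused held-out accuracy around 0.95-1.0 (1.0 on this seed),
# clearly above every single modality (0.78-0.82) — the Dempster-Shafer
# combination concentrates belief where modalities agree and discounts
# the uncertain ones.
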