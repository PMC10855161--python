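"""End-to-end training, evaluation and the masking-robustness protocol.

A run takes raw per-omics matrices plus labels and proceeds strictly
leak-free: subjects are split (stratified train/val/test) first; feature
filtering, ANOVA preselection, [0, 1] scaling and the co-expression edge
matrix are all fitted on training subjects only and frozen before any
held-out subject is touched.  Training optimizes the global evidential
objective end-to-end with Adam, keeping the parameters of the best
validation-accuracy epoch.

The robustness protocol masks a growing fraction of one modality's test
features and tracks two signals: the accuracy-reduction ratio
(ACC_full - ACC_masked) / ACC_full, and the mean subjective-logic
uncertainty u of the masked modality — a trustworthy fusion should both
degrade gracefully and *know* that the masked modality became unreliable.
"""

from __future__ import annotations

import json
import pathlib
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import train_test_split

from . import netbuild, objective, preprocess, simdata
from .encoder import EncoderConfig
from .model import MultiOmicsModel
from .nn import Adam
from .objective import LossConfig


@dataclass
class RunConfig:
    """Everything one experiment needs."""

    seed: int = 0
    n_classes: int = 2
    split: tuple = (0.7, 0.15, 0.15)
    epochs: int = 200
    patience: int = 25
    lr: float = 2e-2
    weight_decay: float = 1e-4
    anova_k: int | None = None
    beta: float | str = 6.0
    threshold: float = netbuild.DEFAULT_THRESHOLD
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    loss: LossConfig | None = None
    mask_ratios: tuple = (0.0, 0.2, 0.4, 0.6, 0.8)

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss is None:
            self.loss = LossConfig(n_classes=self.n_classes)


@dataclass
class MetricReport:
    """Metric set appropriate to the class count.

    Binary tasks report ACC / F1 / AUC; multi-class tasks report
    ACC / weighted F1 / macro F1 (multi-class AUC is deliberately not
    reported).
    """

    acc: float
    f1: float | None = None
    auc: float | None = None
    f1_weighted: float | None = None
    f1_macro: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def stratified_split(labels, fractions, seed: int):
    """Index arrays (train, val, test), stratified by class."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    f_train, f_val, f_test = fractions
    train, rest = train_test_split(
        idx, test_size=f_val + f_test, stratify=labels, random_state=seed)
    val, test = train_test_split(
        rest, test_size=f_test / (f_val + f_test), stratify=labels[rest],
        random_state=seed + 1)
    return np.sort(train), np.sort(val), np.sort(test)


@dataclass
class FittedRun:
    """A trained model plus the frozen preprocessing/network state."""

    model: MultiOmicsModel
    preprocessors: list
    networks: list
    config: RunConfig
    split_indices: tuple
    training_log: pd.DataFrame

    def transform(self, blocks):
        """Apply the frozen per-omics preprocessing to raw matrices."""
        return [fp.transform(x) for fp, x in zip(self.preprocessors, blocks)]

    def predict_matrices(self, processed_blocks):
        return self.model.predict([x.values for x in processed_blocks])


def evaluate(labels_true, labels_pred, probabilities=None,
             n_classes: int | None = None) -> MetricReport:
    """Compute the metric set for one prediction batch."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    k = n_classes or int(max(labels_true.max(), labels_pred.max())) + 1
    acc = float(accuracy_score(labels_true, labels_pred))
    if k == 2:
        auc = None
        if probabilities is not None and len(np.unique(labels_true)) == 2:
            auc = float(roc_auc_score(labels_true, probabilities[:, 1]))
        return MetricReport(acc=acc,
                            f1=float(f1_score(labels_true, labels_pred)),
                            auc=auc)
    return MetricReport(
        acc=acc,
        f1_weighted=float(f1_score(labels_true, labels_pred,
                                   average="weighted")),
        f1_macro=float(f1_score(labels_true, labels_pred, average="macro")))


def train(blocks, labels, config: RunConfig, verbose: bool = False):
    """Fit the full pipeline on raw omics blocks; returns a FittedRun.

    ``blocks`` is a list of raw OmicsMatrix sharing subject order with
    ``labels``.  Deterministic given ``config.seed``.
    """
    labels = np.asarray(labels)
    tr, va, te = stratified_split(labels, config.split, config.seed)
    ids = list(blocks[0].subject_ids)
    tr_ids = [ids[i] for i in tr]

    processed, preprocessors, networks = [], [], []
    for x in blocks:
        xt, fp = preprocess.fit_preprocess(
            x, labels[tr], tr_ids, k=config.anova_k)
        net = netbuild.build_network(
            xt.subset_subjects(tr_ids), beta=config.beta,
            threshold=config.threshold)
        processed.append(xt)
        preprocessors.append(fp)
        networks.append(net)

    model = MultiOmicsModel(
        omics_names=[x.omics_name for x in blocks],
        edge_matrices=[n.edge_matrix for n in networks],
        n_classes=config.n_classes, config=config.encoder, seed=config.seed)

    xtr = [x.values[tr] for x in processed]
    xva = [x.values[va] for x in processed]
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    drop_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]))

    best_acc, best_state, best_epoch, stale = -1.0, None, -1, 0
    rows = []
    for epoch in range(config.epochs):
        fused_alpha, per_alphas, logits, _, _ = model.forward(
            xtr, training=True, rng=drop_rng)
        breakdown = objective.global_loss(
            fused_alpha, per_alphas, logits, labels[tr], config.loss,
            epoch=epoch)
        if not np.isfinite(breakdown.total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {breakdown.as_dict()}")
        opt.zero_grad()
        breakdown.node.backward()
        opt.step()

        pred_va, _, _ = model.predict(xva)
        val_acc = float(accuracy_score(labels[va], pred_va))
        rows.append({"epoch": epoch, "total": breakdown.total,
                     "fused": breakdown.fused_loss,
                     "lambda_t": breakdown.lambda_t,
                     "val_acc": val_acc,
                     **{f"omics{m}": v for m, v in
                        enumerate(breakdown.per_omics_losses)},
                     **{f"gat_ce{m}": v for m, v in
                        enumerate(breakdown.gat_ce)}})
        if val_acc > best_acc:
            best_acc, best_state, best_epoch, stale = \
                val_acc, model.state_dict(), epoch, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch:3d}  loss {breakdown.total:.4f}  "
                  f"val_acc {val_acc:.3f}")

    if best_state is not None:
        model.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best_epoch
    return FittedRun(model=model, preprocessors=preprocessors,
                     networks=networks, config=config,
                     split_indices=(tr, va, te), training_log=log)


def evaluate_run(run: FittedRun, blocks, labels,
                 indices=None) -> MetricReport:
    """Evaluate a fitted run on a subject subset (default: its test split)."""
    labels = np.asarray(labels)
    if indices is None:
        indices = run.split_indices[2]
    processed = run.transform(blocks)
    values = [x.values[indices] for x in processed]
    pred, probs, _ = run.model.predict(values)
    return evaluate(labels[indices], pred, probs,
                    n_classes=run.config.n_classes)


def single_omics_metrics(run: FittedRun, blocks, labels, indices=None):
    """Per-omics accuracy from each modality's own opinion (no refit)."""
    labels = np.asarray(labels)
    if indices is None:
        indices = run.split_indices[2]
    processed = run.transform(blocks)
    values = [x.values[indices] for x in processed]
    out = {}
    for name, (b, _) in zip(run.model.omics_names,
                            run.model.per_omics_opinions(values)):
        out[name] = float(accuracy_score(labels[indices],
                                         np.argmax(b, axis=-1)))
    return out


def robustness_curve(run: FittedRun, blocks, labels, mask_omics: int,
                     ratios=None, seeds=(0, 1, 2)) -> pd.DataFrame:
    """Accuracy-reduction and uncertainty vs masked ratio of one modality.

    For each ratio r, ``floor(r * d)`` feature columns of the chosen
    modality's *test* matrix are zeroed (scaled minimum), predictions are
    recomputed, and the table records the reduction ratio
    (ACC_full - ACC_masked) / ACC_full plus the masked modality's mean
    subjective-logic uncertainty, averaged over masking seeds.
    """
    labels = np.asarray(labels)
    if ratios is None:
        ratios = run.config.mask_ratios
    te = run.split_indices[2]
    processed = run.transform(blocks)
    test_blocks = [x.subset_subjects([blocks[0].subject_ids[i] for i in te])
                   for x in processed]
    base_values = [x.values for x in test_blocks]
    pred, _, _ = run.model.predict(base_values)
    acc_full = float(accuracy_score(labels[te], pred))
    rows = []
    for ratio in ratios:
        accs, mean_us = [], []
        for seed in seeds:
            masked = simdata.mask_modality(
                test_blocks[mask_omics], ratio, seed=seed)
            values = list(base_values)
            values[mask_omics] = masked.values
            pred, _, _ = run.model.predict(values)
            accs.append(float(accuracy_score(labels[te], pred)))
            _, u = run.model.per_omics_opinions(values)[mask_omics]
            mean_us.append(float(u.mean()))
        acc_masked = float(np.mean(accs))
        rows.append({"ratio": float(ratio), "acc_masked": acc_masked,
                     "acc_full": acc_full,
                     "reduction": (acc_full - acc_masked) / acc_full
                     if acc_full > 0 else 0.0,
                     "mean_uncertainty": float(np.mean(mean_us))})
    return pd.DataFrame(rows)


def run_experiment(blocks, labels, config: RunConfig, out_dir,
                   robustness_omics: int | None = None) -> dict:
    """Train, evaluate, optionally probe robustness; archive everything.

    Writes metrics.json, training_log.csv, uncertainty.json, the model
    checkpoint, and robustness.tsv when a modality index is given.
    Reruns with the same config reproduce metrics.json bit-for-bit.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = train(blocks, labels, config)
    report = evaluate_run(run, blocks, labels)
    metrics = {"test": report.as_dict(),
               "single_omics_acc": single_omics_metrics(run, blocks, labels),
               "best_epoch": int(run.training_log.attrs["best_epoch"]),
               "seed": config.seed}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1,
                                                 sort_keys=True))
    run.training_log.to_csv(out / "training_log.csv", index=False)
    run.model.save(out / "model.ckpt")
    with open(out / "run.pkl", "wb") as fh:
        pickle.dump(run, fh)

    te = run.split_indices[2]
    processed = run.transform(blocks)
    reports = run.model.subject_reports(
        [x.values[te] for x in processed],
        [blocks[0].subject_ids[i] for i in te])
    (out / "uncertainty.json").write_text(json.dumps(
        {"reduction_definition": "(acc_full - acc_masked) / acc_full",
         "subjects": [r.as_dict() for r in reports]}, indent=1))

    if robustness_omics is not None:
        curve = robustness_curve(run, blocks, labels, robustness_omics)
        curve.to_csv(out / "robustness.tsv", sep="\t", index=False)
        metrics["robustness"] = curve.to_dict(orient="records")
    return metrics


def summarize_seeds(reports: list) -> dict:
    """mean ± SD aggregation of MetricReports across seeds."""
    keys = set().union(*(r.as_dict() for r in reports))
    out = {}
    for k in sorted(keys):
        vals = [r.as_dict()[k] for r in reports if k in r.as_dict()]
        out[k] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals)),
                  "per_seed": [float(v) for v in vals]}
    return out
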