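"""Global feature-ablation biomarker importance.

Importance of a feature is the drop in test-set performance when that
feature's (already [0, 1]-scaled) values are set to 0 for every test
subject at inference time — the graph topology is untouched and the model
is never refit.  Binary tasks score the drop in F1, multi-class tasks in
macro F1.  Drops are signed: an ablation that *improves* the metric yields
a negative importance and ranks last.  Features with identical drops share
a rank; when a tie group would overflow the report, a random subset of the
tied group is drawn (reproducibly, from a seed) to fill it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import f1_score

from .pipeline import FittedRun


def _metric(labels_true, labels_pred, n_classes: int) -> float:
    average = "binary" if n_classes == 2 else "macro"
    return float(f1_score(labels_true, labels_pred, average=average))


def feature_importance(run: FittedRun, blocks, labels,
                       indices=None, scope: str = "per_omics") -> pd.DataFrame:
    """Ablation importance of every feature of every omics.

    ``scope`` selects the readout whose F1 drop defines importance:

    * ``per_omics`` (default) — a feature of omics m is scored by the drop
      in omics m's *own* classification (the argmax of its opinion).  The
      fusion deliberately compensates for a damaged modality, so the fused
      readout under-reports features whose information another omics also
      carries; each modality's own readout is the identifiable one, and it
      matches the per-modality reporting of the top-biomarker tables.
    * ``fused`` — the drop in the fused prediction's F1.

    Returns a table with columns (omics, feature, importance, rank); ranks
    are dense over descending importance within the whole table, equal
    drops sharing a rank.
    """
    if scope not in ("per_omics", "fused"):
        raise ValueError("scope must be 'per_omics' or 'fused'")
    labels = np.asarray(labels)
    if indices is None:
        indices = run.split_indices[2]
    processed = run.transform(blocks)
    base = [x.values[indices] for x in processed]
    y = labels[indices]
    k = run.config.n_classes

    rows = []
    for m, x in enumerate(processed):
        name = run.model.omics_names[m]
        if scope == "fused":
            pred, _, _ = run.model.predict(base)
        else:
            b, _ = run.model.omics_opinion(m, base[m])
            pred = b.argmax(axis=-1)
        full_score = _metric(y, pred, k)
        for j, feat in enumerate(x.feature_names):
            if scope == "fused":
                values = [v.copy() if i == m else v
                          for i, v in enumerate(base)]
                values[m][:, j] = 0.0
                pred, _, _ = run.model.predict(values)
            else:
                values_m = base[m].copy()
                values_m[:, j] = 0.0
                b, _ = run.model.omics_opinion(m, values_m)
                pred = b.argmax(axis=-1)
            rows.append({"omics": name, "feature": feat,
                         "importance": full_score - _metric(y, pred, k)})
    table = pd.DataFrame(rows)
    table["rank"] = rankdata(-table["importance"],
                             method="dense").astype(int)
    return table.sort_values(["rank", "omics", "feature"],
                             ignore_index=True)


def top_k_report(table: pd.DataFrame, k: int = 5,
                 seed: int = 0) -> pd.DataFrame:
    """Features occupying the top k distinct ranks, tie groups sampled.

    Walks the distinct ranks in order; a tie group larger than the
    remaining room is down-sampled uniformly with ``seed`` so the report
    holds at most ``k`` rows (mirroring a per-omics top-five layout when
    applied per omics group).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    picked = []
    room = k
    for rank in sorted(table["rank"].unique()):
        group = table[table["rank"] == rank]
        if len(group) <= room:
            picked.append(group)
            room -= len(group)
        else:
            chosen = rng.choice(len(group), size=room, replace=False)
            picked.append(group.iloc[np.sort(chosen)])
            room = 0
        if room == 0:
            break
    return pd.concat(picked, ignore_index=True)


def per_omics_top_k(table: pd.DataFrame, k: int = 5,
                    seed: int = 0) -> dict:
    """Top-k report per omics, each ranked within its own modality."""
    out = {}
    for m, (name, group) in enumerate(table.groupby("omics", sort=False)):
        group = group.copy()
        group["rank"] = rankdata(-group["importance"],
                                 method="dense").astype(int)
        group = group.sort_values(["rank", "feature"], ignore_index=True)
        out[name] = top_k_report(group, k=k, seed=seed + m)
    return out
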