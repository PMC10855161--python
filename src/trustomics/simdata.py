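"""Synthetic multi-omics cohorts with planted correlated-module structure.

Real multi-omics cohorts (mRNA expression, DNA methylation, miRNA) share two
properties the downstream stages depend on: features are organised in
co-expressed modules, so thresholded correlation networks are non-trivial,
and a subset of features carries class signal, so both feature preselection
and the classifier have something to find.  The generator plants both
properties with known ground truth:

* each omics block is block-correlated Gaussian — features inside a module
  share an equicorrelation ``within_module_rho``, features in different
  modules are independent;
* a fraction of features per omics is "informative": each informative
  feature is assigned one class (round-robin over the classes that omics is
  allowed to discriminate) and its mean is shifted by
  ``effect_size * noise_sd`` for subjects of that class.

One global seed is split into independent per-omics substreams, so adding a
fourth omics block never perturbs the first three.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OmicsMatrix:
    """One omics block: a subjects x features real matrix with names."""

    values: np.ndarray
    subject_ids: tuple
    feature_names: tuple
    omics_name: str = "omics"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        if values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.subject_ids)} subjects x "
                f"{len(self.feature_names)} features")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if np.isnan(values).any():
            raise ValueError("omics matrix contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def replace(self, **kwargs) -> "OmicsMatrix":
        return dataclasses.replace(self, **kwargs)

    def subset_subjects(self, ids) -> "OmicsMatrix":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in ids]
        return self.replace(values=self.values[rows], subject_ids=tuple(ids))

    def subset_features(self, names) -> "OmicsMatrix":
        index = {f: i for i, f in enumerate(self.feature_names)}
        cols = [index[f] for f in names]
        return self.replace(values=self.values[:, cols],
                            feature_names=tuple(names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.subject_ids),
                            columns=list(self.feature_names))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omics_name: str = "omics"):
        return cls(values=frame.to_numpy(dtype=np.float64),
                   subject_ids=tuple(str(s) for s in frame.index),
                   feature_names=tuple(str(c) for c in frame.columns),
                   omics_name=omics_name)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="subject_id")

    @classmethod
    def read_csv(cls, path, omics_name: str = "omics"):
        return cls.from_frame(pd.read_csv(path, index_col=0), omics_name)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic multi-omics cohort.

    ``module_sizes[m]`` partitions the ``n_features[m]`` features of omics
    ``m`` into equicorrelated blocks.  ``informative_fraction[m]`` controls
    how many features of omics ``m`` carry class signal;
    ``signal_classes[m]`` optionally restricts which classes that omics can
    discriminate (the complementary-modalities setting).
    """

    n_subjects: int = 300
    n_classes: int = 3
    n_features: tuple = (50, 50, 50)
    module_sizes: tuple = ((10, 10, 10, 10, 10),) * 3
    within_module_rho: float = 0.5
    informative_fraction: tuple = (0.1, 0.1, 0.1)
    effect_size: float = 1.5
    noise_sd: float = 1.0
    signal_classes: tuple | None = None
    omics_names: tuple = ("mrna", "methylation", "mirna")
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.within_module_rho < 1.0:
            raise ValueError("within_module_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if len(self.module_sizes) != len(self.n_features):
            raise ValueError("module_sizes and n_features disagree on the "
                             "number of omics blocks")
        for d, sizes in zip(self.n_features, self.module_sizes):
            if sum(sizes) != d or any(s < 1 for s in sizes):
                raise ValueError(
                    f"module sizes {sizes} are not a partition of {d}")
        for frac in self.informative_fraction:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("informative_fraction must lie in [0, 1]")

    @property
    def n_omics(self) -> int:
        return len(self.n_features)


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """Class labels 0..k-1, balanced up to the remainder, in blocks."""
    reps = np.full(k, n // k)
    reps[: n % k] += 1
    return np.repeat(np.arange(k), reps)


def informative_features(spec: SimSpec):
    """Ground-truth signal plan: per omics, a dict feature_index -> class.

    Informative features are the leading features of successive modules
    (spread across modules so module correlation and class signal coexist),
    assigned round-robin to the classes the omics may discriminate.
    """
    plans = []
    for m in range(spec.n_omics):
        d = spec.n_features[m]
        n_inf = int(round(spec.informative_fraction[m] * d))
        sizes = spec.module_sizes[m]
        starts = np.cumsum((0,) + tuple(sizes[:-1]))
        # walk modules breadth-first: first feature of each module, then second...
        order = []
        depth = 0
        while len(order) < d:
            for s, size in zip(starts, sizes):
                if depth < size:
                    order.append(s + depth)
            depth += 1
        classes = (tuple(range(spec.n_classes)) if spec.signal_classes is None
                   else tuple(spec.signal_classes[m]))
        plans.append({int(order[i]): classes[i % len(classes)]
                      for i in range(n_inf)})
    return plans


def generate_cohort(spec: SimSpec):
    """Draw one cohort: a list of OmicsMatrix plus integer labels.

    Regenerating with an identical spec yields bit-identical output.
    """
    labels = _balanced_labels(spec.n_subjects, spec.n_classes)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_omics)
    plans = informative_features(spec)
    rho = spec.within_module_rho
    blocks = []
    for m in range(spec.n_omics):
        rng = np.random.default_rng(streams[m])
        d = spec.n_features[m]
        x = np.empty((spec.n_subjects, d))
        start = 0
        for size in spec.module_sizes[m]:
            # equicorrelated block via a shared-factor construction
            shared = rng.standard_normal((spec.n_subjects, 1))
            eps = rng.standard_normal((spec.n_subjects, size))
            x[:, start:start + size] = (np.sqrt(rho) * shared
                                        + np.sqrt(1.0 - rho) * eps)
            start += size
        x *= spec.noise_sd
        for j, cls in plans[m].items():
            x[labels == cls, j] += spec.effect_size * spec.noise_sd
        name = (spec.omics_names[m] if m < len(spec.omics_names)
                else f"omics{m}")
        blocks.append(OmicsMatrix(
            values=x,
            subject_ids=tuple(f"S{i:04d}" for i in range(spec.n_subjects)),
            feature_names=tuple(f"{name}_f{j:03d}" for j in range(d)),
            omics_name=name))
    return blocks, labels


def mask_modality(x: OmicsMatrix, ratio: float, seed: int) -> OmicsMatrix:
    """Suppress a random ``floor(ratio * d)`` feature columns of one omics.

    Masked columns are set to 0, the minimum of the [0, 1]-scaled range,
    i.e. the "signal removed" state.  The same seed always masks the same
    columns.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"mask ratio must be in [0, 1], got {ratio}")
    d = x.n_features
    n_mask = int(np.floor(ratio * d))
    if n_mask == 0:
        return x
    rng = np.random.default_rng(seed)
    cols = rng.choice(d, size=n_mask, replace=False)
    values = x.values.copy()
    values[:, cols] = 0.0
    return x.replace(values=values)


def write_cohort(blocks, labels, out_dir) -> None:
    """Write `omics_<name>.csv` per block plus `labels.csv`."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for block in blocks:
        block.to_csv(out / f"omics_{block.omics_name}.csv")
    pd.Series(labels, index=list(blocks[0].subject_ids), name="label") \
        .to_csv(out / "labels.csv", index_label="subject_id")


def read_labels(path) -> pd.Series:
    s = pd.read_csv(path, index_col=0).iloc[:, 0]
    return s.astype(int)
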