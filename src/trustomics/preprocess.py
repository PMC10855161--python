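"""Feature selection and scaling for raw omics matrices.

The chain is: drop no-signal (mean exactly 0) and low-variance features,
preselect the k features with the largest one-way ANOVA F statistic, check
that no single direction dominates (first principal component below half of
the total variance), and scale each retained feature linearly to [0, 1].

All fitted statistics — means, standard deviations, F values, PCA loadings,
per-feature min/max — are computed on training subjects only and frozen; the
fitted pipeline is then applied unchanged to held-out subjects, whose scaled
values may legitimately fall outside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

from .simdata import OmicsMatrix

#: Low-variance cutoffs conventional for each omics platform.
DEFAULT_SD_THRESHOLDS = {"mrna": 0.1, "methylation": 0.001, "mirna": 0.0}


@dataclass
class PreprocessReport:
    """Per-stage bookkeeping for one omics block."""

    omics_name: str
    n_input: int
    sd_threshold: float | None = None
    n_after_filter: int | None = None
    k_preselected: int | None = None
    first_pc_fraction: float | None = None
    pca_pass: bool | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_low_signal(x: OmicsMatrix,
                      sd_threshold: float | None = None) -> OmicsMatrix:
    """Drop features with mean exactly 0 and features with SD <= threshold.

    The default threshold is looked up from the omics name
    (:data:`DEFAULT_SD_THRESHOLDS`); unknown names default to 0, which still
    removes constant features.
    """
    if x.n_features == 0:
        raise ValueError("empty omics matrix")
    if sd_threshold is None:
        sd_threshold = DEFAULT_SD_THRESHOLDS.get(x.omics_name, 0.0)
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be >= 0")
    means = x.values.mean(axis=0)
    sds = x.values.std(axis=0, ddof=0)
    keep = (means != 0.0) & (sds > sd_threshold)
    if not keep.any():
        raise ValueError(
            f"low-signal filter removed every feature of '{x.omics_name}' "
            f"(sd_threshold={sd_threshold})")
    names = [f for f, k in zip(x.feature_names, keep) if k]
    return x.subset_features(names)


def anova_preselect(x: OmicsMatrix, labels, k: int) -> OmicsMatrix:
    """Keep the k features with the largest one-way ANOVA F statistic.

    Ties are broken by original feature order, so the result is
    deterministic.  F statistics must be computed on training subjects only;
    pass the training rows of ``x`` and ``labels``.
    """
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.n_features:
        raise ValueError(f"k={k} exceeds feature count {x.n_features}")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ANOVA preselection needs >= 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 subjects for ANOVA")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield F=nan
        f_stat, _ = f_classif(x.values, labels)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    # stable sort on -F preserves input order among ties
    order = np.argsort(-f_stat, kind="stable")[:k]
    order.sort()
    names = [x.feature_names[i] for i in order]
    return x.subset_features(names)


def pca_variance_check(x: OmicsMatrix, limit: float = 0.5):
    """Fraction of variance on the first PC of the standardized matrix.

    Diagnostic only — the matrix is never modified.  Returns
    ``(passed, fraction)`` with ``passed = fraction < limit``.
    """
    if x.n_features < 2 or x.n_subjects < 2:
        raise ValueError("PCA check needs >= 2 features and >= 2 subjects")
    sds = x.values.std(axis=0, ddof=0)
    if np.all(sds == 0):
        raise ValueError("zero total variance: PCA fraction undefined")
    z = (x.values - x.values.mean(axis=0)) / np.where(sds > 0, sds, 1.0)
    pca = PCA(n_components=1, svd_solver="covariance_eigh")
    pca.fit(z)
    fraction = float(pca.explained_variance_ratio_[0])
    return fraction < limit, fraction


@dataclass
class MinMaxScaler01:
    """Per-feature linear map to [0, 1], fitted on a chosen subject subset."""

    mins: np.ndarray
    ranges: np.ndarray

    def transform(self, x: OmicsMatrix) -> OmicsMatrix:
        if x.n_features != self.mins.size:
            raise ValueError("feature count does not match fitted scaler")
        scaled = (x.values - self.mins) / self.ranges
        return x.replace(values=scaled)


def minmax_scale(x: OmicsMatrix, fit_ids=None):
    """Scale every feature to [0, 1] using min/max over the fit subjects.

    Returns the scaled matrix (all subjects transformed) and the fitted
    scaler, reusable on held-out subjects — where values outside [0, 1] are
    preserved.  A feature constant over the fit subjects maps to 0 and a
    warning is emitted.
    """
    if fit_ids is None:
        fit_ids = x.subject_ids
    fit_ids = list(fit_ids)
    if not fit_ids:
        raise ValueError("fit subject set is empty")
    fit = x.subset_subjects(fit_ids)
    mins = fit.values.min(axis=0)
    maxs = fit.values.max(axis=0)
    ranges = maxs - mins
    constant = ranges == 0
    if constant.any():
        names = [f for f, c in zip(x.feature_names, constant) if c]
        warnings.warn(
            f"{len(names)} constant feature(s) over fit subjects mapped to 0 "
            f"in '{x.omics_name}' (e.g. {names[:3]})")
        ranges = np.where(constant, 1.0, ranges)
    scaler = MinMaxScaler01(mins=mins, ranges=ranges)
    return scaler.transform(x), scaler


@dataclass
class FittedPreprocess:
    """Frozen preprocessing state for one omics block."""

    feature_names: tuple
    scaler: MinMaxScaler01
    report: PreprocessReport

    def transform(self, x: OmicsMatrix) -> OmicsMatrix:
        return self.scaler.transform(x.subset_features(self.feature_names))


def fit_preprocess(x: OmicsMatrix, labels, fit_ids,
                   k: int | None = None,
                   sd_threshold: float | None = None,
                   pca_limit: float = 0.5,
                   on_pca_fail: str = "warn"):
    """Run the full chain, fitting on ``fit_ids`` and applying to all subjects.

    ``on_pca_fail`` is one of ``warn`` (default), ``reduce-k`` (decrement k
    by 10% steps until the first-PC fraction passes) or ``abort``.
    Returns ``(transformed OmicsMatrix, FittedPreprocess)``.
    """
    if on_pca_fail not in ("warn", "reduce-k", "abort"):
        raise ValueError(f"unknown on_pca_fail policy: {on_pca_fail}")
    report = PreprocessReport(omics_name=x.omics_name, n_input=x.n_features)
    fit_ids = list(fit_ids)
    train = x.subset_subjects(fit_ids)
    train_labels = np.asarray(labels)

    filtered = filter_low_signal(train, sd_threshold)
    report.sd_threshold = (sd_threshold if sd_threshold is not None
                           else DEFAULT_SD_THRESHOLDS.get(x.omics_name, 0.0))
    report.n_after_filter = filtered.n_features

    k_eff = min(k, filtered.n_features) if k is not None else None
    while True:
        selected = (anova_preselect(filtered, train_labels, k_eff)
                    if k_eff is not None else filtered)
        passed, fraction = pca_variance_check(selected, pca_limit)
        if passed or on_pca_fail != "reduce-k" or k_eff is None:
            break
        next_k = int(np.floor(k_eff * 0.9))
        if next_k < 2 or next_k == k_eff:
            break
        k_eff = next_k
    report.k_preselected = selected.n_features
    report.first_pc_fraction = fraction
    report.pca_pass = passed
    if not passed:
        msg = (f"first PC carries {fraction:.1%} of variance in "
               f"'{x.omics_name}' (limit {pca_limit:.0%})")
        if on_pca_fail == "abort":
            raise ValueError(msg)
        warnings.warn(msg)

    train_selected = train.subset_features(selected.feature_names)
    _, scaler = minmax_scale(train_selected)
    fitted = FittedPreprocess(feature_names=selected.feature_names,
                              scaler=scaler, report=report)
    return fitted.transform(x), fitted
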