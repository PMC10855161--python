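"""Disease-specific co-expression networks and per-subject graphs.

Each omics block gets one cohort-level network: the signed weighted
co-expression adjacency ``A_ij = ((1 + r_ij) / 2) ** beta`` (r = Pearson
correlation across training subjects), binarized at a threshold into an edge
matrix E shared by every subject.  A subject's graph then places that
subject's scaled feature values on the nodes of E — topology is cohort-level
and frozen, node features are per-subject.

The soft-thresholding power beta is chosen the standard WGCNA way: the
smallest candidate whose connectivity distribution fits a scale-free law
with R^2 at or above a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simdata import OmicsMatrix

DEFAULT_THRESHOLD = 0.08           # binarization cutoff
DEFAULT_GRID = np.round(np.arange(0.05, 0.5001, 0.05), 2)  # 0.05 .. 0.5
DEFAULT_BETA_CANDIDATES = tuple(range(1, 13))


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Cohort-level adjacency A, binary edge matrix E, and their parameters."""

    adjacency: np.ndarray
    edge_matrix: np.ndarray
    beta: float
    threshold: float
    feature_names: tuple

    def __post_init__(self):
        a, e = self.adjacency, self.edge_matrix
        if a.shape != e.shape or a.shape[0] != a.shape[1]:
            raise ValueError("A and E must be square and the same shape")
        if a.shape[0] != len(self.feature_names):
            raise ValueError("feature_names length must match A")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def n_features(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_density(self) -> float:
        d = self.n_features
        return float(self.edge_matrix.sum() / (d * (d - 1))) if d > 1 else 0.0


@dataclass(frozen=True)
class SubjectGraph:
    """One subject's view of the network: node features on shared topology."""

    node_features: np.ndarray
    edge_matrix: np.ndarray        # shared reference, not copied
    subject_id: str

    def __post_init__(self):
        if self.node_features.shape[0] != self.edge_matrix.shape[0]:
            raise ValueError("node count must equal edge-matrix dimension")


def compute_adjacency(x: OmicsMatrix, beta: float = 6.0) -> np.ndarray:
    """Signed co-expression adjacency ((1 + r) / 2) ** beta, diagonal 1.

    r is the Pearson correlation of feature pairs across the (training)
    subjects of ``x``.  Zero-variance features have undefined correlations
    and are rejected — run the low-signal filter first.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if x.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a correlation network")
    sds = x.values.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = [f for f, s in zip(x.feature_names, sds) if s == 0]
        raise ValueError(
            f"zero-variance feature(s) {bad[:3]} have undefined correlations; "
            "apply preprocess.filter_low_signal first")
    r = np.corrcoef(x.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log connectivity distribution fit (WGCNA's index).

    Connectivity k_i is the off-diagonal row sum of A.  Connectivities are
    binned; R^2 is the squared correlation of log10(frequency) with
    log10(mean connectivity) over occupied bins.
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    if np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            freqs.append(mask.mean())
            means.append(k[mask].mean())
    freqs, means = np.asarray(freqs), np.asarray(means)
    ok = (freqs > 0) & (means > 0)
    if ok.sum() < 3:
        return 0.0
    lx, ly = np.log10(means[ok]), np.log10(freqs[ok])
    if np.allclose(lx, lx[0]):
        return 0.0
    return float(np.corrcoef(lx, ly)[0, 1] ** 2)


def select_beta(x: OmicsMatrix,
                candidates=DEFAULT_BETA_CANDIDATES,
                fit_target: float = 0.8) -> float:
    """Smallest candidate power reaching scale-free fit R^2 >= fit_target.

    Falls back (with a warning) to the candidate with maximal R^2 when none
    reaches the target.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    fits = []
    for beta in candidates:
        r2 = scale_free_fit(compute_adjacency(x, beta))
        fits.append(r2)
        if r2 >= fit_target:
            return float(beta)
    best = int(np.argmax(fits))
    warnings.warn(
        f"no candidate power reached scale-free R^2 {fit_target}; using "
        f"beta={candidates[best]} (R^2={fits[best]:.3f})")
    return float(candidates[best])


def binarize(adjacency: np.ndarray, threshold: float) -> np.ndarray:
    """Edge matrix: E_ij = 1 iff A_ij >= threshold and i != j."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    e = (adjacency >= threshold).astype(np.int8)
    np.fill_diagonal(e, 0)
    return e


def density_band_criterion(low: float = 0.05, high: float = 0.3):
    """Criterion preferring thresholds whose edge density falls in a band.

    Scores 1 inside [low, high] and decays with the distance outside, so
    the grid search picks the candidate closest to the band (smallest
    threshold on ties).
    """

    def criterion(adjacency: np.ndarray, threshold: float) -> float:
        dens = CoexpressionNetwork(
            adjacency=adjacency, edge_matrix=binarize(adjacency, threshold),
            beta=1.0, threshold=threshold,
            feature_names=tuple(map(str, range(adjacency.shape[0])))
        ).edge_density
        if low <= dens <= high:
            return 1.0
        return 1.0 - min(abs(dens - low), abs(dens - high))

    return criterion


def threshold_grid_search(adjacency: np.ndarray,
                          grid=DEFAULT_GRID,
                          criterion=None) -> float:
    """Pick the binarization threshold maximizing a criterion over a grid.

    ``criterion(adjacency, threshold) -> score``; higher is better; ties go
    to the smallest threshold.  The default criterion targets an edge
    density band; a downstream-validation-accuracy criterion can be passed
    as a closure over a training run.
    """
    grid = [float(t) for t in np.atleast_1d(grid)]
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not 0.0 < t < 1.0 for t in grid):
        raise ValueError("grid thresholds must lie in (0, 1)")
    if criterion is None:
        criterion = density_band_criterion()
    scores = [criterion(adjacency, t) for t in grid]
    order = sorted(range(len(grid)), key=lambda i: (-scores[i], grid[i]))
    return grid[order[0]]


def build_network(x: OmicsMatrix, beta="auto", threshold: float = DEFAULT_THRESHOLD,
                  fit_target: float = 0.8) -> CoexpressionNetwork:
    """Convenience: adjacency + binarization in one call (training subjects)."""
    if beta == "auto":
        beta = select_beta(x, fit_target=fit_target)
    a = compute_adjacency(x, float(beta))
    return CoexpressionNetwork(adjacency=a, edge_matrix=binarize(a, threshold),
                               beta=float(beta), threshold=float(threshold),
                               feature_names=x.feature_names)


def build_subject_graphs(x: OmicsMatrix, edge_matrix: np.ndarray):
    """One SubjectGraph per subject, all sharing ``edge_matrix``."""
    if x.n_features != edge_matrix.shape[0]:
        raise ValueError(
            f"feature count {x.n_features} does not match edge matrix "
            f"dimension {edge_matrix.shape[0]}")
    return [SubjectGraph(node_features=x.values[i], edge_matrix=edge_matrix,
                         subject_id=sid)
            for i, sid in enumerate(x.subject_ids)]


def save_network(net: CoexpressionNetwork, prefix) -> None:
    """Write edge list TSV (i, j, A_ij for E_ij=1) + JSON header."""
    import json
    import pathlib

    prefix = pathlib.Path(prefix)
    ii, jj = np.nonzero(np.triu(net.edge_matrix, 1))
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{net.adjacency[i, j]:.17g}\n")
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"beta": net.beta, "threshold": net.threshold,
                   "feature_names": list(net.feature_names)}, fh, indent=1)


def load_network(prefix) -> CoexpressionNetwork:
    """Reconstruct a network from the edge-list TSV + JSON header pair.

    Off-edge adjacency weights are not stored (they fall below the
    threshold by construction), so they are restored as 0; the edge matrix
    and all stored weights round-trip exactly.
    """
    import json
    import pathlib

    prefix = pathlib.Path(prefix)
    header = json.loads(pathlib.Path(f"{prefix}.json").read_text())
    d = len(header["feature_names"])
    a = np.zeros((d, d))
    e = np.zeros((d, d), dtype=np.int8)
    with open(f"{prefix}.edges.tsv") as fh:
        next(fh)
        for line in fh:
            i, j, w = line.split("\t")
            i, j = int(i), int(j)
            a[i, j] = a[j, i] = float(w)
            e[i, j] = e[j, i] = 1
    np.fill_diagonal(a, 1.0)
    return CoexpressionNetwork(adjacency=a, edge_matrix=e,
                               beta=header["beta"],
                               threshold=header["threshold"],
                               feature_names=tuple(header["feature_names"]))
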