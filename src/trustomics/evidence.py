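"""Subjective-logic opinions and Dempster-Shafer combined-beliefs fusion.

A classifier head emits non-negative evidence ``e = (e_1, ..., e_K)`` per
omics; the corresponding Dirichlet concentration is ``alpha = e + 1`` with
strength ``S = sum(alpha)``.  Subjective logic turns this into an *opinion*:
per-class belief masses ``b_k = e_k / S`` plus an explicit uncertainty mass
``u = K / S``, which sum to one.  Opinions from different omics are merged
by the reduced Dempster-Shafer rule

    b_k^F = (b_k^1 b_k^2 + b_k^1 u^2 + b_k^2 u^1) / (1 - C)
    u^F   = u^1 u^2 / (1 - C),      C = sum_{i != j} b_i^1 b_j^2,

where C measures the conflict between the two sources.  Note C here sums
only cross-class belief products (the rule as used by this model family),
not the full classical Dempster conflict.  The fused opinion maps back to
fused evidence via ``S = K / u`` and ``e_k = b_k * S``.

The ``*_arrays`` functions are written against plain arithmetic plus
``.sum``/broadcasting, so they operate identically on numpy arrays of shape
(..., K) and on autodiff tensors — the training graph and the public
opinion algebra share one set of formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_TOTAL_CONFLICT_EPS = 1e-12


@dataclass(frozen=True)
class Opinion:
    """Subjective-logic state: belief masses plus uncertainty mass."""

    beliefs: np.ndarray
    uncertainty: float

    def __post_init__(self):
        b = np.asarray(self.beliefs, dtype=np.float64)
        object.__setattr__(self, "beliefs", b)
        object.__setattr__(self, "uncertainty", float(self.uncertainty))
        if (b < -1e-12).any() or self.uncertainty < -1e-12:
            raise ValueError("belief and uncertainty masses must be >= 0")
        total = b.sum() + self.uncertainty
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"opinion masses sum to {total}, expected 1")

    @property
    def n_classes(self) -> int:
        return self.beliefs.size

    @classmethod
    def vacuous(cls, k: int) -> "Opinion":
        return cls(beliefs=np.zeros(k), uncertainty=1.0)


@dataclass(frozen=True)
class Evidence:
    """Non-negative per-class evidence with derived Dirichlet parameters."""

    e: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.e, dtype=np.float64)
        object.__setattr__(self, "e", e)
        if (e < 0).any():
            raise ValueError("evidence must be non-negative")

    @property
    def alpha(self) -> np.ndarray:
        return self.e + 1.0

    @property
    def strength(self) -> float:
        return float(self.alpha.sum())

    @property
    def n_classes(self) -> int:
        return self.e.size


@dataclass(frozen=True)
class FusionResult:
    """Fused opinion with its conflict and the inferred fused evidence."""

    fused: Opinion
    conflict: float
    inputs: tuple

    @property
    def evidence(self) -> Evidence:
        return evidence_from_opinion(self.fused)

    @property
    def alpha(self) -> np.ndarray:
        return self.evidence.alpha


# -- batched / polymorphic core ------------------------------------------------

def opinion_arrays(e, k: int):
    """(beliefs, uncertainty) from evidence arrays of shape (..., K).

    Works on numpy arrays and autodiff tensors alike; uncertainty keeps a
    trailing singleton axis for broadcasting.
    """
    s = (e + 1.0).sum(axis=-1, keepdims=True)
    return e / s, float(k) / s


def ds_combine_arrays(b1, u1, b2, u2):
    """One Dempster-Shafer combination step on (..., K) belief arrays.

    The conflict sum_{i != j} b1_i b2_j is computed as
    (sum b1)(sum b2) - sum(b1 b2), which keeps the expression polymorphic.
    Returns (fused beliefs, fused uncertainty, conflict).
    """
    cross = (b1.sum(axis=-1, keepdims=True) * b2.sum(axis=-1, keepdims=True))
    conflict = cross - (b1 * b2).sum(axis=-1, keepdims=True)
    scale = 1.0 / (1.0 - conflict)
    bf = (b1 * b2 + b1 * u2 + b2 * u1) * scale
    uf = u1 * u2 * scale
    return bf, uf, conflict


def fuse_evidence_arrays(evidences: list, k: int):
    """Fuse a list of (..., K) evidence arrays into fused (alpha, u, C)."""
    b, u = opinion_arrays(evidences[0], k)
    conflict = u * 0.0
    for e in evidences[1:]:
        b2, u2 = opinion_arrays(e, k)
        b, u, conflict = ds_combine_arrays(b, u, b2, u2)
    s = float(k) / u
    alpha = b * s + 1.0
    return alpha, u, conflict


# -- public scalar-opinion API -------------------------------------------------

def opinion_from_evidence(e) -> Opinion:
    """Subjective-logic opinion of one evidence vector."""
    if not isinstance(e, Evidence):
        e = Evidence(np.asarray(e, dtype=np.float64))
    b, u = opinion_arrays(e.e, e.n_classes)
    return Opinion(beliefs=b, uncertainty=np.asarray(u).item())


def evidence_from_opinion(m: Opinion) -> Evidence:
    """Invert the opinion map: S = K / u, e_k = b_k * S."""
    if m.uncertainty <= 0:
        raise ValueError("u = 0 corresponds to infinite evidence")
    s = m.n_classes / m.uncertainty
    return Evidence(e=m.beliefs * s)


def ds_combine_pair(m1: Opinion, m2: Opinion) -> FusionResult:
    """Combine two opinions by the reduced Dempster-Shafer rule."""
    if m1.n_classes != m2.n_classes:
        raise ValueError("opinions must share the class count")
    with np.errstate(divide="ignore", invalid="ignore"):
        bf, uf, conflict = ds_combine_arrays(
            m1.beliefs, m1.uncertainty, m2.beliefs, m2.uncertainty)
    conflict = np.asarray(conflict).item()
    if conflict >= 1.0 - _TOTAL_CONFLICT_EPS:
        raise ValueError(
            f"total conflict C={conflict} >= 1: sources are contradictory "
            "and the combination is undefined")
    return FusionResult(
        fused=Opinion(beliefs=bf, uncertainty=np.asarray(uf).item()),
        conflict=conflict, inputs=(m1, m2))


def ds_combine_all(opinions) -> FusionResult:
    """Sequential pairwise combination M1 (+) M2 (+) ... in list order."""
    opinions = list(opinions)
    if not opinions:
        raise ValueError("need at least one opinion")
    if len(opinions) == 1:
        return FusionResult(fused=opinions[0], conflict=0.0,
                            inputs=tuple(opinions))
    result = ds_combine_pair(opinions[0], opinions[1])
    for m in opinions[2:]:
        result = ds_combine_pair(result.fused, m)
    return FusionResult(fused=result.fused, conflict=result.conflict,
                        inputs=tuple(opinions))


def predict_from_fusion(result: FusionResult):
    """Dirichlet-mean class probabilities and the argmax label.

    Probabilities are alpha_k / S of the fused evidence; ties go to the
    smallest class index (numpy argmax convention).
    """
    alpha = result.alpha
    probs = alpha / alpha.sum()
    return int(np.argmax(probs)), probs
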