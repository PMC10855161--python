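"""Evidential losses and the global training objective.

For a Dirichlet with concentration ``alpha`` (alpha = evidence + 1,
S = sum alpha) and a one-hot label y, the evidential cross-entropy is the
expected categorical cross-entropy under the Dirichlet,

    L_ece(alpha, y) = sum_k y_k (psi(S) - psi(alpha_k)),

with psi the digamma function.  Misleading evidence is discouraged by a
KL term that pulls the off-label concentrations toward the uniform
Dirichlet: with adjusted concentration ``alpha~ = y + (1 - y) * alpha``
(true class reset to 1),

    L(alpha) = L_ece(alpha, y) + lambda_t * KL[Dir(alpha~) || Dir(1)],

where lambda_t warms up linearly over training so early, uninformed
evidence is not over-penalized.  The global objective sums the fused-
Dirichlet loss, the per-omics Dirichlet losses, and a gamma-weighted
softmax cross-entropy on each omics' augmentation-module logits
(gamma = 1 by default); we average over the batch, a constant rescaling of
the per-subject sum.

Every function here is polymorphic over numpy arrays and autodiff tensors,
so the public loss API and the training graph share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as sp_special

from .nn import Tensor


def _digamma(x):
    return x.digamma() if isinstance(x, Tensor) else sp_special.digamma(x)


def _gammaln(x):
    return x.gammaln() if isinstance(x, Tensor) else sp_special.gammaln(x)


def _check_one_hot(y) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if not (np.isin(y, (0.0, 1.0)).all()
            and np.allclose(y.sum(axis=-1), 1.0)):
        raise ValueError("labels must be one-hot")
    return y


def one_hot(labels, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros(labels.shape + (k,))
    np.put_along_axis(out, labels[..., None], 1.0, axis=-1)
    return out


@dataclass
class LossConfig:
    """Balance settings of the global objective."""

    n_classes: int
    gamma: float = 1.0
    lambda_cap: float = 1.0
    anneal_horizon: int = 50

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.anneal_horizon < 1:
            raise ValueError("anneal horizon must be >= 1")


@dataclass
class LossBreakdown:
    """Per-term values of the global objective for one batch."""

    fused_loss: float
    per_omics_losses: list
    gat_ce: list
    lambda_t: float
    gamma: float
    total: float
    node: Tensor | None = None   # autodiff node when built from tensors

    def as_dict(self) -> dict:
        return {"fused_loss": self.fused_loss,
                "per_omics_losses": list(self.per_omics_losses),
                "gat_ce": list(self.gat_ce),
                "lambda_t": self.lambda_t, "gamma": self.gamma,
                "total": self.total}


def evidential_ce(alpha, y):
    """Expected cross-entropy under Dir(alpha): sum_k y_k (psi(S)-psi(a_k)).

    ``alpha`` has shape (..., K) with every entry >= 1; ``y`` is one-hot on
    the last axis.  Returns shape (...).
    """
    y = _check_one_hot(y)
    s = alpha.sum(axis=-1, keepdims=True)
    return ((_digamma(s) - _digamma(alpha)) * y).sum(axis=-1)


def adjusted_alpha(alpha, y):
    """Concentration with the true class reset to 1: y + (1 - y) * alpha."""
    y = _check_one_hot(y)
    return alpha * (1.0 - y) + y


def kl_to_uniform(alpha_t):
    """Closed-form KL[Dir(alpha~) || Dir(1)] (natural log).

    = lgamma(S~) - sum lgamma(a~_k) - lgamma(K)
      + sum (a~_k - 1)(psi(a~_k) - psi(S~)).
    """
    k = alpha_t.shape[-1]
    s = alpha_t.sum(axis=-1, keepdims=True)
    term = ((alpha_t - 1.0) * (_digamma(alpha_t) - _digamma(s))).sum(axis=-1)
    log_norm = (_gammaln(s).sum(axis=-1) - _gammaln(alpha_t).sum(axis=-1)
                - float(sp_special.gammaln(k)))
    return log_norm + term


def sample_loss(alpha, y, lambda_t: float):
    """Evidential CE plus lambda_t-weighted KL of the adjusted Dirichlet."""
    if lambda_t < 0:
        raise ValueError("lambda_t must be >= 0")
    loss = evidential_ce(alpha, y)
    if lambda_t > 0:
        loss = loss + lambda_t * kl_to_uniform(adjusted_alpha(alpha, y))
    return loss


def lambda_schedule(epoch: int, horizon: int, cap: float = 1.0) -> float:
    """Linear warm-up: cap * min(1, epoch / horizon)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cap * min(1.0, epoch / float(horizon))


def softmax_cross_entropy(logits, y):
    """Mean softmax cross-entropy; polymorphic over arrays and tensors."""
    y = _check_one_hot(y)
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float64))
    shift = logits.data.max(axis=-1, keepdims=True)   # constant, detached
    z = logits + (-shift)
    lse = z.exp().sum(axis=-1).log()
    out = (lse - (z * y).sum(axis=-1)).mean()
    return out if out.requires_grad else out.data


def global_loss(fused_alpha, per_omics_alphas, per_omics_logits, labels,
                config: LossConfig, epoch: int = 0) -> LossBreakdown:
    """Global objective, averaged over the batch.

    total = L(fused alpha) + sum_m L(alpha^m) + gamma * sum_m CE(logits^m).
    Accepts numpy arrays or autodiff tensors; in the latter case the
    returned breakdown carries the differentiable total in ``.node``.
    """
    y = one_hot(labels, config.n_classes) if np.asarray(labels).ndim == 1 \
        else _check_one_hot(labels)
    lam = lambda_schedule(epoch, config.anneal_horizon, config.lambda_cap)

    def _scalar(v):
        return float(v.data) if isinstance(v, Tensor) else float(v)

    fused = sample_loss(fused_alpha, y, lam).mean()
    per_omics = [sample_loss(a, y, lam).mean() for a in per_omics_alphas]
    gat = [softmax_cross_entropy(lg, y) for lg in per_omics_logits]
    if len(per_omics) != len(gat):
        raise ValueError("per-omics alpha and logit lists differ in length")

    total = fused
    for t in per_omics:
        total = total + t
    for t in gat:
        total = total + config.gamma * t
    return LossBreakdown(
        fused_loss=_scalar(fused),
        per_omics_losses=[_scalar(t) for t in per_omics],
        gat_ce=[_scalar(t) for t in gat],
        lambda_t=lam, gamma=config.gamma, total=_scalar(total),
        node=total if isinstance(total, Tensor) else None)
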