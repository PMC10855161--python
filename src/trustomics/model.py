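"""The full multi-omics evidential classifier.

One :class:`~trustomics.encoder.OmicsEncoder` per omics produces per-class
evidence; the opinions derived from the per-omics evidence are merged by
Dempster-Shafer combination into a fused Dirichlet, whose mean gives the
class probabilities and whose uncertainty mass u quantifies how much the
model does *not* know about a subject.  The fusion is expressed in autodiff
tensors during training, so gradients flow through the combination rule
into every encoder.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig, OmicsEncoder
from .evidence import fuse_evidence_arrays, opinion_arrays


@dataclass
class SubjectReport:
    """Per-subject uncertainty report: the artifact's decision record."""

    subject_id: str
    per_omics: list          # [{omics, beliefs, uncertainty}, ...]
    fused_beliefs: np.ndarray
    fused_uncertainty: float
    conflict: float
    probabilities: np.ndarray
    label: int

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "per_omics": [
                {"omics": p["omics"], "b": list(map(float, p["beliefs"])),
                 "u": float(p["uncertainty"])} for p in self.per_omics],
            "fused": {"b": list(map(float, self.fused_beliefs)),
                      "u": float(self.fused_uncertainty),
                      "C": float(self.conflict)},
            "probabilities": list(map(float, self.probabilities)),
            "label": int(self.label),
        }


class MultiOmicsModel:
    """Per-omics evidential GAT encoders plus Dempster-Shafer fusion."""

    def __init__(self, omics_names, edge_matrices, n_classes: int,
                 config: EncoderConfig | None = None, seed: int = 0):
        if len(omics_names) != len(edge_matrices):
            raise ValueError("need one edge matrix per omics")
        self.omics_names = list(omics_names)
        self.n_classes = int(n_classes)
        self.config = config or EncoderConfig()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.encoders = [
            OmicsEncoder(e.shape[0], self.n_classes, e, self.config, rng)
            for e in edge_matrices]

    @property
    def n_omics(self) -> int:
        return len(self.encoders)

    def parameters(self):
        params = []
        for enc in self.encoders:
            params += enc.parameters()
        return params

    def forward(self, per_omics_values, training: bool = False,
                rng: np.random.Generator | None = None):
        """Differentiable forward pass over a batch of subjects.

        ``per_omics_values``: list of (n, d_m) arrays in model omics order.
        Returns (fused_alpha, per_omics_alphas, per_omics_logits,
        fused_u, conflict) as tensors.
        """
        if len(per_omics_values) != self.n_omics:
            raise ValueError("wrong number of omics blocks")
        evidences, logits = [], []
        for enc, values in zip(self.encoders, per_omics_values):
            e, lg, _ = enc(values, training=training, rng=rng)
            evidences.append(e)
            logits.append(lg)
        fused_alpha, fused_u, conflict = fuse_evidence_arrays(
            evidences, self.n_classes)
        per_omics_alphas = [e + 1.0 for e in evidences]
        return fused_alpha, per_omics_alphas, logits, fused_u, conflict

    # -- inference ------------------------------------------------------------
    def predict(self, per_omics_values):
        """(labels, probabilities, fused uncertainty) without gradients."""
        fused_alpha, _, _, fused_u, _ = self.forward(per_omics_values)
        alpha = fused_alpha.data
        probs = alpha / alpha.sum(axis=-1, keepdims=True)
        return np.argmax(probs, axis=-1), probs, fused_u.data[:, 0]

    def omics_opinion(self, m: int, values):
        """(beliefs (n, K), uncertainty (n,)) of one omics' own opinion."""
        e, _, _ = self.encoders[m](values)
        b, u = opinion_arrays(e.data, self.n_classes)
        return b, u[:, 0]

    def per_omics_opinions(self, per_omics_values):
        """List (per omics) of (beliefs (n, K), uncertainty (n,)) arrays."""
        return [self.omics_opinion(m, values)
                for m, values in enumerate(per_omics_values)]

    def subject_reports(self, per_omics_values, subject_ids):
        """Full uncertainty report per subject."""
        fused_alpha, _, _, fused_u, conflict = self.forward(per_omics_values)
        per = self.per_omics_opinions(per_omics_values)
        alpha = fused_alpha.data
        s = alpha.sum(axis=-1, keepdims=True)
        probs = alpha / s
        fused_b = (alpha - 1.0) / s
        reports = []
        for i, sid in enumerate(subject_ids):
            reports.append(SubjectReport(
                subject_id=str(sid),
                per_omics=[{"omics": name, "beliefs": per[m][0][i],
                            "uncertainty": per[m][1][i]}
                           for m, name in enumerate(self.omics_names)],
                fused_beliefs=fused_b[i],
                fused_uncertainty=float(fused_u.data[i, 0]),
                conflict=float(conflict.data[i, 0]),
                probabilities=probs[i],
                label=int(np.argmax(probs[i]))))
        return reports

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()

    def save(self, path) -> None:
        meta = {"omics_names": self.omics_names, "n_classes": self.n_classes,
                "config": self.config,
                "edge_matrices": [enc.mask for enc in self.encoders],
                "state": self.state_dict()}
        with open(path, "wb") as fh:
            pickle.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "MultiOmicsModel":
        with open(path, "rb") as fh:
            meta = pickle.load(fh)
        edges = []
        for m in meta["edge_matrices"]:
            e = m.copy()
            np.fill_diagonal(e, 0)
            edges.append(e)
        model = cls(meta["omics_names"], edges, meta["n_classes"],
                    config=meta["config"])
        model.load_state_dict(meta["state"])
        return model
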