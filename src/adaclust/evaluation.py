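"""Clustering evaluation: NMI, ARI, scaled silhouette, deviation ratio."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn import metrics as _skm

from .errors import DomainError, ValidationError

__all__ = [
    "LabelVector",
    "MetricReport",
    "nmi",
    "ari",
    "silhouette_scaled",
    "deviation_ratio",
    "evaluate",
]


@dataclass
class LabelVector:
    labels: np.ndarray
    name: str = "labels"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size < 2:
            raise ValidationError("labels must be a 1-D vector of length >= 2")
        if self.labels.dtype.kind == "f" and np.isnan(self.labels).any():
            raise ValidationError("labels contain missing values")

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)


def _as_labels(v) -> np.ndarray:
    return v.labels if isinstance(v, LabelVector) else np.asarray(v)


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise ValidationError(f"label length mismatch: {a.shape[0]} vs {b.shape[0]}")


def nmi(truth, pred) -> float:
    """Mutual information normalized by the arithmetic mean of the entropies."""
    t, p = _as_labels(truth), _as_labels(pred)
    _check_lengths(t, p)
    return float(_skm.normalized_mutual_info_score(t, p, average_method="arithmetic"))


def ari(truth, pred) -> float:
    """Adjusted Rand index (pair counting, hypergeometric chance correction).

    Can be negative for partitions worse than chance.
    """
    t, p = _as_labels(truth), _as_labels(pred)
    _check_lengths(t, p)
    return float(_skm.adjusted_rand_score(t, p))


def silhouette_scaled(Z: np.ndarray, pred) -> float:
    """Mean silhouette on the latent matrix (Euclidean), rescaled to [0, 1]."""
    p = _as_labels(pred)
    Z = np.asarray(Z, dtype=np.float64)
    _check_lengths(Z, p)
    if np.unique(p).size < 2:
        raise DomainError("silhouette undefined for a single predicted cluster")
    s = _skm.silhouette_score(Z, p, metric="euclidean")
    return float((s + 1.0) / 2.0)


def deviation_ratio(k_pred: int, k_true: int) -> float:
    """(k_pred - k_true) / k_true; negative means too few predicted clusters."""
    if k_true < 1:
        raise DomainError(f"k_true must be >= 1, got {k_true}")
    return (k_pred - k_true) / k_true


@dataclass
class MetricReport:
    nmi: float
    ari: float
    sc_scaled: float | None
    deviation_ratio: float
    k_true: int
    k_pred: int

    @property
    def mean_score(self) -> float:
        parts = [self.nmi, self.ari] + ([self.sc_scaled] if self.sc_scaled is not None else [])
        return float(np.mean(parts))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mean_score"] = self.mean_score
        return d

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(truth, pred, Z: np.ndarray | None = None) -> MetricReport:
    """Compute the full metric report; silhouette is None without a latent matrix
    or with a single predicted cluster."""
    t, p = _as_labels(truth), _as_labels(pred)
    _check_lengths(t, p)
    sc = None
    if Z is not None:
        try:
            sc = silhouette_scaled(Z, p)
        except DomainError:
            sc = None
    k_true = int(np.unique(t).size)
    k_pred = int(np.unique(p).size)
    return MetricReport(
        nmi=nmi(t, p),
        ari=ari(t, p),
        sc_scaled=sc,
        deviation_ratio=deviation_ratio(k_pred, k_true),
        k_true=k_true,
        k_pred=k_pred,
    )
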