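"""Link-prediction scoring and alignment utilities.

AUC-ROC is computed in its rank (Mann–Whitney) form — the probability
that a randomly chosen observed link is scored above a randomly chosen
non-link, ties counting one half.  Uncertainty follows a
subsample-then-bootstrap protocol: a random sample of pairs is drawn from
the scored set, then class-stratified bootstrap replicates (positives and
negatives resampled separately, with replacement, preserving class
counts) give a percentile confidence interval.  Orthogonal Procrustes
alignment supports coordinate-recovery diagnostics, since latent
positions are identified only up to an orthogonal transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.linalg import orthogonal_procrustes
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ScoredLinks",
    "EvaluationReport",
    "auc",
    "confusion_metrics",
    "bootstrap_auc_ci",
    "procrustes_align",
]


@dataclass
class ScoredLinks:
    """Parallel probability scores and 0/1 observed labels per pair."""

    scores: np.ndarray
    labels: np.ndarray
    pair_ids: list | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError("scores must lie in [0, 1]")
        self.labels = self.labels.astype(np.int8)
        if self.pair_ids is not None and len(self.pair_ids) != len(self.scores):
            raise ValueError("pair_ids length mismatch")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def concat(cls, parts: list["ScoredLinks"]) -> "ScoredLinks":
        ids = None
        if all(p.pair_ids is not None for p in parts):
            ids = [pid for p in parts for pid in p.pair_ids]
        return cls(
            np.concatenate([p.scores for p in parts]),
            np.concatenate([p.labels for p in parts]),
            ids,
        )


@dataclass
class EvaluationReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    accuracy: float
    threshold: float
    n_sampled: int
    n_boot: int
    seed: int
    level: float = 0.95
    ci_method: str = "percentile, class-stratified bootstrap"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def auc(scored: ScoredLinks) -> float:
    """Rank-based AUC-ROC; requires both classes present."""
    if scored.labels.min() == scored.labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(scored.labels, scored.scores))


def roc_points(scored: ScoredLinks) -> np.ndarray:
    """ROC curve as an array of (fpr, tpr, threshold) rows."""
    fpr, tpr, thr = roc_curve(scored.labels, scored.scores)
    return np.column_stack([fpr, tpr, thr])


def confusion_metrics(scored: ScoredLinks, threshold: float = 0.5) -> dict:
    """Sensitivity and accuracy at a hard threshold (link iff score >= t).

    Zero denominators yield NaN markers rather than exceptions.
    """
    if len(scored) == 0:
        raise ValueError("empty scored set")
    pred = scored.scores >= threshold
    pos = scored.labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    acc = (tp + tn) / len(scored)
    return {"sensitivity": sens, "accuracy": acc, "tp": tp, "fp": fp, "tn": tn, "fn": fn}


def bootstrap_auc_ci(
    scored: ScoredLinks,
    n_sample: int = 1000,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    threshold: float = 0.5,
    max_retries: int = 100,
) -> EvaluationReport:
    """AUC with a stratified-bootstrap percentile CI.

    One subsample of ``n_sample`` pairs is drawn without replacement (the
    whole set if smaller); each of the ``n_boot`` replicates then
    resamples positives and negatives separately with replacement,
    preserving the subsample's class counts.
    """
    rng = np.random.default_rng(seed)
    n = len(scored)
    take = min(n_sample, n)
    for _ in range(max_retries):
        idx = rng.choice(n, size=take, replace=False)
        labels = scored.labels[idx]
        if labels.min() != labels.max():
            break
    else:
        raise ValueError("could not draw a subsample containing both classes")
    scores = scored.scores[idx]
    sample = ScoredLinks(scores, labels)
    point = auc(sample)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        rp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        rn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        rep_scores = np.concatenate([scores[rp], scores[rn]])
        rep_labels = np.concatenate(
            [np.ones(len(rp), dtype=np.int8), np.zeros(len(rn), dtype=np.int8)]
        )
        reps[b] = roc_auc_score(rep_labels, rep_scores)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    conf = confusion_metrics(sample, threshold)
    return EvaluationReport(
        auc=point,
        auc_ci=(float(lo), float(hi)),
        sensitivity=conf["sensitivity"],
        accuracy=conf["accuracy"],
        threshold=threshold,
        n_sampled=take,
        n_boot=n_boot,
        seed=seed,
        level=level,
    )


def procrustes_align(X: np.ndarray, Ref: np.ndarray) -> dict:
    """Orthogonal matrix ``W`` minimising ``‖XW − Ref‖_F`` and the residual.

    Reflections are allowed (``det W`` may be −1).  Degenerate all-zero
    ``X`` returns the identity with residual ``‖Ref‖_F``.
    """
    X = np.asarray(X, dtype=float)
    Ref = np.asarray(Ref, dtype=float)
    if X.shape != Ref.shape:
        raise ValueError("shapes must match")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least d points for a d-dimensional alignment")
    if not X.any():
        return {
            "rotation": np.eye(X.shape[1]),
            "residual": float(np.linalg.norm(Ref)),
        }
    W, _ = orthogonal_procrustes(X, Ref)
    return {"rotation": W, "residual": float(np.linalg.norm(X @ W - Ref))}
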