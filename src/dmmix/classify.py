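"""Generative Bayes classification of community profiles.

One DMM is fitted per class (with evidence-based selection of its component
number), class priors are the observed class frequencies, and a new sample
is scored by marginalising its latent composition under each class model:

    P(class c | x)  propto  P(c) * sum_k pi_k^{(c)} p(x | alpha_k^{(c)}).

Leave-one-out validation, confusion matrices at a probability threshold,
and ROC curves built by sweeping the threshold across the observed sample
probabilities summarise performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import CountMatrix, MixtureModel, _check_counts_vector, _log_weights
from .core import log_component_evidence_matrix
from .em import FitConfig, FitResult
from .evidence import select_k

__all__ = [
    "ClassifierModel",
    "ConfusionMatrix",
    "RocCurve",
    "fit_classifier",
    "predict_proba",
    "predict_proba_matrix",
    "loo_validate",
    "confusion_and_error",
    "roc_auc",
    "compare_class_fit",
]


@dataclass
class ClassifierModel:
    """Per-class DMM fits with empirical class priors."""

    class_names: list
    class_priors: np.ndarray
    class_fits: list[FitResult]
    selected_k: list[int]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_names: list

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("confusion counts must be a non-negative 2-D matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def error_rate(self) -> float:
        """Misclassified fraction: off-diagonal sum over total."""
        c = self.counts
        return float((c.sum() - np.trace(c)) / c.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass(frozen=True)
class RocCurve:
    """ROC points swept over thresholds descending from 1 to 0."""

    thresholds: np.ndarray
    false_positive_pct: np.ndarray
    true_positive_pct: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "false_positive_pct": self.false_positive_pct,
                "true_positive_pct": self.true_positive_pct,
            }
        )


def _split_by_class(X: CountMatrix, labels) -> tuple[list, dict]:
    labels = np.asarray(labels)
    if labels.shape[0] != X.n_samples:
        raise ValueError("labels must align with the samples")
    names = sorted(pd.unique(labels).tolist(), key=str)
    groups = {c: np.flatnonzero(labels == c) for c in names}
    for c, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return names, groups


def _subset(X: CountMatrix, idx: np.ndarray) -> CountMatrix:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return CountMatrix(
            counts=X.counts[idx],
            sample_ids=[X.sample_ids[i] for i in idx],
            taxon_names=X.taxon_names,
        )


def fit_classifier(
    X: CountMatrix, labels, cfg: FitConfig | None = None, k_max: int = 3
) -> ClassifierModel:
    """Fit one DMM per class, selecting each K in 1..k_max by Laplace evidence."""
    if cfg is None:
        cfg = FitConfig()
    names, groups = _split_by_class(X, labels)
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    priors = np.array([groups[c].size for c in names], dtype=float)
    priors /= priors.sum()
    fits, ks = [], []
    for c in names:
        sel = select_k(_subset(X, groups[c]), 1, k_max, cfg)
        best = sel.fits[sel.k_values.index(sel.best_k)]
        fits.append(best)
        ks.append(sel.best_k)
    return ClassifierModel(class_names=names, class_priors=priors, class_fits=fits, selected_k=ks)


def _log_class_scores(counts_row: np.ndarray, model: ClassifierModel) -> np.ndarray:
    x = _check_counts_vector(counts_row)
    scores = np.empty(model.n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        Xone = CountMatrix(counts=x[None, :])
    for c, fit in enumerate(model.class_fits):
        m: MixtureModel = fit.model
        log_ev = log_component_evidence_matrix(Xone, m, include_coefficient=True)[0]
        scores[c] = logsumexp(log_ev + _log_weights(m.weights))
    return scores


def predict_proba(x, model: ClassifierModel) -> np.ndarray:
    """Posterior class probabilities for one count vector (sums to 1)."""
    log_s = _log_class_scores(np.asarray(x), model) + np.log(model.class_priors)
    return np.exp(log_s - logsumexp(log_s))


def predict_proba_matrix(X: CountMatrix, model: ClassifierModel) -> np.ndarray:
    """Posterior class probabilities for every sample (N x C)."""
    return np.stack([predict_proba(row, model) for row in X.counts])


def loo_validate(
    X: CountMatrix,
    labels,
    cfg: FitConfig | None = None,
    k_max: int = 3,
    reselect_k: bool = True,
) -> pd.DataFrame:
    """Leave-one-out validation of the generative classifier.

    Each sample is held out in turn, the per-class mixtures retrained on the
    remainder (by default re-running K selection per class; with
    ``reselect_k=False`` the full-data K per class is reused — faster, and
    flagged in the output attrs), and the held-out sample scored.  Returns a
    DataFrame with one row per sample: its ID, true class and the posterior
    probability of each class.  Deterministic given the config seed.
    """
    if cfg is None:
        cfg = FitConfig()
    labels = np.asarray(labels)
    names, groups = _split_by_class(X, labels)
    fixed_k: dict | None = None
    if not reselect_k:
        full = fit_classifier(X, labels, cfg, k_max)
        fixed_k = dict(zip(full.class_names, full.selected_k))
    rows = []
    for i in range(X.n_samples):
        keep = np.array([j for j in range(X.n_samples) if j != i])
        sub_labels = labels[keep]
        counts = pd.Series(sub_labels).value_counts()
        if counts.min() < 2:
            warnings.warn(
                f"skipping fold {i}: removing sample empties a class", UserWarning, stacklevel=2
            )
            continue
        sub_X = _subset(X, keep)
        if fixed_k is not None:
            sub_names, sub_groups = _split_by_class(sub_X, sub_labels)
            priors = np.array([sub_groups[c].size for c in sub_names], float)
            priors /= priors.sum()
            fits, ks = [], []
            for c in sub_names:
                from .em import fit_dmm

                fits.append(fit_dmm(_subset(sub_X, sub_groups[c]), fixed_k[c], cfg))
                ks.append(fixed_k[c])
            cls = ClassifierModel(sub_names, priors, fits, ks)
        else:
            cls = fit_classifier(sub_X, sub_labels, cfg, k_max)
        probs = predict_proba(X.counts[i], cls)
        row = {"sample_id": X.sample_ids[i], "true_class": labels[i]}
        row.update({f"p_{c}": p for c, p in zip(cls.class_names, probs)})
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["reselect_k"] = reselect_k
    out.attrs["class_names"] = names
    return out


def confusion_and_error(
    probs, labels, threshold: float = 0.5, class_names: list | None = None
) -> ConfusionMatrix:
    """Threshold binary class-2 probabilities and tabulate actual x predicted.

    ``probs`` are probabilities of the second (positive) class; a sample is
    predicted positive when its probability is >= threshold.  ``labels`` are
    the actual classes, with the positive class the larger of the two sorted
    class names (or ``class_names[1]`` when given).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels must have equal length")
    if class_names is None:
        class_names = sorted(pd.unique(labels).tolist(), key=str)
    if len(class_names) != 2:
        raise ValueError("confusion_and_error is binary; pass two class names")
    neg, pos = class_names
    predicted = np.where(probs >= threshold, pos, neg)
    counts = np.zeros((2, 2), dtype=np.int64)
    for a, cls_a in enumerate(class_names):
        for p, cls_p in enumerate(class_names):
            counts[a, p] = int(np.sum((labels == cls_a) & (predicted == cls_p)))
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def roc_auc(probs, labels, positive_class=None) -> RocCurve:
    """ROC curve from positive-class probabilities with the >= threshold rule.

    Thresholds run from above the largest sample probability down to 0,
    stepping at each distinct sample probability, so the curve starts at
    (0, 0) and ends at (100, 100).  The AUC is the trapezoidal area under
    the curve on the [0, 1] scale; it is invariant under strictly monotone
    transformations of the scores.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist(), key=str)
    if positive_class is None:
        if len(classes) != 2:
            raise ValueError("designate positive_class for non-binary labels")
        positive_class = classes[1]
    is_pos = labels == positive_class
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate(([np.inf], np.unique(probs)[::-1], [0.0]))
    fp_pct, tp_pct = [], []
    for t in thresholds:
        pred_pos = probs >= t
        tp_pct.append(100.0 * np.sum(pred_pos & is_pos) / n_pos)
        fp_pct.append(100.0 * np.sum(pred_pos & ~is_pos) / n_neg)
    fp = np.array(fp_pct)
    tp = np.array(tp_pct)
    auc = float(np.trapezoid(tp / 100.0, fp / 100.0))
    return RocCurve(
        thresholds=np.where(np.isinf(thresholds), 1.0, thresholds),
        false_positive_pct=fp,
        true_positive_pct=tp,
        auc=auc,
    )


def compare_class_fit(
    X: CountMatrix, labels, cfg: FitConfig | None = None, k_max: int = 3
) -> dict:
    """Does splitting the data by class explain it better than pooling?

    Returns the sum of per-class negative Laplace evidences, the pooled
    negative Laplace evidence, and their difference (split minus pooled);
    a lower split sum (negative difference) favours distinct per-class
    metacommunity structure.
    """
    if cfg is None:
        cfg = FitConfig()
    names, groups = _split_by_class(X, labels)
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    split_sum = 0.0
    for c in names:
        sel = select_k(_subset(X, groups[c]), 1, k_max, cfg)
        split_sum += min(sel.neg_evidences)
    pooled_sel = select_k(X, 1, k_max, cfg)
    pooled = min(pooled_sel.neg_evidences)
    return {
        "split_neg_evidence_sum": float(split_sum),
        "pooled_neg_evidence": float(pooled),
        "difference": float(split_sum - pooled),
        "split_favoured": bool(split_sum < pooled),
    }
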