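"""Confusion-matrix algebra, diagnostic accuracy metrics and ROC analysis.

Implements the quantitative reporting layer of the pipeline:

* collapsing a k-class confusion matrix to a 2x2 table (optionally
  restricting which *predicted* classes enter the table, the convention
  needed to reproduce two-class accuracies quoted "among patients with
  CLD" when a third predicted class exists);
* sensitivity / specificity / likelihood ratios / predictive values;
* ROC curves and AUROC by the average-rank Mann-Whitney statistic (ties
  credited 1/2), with stratified bootstrap confidence intervals,
  subsampling/permutation stability checks and cut-off selection.

Score orientation: disease lowers the AUBP, so ROC analysis of AUBP runs
with ``direction="lower_is_positive"`` and cut-offs are reported with the
"score < cutoff => positive call" convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import (
    CohortSchemaError,
    InfeasibleCutoffError,
    SingleClassError,
    UndefinedMetricError,
)

__all__ = [
    "round_half_up",
    "ConfusionMatrix",
    "BinaryTable",
    "DiagnosticMetrics",
    "ROCResult",
    "StabilityResult",
    "collapse",
    "binary_metrics",
    "roc",
    "auroc_bootstrap_ci",
    "roc_stability",
    "select_cutoff",
]

Direction = Literal["lower_is_positive", "higher_is_positive"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables,
    unlike Python's banker's rounding)."""
    if math.isinf(x):
        return x
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts with actual classes on rows, predicted on columns."""

    class_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if counts.shape != (k, k):
            raise CohortSchemaError(
                f"confusion matrix shape {counts.shape} does not match "
                f"{k} class labels"
            )
        if np.any(counts < 0):
            raise CohortSchemaError("confusion-matrix counts must be >= 0")
        if counts.sum() <= 0:
            raise CohortSchemaError("confusion matrix is empty")
        counts.flags.writeable = False
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_predictions(
        cls,
        actual: Sequence[str],
        predicted: Sequence[str],
        class_labels: Sequence[str],
    ) -> "ConfusionMatrix":
        labels = list(class_labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for a, p in zip(actual, predicted, strict=True):
            counts[index[a], index[p]] += 1
        return cls(class_labels=tuple(labels), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass(frozen=True)
class BinaryTable:
    """2x2 diagnostic table: true/false positives and negatives."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise CohortSchemaError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, likelihood ratios and predictive values.

    ``lr_pos`` is ``+inf`` when specificity is exactly 1 (a legitimate
    perfect-specificity table), and ``lr_neg`` is ``+inf`` when
    specificity is 0.
    """

    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    ppv: float
    npv: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def collapse(
    cm: ConfusionMatrix,
    positive: Sequence[str],
    negative: Sequence[str],
    restrict_predicted: Sequence[str] | None = None,
) -> BinaryTable:
    """Collapse a k-class confusion matrix to a 2x2 diagnostic table.

    Rows (actual classes) are restricted to ``positive | negative``.  A
    prediction counts as a positive call when it lands in ``positive``,
    otherwise as a negative call.  If ``restrict_predicted`` is given,
    predicted columns outside it are dropped *before* collapsing — the
    convention under which two-class accuracies quoted within a disease
    subgroup exclude subjects the k-class model routed to an outside
    class (e.g. cirrhotic patients predicted healthy).
    """
    pos = list(dict.fromkeys(positive))
    neg = list(dict.fromkeys(negative))
    if not pos or not neg:
        raise CohortSchemaError("positive and negative label sets must be non-empty")
    overlap = set(pos) & set(neg)
    if overlap:
        raise CohortSchemaError(f"labels {sorted(overlap)} in both positive and negative sets")
    unknown = (set(pos) | set(neg)) - set(cm.class_labels)
    if unknown:
        raise CohortSchemaError(f"unknown class labels {sorted(unknown)}")
    col_index = {lab: j for j, lab in enumerate(cm.class_labels)}
    if restrict_predicted is None:
        kept_cols = list(cm.class_labels)
    else:
        unknown = set(restrict_predicted) - set(cm.class_labels)
        if unknown:
            raise CohortSchemaError(f"unknown predicted labels {sorted(unknown)}")
        kept_cols = [lab for lab in cm.class_labels if lab in set(restrict_predicted)]
    pos_cols = [col_index[c] for c in kept_cols if c in set(pos)]
    neg_cols = [col_index[c] for c in kept_cols if c not in set(pos)]
    pos_rows = [col_index[c] for c in pos]
    neg_rows = [col_index[c] for c in neg]
    counts = cm.counts
    tp = int(counts[np.ix_(pos_rows, pos_cols)].sum()) if pos_cols else 0
    fn = int(counts[np.ix_(pos_rows, neg_cols)].sum()) if neg_cols else 0
    fp = int(counts[np.ix_(neg_rows, pos_cols)].sum()) if pos_cols else 0
    tn = int(counts[np.ix_(neg_rows, neg_cols)].sum()) if neg_cols else 0
    return BinaryTable(tp=tp, fp=fp, fn=fn, tn=tn)


def binary_metrics(t: BinaryTable) -> DiagnosticMetrics:
    """Diagnostic accuracy metrics of a 2x2 table.

    Requires all four margins (actual positive/negative, predicted
    positive/negative) to be non-zero; otherwise at least one metric has
    an undefined denominator and an :class:`UndefinedMetricError` names
    the zero margin.
    """
    margins = {
        "actual-positive (tp+fn)": t.tp + t.fn,
        "actual-negative (tn+fp)": t.tn + t.fp,
        "predicted-positive (tp+fp)": t.tp + t.fp,
        "predicted-negative (tn+fn)": t.tn + t.fn,
    }
    for name, value in margins.items():
        if value == 0:
            raise UndefinedMetricError(f"undefined metric: zero margin {name}")
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.tn + t.fp)
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.inf if spec == 0.0 else (1.0 - sens) / spec
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ppv=t.tp / (t.tp + t.fp),
        npv=t.tn / (t.tn + t.fn),
    )


# --------------------------------------------------------------------------
# ROC / AUROC


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise SingleClassError("labels must be binary (0/1 or bool)")
    if len(np.unique(y)) < 2:
        raise SingleClassError("ROC needs both a positive and a negative class")
    return y


def _oriented(scores: np.ndarray, direction: Direction) -> np.ndarray:
    if direction == "lower_is_positive":
        return -scores
    if direction == "higher_is_positive":
        return scores
    raise CohortSchemaError(f"unknown direction {direction!r}")


def _auroc_rows(score_rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUROC of each row of ``score_rows`` (higher score = positive).

    Average-rank Mann-Whitney: ties get half credit.  Vectorised so the
    bootstrap can evaluate thousands of replicates in one call.
    """
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    ranks = rankdata(score_rows, axis=-1)
    rank_sum_pos = ranks[..., y == 1].sum(axis=-1)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class ROCResult:
    """ROC operating points plus AUROC for a scored binary contrast.

    ``thresholds`` are on the original score scale, placed at midpoints
    between adjacent distinct scores (with open-ended extremes), ordered
    so that sensitivity is non-decreasing.  Under
    ``direction="lower_is_positive"`` a subject is called positive when
    ``score < threshold``; under ``higher_is_positive`` when
    ``score > threshold``.
    """

    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)
    tp: np.ndarray = field(repr=False)
    fp: np.ndarray = field(repr=False)
    auroc: float = 0.0
    direction: Direction = "lower_is_positive"
    n_pos: int = 0
    n_neg: int = 0
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    seed: int | None = None

    def table_at(self, i: int) -> BinaryTable:
        """2x2 table at operating point ``i``."""
        tp = int(self.tp[i])
        fp = int(self.fp[i])
        return BinaryTable(tp=tp, fp=fp, fn=self.n_pos - tp, tn=self.n_neg - fp)


def roc(
    scores: Sequence[float],
    labels: Sequence,
    direction: Direction = "lower_is_positive",
) -> ROCResult:
    """ROC curve and AUROC of a continuous score for a binary outcome.

    AUROC equals the Mann-Whitney probability that a random positive
    scores more extreme (in the stated direction) than a random negative,
    ties counted 1/2.  Operating points are enumerated at every distinct
    threshold; tied scores collapse into a single threshold.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise CohortSchemaError("scores must be finite")
    y = _as_binary(labels)
    oriented = _oriented(s, direction)
    auroc = float(_auroc_rows(oriented[None, :], y)[0])

    # Thresholds at midpoints between adjacent distinct original scores,
    # plus open-ended extremes so the (0,0) and (1,1) corners appear.
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    if direction == "lower_is_positive":
        calls = s[None, :] < thresholds[:, None]  # ascending threshold -> more calls
    else:
        thresholds = thresholds[::-1]
        calls = s[None, :] > thresholds[:, None]
    tp = (calls & (y == 1)).sum(axis=1)
    fp = (calls & (y == 0)).sum(axis=1)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tp / n_pos,
        specificity=(n_neg - fp) / n_neg,
        tp=tp,
        fp=fp,
        auroc=auroc,
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auroc_bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence,
    direction: Direction = "lower_is_positive",
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the AUROC.

    Resampling is stratified within class (positives and negatives drawn
    with replacement separately) so every replicate retains both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if int(y.sum()) < 2 or int((1 - y).sum()) < 2:
        raise SingleClassError("bootstrap needs >= 2 members in each class")
    oriented = _oriented(s, direction)
    rng = np.random.default_rng(seed)
    pos = oriented[y == 1]
    neg = oriented[y == 0]
    idx_pos = rng.integers(0, pos.size, size=(n_boot, pos.size))
    idx_neg = rng.integers(0, neg.size, size=(n_boot, neg.size))
    rows = np.concatenate([pos[idx_pos], neg[idx_neg]], axis=1)
    y_rep = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    aurocs = _auroc_rows(rows, y_rep)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(aurocs, [alpha, 1.0 - alpha])
    return float(low), float(high)


@dataclass(frozen=True)
class StabilityResult:
    """Subsampling / permutation stability of an AUROC."""

    observed_auroc: float
    resampled_aurocs: np.ndarray = field(repr=False)
    permuted_aurocs: np.ndarray = field(repr=False)
    p_value: float = 1.0
    seed: int | None = None

    @property
    def mean_resampled(self) -> float:
        return float(self.resampled_aurocs.mean())

    @property
    def mean_permuted(self) -> float:
        return float(self.permuted_aurocs.mean())


def roc_stability(
    scores: Sequence[float],
    labels: Sequence,
    direction: Direction = "lower_is_positive",
    n_resamples: int = 10,
    n_permutations: int = 10,
    resample_frac: float = 0.9,
    seed: int | None = None,
) -> StabilityResult:
    """Replication stability of an AUROC.

    Each resample recomputes the AUROC on a stratified subsample of
    ``resample_frac`` of each class drawn *without* replacement; each
    permutation recomputes it after shuffling the class labels.  The
    permutation p-value uses the add-one rule
    ``(1 + #{permuted >= observed}) / (1 + n_permutations)``.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    oriented = _oriented(s, direction)
    rng = np.random.default_rng(seed)
    observed = float(_auroc_rows(oriented[None, :], y)[0])

    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    m_pos = max(2, int(round(resample_frac * pos_idx.size)))
    m_neg = max(2, int(round(resample_frac * neg_idx.size)))
    resampled = np.empty(n_resamples)
    for i in range(n_resamples):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=m_pos, replace=False),
                rng.choice(neg_idx, size=m_neg, replace=False),
            ]
        )
        resampled[i] = _auroc_rows(oriented[None, take], y[take])[0]

    permuted = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        permuted[i] = _auroc_rows(oriented[None, :], y_perm)[0]
    p = (1.0 + int(np.sum(permuted >= observed))) / (1.0 + n_permutations)
    return StabilityResult(
        observed_auroc=observed,
        resampled_aurocs=resampled,
        permuted_aurocs=permuted,
        p_value=p,
        seed=seed,
    )


def select_cutoff(
    rocres: ROCResult,
    criterion: str = "youden",
    q: float | None = None,
) -> tuple[float, DiagnosticMetrics]:
    """Pick a cut-off from ROC coordinates and report its 2x2 metrics.

    Criteria
    --------
    ``"youden"``
        Maximise sensitivity + specificity - 1; ties broken in favour of
        higher specificity.
    ``"min_specificity"``
        Maximise sensitivity subject to specificity >= ``q``.
    ``"min_sensitivity"``
        Maximise specificity subject to sensitivity >= ``q``.

    The threshold is returned on the original score scale with the
    "score < cutoff => positive" reading under ``lower_is_positive``.
    The extreme operating points that call nobody (or everybody)
    positive are excluded: they are clinically meaningless as cut-offs
    and leave a predictive value undefined.
    """
    if rocres.thresholds.size < 2:
        raise InfeasibleCutoffError("ROC result has fewer than 2 operating points")
    sens = rocres.sensitivity
    spec = rocres.specificity
    # the all-call / no-call corners have an undefined predictive value;
    # they are never selectable (they can only tie the best at J = 0)
    n_calls = rocres.tp + rocres.fp
    degenerate = (n_calls == 0) | (n_calls == rocres.n_pos + rocres.n_neg)
    sens = np.where(degenerate, -np.inf, sens)
    if criterion == "youden":
        j = sens + spec - 1.0
        best = np.flatnonzero(j == j.max())
        i = int(best[np.argmax(spec[best])])
    elif criterion in ("min_specificity", "min_sensitivity"):
        if q is None:
            raise InfeasibleCutoffError(f"criterion {criterion!r} requires q")
        feasible = np.flatnonzero(spec >= q) if criterion == "min_specificity" else np.flatnonzero(sens >= q)
        if feasible.size == 0:
            raise InfeasibleCutoffError(
                f"no operating point satisfies constraint {criterion}({q})"
            )
        target, other = (sens, spec) if criterion == "min_specificity" else (spec, sens)
        best = feasible[target[feasible] == target[feasible].max()]
        i = int(best[np.argmax(other[best])])
    else:
        raise InfeasibleCutoffError(f"unknown cut-off criterion {criterion!r}")
    return float(rocres.thresholds[i]), binary_metrics(rocres.table_at(i))
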