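"""Classification metrics and paired significance tests.

Threshold-free discrimination (AUROC via midranks, AUPRC as average
precision), the Youden operating point, confusion-matrix metrics with the
balanced-accuracy identity, DeLong's test for correlated ROC curves,
McNemar's test on matched predictions, the exact paired Wilcoxon
signed-rank test for fold-level metrics, and patient-level percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata


@dataclass
class PredictionSet:
    """Per-image predictions: (image_id, patient_id, fold, probability, label)."""

    image_id: np.ndarray
    patient_id: np.ndarray
    prob_malignant: np.ndarray
    y_true: np.ndarray  # 1 = malignant, 0 = benign/negative
    fold: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image_id = np.asarray(self.image_id)
        self.patient_id = np.asarray(self.patient_id)
        self.prob_malignant = np.asarray(self.prob_malignant, dtype=np.float64)
        self.y_true = np.asarray(self.y_true, dtype=np.int64)
        if self.fold is not None:
            self.fold = np.asarray(self.fold)
        n = len(self.image_id)
        if not (len(self.patient_id) == len(self.prob_malignant) == len(self.y_true) == n):
            raise ValueError("field lengths differ")
        if self.prob_malignant.size and (
            self.prob_malignant.min() < 0 or self.prob_malignant.max() > 1
        ):
            raise ValueError("probabilities outside [0, 1]")
        if not set(np.unique(self.y_true)) <= {0, 1}:
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.image_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "image_id": self.image_id,
            "patient_id": self.patient_id,
            "prob_malignant": self.prob_malignant,
            "y_true": self.y_true,
        })
        if self.fold is not None:
            df["fold"] = self.fold
        return df


@dataclass
class MetricReport:
    """All metrics reported at a fixed operating point plus ranking metrics."""

    accuracy: float
    auroc: float
    auprc: float
    recall_malignant: float
    specificity: float
    balanced_accuracy: float
    threshold: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("accuracy", "auroc", "auprc", "recall_malignant",
                     "specificity", "balanced_accuracy"):
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            rows.append({"metric": name, "value": getattr(self, name),
                         "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    method: str


def _check_two_classes(y_true: np.ndarray) -> None:
    if len(np.unique(y_true)) < 2:
        raise ValueError("need at least one positive and one negative case")


def auroc(y_true: Sequence[int], y_score: Sequence[float]) -> float:
    """AUROC via midranks: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    _check_two_classes(y_true)
    ranks = rankdata(y_score)  # midranks
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(y_true: Sequence[int], y_score: Sequence[float]) -> float:
    """Average precision: sum over descending thresholds of (dRecall * Precision)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    _check_two_classes(y_true)
    n_pos = int(y_true.sum())
    order = np.argsort(-y_score, kind="stable")
    y_sorted = y_true[order]
    s_sorted = y_score[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate at the last index of each tied-score block
    last_of_block = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    tp_b, fp_b = tp[last_of_block], fp[last_of_block]
    recall = tp_b / n_pos
    precision = tp_b / (tp_b + fp_b)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def youden_threshold(y_true: Sequence[int], y_score: Sequence[float]) -> float:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Candidate cut-points are the observed scores (prediction rule is
    prob >= threshold); ties in J break toward the lowest threshold,
    favoring sensitivity.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    _check_two_classes(y_true)
    candidates = np.unique(y_score)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    best_j, best_t = -np.inf, candidates[0]
    for t in candidates:  # ascending: strict > keeps the lowest maximizer
        pred = y_score >= t
        sens = (pred & (y_true == 1)).sum() / n_pos
        spec = (~pred & (y_true == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def confusion_report(y_true: Sequence[int], y_score: Sequence[float],
                     threshold: float) -> MetricReport:
    """Metrics at a fixed threshold (prob >= threshold => predicted malignant)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    _check_two_classes(y_true)
    pred = (y_score >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return MetricReport(
        accuracy=(tp + tn) / len(y_true),
        auroc=auroc(y_true, y_score),
        auprc=auprc(y_true, y_score),
        recall_malignant=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# DeLong's test


def _delong_components(y_true: np.ndarray, y_score: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and structural components V10 (per positive), V01 (per negative)."""
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.r_[pos, neg])
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def delong_test(y_true: Sequence[int], score_a: Sequence[float],
                score_b: Sequence[float]) -> PairedTestResult:
    """Paired comparison of two correlated AUROCs on the same cases.

    Uses the midrank structural-component formulation; zero variance of the
    difference (e.g. identical scores) is handled as z = 0, p = 1.
    """
    y_true = np.asarray(y_true)
    score_a = np.asarray(score_a, dtype=np.float64)
    score_b = np.asarray(score_b, dtype=np.float64)
    if not (len(y_true) == len(score_a) == len(score_b)):
        raise ValueError("mismatched case sets")
    _check_two_classes(y_true)
    auc_a, v10_a, v01_a = _delong_components(y_true, score_a)
    auc_b, v10_b, v01_b = _delong_components(y_true, score_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return PairedTestResult(0.0, 1.0, "delong")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedTestResult(float(z), float(min(p, 1.0)), "delong")


def delong_variance(y_true: Sequence[int], y_score: Sequence[float]) -> float:
    """DeLong variance of a single AUROC (used for cross-checks)."""
    y_true = np.asarray(y_true)
    auc, v10, v01 = _delong_components(y_true, np.asarray(y_score, dtype=np.float64))
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


# ---------------------------------------------------------------------------
# McNemar and Wilcoxon


def mcnemar_test(correct_a: Sequence[bool], correct_b: Sequence[bool],
                 exact_switch: int = 25) -> PairedTestResult:
    """Paired test on discordant outcomes of two classifiers.

    b = cases A got right and B wrong, c = the converse.  With
    b + c >= ``exact_switch``: continuity-corrected chi-square
    (|b-c|-1)^2/(b+c) on 1 df; otherwise the exact two-sided binomial test
    (doubled smaller tail, capped at 1).
    """
    correct_a = np.asarray(correct_a, dtype=bool)
    correct_b = np.asarray(correct_b, dtype=bool)
    if len(correct_a) != len(correct_b):
        raise ValueError("mismatched case sets")
    b = int((correct_a & ~correct_b).sum())
    c = int((~correct_a & correct_b).sum())
    if b + c == 0:
        return PairedTestResult(0.0, 1.0, "mcnemar")
    if b + c >= exact_switch:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(stats.chi2.sf(chi2, df=1))
        return PairedTestResult(float(chi2), p, "mcnemar")
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), b + c, 0.5)))
    return PairedTestResult(float(min(b, c)), p, "mcnemar")


def wilcoxon_signed_rank(values_a: Sequence[float], values_b: Sequence[float],
                         exact_max_n: int = 12) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test, exact for small n.

    Zero differences are dropped; tied |differences| receive midranks.  For
    n <= ``exact_max_n`` the null distribution of W+ is enumerated over all
    2^n sign assignments (valid under ties as well); larger n falls back to
    the normal approximation with tie correction.  No nonzero differences
    => p = 1 by convention.
    """
    d = np.asarray(values_a, dtype=np.float64) - np.asarray(values_b, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return PairedTestResult(0.0, 1.0, "wilcoxon")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        sums = np.zeros(1)
        for r in ranks:  # convolve the +-r/0 contributions
            sums = np.concatenate([sums, sums + r])
        total = len(sums)
        lo_tail = np.sum(sums <= w_plus + 1e-9) / total
        hi_tail = np.sum(sums >= w_plus - 1e-9) / total
        p = min(1.0, 2.0 * min(lo_tail, hi_tail))
    else:
        mean = n * (n + 1) / 4.0
        tie_term = np.sum(ranks**3 - ranks) / 48.0  # midrank tie correction
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return PairedTestResult(w_plus, float(p), "wilcoxon")


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(preds: PredictionSet,
                 metric: Callable[[np.ndarray, np.ndarray], float],
                 n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Patient-level percentile bootstrap CI for a (y_true, y_score) metric.

    Patients are resampled with replacement, keeping all of a patient's
    images together.  Resamples on which the metric is undefined (e.g. a
    single-class draw for AUROC) are skipped.
    """
    rng = np.random.default_rng(seed)
    patients = np.unique(preds.patient_id)
    by_patient = {p: np.flatnonzero(preds.patient_id == p) for p in patients}
    values = []
    for _ in range(n_boot):
        draw = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([by_patient[p] for p in draw])
        try:
            values.append(metric(preds.y_true[idx], preds.prob_malignant[idx]))
        except ValueError:
            continue
    if not values:
        raise ValueError("metric undefined on every bootstrap resample")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def attach_cis(report: MetricReport, preds: PredictionSet, n_boot: int = 2000,
               seed: int = 0) -> MetricReport:
    """Fill the CI slots of a report via the patient-level bootstrap."""
    t = report.threshold

    def at_threshold(attr: str) -> Callable[[np.ndarray, np.ndarray], float]:
        return lambda y, s: getattr(confusion_report(y, s, t), attr)

    metrics: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
        "accuracy": at_threshold("accuracy"),
        "auroc": auroc,
        "auprc": auprc,
        "recall_malignant": at_threshold("recall_malignant"),
        "specificity": at_threshold("specificity"),
        "balanced_accuracy": at_threshold("balanced_accuracy"),
    }
    for i, (name, fn) in enumerate(metrics.items()):
        report.ci[name] = bootstrap_ci(preds, fn, n_boot=n_boot, seed=seed + i)
    return report
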