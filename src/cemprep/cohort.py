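"""Patient-level, leakage-safe partitioning.

All partitioning happens at the patient level: a patient's images always
travel together, whether into the hold-out test set, a cross-validation
fold, or out of the training set during majority-class undersampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SplitPlan:
    """Patient -> {hold-out test | fold 1..k} assignment."""

    holdout_test: frozenset[str]
    folds: dict[int, frozenset[str]]
    k: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.folds) != set(range(1, self.k + 1)):
            raise ValueError(f"folds must be indexed 1..{self.k}")
        seen: set[str] = set(self.holdout_test)
        for idx in sorted(self.folds):
            fold = self.folds[idx]
            if seen & fold:
                raise ValueError(f"patient overlap involving fold {idx}")
            seen |= fold

    @property
    def all_patients(self) -> frozenset[str]:
        out = set(self.holdout_test)
        for fold in self.folds.values():
            out |= fold
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": p, "partition": "test"} for p in sorted(self.holdout_test)]
        for idx in sorted(self.folds):
            rows += [{"patient_id": p, "partition": f"fold{idx}"} for p in sorted(self.folds[idx])]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def patient_labels(manifest: pd.DataFrame) -> dict[str, str]:
    """Patient-level labels: a patient is malignant iff any image is malignant."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    out: dict[str, str] = {}
    for pid, group in manifest.groupby("patient_id"):
        out[str(pid)] = ("malignant" if (group["label"] == "malignant").any()
                         else "benign_negative")
    return out


def _split_by_class(labels: dict[str, str]) -> tuple[list[str], list[str]]:
    malignant = sorted(p for p, lab in labels.items() if lab == "malignant")
    benign = sorted(p for p, lab in labels.items() if lab == "benign_negative")
    return malignant, benign


def make_holdout(labels: dict[str, str], malignant_fraction: float = 0.15,
                 seed: int = 0) -> tuple[frozenset[str], dict[str, str]]:
    """Draw the hold-out test set and return (test_set, remaining labels).

    round(malignant_fraction * n_malignant) malignant patients are drawn
    uniformly, together with an equal count of benign/negative patients
    (balanced sampling), so test-set balanced accuracy is symmetric.
    """
    malignant, benign = _split_by_class(labels)
    n_test = int(round(malignant_fraction * len(malignant)))
    if n_test > len(benign):
        raise ValueError(
            f"need {n_test} benign/negative patients for a balanced hold-out, "
            f"have {len(benign)}"
        )
    rng = np.random.default_rng(seed)
    test = set(rng.choice(malignant, size=n_test, replace=False)) if n_test else set()
    test |= set(rng.choice(benign, size=n_test, replace=False)) if n_test else set()
    remainder = {p: lab for p, lab in labels.items() if p not in test}
    return frozenset(test), remainder


def make_folds(labels: dict[str, str], k: int = 5, seed: int = 0,
               holdout: frozenset[str] = frozenset()) -> SplitPlan:
    """Stratified k-fold assignment at the patient level.

    Malignant and benign patients are shuffled separately and dealt
    round-robin, so per-fold class counts differ by at most 1 from perfect
    stratification.
    """
    malignant, benign = _split_by_class(labels)
    rng = np.random.default_rng(seed)
    folds: dict[int, set[str]] = {i: set() for i in range(1, k + 1)}
    for group in (malignant, benign):
        order = list(group)
        rng.shuffle(order)
        for i, patient in enumerate(order):
            folds[1 + i % k].add(patient)
    return SplitPlan(
        holdout_test=frozenset(holdout),
        folds={i: frozenset(s) for i, s in folds.items()},
        k=k,
        seed=seed,
    )


def make_split_plan(labels: dict[str, str], k: int = 5,
                    holdout_malignant_fraction: float = 0.15,
                    seed: int = 0) -> SplitPlan:
    """Hold-out draw followed by stratified k-fold on the remainder."""
    holdout, remainder = make_holdout(labels, holdout_malignant_fraction, seed)
    return make_folds(remainder, k=k, seed=seed, holdout=holdout)


def undersample_train(manifest: pd.DataFrame, ratio: float = 2.0,
                      seed: int = 0) -> pd.DataFrame:
    """Reduce the majority class so n_majority <= ratio * n_minority.

    Operates at patient granularity: a patient's images are kept or dropped
    together, preserving the leakage guarantee.  No-op when the classes are
    already within the ratio.
    """
    labels = patient_labels(manifest)
    malignant, benign = _split_by_class(labels)
    if len(malignant) <= len(benign):
        minority, majority = malignant, benign
    else:
        minority, majority = benign, malignant
    target = int(ratio * len(minority))
    if len(majority) <= target:
        return manifest.copy()
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(majority, size=target, replace=False)) | set(minority)
    return manifest[manifest["patient_id"].isin(kept)].copy()


def audit_leakage(plan: SplitPlan, manifest: pd.DataFrame,
                  reference_cdf_rule: str | None = None) -> dict:
    """Assert the leakage-safety contract and return an audit report.

    Checks: no patient in two partitions; every manifest patient assigned;
    the reference-CDF background rule (the only cross-image preprocessing
    statistic) carries no partition tags.
    """
    partitions = [("test", plan.holdout_test)] + [
        (f"fold{i}", plan.folds[i]) for i in sorted(plan.folds)
    ]
    seen: dict[str, str] = {}
    for name, patients in partitions:
        for p in patients:
            if p in seen:
                raise ValueError(f"patient {p} appears in both {seen[p]} and {name}")
            seen[p] = name
    manifest_patients = set(manifest["patient_id"])
    unassigned = manifest_patients - set(seen)
    if unassigned:
        raise ValueError(f"patients missing from split plan: {sorted(unassigned)}")
    if reference_cdf_rule is not None:
        tokens = ("fold", "test", "train", "holdout")
        if any(t in reference_cdf_rule.lower() for t in tokens):
            raise ValueError(
                f"reference CDF rule {reference_cdf_rule!r} carries a partition tag"
            )
    return {
        "n_patients": len(seen),
        "n_test": len(plan.holdout_test),
        "fold_sizes": {i: len(plan.folds[i]) for i in sorted(plan.folds)},
        "overlap": 0,
    }
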