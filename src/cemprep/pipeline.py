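"""Experiment orchestration: representations, shared splits, training, reports.

The controlled comparison trains identical classifiers under different input
representations — the enhanced full-field image versus the same enhanced
image with the anatomical breast mask applied — using one shared
patient-level split plan, a Youden threshold estimated only from aggregated
validation predictions, and a battery of paired statistics on the hold-out
test set.  The two enhanced arms are bitwise identical inside the mask;
masking is the only difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import breastmask as bm
from . import cohort as ch
from . import enhance as en
from .classifier import SmallCNNAdapter, TrainConfig, TrainHistory, train_protocol
from .evalstats import (MetricReport, PairedTestResult, PredictionSet, attach_cis,
                        auroc, confusion_report, delong_test, mcnemar_test,
                        wilcoxon_signed_rank, youden_threshold)
from .phantom import PhantomConfig, PhantomRecord, generate_cohort

REPRESENTATION_MODES = ("raw_windowed", "enhanced_full_field", "enhanced_breast_masked")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a representation-comparison experiment needs."""

    phantom: PhantomConfig = PhantomConfig()
    enhance: en.EnhanceConfig = en.EnhanceConfig()
    train: TrainConfig = TrainConfig()
    arms: tuple[str, str] = ("enhanced_full_field", "enhanced_breast_masked")
    k: int = 5
    holdout_malignant_fraction: float = 0.15
    undersample_ratio: float = 2.0
    bootstrap_n: int = 2000
    seed: int = 42

    def __post_init__(self) -> None:
        for arm in self.arms:
            if arm not in REPRESENTATION_MODES:
                raise ValueError(f"unknown representation mode {arm!r}")


@dataclass
class Representations:
    """Per-image derived rasters keyed by image_id, one entry per mode."""

    images: dict[str, dict[str, np.ndarray]]
    masks: dict[str, bm.BreastMask]
    reference: en.ReferenceCDF

    def stack(self, mode: str, image_ids: list[str]) -> np.ndarray:
        return np.stack([self.images[i][mode] for i in image_ids])


def build_representations(records: list[PhantomRecord],
                          config: en.EnhanceConfig,
                          modes: tuple[str, ...] = REPRESENTATION_MODES,
                          pectoral_removal: bool = True) -> Representations:
    """Compute every requested representation for every record.

    The reference CDF is pooled over the whole cohort (after background
    exclusion) before any splitting, and breast masks are always computed
    from the original, unenhanced image, then resized (nearest-neighbour)
    to the output grid.  The masked representation reuses the enhanced
    pixels unchanged inside the mask.
    """
    windowed = {r.image_id: en.to_uint8(en.percentile_window(r.image, config.windowing))
                for r in records}
    ref = en.build_reference_cdf(list(windowed.values()), en.DEFAULT_BACKGROUND_RULE)

    images: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, bm.BreastMask] = {}
    need_enhanced = {"enhanced_full_field", "enhanced_breast_masked"} & set(modes)
    need_mask = "enhanced_breast_masked" in modes
    for rec in records:
        per_mode: dict[str, np.ndarray] = {}
        if "raw_windowed" in modes:
            per_mode["raw_windowed"] = en.resize(windowed[rec.image_id], config.out_size).pixels
        if need_enhanced:
            enhanced = en.preprocess_image(rec.image, config, ref)
            per_mode["enhanced_full_field"] = enhanced.pixels
            if need_mask:
                mask = bm.segment_breast(rec.image, view=rec.view,
                                         pectoral_removal=pectoral_removal)
                masks[rec.image_id] = mask
                small = bm.resize_mask(mask, config.out_size)
                per_mode["enhanced_breast_masked"] = bm.apply_mask(enhanced, small).pixels
        images[rec.image_id] = per_mode
    return Representations(images=images, masks=masks, reference=ref)


@dataclass
class ArmResult:
    mode: str
    fold_auroc: list[float]
    fold_balanced_accuracy: list[float]
    threshold: float
    validation_preds: PredictionSet
    test_preds: PredictionSet
    test_report: MetricReport
    histories: list[TrainHistory] = field(default_factory=list)


@dataclass
class ExperimentResult:
    arms: dict[str, ArmResult]
    plan: ch.SplitPlan
    delong: PairedTestResult
    mcnemar: PairedTestResult
    wilcoxon_auroc: PairedTestResult
    wilcoxon_balanced_accuracy: PairedTestResult
    config: ExperimentConfig

    def comparison_frame(self) -> pd.DataFrame:
        a, b = self.config.arms
        return pd.DataFrame([
            {"test": "delong_auroc", "statistic": self.delong.statistic,
             "p_value": self.delong.p_value, "arm_a": a, "arm_b": b},
            {"test": "mcnemar", "statistic": self.mcnemar.statistic,
             "p_value": self.mcnemar.p_value, "arm_a": a, "arm_b": b},
            {"test": "wilcoxon_fold_auroc", "statistic": self.wilcoxon_auroc.statistic,
             "p_value": self.wilcoxon_auroc.p_value, "arm_a": a, "arm_b": b},
            {"test": "wilcoxon_fold_balanced_accuracy",
             "statistic": self.wilcoxon_balanced_accuracy.statistic,
             "p_value": self.wilcoxon_balanced_accuracy.p_value, "arm_a": a, "arm_b": b},
        ])

    def write_reports(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        fmt = "%.10g"
        for mode, arm in self.arms.items():
            p = out / f"metrics_{mode}.csv"
            arm.test_report.to_frame().to_csv(p, index=False, float_format=fmt)
            written.append(p)
            p = out / f"fold_metrics_{mode}.csv"
            pd.DataFrame({
                "fold": np.arange(1, len(arm.fold_auroc) + 1),
                "auroc": arm.fold_auroc,
                "balanced_accuracy": arm.fold_balanced_accuracy,
            }).to_csv(p, index=False, float_format=fmt)
            written.append(p)
        p = out / "comparison.csv"
        self.comparison_frame().to_csv(p, index=False, float_format=fmt)
        written.append(p)
        p = out / "split_plan.csv"
        self.plan.to_csv(p)
        written.append(p)
        return written


def _image_table(records: list[PhantomRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "image_id": [r.image_id for r in records],
        "patient_id": [r.patient_id for r in records],
        "label": [r.label for r in records],
    })


def _fold_seed(base_seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([base_seed, fold]).generate_state(1)[0] % (2**31))


def run_arm(mode: str, reps: Representations, table: pd.DataFrame,
            plan: ch.SplitPlan, config: ExperimentConfig) -> ArmResult:
    """Cross-validated training and hold-out evaluation for one representation.

    Fold models are trained on the undersampled union of the other folds and
    produce validation predictions on their own fold; the hold-out test
    probability of each image is the mean over the k fold models.  The seeds
    that drive initialization, shuffling and undersampling depend only on
    (experiment seed, fold), so both arms train under identical randomness.
    """
    y_of = {"malignant": 1, "benign_negative": 0}
    input_size = config.enhance.out_size[0]

    val_parts: list[pd.DataFrame] = []
    fold_auc: list[float] = []
    histories: list[TrainHistory] = []
    test_prob_sum: np.ndarray | None = None

    test_rows = table[table["patient_id"].isin(plan.holdout_test)].reset_index(drop=True)
    test_x = reps.stack(mode, list(test_rows["image_id"]))
    test_y = test_rows["label"].map(y_of).to_numpy()

    for fold in sorted(plan.folds):
        seed = _fold_seed(config.seed, fold)
        val_patients = plan.folds[fold]
        train_patients = frozenset().union(
            *[plan.folds[f] for f in plan.folds if f != fold])
        train_rows = table[table["patient_id"].isin(train_patients)]
        train_rows = ch.undersample_train(train_rows, config.undersample_ratio, seed)
        val_rows = table[table["patient_id"].isin(val_patients)].reset_index(drop=True)

        train_x = reps.stack(mode, list(train_rows["image_id"]))
        train_y = train_rows["label"].map(y_of).to_numpy()
        val_x = reps.stack(mode, list(val_rows["image_id"]))
        val_y = val_rows["label"].map(y_of).to_numpy()

        adapter = SmallCNNAdapter(seed=seed, input_size=input_size)
        tcfg = replace(config.train, seed=seed)
        histories.append(train_protocol(adapter, train_x, train_y, val_x, val_y, tcfg))

        val_prob = adapter.predict_proba(val_x)
        fold_auc.append(auroc(val_y, val_prob))
        val_parts.append(pd.DataFrame({
            "image_id": val_rows["image_id"],
            "patient_id": val_rows["patient_id"],
            "prob": val_prob,
            "y": val_y,
            "fold": fold,
        }))
        prob_t = adapter.predict_proba(test_x)
        test_prob_sum = prob_t if test_prob_sum is None else test_prob_sum + prob_t

    val_df = pd.concat(val_parts, ignore_index=True)
    val_preds = PredictionSet(val_df["image_id"].to_numpy(),
                              val_df["patient_id"].to_numpy(),
                              val_df["prob"].to_numpy(),
                              val_df["y"].to_numpy(),
                              fold=val_df["fold"].to_numpy())
    threshold = youden_threshold(val_preds.y_true, val_preds.prob_malignant)

    fold_balacc = []
    for fold in sorted(plan.folds):
        sel = val_preds.fold == fold
        rep = confusion_report(val_preds.y_true[sel], val_preds.prob_malignant[sel], threshold)
        fold_balacc.append(rep.balanced_accuracy)

    test_prob = test_prob_sum / len(plan.folds)
    test_preds = PredictionSet(test_rows["image_id"].to_numpy(),
                               test_rows["patient_id"].to_numpy(),
                               test_prob, test_y)
    report = confusion_report(test_y, test_prob, threshold)
    if config.bootstrap_n > 0:
        report = attach_cis(report, test_preds, n_boot=config.bootstrap_n,
                            seed=_fold_seed(config.seed, 9999))
    return ArmResult(mode=mode, fold_auroc=fold_auc,
                     fold_balanced_accuracy=fold_balacc, threshold=float(threshold),
                     validation_preds=val_preds, test_preds=test_preds,
                     test_report=report, histories=histories)


def run_experiment(config: ExperimentConfig = ExperimentConfig(),
                   records: list[PhantomRecord] | None = None,
                   out_dir=None) -> ExperimentResult:
    """The full controlled comparison on a phantom cohort.

    One cohort, one split plan, two representations differing only by
    masking; per-arm cross-validation, aggregated-validation Youden
    threshold, hold-out evaluation at that fixed threshold, and paired
    DeLong / McNemar / Wilcoxon statistics between the arms.
    """
    if records is None:
        records = generate_cohort(config.phantom)
    table = _image_table(records)
    labels = ch.patient_labels(table)
    plan = ch.make_split_plan(labels, k=config.k,
                              holdout_malignant_fraction=config.holdout_malignant_fraction,
                              seed=config.seed)
    ch.audit_leakage(plan, table, reference_cdf_rule=en.DEFAULT_BACKGROUND_RULE)

    reps = build_representations(records, config.enhance, modes=tuple(set(config.arms)))
    arms = {mode: run_arm(mode, reps, table, plan, config) for mode in config.arms}

    arm_a, arm_b = (arms[m] for m in config.arms)
    # identical case ordering by construction (same test_rows per arm)
    delong = delong_test(arm_a.test_preds.y_true,
                         arm_a.test_preds.prob_malignant,
                         arm_b.test_preds.prob_malignant)
    correct_a = (arm_a.test_preds.prob_malignant >= arm_a.threshold) == arm_a.test_preds.y_true
    correct_b = (arm_b.test_preds.prob_malignant >= arm_b.threshold) == arm_b.test_preds.y_true
    mcn = mcnemar_test(correct_a, correct_b)
    wil_auc = wilcoxon_signed_rank(arm_a.fold_auroc, arm_b.fold_auroc)
    wil_bal = wilcoxon_signed_rank(arm_a.fold_balanced_accuracy,
                                   arm_b.fold_balanced_accuracy)
    result = ExperimentResult(arms=arms, plan=plan, delong=delong, mcnemar=mcn,
                              wilcoxon_auroc=wil_auc,
                              wilcoxon_balanced_accuracy=wil_bal, config=config)
    if out_dir is not None:
        result.write_reports(out_dir)
    return result


def scaled_experiment_config(seed: int = 42, n_patients: int = 200,
                             image_size: int = 64,
                             confound_strength: float = 0.8,
                             bootstrap_n: int = 200) -> ExperimentConfig:
    """Desk-scale study conditions for the phantom representation comparison.

    200 patients at 64 px with a strong (0.8) marker-label confound; the
    enhancement chain runs at the phantom resolution and the reference CNN
    trains under the scaled-down schedule.
    """
    phantom = PhantomConfig(
        n_patients=n_patients,
        malignant_fraction=0.3,
        image_size=image_size,
        confound_strength=confound_strength,
        artifact_rate=0.3,
        seed=seed,
    )
    enh = en.EnhanceConfig(out_size=(image_size, image_size))
    train = TrainConfig().scaled_down()
    return ExperimentConfig(phantom=phantom, enhance=enh, train=train,
                            bootstrap_n=bootstrap_n, seed=seed)
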