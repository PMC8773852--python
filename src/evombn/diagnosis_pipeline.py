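"""MI detection and localization orchestration, metrics and cross validation.

Detection is MI-vs-HC binary classification (all MI subcategories collapse to
one positive class).  Localization distinguishes the five location-based MI
subcategories plus HC and can run either as a single multiclass classifier
(``model_m``) or as a group of one-vs-rest binary classifiers whose prediction
is the class with the maximum positive probability (``model_b``).

All evaluation follows the inter-patient paradigm: train/test splits and
cross-validation folds partition *patients*, never beats, and the partition
property is asserted structurally on every split.  Metrics are the standard
one-vs-rest Sen/Spe/Ppv/Acc percentages and the F1 score
2*TP/(2*TP + FP + FN) = 2*Sen*Ppv/(Sen + Ppv) on the fractional scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .branch_network import FeatureBank, build_feature_bank
from .data import BeatDataset
from .ga_search import GAConfig, LSEFitnessEvaluator, evolve
from .leads import LOCALIZATION_CLASSES
from .lse_summarizer import LSEConfig, predict_proba, train_lse


@dataclass
class ConfusionMatrix:
    """Beat counts indexed [true class, predicted class] in a fixed order."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self):
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square over the class order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = tuple(classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(classes, counts)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot pool matrices with different class orders")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Per-class and mean Sen/Spe/Ppv (in %), overall Acc (%), F1 (fraction)."""

    task: str
    cm: ConfusionMatrix
    per_class: dict
    mean: dict
    overall_acc: float

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "classes": list(self.cm.classes),
            "confusion_matrix": self.cm.counts.tolist(),
            "per_class": self.per_class,
            "mean": self.mean,
            "overall_acc": self.overall_acc,
        }


def compute_metrics(cm: ConfusionMatrix, task: str = "") -> EvaluationReport:
    """One-vs-rest metrics per class, their unweighted mean, and overall Acc.

    A class with zero positives has undefined sensitivity; it is reported as
    missing (NaN) and excluded from the mean row with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    total = cm.total
    per_class = {}
    for i, c in enumerate(cm.classes):
        tp = int(counts[i, i])
        fn = int(counts[i, :].sum() - tp)
        fp = int(counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {c} has no positive samples; Sen/F1 undefined")
            sen = np.nan
        else:
            sen = 100.0 * tp / (tp + fn)
        spe = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
        ppv = 100.0 * tp / (tp + fp) if (tp + fp) else np.nan
        acc = 100.0 * (tp + tn) / total
        denom = 2 * tp + fp + fn
        f1 = (2.0 * tp / denom) if denom else np.nan
        per_class[c] = {"Sen": sen, "Spe": spe, "Ppv": ppv, "Acc": acc, "F1": f1}

    def _mean(key):
        vals = [per_class[c][key] for c in cm.classes
                if np.isfinite(per_class[c][key])]
        return float(np.mean(vals)) if vals else np.nan

    mean = {k: _mean(k) for k in ("Sen", "Spe", "Ppv", "Acc", "F1")}
    overall = 100.0 * float(np.trace(counts)) / total
    return EvaluationReport(task=task, cm=cm, per_class=per_class, mean=mean,
                            overall_acc=overall)


# --------------------------------------------------------------------------
# inter-patient splitting
# --------------------------------------------------------------------------

def _patient_class_map(labels, patient_ids) -> dict:
    mapping = {}
    for pid, lab in zip(patient_ids, labels):
        mapping.setdefault(pid, lab)
    return mapping


def patient_folds(labels, patient_ids, folds: int, seed: int = 0):
    """Partition patients into class-stratified folds; returns per-fold test
    masks over beats.  Raises if any class has fewer patients than folds."""
    pmap = _patient_class_map(labels, patient_ids)
    classes = sorted(set(pmap.values()))
    rng = np.random.default_rng(seed)
    assignment = {}
    for c in classes:
        cp = sorted(p for p, lab in pmap.items() if lab == c)
        if len(cp) < folds:
            raise ValueError(f"class {c} has {len(cp)} patients; need >= {folds}")
        cp = list(rng.permutation(cp))
        for i, p in enumerate(cp):
            assignment[p] = i % folds
    masks = []
    pid_arr = np.asarray(patient_ids)
    for f in range(folds):
        test_patients = {p for p, ff in assignment.items() if ff == f}
        mask = np.isin(pid_arr, sorted(test_patients))
        masks.append(mask)
    return masks


def patient_split(labels, patient_ids, test_fraction: float = 0.2, seed: int = 0):
    """Single stratified patient-wise split; returns (train_mask, test_mask)."""
    pmap = _patient_class_map(labels, patient_ids)
    classes = sorted(set(pmap.values()))
    rng = np.random.default_rng(seed)
    test_patients = set()
    for c in classes:
        cp = sorted(p for p, lab in pmap.items() if lab == c)
        n_test = max(1, int(round(test_fraction * len(cp))))
        if n_test >= len(cp):
            raise ValueError(f"class {c} has too few patients to split")
        test_patients.update(list(rng.permutation(cp))[:n_test])
    pid_arr = np.asarray(patient_ids)
    test_mask = np.isin(pid_arr, sorted(test_patients))
    assert not set(pid_arr[~test_mask]) & set(pid_arr[test_mask])
    return ~test_mask, test_mask


@dataclass
class PipelineConfig:
    """Settings shared by the detection/localization runners."""

    ga: GAConfig = field(default_factory=GAConfig)
    lse: LSEConfig = field(default_factory=LSEConfig)
    final_lse_epochs: int = 30
    test_fraction: float = 0.2
    seed: int = 0


def _final_lse_config(config: PipelineConfig, seed_offset: int = 0) -> LSEConfig:
    return LSEConfig(epochs=config.final_lse_epochs, batch=config.lse.batch,
                     lr=config.lse.lr, r=config.lse.r,
                     seed=config.seed + 1000 + seed_offset,
                     force_excitation=config.lse.force_excitation)


def run_detection(bank: FeatureBank, config: PipelineConfig,
                  split=None):
    """Evolve one genome for MI-vs-HC detection and score it on held-out
    patients.  Returns ``(best Individual, EvaluationReport, history)``."""
    if "HC" not in set(bank.labels):
        raise ValueError("detection requires an HC class in the bank")
    mi_classes = [c for c in bank.class_set if c != "HC"]
    det_bank = bank.relabel({c: "MI" for c in mi_classes}, ("HC", "MI"))
    if split is None:
        split = patient_split(det_bank.labels, det_bank.patient_ids,
                              config.test_fraction, config.seed)
    train_mask, test_mask = split
    train_bank = det_bank.subset(train_mask)
    test_bank = det_bank.subset(test_mask)

    evaluator = LSEFitnessEvaluator(train_bank, task="binary",
                                    positive_class="MI", classes=("HC", "MI"),
                                    lse=config.lse, seed=config.seed)
    best, history = evolve(evaluator, config.ga)

    model, _ = train_lse(train_bank, best.genome, _final_lse_config(config),
                         classes=("HC", "MI"), class_mode="binary",
                         positive_class="MI")
    proba = predict_proba(model, test_bank,
                          force_excitation=config.lse.force_excitation)
    y_pred = np.where(proba >= 0.5, "MI", "HC")
    cm = ConfusionMatrix.from_labels(test_bank.labels, y_pred, ("MI", "HC"))
    report = compute_metrics(cm, task="detection")
    return best, report, history


def run_localization(bank: FeatureBank, mode: str, config: PipelineConfig,
                     split=None, classes=None):
    """Localization with a multiclass head or a group of binary heads.

    Returns ``(genomes, EvaluationReport)`` where ``genomes`` maps class name
    to its evolved genome in ``binary_group`` mode, or has the single key
    ``"multiclass"`` otherwise.
    """
    if mode not in ("multiclass", "binary_group"):
        raise ValueError("mode must be 'multiclass' or 'binary_group'")
    if classes is None:
        classes = tuple(c for c in LOCALIZATION_CLASSES if c in set(bank.labels))
    if len(classes) < 2:
        raise ValueError("localization needs at least two classes")
    loc_bank = bank.subset(np.isin(bank.labels, classes))
    loc_bank = FeatureBank(features=loc_bank.features, labels=loc_bank.labels,
                           patient_ids=loc_bank.patient_ids,
                           level_set=loc_bank.level_set, class_set=classes)
    if split is None:
        split = patient_split(loc_bank.labels, loc_bank.patient_ids,
                              config.test_fraction, config.seed)
    train_mask, test_mask = split
    train_bank = loc_bank.subset(train_mask)
    test_bank = loc_bank.subset(test_mask)

    if mode == "multiclass":
        evaluator = LSEFitnessEvaluator(train_bank, task="multiclass",
                                        classes=classes, lse=config.lse,
                                        seed=config.seed)
        best, _ = evolve(evaluator, config.ga)
        model, _ = train_lse(train_bank, best.genome, _final_lse_config(config),
                             classes=classes, class_mode="multiclass")
        proba = predict_proba(model, test_bank,
                              force_excitation=config.lse.force_excitation)
        y_pred = np.array([classes[i] for i in np.argmax(proba, axis=1)])
        genomes = {"multiclass": best.genome}
        models = {"multiclass": model}
    else:
        genomes, models = {}, {}
        pos_proba = np.zeros((test_bank.n_beats, len(classes)))
        for j, c in enumerate(classes):
            ga = GAConfig(**{**config.ga.__dict__, "seed": config.ga.seed + j})
            evaluator = LSEFitnessEvaluator(train_bank, task="binary",
                                            positive_class=c, classes=classes,
                                            lse=config.lse, seed=config.seed + j)
            best, _ = evolve(evaluator, ga)
            model, _ = train_lse(train_bank, best.genome,
                                 _final_lse_config(config, j), classes=classes,
                                 class_mode="binary", positive_class=c)
            genomes[c] = best.genome
            models[c] = model
            pos_proba[:, j] = predict_proba(
                model, test_bank, force_excitation=config.lse.force_excitation)
        # argmax over per-class positive probabilities; np.argmax keeps the
        # first (fixed class order) index on ties
        y_pred = np.array([classes[i] for i in np.argmax(pos_proba, axis=1)])

    cm = ConfusionMatrix.from_labels(test_bank.labels, y_pred, classes)
    report = compute_metrics(cm, task=f"localization/{mode}")
    return genomes, report, models


def cross_validate(bank: FeatureBank, task: str, folds: int = 5,
                   config: PipelineConfig | None = None, mode: str = "binary_group"):
    """Inter-patient k-fold cross validation on a prebuilt feature bank.

    ``task`` is ``"detection"`` or ``"localization"``.  Folds partition
    patients (stratified by class); the pooled confusion matrix is the
    elementwise sum over folds.  Returns ``(fold_reports, pooled_report)``.
    """
    config = config or PipelineConfig()
    masks = patient_folds(bank.labels, bank.patient_ids, folds, config.seed)
    reports = []
    pooled = None
    for f, test_mask in enumerate(masks):
        train_pids = set(bank.patient_ids[~test_mask])
        test_pids = set(bank.patient_ids[test_mask])
        assert not train_pids & test_pids, "inter-patient guarantee violated"
        split = (~test_mask, test_mask)
        fold_cfg = PipelineConfig(ga=GAConfig(**{**config.ga.__dict__,
                                                 "seed": config.ga.seed + 101 * f}),
                                  lse=config.lse,
                                  final_lse_epochs=config.final_lse_epochs,
                                  test_fraction=config.test_fraction,
                                  seed=config.seed + 101 * f)
        if task == "detection":
            _, report, _ = run_detection(bank, fold_cfg, split=split)
        elif task == "localization":
            _, report, _ = run_localization(bank, mode, fold_cfg, split=split)
        else:
            raise ValueError("task must be 'detection' or 'localization'")
        reports.append(report)
        pooled = report.cm if pooled is None else pooled + report.cm
    return reports, compute_metrics(pooled, task=f"{task}/pooled")


def transfer_architecture(genomes: dict, nets, new_dataset: BeatDataset,
                          config: PipelineConfig, task: str = "detection"):
    """Reuse frozen branch extractors and learned genomes on a new dataset.

    Branch weights are untouched (checksummed before/after); a fresh feature
    bank is built on the new dataset and only the LSE head(s) are retrained.
    Returns ``(EvaluationReport, bank)``.
    """
    from .leads import LEAD_NAMES
    if tuple(new_dataset.lead_order) != LEAD_NAMES:
        raise ValueError("lead order mismatch between source and target datasets")
    checksums = [net.param_checksum() for net in nets]
    bank = build_feature_bank(nets, new_dataset)
    after = [net.param_checksum() for net in nets]
    assert checksums == after, "branch weights changed during transfer"

    split = patient_split(bank.labels, bank.patient_ids, config.test_fraction,
                          config.seed)
    if task == "detection":
        genome = genomes.get("detection") or next(iter(genomes.values()))
        mi_classes = [c for c in bank.class_set if c != "HC"]
        det_bank = bank.relabel({c: "MI" for c in mi_classes}, ("HC", "MI"))
        train_bank = det_bank.subset(split[0])
        test_bank = det_bank.subset(split[1])
        model, _ = train_lse(train_bank, genome, _final_lse_config(config),
                             classes=("HC", "MI"), class_mode="binary",
                             positive_class="MI")
        proba = predict_proba(model, test_bank)
        y_pred = np.where(proba >= 0.5, "MI", "HC")
        cm = ConfusionMatrix.from_labels(test_bank.labels, y_pred, ("MI", "HC"))
        report = compute_metrics(cm, task="transfer/detection")
    else:
        classes = tuple(c for c in LOCALIZATION_CLASSES if c in set(bank.labels))
        train_bank = bank.subset(split[0])
        test_bank = bank.subset(split[1])
        pos_proba = np.zeros((test_bank.n_beats, len(classes)))
        for j, c in enumerate(classes):
            model, _ = train_lse(train_bank, genomes[c], _final_lse_config(config, j),
                                 classes=classes, class_mode="binary",
                                 positive_class=c)
            pos_proba[:, j] = predict_proba(model, test_bank)
        y_pred = np.array([classes[i] for i in np.argmax(pos_proba, axis=1)])
        cm = ConfusionMatrix.from_labels(test_bank.labels, y_pred, classes)
        report = compute_metrics(cm, task="transfer/localization")
    assert [net.param_checksum() for net in nets] == checksums
    return report, bank
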