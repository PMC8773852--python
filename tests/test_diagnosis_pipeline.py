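"""Metrics, inter-patient splitting, detection/localization, transfer."""

import numpy as np
import pytest

from evombn import generate_beat_dataset
from evombn.branch_network import build_feature_bank
from evombn.diagnosis_pipeline import (ConfusionMatrix, PipelineConfig,
                                       compute_metrics, cross_validate,
                                       patient_folds, patient_split, run_detection,
                                       run_localization, transfer_architecture)
from evombn.ga_search import GAConfig
from evombn.lse_summarizer import LSEConfig


def _fast_config(seed=11, pop=20):
    return PipelineConfig(
        ga=GAConfig(pop_size=pop, n_parents=4, max_generations=5, seed=seed),
        lse=LSEConfig(epochs=15, seed=seed), final_lse_epochs=30, seed=seed)


class TestComputeMetrics:
    def test_hand_worked_binary_table(self):
        # TP=90, FN=10, TN=80, FP=20 with MI positive
        counts = np.array([[90, 10], [20, 80]])
        cm = ConfusionMatrix(("MI", "HC"), counts)
        rep = compute_metrics(cm)
        mi = rep.per_class["MI"]
        np.testing.assert_allclose(mi["Sen"], 90.0, atol=1e-9)
        np.testing.assert_allclose(mi["Spe"], 80.0, atol=1e-9)
        np.testing.assert_allclose(mi["Ppv"], 100 * 90 / 110, atol=1e-9)  # 81.82
        np.testing.assert_allclose(mi["Acc"], 85.0, atol=1e-9)
        np.testing.assert_allclose(mi["F1"], 2 * 90 / (180 + 20 + 10), atol=1e-9)
        np.testing.assert_allclose(rep.overall_acc, 85.0, atol=1e-9)

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(("A", "B", "C"), np.diag([5, 7, 9]))
        rep = compute_metrics(cm)
        for c in ("A", "B", "C"):
            assert rep.per_class[c]["Sen"] == 100.0
            assert rep.per_class[c]["Spe"] == 100.0
            assert rep.per_class[c]["F1"] == 1.0
        assert rep.overall_acc == 100.0

    def test_zero_positive_class_warns_and_excluded_from_mean(self):
        counts = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 0]])
        cm = ConfusionMatrix(("A", "B", "C"), counts)
        with pytest.warns(UserWarning, match="C"):
            rep = compute_metrics(cm)
        assert np.isnan(rep.per_class["C"]["Sen"])
        assert np.isfinite(rep.mean["Sen"])

    def test_identities_against_brute_force_tally(self):
        """Acc and F1 identities hold vs an independent label-level tally on
        random contingency tables."""
        rng = np.random.default_rng(0)
        classes = ("w", "x", "y")
        for _ in range(20):
            y_true = rng.choice(classes, size=200)
            y_pred = rng.choice(classes, size=200)
            cm = ConfusionMatrix.from_labels(y_true, y_pred, classes)
            rep = compute_metrics(cm)
            np.testing.assert_allclose(rep.overall_acc,
                                       100 * np.mean(y_true == y_pred), atol=1e-9)
            for c in classes:
                tp = np.sum((y_true == c) & (y_pred == c))
                tn = np.sum((y_true != c) & (y_pred != c))
                fp = np.sum((y_true != c) & (y_pred == c))
                fn = np.sum((y_true == c) & (y_pred != c))
                m = rep.per_class[c]
                np.testing.assert_allclose(
                    m["Acc"], 100 * (tp + tn) / (tp + tn + fp + fn), atol=1e-9)
                if np.isfinite(m["F1"]) and m["Sen"] + m["Ppv"] > 0:
                    harmonic = (2 * (m["Sen"] / 100) * (m["Ppv"] / 100)
                                / (m["Sen"] / 100 + m["Ppv"] / 100))
                    np.testing.assert_allclose(m["F1"], harmonic, atol=1e-9)

    def test_pooled_matrix_conservation(self):
        a = ConfusionMatrix(("A", "B"), np.array([[3, 1], [2, 4]]))
        b = ConfusionMatrix(("A", "B"), np.array([[5, 0], [1, 2]]))
        assert (a + b).total == a.total + b.total


class TestSplitting:
    def test_patient_split_is_inter_patient(self):
        ds = generate_beat_dataset(20, ("HC", "IMI"), n_patients=10, seed=1)
        train, test = patient_split(ds.labels, ds.patient_ids, 0.2, 0)
        assert not set(ds.patient_ids[train]) & set(ds.patient_ids[test])
        assert test.sum() > 0 and train.sum() > 0

    def test_folds_partition_patients(self):
        ds = generate_beat_dataset(30, ("HC", "IMI"), n_patients=10, seed=2)
        masks = patient_folds(ds.labels, ds.patient_ids, 5, seed=0)
        total = np.zeros(len(ds), dtype=int)
        for m in masks:
            total += m
            # 10 patients, 5 folds -> 2 test patients per fold
            assert len(set(ds.patient_ids[m])) == 2
        np.testing.assert_array_equal(total, 1)  # each beat tested exactly once

    def test_too_few_patients_rejected(self):
        ds = generate_beat_dataset(10, ("HC", "IMI"), n_patients=4, seed=3)
        with pytest.raises(ValueError):
            patient_folds(ds.labels, ds.patient_ids, 5, seed=0)


class TestDetection:
    def test_separable_detection_end_to_end(self, feature_bank7):
        best, report, history = run_detection(feature_bank7, _fast_config())
        assert report.task == "detection"
        assert tuple(report.cm.classes)[0] == "MI"  # MI is the positive class
        assert report.overall_acc > 90.0
        assert len(history) >= 1

    def test_label_collapse(self, feature_bank7):
        mi = [c for c in feature_bank7.class_set if c != "HC"]
        det = feature_bank7.relabel({c: "MI" for c in mi}, ("HC", "MI"))
        assert set(det.labels) == {"HC", "MI"}
        assert (det.labels == "MI").sum() == sum(
            (feature_bank7.labels == c).sum() for c in mi)

    def test_missing_hc_rejected(self, feature_bank7):
        no_hc = feature_bank7.subset(feature_bank7.labels != "HC")
        with pytest.raises(ValueError):
            run_detection(no_hc, _fast_config())


class TestLocalization:
    def test_both_modes_beat_chance_on_separable_data(self, feature_bank7):
        cfg = _fast_config()
        _, rep_m, _ = run_localization(feature_bank7, "multiclass", cfg)
        genomes, rep_b, _ = run_localization(feature_bank7, "binary_group", cfg)
        assert rep_m.overall_acc > 80.0
        assert rep_b.overall_acc > 80.0
        # one genome per class, as the per-class one-vs-rest protocol requires
        assert set(genomes) == {"HC", "AMI", "ASMI", "ALMI", "IMI", "ILMI"}

    def test_omi_excluded_from_localization(self, feature_bank7):
        _, report, _ = run_localization(feature_bank7, "multiclass",
                                        _fast_config())
        assert "OMI" not in report.cm.classes

    def test_binary_group_argmax_semantics(self):
        # a classifier outputting probability 1 for its class wins the argmax
        pos = np.array([[0.2, 1.0, 0.3], [0.5, 0.5, 0.5]])
        classes = ("HC", "AMI", "IMI")
        picks = [classes[i] for i in np.argmax(pos, axis=1)]
        assert picks[0] == "AMI"
        assert picks[1] == "HC"  # tie broken by fixed class order

    def test_unknown_mode_rejected(self, feature_bank7):
        with pytest.raises(ValueError):
            run_localization(feature_bank7, "bogus", _fast_config())


class TestCrossValidation:
    def test_detection_cv_structure(self, feature_bank7):
        cfg = _fast_config(pop=8)
        cfg.ga.n_parents = 2
        cfg.ga.max_generations = 2
        reports, pooled = cross_validate(feature_bank7, "detection", folds=3,
                                         config=cfg)
        assert len(reports) == 3
        assert pooled.cm.total == feature_bank7.n_beats
        assert pooled.cm.counts.tolist() == sum(
            r.cm.counts for r in reports).tolist()


@pytest.fixture(scope="module")
def two_class_transfer_setup():
    """Source HC/IMI branches + bank, and a fresh target dataset from the
    same generator (different seed), for low-variance transfer controls."""
    from evombn.branch_network import DESK_WIDTH_PLAN, TrainSchedule, train_all_branches

    source = generate_beat_dataset(40, ("HC", "IMI"), n_patients=10,
                                   noise_sd=0.05, seed=0)
    nets, _ = train_all_branches(source, DESK_WIDTH_PLAN,
                                 TrainSchedule(lr0=0.05, batch=32, epochs=3,
                                               seed=0), seed=0)
    bank = build_feature_bank(nets, source)
    target = generate_beat_dataset(40, ("HC", "IMI"), n_patients=10,
                                   noise_sd=0.05, seed=1)
    return nets, bank, target


class TestTransfer:
    def test_frozen_branches_and_verbatim_genomes(self, two_class_transfer_setup):
        nets, bank, target = two_class_transfer_setup
        cfg = _fast_config(seed=0)
        best, _, _ = run_detection(bank, cfg)
        before = [net.param_checksum() for net in nets]
        report, target_bank = transfer_architecture({"detection": best.genome},
                                                    nets, target, cfg)
        after = [net.param_checksum() for net in nets]
        assert before == after
        assert report.task == "transfer/detection"
        assert target_bank.n_beats == len(target)

    def test_same_distribution_transfer_accuracy(self, two_class_transfer_setup):
        """Transfer between two datasets from the same generator stays within
        10 points of in-domain accuracy."""
        nets, bank, target = two_class_transfer_setup
        cfg = _fast_config(seed=0)
        best, in_domain, _ = run_detection(bank, cfg)
        report, _ = transfer_architecture({"detection": best.genome},
                                          nets, target, cfg)
        assert report.overall_acc >= in_domain.overall_acc - 10.0


class TestAblationOrdering:
    def test_lse_with_ga_not_worse_than_fixed_mbn_head(self, feature_bank7):
        """Full system (GA + LSE) vs the conventional fixed all-17 head with
        excitation forced to 1, on the same split and seed."""
        from evombn.lse_summarizer import predict_proba, train_lse

        cfg = _fast_config(seed=11)
        _, full_report, _ = run_detection(feature_bank7, cfg)

        # baseline: fixed all-17 genome, excitation pinned to 1 (plain
        # concatenation + fully-connected head), same split and seed
        mi = [c for c in feature_bank7.class_set if c != "HC"]
        det = feature_bank7.relabel({c: "MI" for c in mi}, ("HC", "MI"))
        train, test = patient_split(det.labels, det.patient_ids,
                                    cfg.test_fraction, cfg.seed)
        model, _ = train_lse(det.subset(train), (17,) * 12,
                             LSEConfig(epochs=30, seed=11,
                                       force_excitation=1.0),
                             classes=("HC", "MI"), class_mode="binary",
                             positive_class="MI")
        proba = predict_proba(model, det.subset(test), force_excitation=1.0)
        mbn_acc = 100 * np.mean((proba >= 0.5) == (det.labels[test] == "MI"))
        assert full_report.overall_acc >= mbn_acc - 1e-9
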