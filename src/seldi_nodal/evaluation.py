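"""Confusion-matrix metrics and the end-to-end experiment driver.

Counts are kept as exact integers; percentages are derived on demand and
rounded (2 dp, half-up) only when a report is serialized, so 32/35 prints
as 91.43.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seldi_nodal.spectra_io import NODE_POSITIVE, PipelineConfig


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: str = "blind_test"
    fold_reports: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": _round2(self.sensitivity),
            "specificity": _round2(self.specificity),
            "accuracy": _round2(self.accuracy),
            "ppv": _round2(self.ppv) if self.ppv is not None else "n/a",
        }


def _round2(x: float) -> float:
    return float(decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def compute_metrics(predictions, truth, mode: str = "blind_test",
                    positive_label: str = NODE_POSITIVE) -> PerformanceReport:
    """Confusion counts of predictions against truth (order-invariant)."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must be equal length")
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truth):
        if t == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn, mode=mode)


def match_tree_features(model, matrix, window: float = 0.005):
    """Rename a model's m/z features to the closest matrix columns.

    Needed when a fixed tree (nominal peak positions) is applied to a
    detected matrix whose cluster centers differ by a fraction of a Da.
    A feature with no cluster within +-``window``/2 raises.
    """
    from seldi_nodal.oblique_tree import SplitNode, TreeModel

    centers = np.array([c.mz_center for c in matrix.clusters])
    names = matrix.feature_names
    mapping = {}
    for feat in model.features():
        target = float(feat.split("_", 1)[1])
        k = int(np.argmin(np.abs(centers - target)))
        if abs(centers[k] - target) > window / 2 * target:
            raise ValueError(f"no matrix cluster within {window / 2:.2%} of "
                             f"model feature {feat!r}")
        mapping[feat] = names[k]
    nodes = {}
    for nid, node in model.nodes.items():
        if isinstance(node, SplitNode):
            nodes[nid] = SplitNode(
                node_id=nid,
                coefficients={mapping[f]: c for f, c in node.coefficients.items()},
                threshold=node.threshold,
                left_child=node.left_child, right_child=node.right_child)
        else:
            nodes[nid] = node
    out = TreeModel(nodes=nodes, root_id=model.root_id,
                    training_meta=dict(model.training_meta,
                                       feature_mapping=mapping))
    out.validate()
    return out


def run_experiment(gen_config=None, pipe_config: PipelineConfig = None,
                   seed: int = 0, tree_params=None, out_dir=None,
                   n_train=(70, 75), n_test=(35, 30)) -> dict:
    """Simulate cohorts, run the full pipeline, report every evaluation mode.

    Training cohort (default 70 positive / 75 negative) and blind-test
    cohort (35/30) are generated, preprocessed and peak-detected; the
    training matrix drives the t screen and tree fitting. Reported:
    learning-mode (resubstitution) metrics of the fully grown tree,
    cross-validated metrics, blind-test metrics of the pruned tree, and the
    published fixed tree on both cohorts. Deterministic given ``seed``.
    """
    from seldi_nodal import synthetic_data as sd
    from seldi_nodal.oblique_tree import (
        TreeParams, cross_validate, fit_tree, predict_matrix, published_tree,
        variable_importance,
    )
    from seldi_nodal.peak_detection import build_peak_matrix, cluster_and_complete, detect_peaks, first_pass_filter
    from seldi_nodal.preprocessing import preprocess_cohort
    from seldi_nodal.univariate_stats import results_table, screen_differential, t_test_peaks

    gen_config = gen_config or sd.default_generator_config()
    pipe = pipe_config or PipelineConfig(seed=seed)
    tree_params = tree_params or TreeParams(seed=seed)

    stage = "simulate"
    try:
        root = np.random.SeedSequence(seed)
        s_train, s_test = [int(s.generate_state(1)[0]) for s in root.spawn(2)]
        train = sd.generate_cohort(gen_config, *n_train, role="training",
                                   seed=s_train)
        test = sd.generate_cohort(gen_config, *n_test, role="test", seed=s_test)

        stage = "preprocess"
        train_p = preprocess_cohort(train, pipe.mz_min, pipe.mz_max,
                                    pipe.baseline_half_width)
        test_p = preprocess_cohort(test, pipe.mz_min, pipe.mz_max,
                                   pipe.baseline_half_width)

        stage = "detect"
        train_matrix = build_peak_matrix(
            train_p, snr_first=pipe.snr_first_pass,
            min_fraction=pipe.min_peak_threshold,
            window=pipe.cluster_window, snr_second=pipe.snr_second_pass,
            noise_window_points=pipe.noise_window_points)
        # complete the blind-test matrix against the training clusters
        per_spectrum = {
            s.sample_id: detect_peaks(s, snr_min=pipe.snr_first_pass,
                                      noise_window_points=pipe.noise_window_points,
                                      neighborhood_fraction=pipe.cluster_window / 2)
            for s in test_p
        }
        provisional = [
            {"mz_center": c.mz_center,
             "members": [p for peaks in per_spectrum.values() for p in peaks
                         if c.contains(p.mz)],
             "prevalence": c.prevalence}
            for c in train_matrix.clusters
        ]
        test_matrix = cluster_and_complete(
            test_p, provisional, window=pipe.cluster_window,
            snr_second=pipe.snr_second_pass,
            noise_window_points=pipe.noise_window_points)

        stage = "screen"
        tests = t_test_peaks(train_matrix, alpha=pipe.alpha_report)
        screen = screen_differential(tests, alpha_strict=pipe.alpha_strict,
                                     alpha_report=pipe.alpha_report)

        stage = "train"
        full_params = TreeParams(**{**vars(tree_params),
                                    "prune": False, "min_node_size": 1})
        full_tree = fit_tree(train_matrix, params=full_params)
        learning = compute_metrics(predict_matrix(full_tree, train_matrix),
                                   train_matrix.labels, mode="learning")
        pruned_tree = fit_tree(train_matrix, params=tree_params)
        cv_report = cross_validate(train_matrix, params=tree_params)
        importance = variable_importance(pruned_tree, train_matrix)

        stage = "evaluate"
        blind = compute_metrics(predict_matrix(pruned_tree, test_matrix),
                                test_matrix.labels, mode="blind_test")
        pub = published_tree()
        pub_train = match_tree_features(pub, train_matrix, pipe.cluster_window)
        pub_test = match_tree_features(pub, test_matrix, pipe.cluster_window)
        published_training = compute_metrics(
            predict_matrix(pub_train, train_matrix), train_matrix.labels,
            mode="learning")
        published_blind = compute_metrics(
            predict_matrix(pub_test, test_matrix), test_matrix.labels,
            mode="blind_test")
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "provenance": {
            "seed": seed,
            "cohorts": {"train": list(n_train), "test": list(n_test)},
            "n_clusters": len(train_matrix.clusters),
        },
        "screen": {
            "n_strict": len(screen["strict"]),
            "n_reported": len(screen["reported"]),
            "reported_mz": [r.mz_center for r in screen["reported"]],
        },
        "reports": {
            "learning": learning.as_dict(),
            "cv": cv_report.as_dict(),
            "blind_test": blind.as_dict(),
            "published_learning": published_training.as_dict(),
            "published_blind_test": published_blind.as_dict(),
        },
        "importance": importance,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
            fh.write("\n")
        (out_dir / "report.md").write_text(performance_markdown(bundle))
        train_matrix.to_csv(out_dir / "train_matrix.csv")
        test_matrix.to_csv(out_dir / "test_matrix.csv")
        results_table(tests).to_csv(out_dir / "t_tests.csv", index=False)
        from seldi_nodal.spectra_io import write_tree_model
        write_tree_model(pruned_tree, out_dir / "model.json")
    bundle["_objects"] = {
        "train_matrix": train_matrix, "test_matrix": test_matrix,
        "full_tree": full_tree, "pruned_tree": pruned_tree,
    }
    return bundle


def performance_markdown(bundle: dict) -> str:
    """Markdown performance table (training learning/CV modes, blind test)."""
    rows = [
        ("Training set, learning mode", bundle["reports"]["learning"]),
        ("Training set, test mode (CV)", bundle["reports"]["cv"]),
        ("Test set (blind)", bundle["reports"]["blind_test"]),
        ("Published tree, training set", bundle["reports"]["published_learning"]),
        ("Published tree, test set", bundle["reports"]["published_blind_test"]),
    ]
    lines = [
        "| Set | Sensitivity (%) | Specificity (%) | Accuracy (%) | PPV (%) |",
        "| --- | --- | --- | --- | --- |",
    ]
    for name, rep in rows:
        lines.append(
            f"| {name} | {rep['sensitivity']} | {rep['specificity']} "
            f"| {rep['accuracy']} | {rep['ppv']} |"
        )
    return "\n".join(lines) + "\n"


def predictions_frame(sample_ids, truth, predictions, paths=None) -> pd.DataFrame:
    df = pd.DataFrame({"sample_id": sample_ids, "truth": truth,
                       "predicted": predictions})
    if paths is not None:
        df["terminal_node"] = [p[-1] for p in paths]
    return df
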