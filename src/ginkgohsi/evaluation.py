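"""Dataset splitting, metrics, and the synthetic experiment runner.

The split follows a 3:1:1 calibration:validation:prediction ratio realized
inside a 4-fold cross-validation routine: a fixed 20% prediction hold-out,
with the remaining 80% rotated through 4 folds (each fold once as the
validation set, giving 3:1 calibration:validation).  Splitting is
group-aware so all observations of one leaf/tree stay in the same part.

``run_experiment`` replays the single- vs two-period and PP comparisons on
synthetic data, emitting a 12-row accuracy table (period x data x method)
plus PP confusion matrices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers
from .image_features import SPECTRAL_LENGTH
from .pp_pipeline import evaluate_pp, featurize_cube, train_pp
from .synthetic_leaves import GeneratorParams, iter_dataset

__all__ = [
    "SplitIndices",
    "split_dataset",
    "accuracy",
    "confusion_matrix",
    "build_feature_table",
    "ExperimentConfig",
    "run_experiment",
]


@dataclass
class SplitIndices:
    """One fold's disjoint calibration/validation/prediction index lists."""

    calibration: np.ndarray
    validation: np.ndarray
    prediction: np.ndarray
    fold_id: int
    seed: int

    def parts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.calibration, self.validation, self.prediction


def split_dataset(
    n_or_groups,
    folds: int = 4,
    seed: int = 0,
) -> list[SplitIndices]:
    """3:1:1 split within a ``folds``-fold rotation.

    ``n_or_groups`` is either a sample count (each sample its own group) or
    a sequence of group keys.  The prediction part is a fixed ~1/5 hold-out
    shared by all folds; the remaining groups are dealt into ``folds``
    validation folds.  Groups never straddle parts.
    """
    if np.isscalar(n_or_groups):
        groups = np.arange(int(n_or_groups))
    else:
        groups = np.asarray(n_or_groups)
    n = groups.shape[0]
    if n < folds + 1:
        raise ValueError(f"need at least {folds + 1} samples, got {n}")
    uniq, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv)
    target_pred = n / (folds + 1)
    part = max(1, n // (folds + 1))
    if sizes.max() > part:
        raise ValueError(
            f"largest group ({sizes.max()} samples) exceeds a part ({part} samples)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)

    members = [np.flatnonzero(inv == g) for g in range(uniq.size)]
    pred_idx: list[int] = []
    rest_groups: list[int] = []
    count = 0
    for g in order:
        if count < round(target_pred):
            pred_idx.extend(members[g])
            count += sizes[g]
        else:
            rest_groups.append(g)
    # deal remaining groups into folds, largest first onto the lightest fold
    rest_sorted = sorted(rest_groups, key=lambda g: (-sizes[g], g))
    fold_members: list[list[int]] = [[] for _ in range(folds)]
    fold_sizes = np.zeros(folds, dtype=int)
    for g in rest_sorted:
        f = int(np.argmin(fold_sizes))
        fold_members[f].extend(members[g])
        fold_sizes[f] += sizes[g]

    prediction = np.sort(np.array(pred_idx, dtype=int))
    splits = []
    for f in range(folds):
        validation = np.sort(np.array(fold_members[f], dtype=int))
        calibration = np.sort(
            np.concatenate(
                [np.array(fold_members[j], dtype=int) for j in range(folds) if j != f]
            )
        )
        splits.append(
            SplitIndices(
                calibration=calibration,
                validation=validation,
                prediction=prediction,
                fold_id=f,
                seed=seed,
            )
        )
    return splits


def accuracy(y_true, y_pred) -> float:
    """Percentage of matching labels: 100 * matches / total."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] == 0:
        raise ValueError("empty input")
    if y_true.shape[0] != y_pred.shape[0]:
        raise ValueError("y_true and y_pred lengths differ")
    return 100.0 * float(np.mean(y_true == y_pred))


def confusion_matrix(y_true, y_pred, class_order) -> pd.DataFrame:
    """K x K count matrix; rows = true class, columns = predicted class."""
    from sklearn.metrics import confusion_matrix as _sk_cm

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = list(class_order)
    known = set(classes)
    bad = (set(np.unique(y_true)) | set(np.unique(y_pred))) - known
    if bad:
        raise ValueError(f"labels outside class order: {sorted(bad)}")
    cm = _sk_cm(y_true, y_pred, labels=classes)
    return pd.DataFrame(cm, index=classes, columns=classes)


def build_feature_table(
    n_per_class: int,
    params: GeneratorParams | None = None,
    seed: int = 0,
    use_truth_mask: bool = False,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Generate a synthetic dataset and run the full feature pipeline on it.

    Cubes are generated and featurized one at a time (a cube is two orders
    of magnitude larger than its feature vector).  Returns the n x 263
    fusion matrix, the metadata table, and the block map.
    """
    rows = []
    feats = []
    block_map = None
    for labeled, row in iter_dataset(n_per_class, params, seed):
        fv = featurize_cube(
            labeled.cube, mask=labeled.truth_mask if use_truth_mask else None
        )
        block_map = fv.block_map
        feats.append(fv.values)
        rows.append(row)
    return np.vstack(feats), pd.DataFrame(rows), block_map


@dataclass
class ExperimentConfig:
    """Fully seeded configuration of the synthetic replay experiment."""

    n_per_class: int = 50
    params: GeneratorParams = field(default_factory=GeneratorParams)
    seed: int = 0
    pp_presets: tuple[str, ...] = ("spectral_pp", "fusion_pp")
    methods: tuple[str, ...] = ("LDA", "SVM", "SDA")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "n_per_class": self.n_per_class,
                "seed": self.seed,
                "pp_presets": list(self.pp_presets),
                "methods": list(self.methods),
                "delta_green": self.params.delta_green,
                "delta_yellow": self.params.delta_yellow,
                "texture_sex_contrast": self.params.texture_sex_contrast,
                "noise_sigma": self.params.noise_sigma,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_METHOD_TRAINERS = {
    "LDA": lambda X, y, seed: classifiers.train_lda(X, y),
    "SVM": lambda X, y, seed: classifiers.train_svm_quadratic(X, y),
    "SDA": lambda X, y, seed: classifiers.train_sda(X, y, seed=seed),
}


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Replay the model comparisons on synthetic data.

    Produces the 12-row spectral accuracy table -- one row per
    (period in {G, Y}) x (data in {d: two-period, s: single-period}) x
    (method in {LDA, SVM, SDA}) -- with calibration / mean-validation /
    prediction accuracies, plus evaluation reports for the requested PP
    presets.  Fully seeded and repeatable.
    """
    config = config or ExperimentConfig()
    X, meta, _ = build_feature_table(
        config.n_per_class, config.params, seed=config.seed
    )
    S = X[:, :SPECTRAL_LENGTH]
    periods = meta["period"].to_numpy()
    sexes = meta["sex"].to_numpy()
    splits = split_dataset(meta["id"].to_numpy(), seed=config.seed)
    pred_idx = splits[0].prediction
    trainval_idx = np.sort(np.concatenate([splits[0].calibration,
                                           splits[0].validation]))

    rows = []
    for period_code, period in (("G", "green"), ("Y", "yellow")):
        for data_code in ("d", "s"):
            for method in config.methods:
                val_accs, cal_accs = [], []
                for sp in splits:
                    cal, val = sp.calibration, sp.validation
                    if data_code == "s":
                        cal = cal[periods[cal] == period]
                    model = _METHOD_TRAINERS[method](
                        S[cal], sexes[cal], config.seed
                    )
                    cal_accs.append(accuracy(sexes[cal],
                                             classifiers.predict(model, S[cal])))
                    val_p = val[periods[val] == period]
                    val_accs.append(accuracy(sexes[val_p],
                                             classifiers.predict(model, S[val_p])))
                # refit on the full 80% for the prediction accuracy
                fit_idx = trainval_idx
                if data_code == "s":
                    fit_idx = fit_idx[periods[fit_idx] == period]
                model = _METHOD_TRAINERS[method](S[fit_idx], sexes[fit_idx],
                                                 config.seed)
                test = pred_idx[periods[pred_idx] == period]
                rows.append(
                    {
                        "period": period_code,
                        "data": data_code,
                        "method": method,
                        "calibration_accuracy": float(np.mean(cal_accs)),
                        "validation_accuracy": float(np.mean(val_accs)),
                        "prediction_accuracy": accuracy(
                            sexes[test], classifiers.predict(model, S[test])
                        ),
                    }
                )
    table = pd.DataFrame(rows)

    pp_reports = {}
    for preset in config.pp_presets:
        mode_X = X if preset.startswith("fusion") else S
        model = train_pp(
            mode_X[trainval_idx], periods[trainval_idx], sexes[trainval_idx],
            preset=preset, seed=config.seed,
        )
        pp_reports[preset] = evaluate_pp(
            model, mode_X[pred_idx], periods[pred_idx], sexes[pred_idx]
        )

    return {
        "accuracy_table": table,
        "pp_reports": pp_reports,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": int(X.shape[0]),
    }


def save_report(report: dict, out_dir: str | Path) -> Path:
    """Write the experiment report as CSV + JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["accuracy_table"].to_csv(out / "accuracy_table.csv", index=False)
    summary = {
        "seed": report["seed"],
        "config_hash": report["config_hash"],
        "n_samples": report["n_samples"],
        "pp": {},
    }
    for preset, rep in report["pp_reports"].items():
        rep["confusion_matrix"].to_csv(out / f"confusion_{preset}.csv")
        summary["pp"][preset] = {
            "overall_accuracy": rep["overall_accuracy"],
            "period_accuracy": rep["period_accuracy"],
            "sex_accuracy": rep["sex_accuracy"],
            "n": rep["n"],
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
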