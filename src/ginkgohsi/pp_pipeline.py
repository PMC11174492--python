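"""Two-stage Period-Predetermined (PP) sex classification.

Stage 1 classifies the phenological period (green vs yellow leaf stage)
with an LDA on the spectral block -- the stage signal is large, so this
stage is near-perfect.  Stage 2 routes the sample to a period-specific sex
model bank: a single model, or an odd-sized committee aggregated by
majority vote.  Banks operate on spectral-only (210) or fusion (263)
feature vectors; the period stage always consumes the spectral block.

Named presets mirror the evaluated bank compositions; ``-s`` members are
trained on single-period data, ``-d`` members on data from both periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import (
    TrainedModel,
    majority_vote,
    predict,
    train_lda,
    train_sda,
    train_svm_quadratic,
)
from .hsi_io import HsiCube, synthesize_rgb
from .image_features import (
    FUSION_LENGTH,
    SPECTRAL_LENGTH,
    FeatureVector,
    extract_image_features,
    fuse,
)
from .leaf_spectra import BinaryMask, crop_spectrum, extract_mean_spectrum, segment_cube

__all__ = [
    "PpModel",
    "PpPrediction",
    "BankMember",
    "PRESETS",
    "featurize_cube",
    "train_pp",
    "predict_pp",
    "predict_pp_batch",
    "evaluate_pp",
    "JOINT_CLASSES",
]

PERIOD_LABELS = ("green", "yellow")
JOINT_CLASSES = ("G-M", "G-F", "Y-M", "Y-F")


@dataclass(frozen=True)
class BankMember:
    """Specification of one sex-bank model: family x training scope."""

    family: str  # {lda, svm, sda}
    scope: str  # {single, double}


def _bank(*specs: tuple[str, str]) -> tuple[BankMember, ...]:
    return tuple(BankMember(f, s) for f, s in specs)


# Preset bank compositions (mode, green bank, yellow bank).
PRESETS: dict[str, dict] = {
    "spectral_pp": {
        "mode": "spectral",
        "green": _bank(("sda", "single")),
        "yellow": _bank(("lda", "single")),
    },
    "spectral_pp_vote": {
        "mode": "spectral",
        "green": _bank(("svm", "single"), ("sda", "single"), ("lda", "double")),
        "yellow": _bank(("lda", "single"), ("sda", "single"), ("sda", "double")),
    },
    "fusion_pp": {
        "mode": "fusion",
        "green": _bank(("sda", "single")),
        "yellow": _bank(("sda", "single")),
    },
    "fusion_pp_vote": {
        "mode": "fusion",
        "green": _bank(("sda", "single"), ("lda", "single"), ("lda", "double")),
        "yellow": _bank(("sda", "single"), ("lda", "single"), ("lda", "double")),
    },
}

_MODE_DIM = {"spectral": SPECTRAL_LENGTH, "fusion": FUSION_LENGTH}


@dataclass
class PpModel:
    """Stage-1 period model plus per-period sex model banks."""

    period_model: TrainedModel
    sex_banks: dict[str, list[TrainedModel]]
    feature_mode: str  # {spectral, fusion}
    preset_name: str = "custom"
    bank_specs: dict[str, tuple[BankMember, ...]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.feature_mode not in _MODE_DIM:
            raise ValueError(f"feature_mode must be one of {list(_MODE_DIM)}")
        for period, bank in self.sex_banks.items():
            if len(bank) == 0:
                raise ValueError(f"sex bank for period '{period}' is empty")
            if len(bank) > 1 and len(bank) % 2 == 0:
                raise ValueError(
                    f"sex bank for period '{period}' has even size {len(bank)}; "
                    "majority voting requires an odd committee"
                )

    @property
    def n_features(self) -> int:
        return _MODE_DIM[self.feature_mode]


@dataclass
class PpPrediction:
    """Routed prediction for one sample."""

    period: str
    sex: str
    member_votes: list[str]


def featurize_cube(
    cube: HsiCube,
    mask: BinaryMask | None = None,
    levels: int = 16,
) -> FeatureVector:
    """Full per-sample feature pipeline: segment (unless a mask is given),
    mean spectrum cropped to 437-998 nm, RGB synthesis, 53 image features,
    spectral-first fusion to 263."""
    if mask is None:
        mask = segment_cube(cube)
    spectrum = crop_spectrum(extract_mean_spectrum(cube, mask))
    rgb = synthesize_rgb(cube)
    image = extract_image_features(rgb, mask, levels=levels)
    return fuse(spectrum, image)


def _spectral_block(X: np.ndarray, mode: str) -> np.ndarray:
    # fusion vectors are spectral-first, so the block is always a prefix
    return X[:, :SPECTRAL_LENGTH] if mode == "fusion" else X


_TRAINERS = {
    "lda": lambda X, y, seed: train_lda(X, y),
    "svm": lambda X, y, seed: train_svm_quadratic(X, y),
    "sda": lambda X, y, seed: train_sda(X, y, seed=seed),
}


def train_pp(
    X,
    periods,
    sexes,
    preset: str = "fusion_pp",
    banks: dict[str, tuple[BankMember, ...]] | None = None,
    feature_mode: str | None = None,
    seed: int = 0,
) -> PpModel:
    """Fit the two-stage model from labeled feature vectors.

    ``preset`` selects a named bank composition; pass ``banks`` (and
    ``feature_mode``) for a custom configuration instead.
    """
    X = np.asarray(X, dtype=float)
    periods = np.asarray(periods)
    sexes = np.asarray(sexes)
    if banks is None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset '{preset}'; have {list(PRESETS)}")
        cfg = PRESETS[preset]
        banks = {"green": cfg["green"], "yellow": cfg["yellow"]}
        mode = cfg["mode"]
        name = preset
    else:
        if feature_mode is None:
            raise ValueError("custom banks require feature_mode")
        mode = feature_mode
        name = "custom"
    if X.shape[1] != _MODE_DIM[mode]:
        raise ValueError(
            f"mode '{mode}' expects {_MODE_DIM[mode]} features, got {X.shape[1]}"
        )
    for period in PERIOD_LABELS:
        for sex in ("male", "female"):
            if not np.any((periods == period) & (sexes == sex)):
                raise ValueError(f"missing training stratum: {period}/{sex}")

    period_model = train_lda(_spectral_block(X, mode), periods)

    # '-d' members of the same family can be shared across banks
    double_cache: dict[str, TrainedModel] = {}
    sex_banks: dict[str, list[TrainedModel]] = {}
    for k, (period, bank_spec) in enumerate(banks.items()):
        fitted = []
        for j, member in enumerate(bank_spec):
            member_seed = seed + 1000 * k + j
            if member.scope == "single":
                rows = periods == period
                fitted.append(_TRAINERS[member.family](X[rows], sexes[rows],
                                                       member_seed))
            elif member.scope == "double":
                key = member.family
                if key not in double_cache:
                    double_cache[key] = _TRAINERS[member.family](X, sexes, seed)
                fitted.append(double_cache[key])
            else:
                raise ValueError(f"unknown member scope '{member.scope}'")
        sex_banks[period] = fitted
    return PpModel(
        period_model=period_model,
        sex_banks=sex_banks,
        feature_mode=mode,
        preset_name=name,
        bank_specs=dict(banks),
        seed=seed,
    )


def predict_pp_batch(
    model: PpModel, X
) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Vectorized routing: returns (periods, sexes, per-sample member votes)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    periods = predict(model.period_model, _spectral_block(X, model.feature_mode))
    sexes = np.empty(X.shape[0], dtype=object)
    votes: list[list[str]] = [[] for _ in range(X.shape[0])]
    for period, bank in model.sex_banks.items():
        rows = np.flatnonzero(periods == period)
        if rows.size == 0:
            continue
        member_preds = [predict(m, X[rows]) for m in bank]
        final = member_preds[0] if len(bank) == 1 else majority_vote(member_preds)
        for i, r in enumerate(rows):
            sexes[r] = final[i]
            votes[r] = [str(p[i]) for p in member_preds]
    return periods, sexes.astype(str), votes


def predict_pp(model: PpModel, sample) -> PpPrediction:
    """Route a single feature vector through the two stages."""
    periods, sexes, votes = predict_pp_batch(model, np.asarray(sample, float))
    return PpPrediction(period=str(periods[0]), sex=str(sexes[0]),
                        member_votes=votes[0])


def _joint_label(period, sex) -> str:
    return f"{'G' if period == 'green' else 'Y'}-{'M' if sex == 'male' else 'F'}"


def evaluate_pp(model: PpModel, X, periods, sexes) -> dict:
    """Evaluate on a labeled test set.

    Returns overall joint accuracy (period and sex both correct,
    trace/total x 100), period-stage accuracy, per-period sex accuracy
    (among samples truly of that period), and the 4x4 confusion matrix over
    G-M / G-F / Y-M / Y-F (rows = true, columns = predicted).
    """
    X = np.asarray(X, dtype=float)
    periods = np.asarray(periods)
    sexes = np.asarray(sexes)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    pred_p, pred_s, _ = predict_pp_batch(model, X)

    from .evaluation import confusion_matrix  # local import avoids a cycle

    true_joint = [_joint_label(p, s) for p, s in zip(periods, sexes)]
    pred_joint = [_joint_label(p, s) for p, s in zip(pred_p, pred_s)]
    cm = confusion_matrix(true_joint, pred_joint, class_order=JOINT_CLASSES)
    total = cm.to_numpy().sum()
    overall = 100.0 * np.trace(cm.to_numpy()) / total
    period_acc = 100.0 * float(np.mean(pred_p == periods))
    per_period_sex = {}
    for period in PERIOD_LABELS:
        rows = periods == period
        if rows.any():
            per_period_sex[period] = 100.0 * float(
                np.mean(pred_s[rows] == sexes[rows])
            )
    return {
        "overall_accuracy": float(overall),
        "period_accuracy": period_acc,
        "sex_accuracy": per_period_sex,
        "confusion_matrix": cm,
        "n": int(total),
    }
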