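"""End-to-end cross-subject evaluation: joint features + transfer classifiers.

The evaluation protocol is leave-one-subject-out (LOSO): one subject is the
target domain, all others are pooled as the source domain.  A small labeled
fraction of the target subject's trials joins the training pool; the rest is
the held-out test set.  Feature extractors (CSP filters, per-block z-scoring)
are fit on source + target-train only — the test partition is only ever
transformed and predicted, never fit on.

Classifier modes form the ablation grid:

- ``svm``                weight-free RBF-SVM on the pooled training features,
- ``kmm_weighted``       KMM importance weights as per-sample weights in a
                         single weight-sensitive classifier,
- ``tradaboost_uniform`` TrAdaBoost with uniform initial weights,
- ``kt_full``            TrAdaBoost initialized from the KMM weight vector
                         (the full method).

Feature modes ``csp`` / ``psd`` / ``joint`` select the spatial block, the
spectral block, or their concatenation (each block z-scored per column with
training-set statistics before concatenation, so neither block dominates by
scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from . import csp as csp_mod
from . import kmm as kmm_mod
from . import tradaboost as tb
from . import welch as welch_mod
from .containers import EpochSet, concatenate_epochs
from .synthetic import Cohort

FEATURE_MODES = ("csp", "psd", "joint")
CLASSIFIER_MODES = ("svm", "kmm_weighted", "tradaboost_uniform", "kt_full")


@dataclass
class JointFeatureMatrix:
    """Standardized per-trial features with a named block map.

    ``block_map`` gives the half-open column range of each block; the spatial
    block always precedes the spectral block.
    """

    values: np.ndarray
    block_map: dict[str, tuple[int, int]]
    column_names: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass
class FittedTransforms:
    """Everything fit on the training set and reused on apply sets."""

    bank: Optional[csp_mod.SpatialFilterBank]
    welch_cfg: Optional[welch_mod.WelchConfig]
    bands: list[tuple[float, float]]
    block_means: dict[str, np.ndarray]
    block_stds: dict[str, np.ndarray]
    feature_mode: str
    log_power: bool = True
    balance_blocks: bool = True


@dataclass
class ExperimentConfig:
    """One cell of the ablation grid plus all stage sub-configurations."""

    feature_mode: str = "joint"
    classifier_mode: str = "kt_full"
    target_subject: Optional[str] = None
    target_train_fraction: float = 0.2
    n_csp_filters: Optional[int] = None  # default: by montage size
    welch: Optional[welch_mod.WelchConfig] = None
    bands: Optional[list[tuple[float, float]]] = None
    kernel: kmm_mod.KernelConfig = field(default_factory=kmm_mod.KernelConfig)
    boost: tb.BoostConfig = field(default_factory=tb.BoostConfig)
    svm_c: float = 1.0
    # log-transform band powers before z-scoring (standard for EEG spectra,
    # which are heavily right-skewed)
    log_power: bool = True
    # rescale z-scored blocks so each block contributes equal aggregate
    # variance (the wide spectral block cannot out-vote the narrow spatial
    # block) while the total feature variance stays at the plain z-score
    # level
    balance_blocks: bool = True

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
        if self.classifier_mode not in CLASSIFIER_MODES:
            raise ValueError(f"classifier_mode must be one of {CLASSIFIER_MODES}")
        if not (0.0 < self.target_train_fraction < 1.0):
            raise ValueError("target_train_fraction must be in (0, 1)")


@dataclass
class EvaluationReport:
    """Accuracy and confusion counts for one target subject.

    Counts are pooled over seeds; with equal-sized test splits the pooled
    accuracy equals the mean of per-seed accuracies.  Class 2 ("right") is
    the positive class of the confusion counts.
    """

    target_subject: str
    accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int
    seeds: list[int]
    config: ExperimentConfig = field(repr=False, default=None)


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """``(TP + TN) / (TP + TN + FP + FN)``, in [0, 1]."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return (tp + tn) / total


def build_joint_features(
    epochs_train: EpochSet,
    epochs_apply: Optional[EpochSet],
    cfg: ExperimentConfig,
) -> tuple[JointFeatureMatrix, Optional[JointFeatureMatrix], FittedTransforms]:
    """Fit feature extractors on ``epochs_train``, transform both sets."""
    mode = cfg.feature_mode
    bank = None
    welch_cfg = None
    bands = list(cfg.bands if cfg.bands is not None else welch_mod.DEFAULT_BANDS)
    blocks_train: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    if mode in ("csp", "joint"):
        m = cfg.n_csp_filters or csp_mod.default_n_filters(epochs_train.n_channels)
        bank = csp_mod.fit_csp(epochs_train, m)
        blocks_train["spatial"] = csp_mod.spatial_features(bank, epochs_train).values
        names["spatial"] = [f"csp{j + 1}" for j in range(m)]
    if mode in ("psd", "joint"):
        welch_cfg = cfg.welch or welch_mod.WelchConfig(fs=epochs_train.fs)
        block = welch_mod.band_features(epochs_train, welch_cfg, bands)
        blocks_train["frequency"] = (
            _log_power(block.values) if cfg.log_power else block.values
        )
        names["frequency"] = block.column_names

    means = {k: v.mean(axis=0) for k, v in blocks_train.items()}
    stds = {
        k: np.maximum(v.std(axis=0), 1e-12) for k, v in blocks_train.items()
    }
    transforms = FittedTransforms(
        bank=bank, welch_cfg=welch_cfg, bands=bands,
        block_means=means, block_stds=stds, feature_mode=mode,
        log_power=cfg.log_power, balance_blocks=cfg.balance_blocks,
    )

    def assemble(blocks: dict[str, np.ndarray]) -> JointFeatureMatrix:
        parts, block_map, cols = [], {}, []
        start = 0
        scales = _block_scales(
            {k: blocks[k].shape[1] for k in blocks}, cfg.balance_blocks
        )
        for key in ("spatial", "frequency"):  # spatial block first
            if key not in blocks:
                continue
            z = (blocks[key] - means[key]) / stds[key] * scales[key]
            parts.append(z)
            block_map[key] = (start, start + z.shape[1])
            start += z.shape[1]
            cols.extend(names[key])
        return JointFeatureMatrix(np.hstack(parts), block_map, cols)

    train_jfm = assemble(blocks_train)
    apply_jfm = (
        assemble(_raw_blocks(epochs_apply, transforms))
        if epochs_apply is not None
        else None
    )
    return train_jfm, apply_jfm, transforms


def _log_power(values: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(values, 1e-30))


def _block_scales(widths: dict[str, int], balance: bool) -> dict[str, float]:
    """Per-block scale factors applied after column z-scoring.

    With balancing, block ``k`` is scaled by
    ``sqrt(total_width / (n_blocks * width_k))``: every block then carries
    the same aggregate variance, and the total across all columns equals
    the plain z-score total (so downstream classifiers see an unchanged
    overall feature scale).
    """
    if not balance or len(widths) < 2:
        return {k: 1.0 for k in widths}
    total = sum(widths.values())
    n_blocks = len(widths)
    return {
        k: float(np.sqrt(total / (n_blocks * w))) for k, w in widths.items()
    }


def _raw_blocks(
    epochs: EpochSet, transforms: FittedTransforms
) -> dict[str, np.ndarray]:
    blocks = {}
    if transforms.bank is not None:
        blocks["spatial"] = csp_mod.spatial_features(transforms.bank, epochs).values
    if transforms.welch_cfg is not None:
        freq = welch_mod.band_features(
            epochs, transforms.welch_cfg, transforms.bands
        ).values
        blocks["frequency"] = _log_power(freq) if transforms.log_power else freq
    return blocks


def transform_features(
    epochs: EpochSet, transforms: FittedTransforms
) -> JointFeatureMatrix:
    """Apply previously fitted transforms to a new epoch set."""
    blocks = _raw_blocks(epochs, transforms)
    parts, block_map = [], {}
    start = 0
    scales = _block_scales(
        {k: blocks[k].shape[1] for k in blocks}, transforms.balance_blocks
    )
    for key in ("spatial", "frequency"):
        if key not in blocks:
            continue
        z = (blocks[key] - transforms.block_means[key]) / transforms.block_stds[key]
        z = z * scales[key]
        parts.append(z)
        block_map[key] = (start, start + z.shape[1])
        start += z.shape[1]
    return JointFeatureMatrix(np.hstack(parts), block_map)


def _split_target(
    target: EpochSet, fraction: float, seed: int
) -> tuple[EpochSet, EpochSet]:
    idx = np.arange(target.n_trials)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=fraction,
        stratify=target.labels,
        random_state=seed,
    )
    if len(test_idx) == 0:
        raise ValueError("degenerate split: no target test trials")
    return target.subset(np.sort(train_idx)), target.subset(np.sort(test_idx))


def _classify(
    cfg: ExperimentConfig,
    f_source: np.ndarray,
    y_source: np.ndarray,
    f_ttrain: np.ndarray,
    y_ttrain: np.ndarray,
    f_test: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Train per ``classifier_mode`` and predict labels for the test features."""
    mode = cfg.classifier_mode
    x_pool = np.vstack([f_source, f_ttrain])
    y_pool = np.concatenate([y_source, y_ttrain])
    if mode == "svm":
        clf = SVC(kernel="rbf", C=cfg.svm_c, gamma="scale", random_state=seed)
        clf.fit(x_pool, y_pool)
        return clf.predict(f_test)
    if mode == "kmm_weighted":
        sw = kmm_mod.solve_weights(f_source, f_ttrain, cfg.kernel, seed=seed)
        weights = np.concatenate([sw.weights, np.full(len(y_ttrain), 1.0)])
        clf = SVC(kernel="rbf", C=cfg.svm_c, gamma="scale", random_state=seed)
        clf.fit(x_pool, y_pool, sample_weight=np.maximum(weights, 1e-6))
        return clf.predict(f_test)
    boost_cfg = replace(cfg.boost, seed=seed)
    if mode == "tradaboost_uniform":
        boost_cfg = replace(boost_cfg, init_mode="uniform")
        model = tb.fit(f_source, y_source, f_ttrain, y_ttrain, boost_cfg)
        return model.predict(f_test)
    # kt_full: KMM weights seed the boosting initialization
    sw = kmm_mod.solve_weights(f_source, f_ttrain, cfg.kernel, seed=seed)
    boost_cfg = replace(boost_cfg, init_mode="kmm")
    model = tb.fit(
        f_source, y_source, f_ttrain, y_ttrain, boost_cfg, kmm_weights=sw
    )
    return model.predict(f_test)


def run_transfer_experiment(
    cohort: Cohort,
    cfg: ExperimentConfig,
    seeds: list[int] | None = None,
) -> EvaluationReport:
    """Evaluate one target subject against the pooled remaining subjects."""
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 subjects")
    if cfg.target_subject is None:
        raise ValueError("cfg.target_subject must be set")
    ids = cohort.subject_ids()
    if cfg.target_subject not in ids:
        raise KeyError(f"target subject {cfg.target_subject!r} not in cohort {ids}")
    seeds = list(seeds) if seeds is not None else [0]
    target = cohort.get(cfg.target_subject)
    source = concatenate_epochs(
        [es for sid, es in cohort if sid != cfg.target_subject]
    )
    accs: list[float] = []
    tp = tn = fp = fn = 0
    for seed in seeds:
        t_train, t_test = _split_target(target, cfg.target_train_fraction, seed)
        fit_pool = concatenate_epochs([source, t_train])
        _, _, transforms = build_joint_features(fit_pool, None, cfg)
        f_source = transform_features(source, transforms).values
        f_ttrain = transform_features(t_train, transforms).values
        f_test = transform_features(t_test, transforms).values
        pred = _classify(
            cfg, f_source, source.labels, f_ttrain, t_train.labels, f_test, seed
        )
        truth = t_test.labels
        tp_i = int(((pred == 2) & (truth == 2)).sum())
        tn_i = int(((pred == 1) & (truth == 1)).sum())
        fp_i = int(((pred == 2) & (truth == 1)).sum())
        fn_i = int(((pred == 1) & (truth == 2)).sum())
        tp, tn, fp, fn = tp + tp_i, tn + tn_i, fp + fp_i, fn + fn_i
        accs.append(accuracy(tp_i, tn_i, fp_i, fn_i))
    return EvaluationReport(
        target_subject=cfg.target_subject,
        accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        tp=tp, tn=tn, fp=fp, fn=fn,
        seeds=seeds,
        config=cfg,
    )


def run_loso(
    cohort: Cohort,
    cfg: ExperimentConfig,
    seeds: list[int] | None = None,
) -> list[EvaluationReport]:
    """One transfer experiment per subject as target, in cohort order."""
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least 2 subjects")
    return [
        run_transfer_experiment(cohort, replace(cfg, target_subject=sid), seeds)
        for sid in cohort.subject_ids()
    ]


def loso_summary(reports: list[EvaluationReport]) -> dict:
    """Mean +/- SD of per-subject mean accuracies, Table-style."""
    means = [r.mean_accuracy for r in reports]
    return {
        "per_subject": {r.target_subject: r.mean_accuracy for r in reports},
        "mean": float(np.mean(means)),
        "sd": float(np.std(means)),
    }
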