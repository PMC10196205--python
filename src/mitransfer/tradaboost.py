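"""TrAdaBoost: boosting for instance transfer.

The training pool is source-domain samples (possibly mis-matched to the
target distribution) plus a small labeled target-domain set.  Each iteration
fits a weight-sensitive weak learner on the pooled samples, measures its
error on the target portion only,

    eps_t = sum_target w_i |h_t(x_i) - c(x_i)| / sum_target w_i,

and updates weights in opposite directions: a misclassified *source* sample
is down-weighted by the fixed Hedge rate

    beta = 1 / (1 + sqrt(2 ln n / N)),

(its information is presumed distribution-dissimilar), while a misclassified
*target* sample is up-weighted AdaBoost-style by ``beta_t^{-1}`` with
``beta_t = eps_t / (1 - eps_t)``.  The strong classifier votes only over the
second half of the iterations:

    h(x) = 1  iff  sum_{t=ceil(N/2)}^{N} ln(1/beta_t) h_t(x)
                   >= (1/2) sum_{t=ceil(N/2)}^{N} ln(1/beta_t).

Initial weights may come from kernel mean matching (``init_mode="kmm"``): the
normalized KMM weights replace the uniform ``1/n`` source allocation, biasing
the first weak learners toward source trials that resemble the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .kmm import SourceWeightVector

BETA_T_FLOOR = 1e-10

_WEAK_LEARNERS = {
    "tree": lambda seed: DecisionTreeClassifier(max_depth=2, random_state=seed),
    "stump": lambda seed: DecisionTreeClassifier(max_depth=1, random_state=seed),
    "linear_svm": lambda seed: SVC(kernel="linear", C=1.0, random_state=seed),
}


class UnderTrainedWarning(UserWarning):
    """Fewer than half the requested boosting iterations completed."""


@dataclass
class BoostConfig:
    """Boosting settings.

    ``weak_learner`` is a preset name (``linear_svm`` / ``tree`` / ``stump``)
    or any scikit-learn classifier whose ``fit`` accepts ``sample_weight``
    (contract-checked at construction time).  The default is a linear SVM:
    the target-domain training set is deliberately small, and a learner
    expressive enough to interpolate it drives every target error rate to
    zero, which floors ``beta_t`` and freezes the boosting dynamics; a
    linear margin keeps the error signal informative.
    """

    n_iterations: int = 10
    weak_learner: object = "linear_svm"
    init_mode: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.init_mode not in ("uniform", "kmm"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        self._probe_weak_learner(self.make_weak_learner())

    def make_weak_learner(self) -> BaseEstimator:
        if isinstance(self.weak_learner, str):
            try:
                return _WEAK_LEARNERS[self.weak_learner](self.seed)
            except KeyError:
                raise ValueError(
                    f"unknown weak learner {self.weak_learner!r}; "
                    f"presets: {sorted(_WEAK_LEARNERS)}"
                ) from None
        return clone(self.weak_learner)

    @staticmethod
    def _probe_weak_learner(est: BaseEstimator) -> None:
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        try:
            est.fit(x, y, sample_weight=np.array([0.4, 0.4, 0.1, 0.1]))
        except TypeError as exc:
            raise ValueError(
                "weak learner must accept sample_weight in fit()"
            ) from exc


@dataclass
class StrongClassifier:
    """Boosted ensemble with the second-half weighted-vote decision rule."""

    hypotheses: list
    betas: list  # beta_t per completed iteration
    n_planned: int
    classes: np.ndarray  # maps internal {0, 1} back to API labels
    errors: list = field(default_factory=list)  # eps_t per iteration
    under_trained: bool = False

    @property
    def n_completed(self) -> int:
        return len(self.hypotheses)

    def decision_scores(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        """Weighted vote sum over the second-half hypotheses and the threshold."""
        if not self.hypotheses:
            raise ValueError("model has no completed iterations")
        n = self.n_completed
        start = int(np.ceil(n / 2.0)) - 1  # 1-indexed ceil(N/2) .. N
        log_inv = [np.log(1.0 / b) for b in self.betas[start:]]
        votes = np.zeros(np.atleast_2d(x).shape[0])
        for h, li in zip(self.hypotheses[start:], log_inv):
            votes += li * (h.predict(x) == 1).astype(float)
        return votes, 0.5 * float(np.sum(log_inv))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class labels; ties (vote == threshold) resolve to the positive class."""
        votes, threshold = self.decision_scores(x)
        return self.classes[(votes >= threshold).astype(int)]


def init_weights(
    n: int,
    m: int,
    mode: str = "uniform",
    kmm_weights: Optional[SourceWeightVector] = None,
) -> np.ndarray:
    """Initial weight vector over ``n`` source then ``m`` target samples.

    Uniform mode assigns ``1/n`` to each source and ``1/m`` to each target
    sample (unit mass per domain).  KMM mode replaces the source allocation
    with the KMM weights normalized to unit mass, so uniform KMM weights
    reproduce the uniform initialization exactly.
    """
    if n < 1 or m < 1:
        raise ValueError("need at least one source and one target sample")
    if mode == "uniform":
        return np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    if mode == "kmm":
        if kmm_weights is None:
            raise ValueError("init_mode='kmm' requires kmm_weights")
        w = np.asarray(
            kmm_weights.weights
            if isinstance(kmm_weights, SourceWeightVector)
            else kmm_weights,
            dtype=float,
        )
        if w.shape != (n,):
            raise ValueError(f"kmm_weights length {w.shape} != source count {n}")
        total = w.sum()
        if total <= 0:
            raise ValueError("KMM weights sum to zero")
        return np.concatenate([w / total, np.full(m, 1.0 / m)])
    raise ValueError(f"unknown init mode {mode!r}")


def beta_source(n: int, n_iterations: int) -> float:
    """Hedge down-weighting rate ``1 / (1 + sqrt(2 ln n / N))``."""
    if n < 1 or n_iterations < 1:
        raise ValueError("n and n_iterations must be >= 1")
    return 1.0 / (1.0 + np.sqrt(2.0 * np.log(n) / n_iterations))


def weighted_error(
    predictions: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> float:
    """Weight-normalized 0/1 error over the target-domain training samples."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("total target weight is zero")
    miss = np.abs(np.asarray(predictions) - np.asarray(targets)).astype(float)
    return float((weights * miss).sum() / total)


def update_weights(
    w: np.ndarray,
    misses: np.ndarray,
    n: int,
    beta: float,
    beta_t: float,
) -> np.ndarray:
    """One multiplicative weight update (source shrinks, target grows).

    ``misses`` is the 0/1 miss indicator over all ``n + m`` samples.
    Correctly classified samples keep their weight exactly.
    """
    w = np.asarray(w, dtype=float).copy()
    miss = np.asarray(misses, dtype=float)
    w[:n] *= beta ** miss[:n]
    w[n:] *= beta_t ** (-miss[n:])
    return w


def fit(
    x_source: np.ndarray,
    y_source: np.ndarray,
    x_target: np.ndarray,
    y_target: np.ndarray,
    cfg: BoostConfig | None = None,
    init: Optional[np.ndarray] = None,
    kmm_weights: Optional[SourceWeightVector] = None,
) -> StrongClassifier:
    """Train the TrAdaBoost ensemble.

    ``init`` overrides the initial weight vector; otherwise it is built from
    ``cfg.init_mode`` (and ``kmm_weights`` when the mode is ``"kmm"``).
    Labels may be any two values shared by source and target; they are mapped
    to the internal {0, 1} convention and restored at prediction time.
    """
    cfg = cfg or BoostConfig()
    x_source = np.atleast_2d(np.asarray(x_source, dtype=float))
    x_target = np.atleast_2d(np.asarray(x_target, dtype=float))
    y_source = np.asarray(y_source)
    y_target = np.asarray(y_target)
    n, m = x_source.shape[0], x_target.shape[0]
    classes = np.unique(np.concatenate([y_source, y_target]))
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    x_all = np.vstack([x_source, x_target])
    y_all = np.concatenate([
        (y_source == classes[1]).astype(int),
        (y_target == classes[1]).astype(int),
    ])

    if init is not None:
        w = np.asarray(init, dtype=float).copy()
        if w.shape != (n + m,):
            raise ValueError(f"init length {w.shape} != n + m = {n + m}")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("init weights must be non-negative with positive mass")
    elif n > 0:
        w = init_weights(n, m, cfg.init_mode, kmm_weights)
    else:  # degenerate no-source case: plain target-only boosting
        w = np.full(m, 1.0 / m)

    big_n = cfg.n_iterations
    beta = beta_source(n, big_n) if n > 0 else 1.0
    hypotheses, betas, errors = [], [], []
    first_learner, first_eps = None, None
    for t in range(big_n):
        p = w / w.sum()
        learner = cfg.make_weak_learner()
        if hasattr(learner, "random_state"):
            learner.random_state = cfg.seed + t
        learner.fit(x_all, y_all, sample_weight=p)
        pred = learner.predict(x_all)
        eps_t = weighted_error(pred[n:], y_all[n:], w[n:])
        if t == 0:
            first_learner, first_eps = learner, eps_t
        if eps_t >= 0.5:
            break  # weak-learner contract violated on target; keep prior rounds
        beta_t = max(eps_t / (1.0 - eps_t), BETA_T_FLOOR)
        w = update_weights(w, (pred != y_all).astype(float), n, beta, beta_t)
        hypotheses.append(learner)
        betas.append(beta_t)
        errors.append(eps_t)

    if not hypotheses:
        # the very first round failed the error contract (possible when the
        # labeled target set is tiny); keep that hypothesis with its error
        # capped just below 1/2 so callers still get a usable model
        capped = min(first_eps, 0.5 - 1e-6)
        hypotheses, errors = [first_learner], [capped]
        betas = [capped / (1.0 - capped)]
    under_trained = len(hypotheses) < int(np.ceil(big_n / 2.0))
    if under_trained:
        warnings.warn(
            f"only {len(hypotheses)} of {big_n} iterations completed",
            UnderTrainedWarning,
        )
    return StrongClassifier(
        hypotheses=hypotheses,
        betas=betas,
        n_planned=big_n,
        classes=classes,
        errors=errors,
        under_trained=under_trained,
    )


def predict(model: StrongClassifier, x: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`StrongClassifier.predict`."""
    return model.predict(np.atleast_2d(np.asarray(x, dtype=float)))
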