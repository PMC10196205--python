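"""Common spatial patterns (CSP) for two-class motor imagery.

CSP finds spatial filters that simultaneously diagonalize the two class
covariance matrices, so that the variance of the filtered signal is maximally
discriminative: a filter whose whitened-space eigenvalue for class 1 is
``lambda`` carries ``1 - lambda`` for class 2.  The procedure:

1. per-class average of trace-normalized trial covariances ``X X^T / tr``,
2. whitening ``R`` of the composite covariance ``Hc = C1 + C2`` so that
   ``R Hc R^T = I``,
3. eigendecomposition of the whitened class-1 covariance ``R C1 R^T =
   Q P1 Q^T`` (then ``P2 = I - P1``),
4. projection matrix ``W = Q^T R``; the ``m/2`` filters with the largest and
   the ``m/2`` with the smallest eigenvalues are retained,
5. per-trial features are the normalized variances of the filtered signals,
   ``f_j = var(Z_j) / sum_j var(Z_j)`` — each feature row sums to one and is
   invariant to per-trial gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .containers import EpochSet, VALID_LABELS


@dataclass
class SpatialFilterBank:
    """Learned CSP projection.

    ``filters`` has one spatial filter per row, sorted by descending
    discriminability ``|lambda - 0.5|``.  ``eigenvalues[j]`` is the class-1
    share of whitened variance passed by filter ``j`` (class-2 share is its
    complement).
    """

    filters: np.ndarray      # (m, n_channels)
    eigenvalues: np.ndarray  # (m,), in [0, 1]
    whitener: np.ndarray     # (n_channels, n_channels)
    m: int

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]


@dataclass
class SpatialFeatureBlock:
    """Per-trial normalized variance features, shape ``(n_trials, m)``."""

    values: np.ndarray
    m: int


def _trial_covariance(x: np.ndarray) -> np.ndarray:
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0.0:
        raise ValueError("degenerate trial: zero total power")
    return c / tr


def class_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-class average of trace-normalized trial covariances.

    Each returned matrix is symmetric PSD with unit trace; scaling any trial
    by a constant leaves its contribution unchanged.
    """
    present = set(epochs.labels.tolist())
    if present != set(VALID_LABELS):
        raise ValueError(
            f"both classes {VALID_LABELS} required, got labels {sorted(present)}"
        )
    covs = []
    for label in VALID_LABELS:
        trials = epochs.data[epochs.labels == label]
        c = np.mean([_trial_covariance(x) for x in trials], axis=0)
        covs.append((c + c.T) / 2.0)
    return covs[0], covs[1]


def whiten(hc: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Whitening matrix ``R = P^{-1/2} U^T`` with ``R Hc R^T = I``."""
    hc = np.asarray(hc, dtype=float)
    if not np.allclose(hc, hc.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    vals, vecs = eigh(hc)
    if vals[0] <= tol * max(vals[-1], 1.0):
        raise ValueError(
            "covariance is rank-deficient; remove redundant channels or apply "
            "diagonal-loading shrinkage (gamma > 0)"
        )
    order = np.argsort(-vals, kind="stable")  # descending, ties keep order
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(len(vals))])
    vecs = vecs * signs
    return (vecs / np.sqrt(vals)).T


def fit_filters(
    c1: np.ndarray,
    c2: np.ndarray,
    m: int,
    shrinkage: float = 0.0,
) -> SpatialFilterBank:
    """Fit ``m`` CSP filters from the two class covariances.

    ``m`` must be even: half the filters come from each end of the eigenvalue
    spectrum.  ``shrinkage`` adds ``gamma * tr(C)/k * I`` diagonal loading to
    each class covariance before decomposition (for rank-deficient montages).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    k = c1.shape[0]
    if m % 2 != 0 or not (2 <= m <= k):
        raise ValueError(f"m must be even and in [2, {k}], got {m}")
    if shrinkage > 0.0:
        c1 = c1 + shrinkage * np.trace(c1) / k * np.eye(k)
        c2 = c2 + shrinkage * np.trace(c2) / k * np.eye(k)
    r = whiten(c1 + c2)
    s1 = r @ c1 @ r.T
    vals, q = eigh((s1 + s1.T) / 2.0)  # ascending
    w_full = q.T @ r                   # row j pairs with vals[j]
    order = np.argsort(vals)[::-1]
    selected = np.concatenate([order[: m // 2], order[len(order) - m // 2:]])
    # most discriminative first: descending distance from the 0.5 midpoint
    selected = selected[np.argsort(-np.abs(vals[selected] - 0.5), kind="stable")]
    return SpatialFilterBank(
        filters=w_full[selected],
        eigenvalues=np.clip(vals[selected], 0.0, 1.0),
        whitener=r,
        m=m,
    )


def spatial_features(bank: SpatialFilterBank, epochs: EpochSet) -> SpatialFeatureBlock:
    """Normalized variance of each filtered signal; rows sum to one."""
    if bank.n_channels != epochs.n_channels:
        raise ValueError(
            f"filter bank expects {bank.n_channels} channels, "
            f"epochs have {epochs.n_channels}"
        )
    z = np.einsum("mc,tcs->tms", bank.filters, epochs.data)
    v = z.var(axis=2)
    return SpatialFeatureBlock(values=v / v.sum(axis=1, keepdims=True), m=bank.m)


def fit_csp(epochs: EpochSet, m: int, shrinkage: float = 0.0) -> SpatialFilterBank:
    """Convenience: class covariances + filter fit in one call."""
    c1, c2 = class_covariances(epochs)
    return fit_filters(c1, c2, m, shrinkage=shrinkage)


def default_n_filters(n_channels: int) -> int:
    """Default filter count by montage size: 6 for >=8 channels, else 2-4."""
    if n_channels >= 8:
        return 6
    if n_channels >= 4:
        return 4
    return 2
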