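"""Geometry of symmetric positive-definite (SPD) covariance matrices.

EEG trials are multivariate time series whose second-order statistics —
spatial covariance matrices — live on the SPD manifold.  This module provides
covariance estimation, the three standard SPD centroids (Euclidean,
log-Euclidean, Riemannian/Karcher), the affine-invariant Riemannian distance,
centroid-alignment whitening of raw trials, and the tangent-space map that
turns SPD matrices into Euclidean feature vectors suitable for linear
classifiers.

All matrix functions (sqrt, inverse sqrt, log, exp) of SPD arguments are
computed through the symmetric eigendecomposition, which guarantees symmetric
output and lets eigenvalues be floored for numerical safety.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .exceptions import InvalidInputError, NotPositiveDefiniteError

__all__ = [
    "TrialSet",
    "FeatureSet",
    "sample_covariance",
    "trial_covariances",
    "euclidean_mean",
    "log_euclidean_mean",
    "riemannian_mean",
    "riemannian_distance",
    "align_trials",
    "tangent_space_map",
    "mean_covariance",
]

#: Default relative jitter added to covariance diagonals before inversion.
DEFAULT_JITTER = 1e-10
#: Eigenvalues below this fraction of the largest are floored.
EIG_FLOOR_REL = 1e-12

MeanKind = Literal["euclidean", "log_euclidean", "riemannian"]


@dataclass
class TrialSet:
    """A subject's EEG trials plus labels.

    Parameters
    ----------
    trials:
        Array of shape ``(n, ch, Ts)`` — n trials, ch channels, Ts samples.
    labels:
        Integer class labels of length n, or None for an unlabeled (target)
        subject.
    subject_id:
        Identifier used in task bookkeeping and on-disk containers.
    sampling_rate:
        Metadata only; never enters any computation here.
    """

    trials: np.ndarray
    labels: np.ndarray | None = None
    subject_id: str = ""
    sampling_rate: float = 250.0

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise InvalidInputError(
                f"trials must be (n, ch, Ts), got shape {self.trials.shape}"
            )
        n, ch, ts = self.trials.shape
        if n < 1 or ch < 2:
            raise InvalidInputError("need n >= 1 trials and ch >= 2 channels")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise InvalidInputError(
                    f"labels length {self.labels.shape} != number of trials {n}"
                )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]


@dataclass
class FeatureSet:
    """Tangent-space (or otherwise vectorized) features, one row per trial."""

    features: np.ndarray
    labels: np.ndarray | None = None
    domain_tag: str = field(default="source")

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise InvalidInputError("features must be a 2-D (n, D) array")
        if not np.all(np.isfinite(self.features)):
            raise InvalidInputError("features contain non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.features.shape[0],):
                raise InvalidInputError("labels length mismatch")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# symmetric matrix functions


def _check_square(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError(f"{name} must be square, got {m.shape}")
    return m


def _sym_eig(m: np.ndarray, floor: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a (near-)symmetric matrix with eigenvalue floor."""
    m = 0.5 * (m + m.T)
    w, v = scipy.linalg.eigh(m)
    if floor:
        w = np.maximum(w, EIG_FLOOR_REL * max(w[-1], 0.0))
    return w, v


def _sym_fun(m: np.ndarray, fun, check_pd: bool = False) -> np.ndarray:
    w, v = _sym_eig(m)
    if check_pd and w[0] <= 0:
        raise NotPositiveDefiniteError("matrix is not positive definite")
    return (v * fun(w)) @ v.T


def sqrtm(m: np.ndarray) -> np.ndarray:
    """Symmetric square root of an SPD matrix."""
    return _sym_fun(m, np.sqrt)


def invsqrtm(m: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of an SPD matrix."""
    return _sym_fun(m, lambda w: 1.0 / np.sqrt(w), check_pd=True)


def logm(m: np.ndarray) -> np.ndarray:
    """Symmetric matrix logarithm of an SPD matrix."""
    return _sym_fun(m, np.log, check_pd=True)


def expm(m: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix."""
    m = 0.5 * (m + m.T)
    w, v = scipy.linalg.eigh(m)
    return (v * np.exp(w)) @ v.T


# ---------------------------------------------------------------------------
# covariance estimation


def sample_covariance(trial: np.ndarray, jitter: float = DEFAULT_JITTER) -> np.ndarray:
    """Spatial covariance of one trial, ``(x xᵀ)/Ts`` plus diagonal jitter.

    The 1/Ts normalisation keeps covariances well conditioned across trial
    lengths; centroid alignment is invariant to any global positive scaling
    of the covariance, so downstream results do not depend on it.

    Parameters
    ----------
    trial:
        ``(ch, Ts)`` array of channel time series.
    jitter:
        Nonnegative relative diagonal loading: ``jitter * mean(diag) * I`` is
        added, guaranteeing positive definiteness for any nonzero trial.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise InvalidInputError(f"trial must be 2-D (ch, Ts), got {trial.shape}")
    if not np.all(np.isfinite(trial)):
        raise InvalidInputError("trial contains non-finite values")
    if jitter < 0:
        raise InvalidInputError("jitter must be nonnegative")
    ts = trial.shape[1]
    cov = trial @ trial.T / ts
    mean_diag = float(np.mean(np.diag(cov)))
    if mean_diag <= 0.0 and jitter == 0.0:
        raise NotPositiveDefiniteError("all-zero trial yields a zero covariance")
    cov = cov + jitter * mean_diag * np.eye(trial.shape[0])
    if jitter == 0.0:
        w = scipy.linalg.eigvalsh(cov)
        if w[0] <= 0:
            raise NotPositiveDefiniteError(
                "trial covariance is rank deficient and jitter is zero"
            )
    return 0.5 * (cov + cov.T)


def trial_covariances(
    trialset: TrialSet, jitter: float = DEFAULT_JITTER
) -> np.ndarray:
    """Stack of per-trial covariances, shape ``(n, ch, ch)``."""
    return np.stack(
        [sample_covariance(t, jitter=jitter) for t in trialset.trials]
    )


# ---------------------------------------------------------------------------
# SPD means and distance


def _as_cov_stack(covs: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    covs = np.asarray(covs, dtype=float)
    if covs.ndim == 2:
        covs = covs[None]
    if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
        raise InvalidInputError("expected a stack of square matrices")
    if covs.shape[0] == 0:
        raise InvalidInputError("empty covariance list")
    return covs


def euclidean_mean(covs: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of SPD matrices."""
    covs = _as_cov_stack(covs)
    m = covs.mean(axis=0)
    return 0.5 * (m + m.T)


def log_euclidean_mean(covs: Sequence[np.ndarray]) -> np.ndarray:
    """exp of the arithmetic mean of matrix logarithms."""
    covs = _as_cov_stack(covs)
    return expm(np.mean([logm(c) for c in covs], axis=0))


def riemannian_distance(m1: np.ndarray, m2: np.ndarray) -> float:
    """Affine-invariant Riemannian distance ``‖log(M1^{-1} M2)‖_F``.

    Computed from the generalized eigenvalues of the pencil (M2, M1), which
    coincide with the eigenvalues of the symmetric form M1^{-1/2} M2 M1^{-1/2}.
    """
    m1 = _check_square(m1, "M1")
    m2 = _check_square(m2, "M2")
    if m1.shape != m2.shape:
        raise InvalidInputError("M1 and M2 must have the same shape")
    w = scipy.linalg.eigvalsh(0.5 * (m2 + m2.T), 0.5 * (m1 + m1.T))
    if np.any(w <= 0):
        raise NotPositiveDefiniteError("inputs must both be positive definite")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def riemannian_mean(
    covs: Sequence[np.ndarray],
    tol: float = 1e-9,
    max_iter: int = 50,
) -> np.ndarray:
    """Karcher (Fréchet) mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration ``M ← M^{1/2} exp((1/n) Σ log(M^{-1/2} M_i M^{-1/2})) M^{1/2}``
    initialized at the Euclidean mean.  Stops when the Frobenius norm of the
    tangent-space gradient drops below ``tol``; non-convergence within
    ``max_iter`` raises a ``RuntimeWarning`` and returns the last iterate.
    """
    covs = _as_cov_stack(covs)
    if covs.shape[0] == 1:
        return covs[0].copy()
    m = euclidean_mean(covs)
    for _ in range(max_iter):
        m_isqrt = invsqrtm(m)
        m_sqrt = sqrtm(m)
        grad = np.mean([logm(m_isqrt @ c @ m_isqrt) for c in covs], axis=0)
        m = m_sqrt @ expm(grad) @ m_sqrt
        m = 0.5 * (m + m.T)
        if np.linalg.norm(grad, "fro") <= tol:
            break
    else:
        warnings.warn(
            f"Karcher mean did not reach tol={tol} in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return m


def mean_covariance(
    covs: Sequence[np.ndarray], kind: MeanKind = "euclidean", **kwargs
) -> np.ndarray:
    """Centroid of SPD matrices under the requested mean."""
    if kind == "euclidean":
        return euclidean_mean(covs)
    if kind == "log_euclidean":
        return log_euclidean_mean(covs)
    if kind == "riemannian":
        return riemannian_mean(covs, **kwargs)
    raise InvalidInputError(f"unknown mean kind {kind!r}")


# ---------------------------------------------------------------------------
# centroid alignment


def align_trials(
    trialset: TrialSet,
    mean_kind: MeanKind = "euclidean",
    jitter: float = DEFAULT_JITTER,
) -> TrialSet:
    """Whiten every trial by the inverse square root of the subject centroid.

    With the Euclidean mean this is Euclidean alignment: the arithmetic mean
    of the aligned trial covariances equals the identity, so different
    subjects end up with a common covariance centroid.
    """
    covs = trial_covariances(trialset, jitter=jitter)
    centroid = mean_covariance(covs, kind=mean_kind)
    w = invsqrtm(centroid)
    aligned = np.einsum("ab,nbt->nat", w, trialset.trials)
    return TrialSet(
        trials=aligned,
        labels=None if trialset.labels is None else trialset.labels.copy(),
        subject_id=trialset.subject_id,
        sampling_rate=trialset.sampling_rate,
    )


# ---------------------------------------------------------------------------
# tangent-space features


def _upper_indices(ch: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(ch)


def tangent_space_map(
    covs: Sequence[np.ndarray],
    reference: np.ndarray,
    labels: np.ndarray | None = None,
    domain_tag: str = "source",
) -> FeatureSet:
    """Map SPD matrices to tangent-space feature vectors at ``reference``.

    Each covariance ``M_i`` becomes ``upper(log(M_ref M_i M_ref))`` with
    ``M_ref = reference^{-1/2}``; the upper triangle is vectorized with
    off-diagonal entries scaled by √2 so the Euclidean norm of a feature row
    equals the Riemannian distance from the reference to ``M_i`` — an isometry
    of the tangent space.  Output rows have length ``ch (ch + 1) / 2``.
    """
    reference = _check_square(reference, "reference")
    w = scipy.linalg.eigvalsh(reference)
    if w[0] <= 0:
        raise InvalidInputError("reference must be positive definite")
    covs = _as_cov_stack(covs)
    if covs.shape[1] != reference.shape[0]:
        raise InvalidInputError("covariance / reference shape mismatch")
    ch = reference.shape[0]
    m_ref = invsqrtm(reference)
    iu, ju = _upper_indices(ch)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    rows = np.empty((covs.shape[0], iu.size))
    for k, c in enumerate(covs):
        s = logm(m_ref @ c @ m_ref)
        rows[k] = s[iu, ju] * weights
    return FeatureSet(features=rows, labels=labels, domain_tag=domain_tag)


def tangent_dim(ch: int) -> int:
    """Length of a tangent-space feature vector for ``ch`` channels."""
    return ch * (ch + 1) // 2
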