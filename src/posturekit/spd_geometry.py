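"""Covariance estimation and operations on the SPD manifold.

Spatial covariance matrices of multichannel recordings are symmetric
positive-definite (SPD).  Treated as points of the SPD manifold under the
affine-invariant metric, they can be compared by the Riemannian distance

    delta_R(C1, C2) = sqrt( sum_i log^2 lambda_i ),

with lambda_i the (real, positive) eigenvalues of C1^{-1} C2.  The distance is
unchanged by any common invertible channel transform V (C -> V C V^T), which
for motion-capture data absorbs sensor placement, subject height and body
proportions.  For classification, matrices are mapped into the tangent space
at a reference point C,

    S_i = Log( C^{-1/2} C_i C^{-1/2} ),

and vectorized with unit weight on the diagonal and sqrt(2) off the diagonal,
so the Euclidean norm of the vector equals the Riemannian distance of C_i to
the reference.  The reference is the log-Euclidean mean, a fast surrogate for
the Karcher mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from posturekit.datamodel_io import JointSubset, Trial

#: Default diagonal shrinkage (fraction of the mean channel variance) added
#: when estimating covariance; near-constant channels (e.g. crossed-arm
#: postures) otherwise produce eigenvalues too small for the matrix log.
DEFAULT_SHRINKAGE = 1e-6

_SYMMETRY_RTOL = 1e-8


class NotSPDError(np.linalg.LinAlgError):
    """A matrix required to be symmetric positive definite is not."""


class NotSPDWarning(UserWarning):
    """An estimated covariance is not positive definite (flagged, not fatal)."""


def _check_symmetric(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    scale = max(np.abs(a).max(), 1.0)
    if np.abs(a - a.T).max() > _SYMMETRY_RTOL * scale:
        raise NotSPDError(f"{name} is not symmetric within tolerance")
    return 0.5 * (a + a.T)


def is_spd(a: np.ndarray, tol: float = 0.0) -> bool:
    """True if ``a`` is symmetric with smallest eigenvalue > ``tol``."""
    try:
        a = _check_symmetric(a)
    except (NotSPDError, ValueError):
        return False
    return float(np.linalg.eigvalsh(a)[0]) > tol


def spd_logm(c: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition."""
    c = _check_symmetric(c, name)
    w, v = np.linalg.eigh(c)
    if w[0] <= 0:
        raise NotSPDError(
            f"{name} has non-positive eigenvalue {w[0]:.3e}; "
            "increase shrinkage"
        )
    return (v * np.log(w)) @ v.T


def spd_expm(s: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (always SPD)."""
    s = _check_symmetric(s)
    w, v = np.linalg.eigh(s)
    return (v * np.exp(w)) @ v.T


def spd_invsqrtm(c: np.ndarray, name: str = "matrix") -> np.ndarray:
    c = _check_symmetric(c, name)
    w, v = np.linalg.eigh(c)
    if w[0] <= 0:
        raise NotSPDError(f"{name} has non-positive eigenvalue {w[0]:.3e}")
    return (v * (w ** -0.5)) @ v.T


def estimate_covariance(
    trial: Trial | np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> np.ndarray:
    """Spatial covariance of a trial: (1/Nt) (X - Xbar)(X - Xbar)^T.

    The per-channel mean (first-order moment) is removed, so the descriptor is
    independent of the subject's resting posture and sensor offset.  The 1/Nt
    normalization is used (not 1/(Nt-1)).  ``shrinkage`` adds
    ``shrinkage * (trace/N)`` to the diagonal to keep eigenvalues strictly
    positive; a non-SPD result (possible at ``shrinkage=0`` with constant or
    collinear channels) is returned but flagged with :class:`NotSPDWarning`
    so the caller may retry with regularization.
    """
    x = trial.samples if isinstance(trial, Trial) else np.asarray(trial, float)
    if x.ndim != 2:
        raise ValueError("expected a channels x frames matrix")
    n, nt = x.shape
    if nt < 2:
        raise ValueError(f"need at least 2 frames, got {nt}")
    xc = x - x.mean(axis=1, keepdims=True)
    c = (xc @ xc.T) / nt
    c = 0.5 * (c + c.T)
    if shrinkage > 0:
        c = c + shrinkage * (np.trace(c) / n) * np.eye(n)
    if np.linalg.eigvalsh(c)[0] <= 0:
        warnings.warn(
            "estimated covariance is not positive definite "
            "(constant or collinear channels); retry with shrinkage > 0",
            NotSPDWarning,
            stacklevel=2,
        )
    return c


def riemannian_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    Computed through the symmetric generalized eigenproblem
    ``C2 v = lambda C1 v`` (Cholesky whitening of ``C1``) rather than the
    non-symmetric product C1^{-1} C2, for numerical stability; the
    eigenvalues coincide in exact arithmetic.
    """
    c1 = _check_symmetric(c1, "c1")
    c2 = _check_symmetric(c2, "c2")
    if c1.shape != c2.shape:
        raise ValueError(f"dimension mismatch: {c1.shape} vs {c2.shape}")
    try:
        w = scipy.linalg.eigh(c2, c1, eigvals_only=True)
    except scipy.linalg.LinAlgError as exc:
        raise NotSPDError(f"c1 is not positive definite: {exc}") from exc
    if w[0] <= 0:
        raise NotSPDError(
            f"c2 has non-positive generalized eigenvalue {w[0]:.3e}"
        )
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def logeuclidean_mean(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Log-Euclidean mean Exp( (1/K) sum_i Log(C_i) ) of SPD matrices."""
    if len(matrices) == 0:
        raise ValueError("cannot average an empty list of matrices")
    logs = [spd_logm(c, f"matrix #{i}") for i, c in enumerate(matrices)]
    return spd_expm(np.mean(logs, axis=0))


def upper_vectorize(s: np.ndarray) -> np.ndarray:
    """Row-major upper triangle of a symmetric matrix, off-diagonal x sqrt(2).

    The sqrt(2) weight makes the vector's 2-norm equal the Frobenius norm of
    the matrix, preserving tangent-space distances under vectorization.
    """
    s = _check_symmetric(s, "tangent matrix")
    n = s.shape[0]
    iu = np.triu_indices(n)
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return s[iu] * weights


def unvectorize(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`upper_vectorize`."""
    v = np.asarray(v, dtype=float)
    m = v.shape[0]
    n = int((np.sqrt(8 * m + 1) - 1) / 2)
    if n * (n + 1) // 2 != m:
        raise ValueError(f"length {m} is not a triangular number")
    iu = np.triu_indices(n)
    s = np.zeros((n, n))
    weights = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    s[iu] = v / weights
    return s + np.triu(s, 1).T


@dataclass(frozen=True)
class TangentFeatureModel:
    """Fitted tangent-space feature map.

    Holds the reference point (log-Euclidean mean of the training
    covariances), its cached inverse square root, and the channel-subset and
    shrinkage settings under which covariances must be estimated.
    """

    reference: np.ndarray
    inverse_sqrt_reference: np.ndarray
    shrinkage: float
    subset: JointSubset | None  # None for force-plate (2-channel) data

    def __post_init__(self) -> None:
        ref = _check_symmetric(self.reference, "reference")
        isr = _check_symmetric(self.inverse_sqrt_reference,
                               "inverse_sqrt_reference")
        ident = isr @ ref @ isr
        if np.abs(ident - np.eye(ref.shape[0])).max() > 1e-8:
            raise NotSPDError(
                "inverse_sqrt_reference does not whiten the reference"
            )
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "inverse_sqrt_reference", isr)

    @property
    def n_channels(self) -> int:
        return self.reference.shape[0]

    @property
    def n_features(self) -> int:
        n = self.n_channels
        return n * (n + 1) // 2

    @classmethod
    def from_reference(
        cls,
        reference: np.ndarray,
        shrinkage: float = DEFAULT_SHRINKAGE,
        subset: JointSubset | None = None,
    ) -> "TangentFeatureModel":
        return cls(
            reference=reference,
            inverse_sqrt_reference=spd_invsqrtm(reference, "reference"),
            shrinkage=shrinkage,
            subset=subset,
        )


def tangent_project(c: np.ndarray, model: TangentFeatureModel) -> np.ndarray:
    """Project an SPD matrix into the tangent space at the model's reference.

    Returns the weighted upper-triangle vector of
    ``Log(C_ref^{-1/2} C C_ref^{-1/2})``; its 2-norm equals
    ``riemannian_distance(c, model.reference)``.
    """
    c = _check_symmetric(c, "covariance")
    if c.shape != model.reference.shape:
        raise ValueError(
            f"dimension mismatch: {c.shape} vs reference "
            f"{model.reference.shape}"
        )
    isr = model.inverse_sqrt_reference
    s = spd_logm(isr @ c @ isr, "whitened covariance")
    return upper_vectorize(s)


def fit_feature_model(
    trials: Sequence[Trial],
    subset: JointSubset | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> tuple[TangentFeatureModel, np.ndarray]:
    """Estimate covariances, fit the tangent reference, project all trials.

    1. estimate each trial's spatial covariance (after optional joint-subset
       selection for motion-capture trials);
    2. compute the log-Euclidean mean of those covariances as reference;
    3. project each covariance into the tangent space at the reference;
    4. return the fitted model and the K x N(N+1)/2 feature matrix.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    covs = [covariance_for_trial(t, subset, shrinkage) for t in trials]
    reference = logeuclidean_mean(covs)
    model = TangentFeatureModel.from_reference(reference, shrinkage, subset)
    features = np.vstack([tangent_project(c, model) for c in covs])
    return model, features


def covariance_for_trial(
    trial: Trial,
    subset: JointSubset | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> np.ndarray:
    """Covariance of a trial after optional joint-subset selection."""
    from posturekit.datamodel_io import Device, select_channels

    if subset is not None and trial.device is Device.MK2:
        trial = select_channels(trial, subset)
    return estimate_covariance(trial, shrinkage)
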