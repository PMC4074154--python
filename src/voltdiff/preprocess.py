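"""Dimensionality reduction of voltammetric signals.

Three routes are provided for reducing a 1000+-point current trace before
regression:

* manual extraction of seven peak descriptors (forward/half/reverse peak
  potentials and currents, peak separation, peak-current ratio),
* plain downsampling (keep every ``factor``-th sample),
* principal component analysis fitted on training rows only.

plus current normalization by (c0 * v) to bring voltammograms recorded at
mixed concentrations and scan rates onto a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import Voltammogram
from .errors import (
    DimensionMismatchError,
    InvalidInputError,
    NoPeakError,
)

__all__ = [
    "PeakFeatures",
    "PEAK_FEATURE_NAMES",
    "extract_peak_features",
    "downsample",
    "PCAModel",
    "pca_fit",
    "pca_transform",
    "normalize_current",
]

PEAK_FEATURE_NAMES = (
    "Ep_for",
    "E_half",
    "Ep_rev",
    "dEp",
    "ip_for",
    "ip_half",
    "peak_ratio",
)


@dataclass(frozen=True)
class PeakFeatures:
    """The seven manually extracted peak descriptors of a voltammogram.

    ``ip_half`` is the half-peak current (ip_for / 2 by definition); E_half
    is the potential on the rising flank of the forward wave where the
    current first reaches that value.  ``peak_ratio`` is ip_for / ip_rev
    measured from the zero-current baseline (this is not Nicholson's
    baseline-corrected ratio).  ``degraded_reverse`` flags traces whose
    reverse extremum sits at a branch endpoint.
    """

    Ep_for: float
    E_half: float
    Ep_rev: float
    dEp: float
    ip_for: float
    ip_half: float
    peak_ratio: float
    ip_rev: float
    degraded_reverse: bool = False

    def as_vector(self) -> np.ndarray:
        """The feature vector in the canonical order of PEAK_FEATURE_NAMES."""
        return np.array([getattr(self, name) for name in PEAK_FEATURE_NAMES])


def extract_peak_features(cv: Voltammogram) -> PeakFeatures:
    """Extract the seven peak descriptors from a voltammogram.

    The forward peak is the maximum of the forward branch (oxidation
    convention), the reverse peak the minimum of the reverse branch.  The
    half-peak potential is found by linear interpolation between the two
    samples bracketing ip_for/2 on the rising flank.

    Raises
    ------
    NoPeakError
        If the forward branch is monotone (no interior maximum).
    """
    e_for, i_for = cv.forward
    k = int(np.argmax(i_for))
    if k == 0 or k == len(i_for) - 1:
        raise NoPeakError("forward branch has no interior current maximum")
    ep_for = float(e_for[k])
    ip_for = float(i_for[k])
    ip_half = ip_for / 2.0

    # rising flank: last crossing of ip_half before the peak
    below = np.nonzero(i_for[:k] <= ip_half)[0]
    if len(below) == 0:
        e_half = float(e_for[0])
    else:
        j = int(below[-1])
        i0, i1 = i_for[j], i_for[j + 1]
        frac = 0.0 if i1 == i0 else (ip_half - i0) / (i1 - i0)
        e_half = float(e_for[j] + frac * (e_for[j + 1] - e_for[j]))

    e_rev, i_rev = cv.reverse
    kr = int(np.argmin(i_rev))
    degraded = kr == 0 or kr == len(i_rev) - 1
    ep_rev = float(e_rev[kr])
    ip_rev = float(i_rev[kr])
    ratio = np.inf if ip_rev == 0 else ip_for / ip_rev
    return PeakFeatures(
        Ep_for=ep_for,
        E_half=e_half,
        Ep_rev=ep_rev,
        dEp=ep_for - ep_rev,
        ip_for=ip_for,
        ip_half=ip_half,
        peak_ratio=float(ratio),
        ip_rev=ip_rev,
        degraded_reverse=degraded,
    )


def downsample(signal, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample (indices 0, factor, 2*factor, ...).

    Accepts a vector or a :class:`Voltammogram` (whose currents are used).
    The result has ``ceil(len / factor)`` entries.
    """
    if int(factor) != factor or factor < 1:
        raise InvalidInputError(f"downsampling factor must be a positive integer, got {factor}")
    vec = signal.currents if isinstance(signal, Voltammogram) else np.asarray(signal)
    return vec[:: int(factor)].copy()


@dataclass(frozen=True)
class PCAModel:
    """Mean-centered principal component model.

    ``loadings`` is the d x k orthonormal basis of the retained subspace,
    ``eigenvalues`` the corresponding score variances (descending), and
    ``explained_variance_ratio`` the fraction of total variance captured.
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: float
    total_variance: float


def pca_fit(X, k: int) -> PCAModel:
    """Fit a k-component PCA to the rows of X (no column scaling).

    Components are computed by SVD of the mean-centered matrix; eigenvalues
    are the score variances with denominator (m - 1).  Component signs are
    fixed so the largest-magnitude loading entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionMismatchError("X must be a 2-D matrix")
    m, d = X.shape
    if m < 2:
        raise InvalidInputError("PCA needs at least two rows")
    if not 1 <= k <= min(m - 1, d):
        raise InvalidInputError(f"k={k} must satisfy 1 <= k <= min(m-1, d)")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum() / (m - 1))
    if total == 0.0:
        raise InvalidInputError("total variance is zero; PCA is undefined")
    eig = s[:k] ** 2 / (m - 1)
    loadings = vt[:k].T
    # deterministic sign convention
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCAModel(
        mean=mean,
        loadings=loadings,
        eigenvalues=eig,
        explained_variance_ratio=float(eig.sum() / total),
        total_variance=total,
    )


def pca_transform(model: PCAModel, X) -> np.ndarray:
    """Project rows of X onto the model's subspace using the *training* mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise DimensionMismatchError(
            f"X has {X.shape[1]} columns, model expects {model.mean.shape[0]}"
        )
    return (X - model.mean) @ model.loadings


def normalize_current(cv: Voltammogram) -> np.ndarray:
    """Current trace divided by (c0 * v), for mixed-condition comparability."""
    cond = cv.conditions
    return cv.currents / (cond.bulk_concentration * cond.scan_rate)
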