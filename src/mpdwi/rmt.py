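"""Random-matrix-theory machinery for patch-level MPPCA denoising.

A patch of a diffusion-weighted series is arranged as a data matrix ``X`` of
shape M x N (M measurements/volumes by N voxels).  When the noise-free signal
is low-rank, the eigenvalues of ``X @ X.T`` split into a few large
signal-carrying components and a bulk of pure-noise components whose empirical
distribution follows the Marchenko-Pastur (MP) law.  This module locates the
split self-consistently (symmetric thresholding), estimates the noise level
from the bulk, and reconstructs a low-rank denoised matrix with optional
optimal singular-value shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MPFit",
    "mp_fit_symmetric",
    "gd_shrinker",
    "denoise_matrix",
]


@dataclass(frozen=True)
class MPFit:
    """Result of fitting the MP bulk to one patch eigenspectrum.

    Attributes
    ----------
    p : int
        Number of retained signal components, ``0 <= p <= M' - 1``.
    sigma2 : float
        Noise variance estimated from the bulk.  For complex-valued patches
        this is the total complex variance (real plus imaginary channel);
        divide by 2 for the per-channel variance.
    """

    p: int
    sigma2: float

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


def mp_fit_symmetric(x: np.ndarray, m_prime: int | None = None,
                     n_prime: int | None = None) -> MPFit:
    """Select the signal rank ``p`` by symmetric MP thresholding.

    Parameters
    ----------
    x : ndarray
        Eigenvalues of ``X @ X.T`` (squared singular values of ``X``), sorted
        in descending order, length ``M' = min(M, N)``.
    m_prime, n_prime : int
        ``min(M, N)`` and ``max(M, N)``.  Default ``M' = len(x)``; ``N'``
        must be given when it differs from ``M'``.

    Notes
    -----
    Two bulk-variance estimators are formed from the bottom ``M' - p``
    eigenvalues,

        sigma1^2(p) = sum_{i>p} x_i / ((N'-p)(M'-p))
        sigma2^2(p) = (x_{p+1} - x_{M'}) / (4 sqrt((N'-p)(M'-p)))

    (mean of the bulk, and its spread normalised by the MP edge width).  Both
    are symmetric in M' and N'.  While signal components are still counted in
    the bulk the spread estimator exceeds the mean estimator; the smallest
    ``p`` with ``sigma2^2(p) <= sigma1^2(p)`` marks consistency with an MP
    bulk and is returned, with ``sigma2 = sigma1^2(p)``.

    If no crossing occurs the patch is degenerate; everything is treated as
    signal (``p = M' - 1``, ``sigma2 = 0``) so that signal is never destroyed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("eigenspectrum must be 1-D with at least 2 entries")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("eigenvalues must be finite and non-negative")
    if np.any(np.diff(x) > 0):
        raise ValueError("eigenvalues must be sorted in descending order")
    mp = x.size if m_prime is None else int(m_prime)
    np_ = mp if n_prime is None else int(n_prime)
    if mp < 2:
        raise ValueError("need M' >= 2")
    if np_ < mp:
        raise ValueError("require N' >= M'")

    ps = np.arange(mp - 1)
    # tail sums: sum over the bottom M'-p eigenvalues, x[p:] in 0-based terms
    csum = np.concatenate([[0.0], np.cumsum(x)])
    tails = csum[-1] - csum[ps]
    denom = (np_ - ps) * (mp - ps)
    sig1 = tails / denom
    sig2 = (x[ps] - x[-1]) / (4.0 * np.sqrt(denom))
    ok = sig2 <= sig1
    if not np.any(ok):
        return MPFit(p=mp - 1, sigma2=0.0)
    p = int(ps[ok][0])
    return MPFit(p=p, sigma2=float(sig1[p]))


def gd_shrinker(y: np.ndarray | float, gamma: float) -> np.ndarray | float:
    """Optimal Frobenius-norm singular-value shrinker.

    For a scaled singular value ``y`` observed from a unit-noise model with
    aspect ratio ``gamma = M'/N' in (0, 1]``, the minimum-MSE estimate of the
    underlying clean singular value is

        eta(y) = sqrt((y^2 - gamma - 1)^2 - 4 gamma) / y   for y > 1 + sqrt(gamma)
        eta(y) = 0                                          otherwise.

    The shrinker vanishes at the bulk edge, is monotone in ``y`` and always
    satisfies ``eta(y) <= y``.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    edge = 1.0 + np.sqrt(gamma)
    above = y > edge
    out = np.zeros_like(y)
    ya = y[above]
    arg = (ya**2 - gamma - 1.0) ** 2 - 4.0 * gamma
    out[above] = np.sqrt(np.maximum(arg, 0.0)) / ya
    if out.ndim == 0:
        return float(out)
    return out


def denoise_matrix(X: np.ndarray, shrink: bool = True,
                   scale: str = "M") -> tuple[np.ndarray, MPFit]:
    """Low-rank denoise one patch matrix.

    Parameters
    ----------
    X : (M, N) ndarray, real or complex
        Patch data matrix; no mean-centering is applied.
    shrink : bool
        With ``shrink`` off the top ``p`` singular values are kept unchanged
        (hard thresholding); with it on each kept value ``s`` is replaced by
        ``sqrt(M') sigma * eta(s / (sqrt(M') sigma))``.
    scale : {"M", "N"}
        Which dimension scales sigma inside the shrinker argument.  The
        default uses ``M' = min(M, N)``.

    Returns
    -------
    X_hat : ndarray
        Rank-``p`` reconstruction (zero matrix when ``p = 0``).
    fit : MPFit
    """
    X = np.asarray(X)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("X must be 2-D with both dimensions >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must have finite entries")
    if scale not in ("M", "N"):
        raise ValueError("scale must be 'M' or 'N'")
    M, N = X.shape
    mp, np_ = (M, N) if M <= N else (N, M)

    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    fit = mp_fit_symmetric(s**2, m_prime=mp, n_prime=np_)
    p = fit.p
    if p == 0:
        return np.zeros_like(X), fit

    s_kept = s[:p].copy()
    sigma = fit.sigma
    if shrink and sigma > 0:
        dim = mp if scale == "M" else np_
        root = np.sqrt(dim) * sigma
        gamma = mp / np_
        s_kept = root * np.asarray(gd_shrinker(s_kept / root, gamma))
    X_hat = (U[:, :p] * s_kept) @ Vh[:p]
    return X_hat, fit
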