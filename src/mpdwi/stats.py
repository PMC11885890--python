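"""Scan-rescan reproducibility statistics.

Pairwise coefficient of variation, Lin's concordance correlation
coefficient, ICC(A,1), the Rayleigh noise-floor estimator, and two-group
sample-size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .series import DWISeries

__all__ = [
    "pair_cv",
    "lin_ccc",
    "icc_a1",
    "noise_floor",
    "required_sample_size",
    "PowerInputs",
]


def pair_cv(x1: np.ndarray, x2: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Element-wise test-retest mean, absolute error, and CV.

    mu = (x1 + x2)/2,  sigma = sqrt(pi/2) |x1 - x2|,  CV = sigma/mu.

    With two independent measurements of per-measurement SD s, the
    expectation of sigma is s*sqrt(2) (it estimates the SD of the
    difference, since E|x1-x2| = 2 s / sqrt(pi)).  CV is NaN where mu = 0;
    summarise it with a small-mean exclusion (see ``cv_summary``).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have the same shape")
    if x1.size == 0:
        raise ValueError("empty input")
    mu = 0.5 * (x1 + x2)
    sigma = np.sqrt(np.pi / 2.0) * np.abs(x1 - x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu != 0, sigma / mu, np.nan)
    return mu, sigma, cv


def cv_summary(x1: np.ndarray, x2: np.ndarray, mask: np.ndarray | None = None,
               eps: float = 1e-12) -> dict[str, float]:
    """Voxel-wise and ROI-level CV summaries for one parameter map pair.

    * ``cv_voxel``: per-voxel CV averaged (mean) over the mask, excluding
      voxels with |mu| <= eps or non-finite values (their count is
      reported) — normalising by a near-zero mean is unstable.
    * ``cv_roi``: CV of the two ROI-mean parameter values.
    """
    if mask is None:
        mask = np.ones(np.shape(x1), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    mu, sigma, cv = pair_cv(np.asarray(x1)[mask], np.asarray(x2)[mask])
    good = np.isfinite(cv) & (np.abs(mu) > eps)
    r1 = float(np.nanmean(np.asarray(x1, dtype=float)[mask]))
    r2 = float(np.nanmean(np.asarray(x2, dtype=float)[mask]))
    _, rsig, rcv = pair_cv(np.array([r1]), np.array([r2]))
    return {
        "cv_voxel": float(cv[good].mean()) if good.any() else float("nan"),
        "sigma_voxel": float(sigma[np.isfinite(sigma)].mean()),
        "n_excluded": int((~good).sum()),
        "cv_roi": float(rcv[0]),
        "sigma_roi": float(rsig[0]),
    }


def lin_ccc(x1: np.ndarray, x2: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population variances).

    CCC = 2 cov(x1, x2) / (var x1 + var x2 + (mu1 - mu2)^2); equals 1 only
    for perfect agreement, penalising both correlation loss and mean/scale
    shifts.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape or x1.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    m1, m2 = x1.mean(), x2.mean()
    v1 = np.mean((x1 - m1) ** 2)
    v2 = np.mean((x2 - m2) ** 2)
    cov = np.mean((x1 - m1) * (x2 - m2))
    denom = v1 + v2 + (m1 - m2) ** 2
    if denom == 0:
        return 1.0  # both constant with equal means: perfect agreement
    return float(2.0 * cov / denom)


def icc_a1(data: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``data`` is an (n subjects x k conditions) complete matrix.  From the
    two-way ANOVA mean squares (rows MS_R, columns MS_C, error MS_E):

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("incomplete matrix: non-finite entries present")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) /
                 (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)))


def noise_floor(dwi: DWISeries, mask: np.ndarray,
                shell: float = 2000.0) -> tuple[np.ndarray, float]:
    """Rayleigh noise-floor estimate in a zero-signal region.

    Per in-mask voxel: the direction-averaged signal on the given shell,
    normalised by that voxel's mean b=0 signal S0.  Where the underlying
    signal vanishes (CSF at b = 2000, attenuation ~ e^-6) the magnitude of
    pure complex Gaussian noise is Rayleigh distributed with mean
    sigma*sqrt(pi/2), so the pooled floor distribution estimates the
    relative noise level.  Voxels with S0 <= 0 are excluded.

    Returns (pooled per-voxel floors, their median).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.signal.shape[:3]:
        raise ValueError("mask must match the spatial shape")
    if not mask.any():
        raise ValueError("empty mask")
    shell_mask = dwi.shell_mask(shell)
    if not shell_mask.any():
        raise ValueError(f"no volumes on shell b={shell}")
    b0 = dwi.signal[..., dwi.b0_mask].mean(axis=-1)
    mean_dwi = dwi.signal[..., shell_mask].mean(axis=-1)
    s0 = b0[mask]
    floors = mean_dwi[mask]
    keep = s0 > 0
    floors = floors[keep] / s0[keep]
    return floors, float(np.median(floors))


@dataclass(frozen=True)
class PowerInputs:
    """Inputs for the two-group sample-size formula.

    mu1, mu2 : group means of the parameter compared.
    var_between : variance of test measurements over subjects, var(x1).
    sigma_bar2 : population-averaged squared test-retest error.
    alpha : two-sided significance level.  power : 1 - beta.
    """

    mu1: float
    mu2: float
    var_between: float
    sigma_bar2: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.var_between < 0 or self.sigma_bar2 < 0:
            raise ValueError("variances must be >= 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def required_sample_size(p: PowerInputs) -> int:
    """Per-group sample size for a two-sided z-approximate two-sample test.

    n1 = 2 (Z_{alpha/2} + Z_beta)^2 sigma_p^2 / (mu1 - mu2)^2, with
    sigma_p^2 = var(x1) + sigma_bar^2 the sum of intersubject and
    test-retest variance.  Normal (not t) quantiles are used, as in the
    standard closed-form formula.  Returned as ceil(n1) with a floor of 2.
    """
    if p.mu1 == p.mu2:
        raise ValueError("mu1 == mu2: required sample size is infinite")
    z_a = sps.norm.ppf(1.0 - p.alpha / 2.0)
    z_b = sps.norm.ppf(p.power)
    sigma_p2 = p.var_between + p.sigma_bar2
    n1 = 2.0 * (z_a + z_b) ** 2 * sigma_p2 / (p.mu1 - p.mu2) ** 2
    return max(2, math.ceil(n1))
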