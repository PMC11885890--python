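"""Diffusion and kurtosis tensor estimation and scalar maps.

The signal model is the cumulant expansion to second order in b,

    ln S(b, n) / S(0) = -b D(n) + (1/6) b^2 Dbar^2 W(n),

with D(n) = D_ij n_i n_j the diffusion tensor quadratic form (um^2/ms; b is
converted to ms/um^2 internally so D carries those units and W is
dimensionless) and W(n) = W_ijkl n_i n_j n_k n_l the dimensionless kurtosis
tensor quartic form, Dbar = tr(D)/3.

Fitting is unconstrained weighted linear least squares (WLLS): ordinary
least squares on log-signals followed by re-weighting with the squared
predicted signals, iterated.  Scalar maps come in two conventions:

* W convention (mean/axial/radial of the cumulant W(n)) — MW is an exact
  tensor trace, AW/RW are projections along / transverse to the principal
  fiber direction; robust to outliers.
* K convention (mean/axial/radial of the directional kurtosis
  K(n) = Dbar^2 W(n) / D(n)^2) — requires angular integration and is
  outlier-prone where D(n) is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import DWISeries

__all__ = [
    "TensorFitResult",
    "shell_spherical_mean",
    "fit_wlls_dki",
    "fit_dti",
    "dti_metrics",
    "kurtosis_metrics_W",
    "kurtosis_metrics_K",
    "count_outliers",
    "compute_parameter_maps",
    "dt_to_tensor",
    "kt_to_tensor",
    "fibonacci_sphere",
]

# unique-element bookkeeping ------------------------------------------------

# D_ij order (lower-triangular pairs)
DT_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
DT_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

# W_ijkl order; multiplicity = number of index permutations
KT_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
KT_MULT = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0,
                    4.0, 4.0, 4.0, 6.0, 6.0, 6.0, 12.0, 12.0, 12.0])


def quadratic_form_design(n: np.ndarray) -> np.ndarray:
    """(len(n), 6) design so that design @ dt6 = D(n)."""
    n = np.atleast_2d(n)
    cols = [DT_MULT[a] * n[:, i] * n[:, j] for a, (i, j) in enumerate(DT_IDX)]
    return np.stack(cols, axis=1)


def quartic_form_design(n: np.ndarray) -> np.ndarray:
    """(len(n), 15) design so that design @ kt15 = W(n)."""
    n = np.atleast_2d(n)
    cols = [KT_MULT[a] * n[:, i] * n[:, j] * n[:, k] * n[:, l]
            for a, (i, j, k, l) in enumerate(KT_IDX)]
    return np.stack(cols, axis=1)


def dt_to_tensor(dt6: np.ndarray) -> np.ndarray:
    """Unique elements (..., 6) -> full symmetric tensor (..., 3, 3)."""
    dt6 = np.asarray(dt6)
    D = np.zeros(dt6.shape[:-1] + (3, 3))
    for a, (i, j) in enumerate(DT_IDX):
        D[..., i, j] = dt6[..., a]
        D[..., j, i] = dt6[..., a]
    return D


def kt_to_tensor(kt15: np.ndarray) -> np.ndarray:
    """Unique elements (..., 15) -> fully symmetric tensor (..., 3, 3, 3, 3)."""
    kt15 = np.asarray(kt15)
    W = np.zeros(kt15.shape[:-1] + (3, 3, 3, 3))
    from itertools import permutations
    for a, idx in enumerate(KT_IDX):
        for perm in set(permutations(idx)):
            W[(...,) + perm] = kt15[..., a]
    return W


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform point set on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


# fitting -------------------------------------------------------------------


@dataclass
class TensorFitResult:
    """Per-voxel tensors from a (D)KI fit.

    s0 : (...,) non-negative signal at b=0.
    dt : (..., 6) diffusion tensor unique elements [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz],
         um^2/ms.
    kt : (..., 15) kurtosis tensor W unique elements (dimensionless), zero
         for a DTI-only fit.
    valid : (...,) bool, False where the fit failed (outputs NaN there).
    """

    s0: np.ndarray
    dt: np.ndarray
    kt: np.ndarray
    valid: np.ndarray

    @property
    def md(self) -> np.ndarray:
        return np.mean(self.dt[..., :3], axis=-1)


def shell_spherical_mean(dwi: DWISeries) -> dict[float, np.ndarray]:
    """Arithmetic direction-average of the signal per shell.

    The zeroth rotational invariant of the signal on each shell, estimated
    linearly as the mean over that shell's directions.
    """
    out: dict[float, np.ndarray] = {}
    shells = dwi.shells
    for b in np.unique(shells):
        mask = shells == b
        if not np.any(mask):
            raise ValueError(f"empty shell b={b}")
        out[float(b)] = dwi.signal[..., mask].mean(axis=-1)
    return out


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray,
                   order: int) -> np.ndarray:
    """WLLS design: [1, -b*quad6, (1/6) b^2 * quart15] with b in ms/um^2."""
    b = np.asarray(bvals, dtype=float) / 1000.0
    n = np.asarray(bvecs, dtype=float)
    cols = [np.ones_like(b)]
    cols.append(-b[:, None] * quadratic_form_design(n))
    if order == 4:
        cols.append((b**2 / 6.0)[:, None] * quartic_form_design(n))
    return np.concatenate([c if c.ndim == 2 else c[:, None] for c in cols],
                          axis=1)


def _wlls(A: np.ndarray, logs: np.ndarray, n_iter: int) -> np.ndarray:
    """Batched WLLS solve: A (M, P), logs (V, M) -> theta (V, P)."""
    theta = np.linalg.lstsq(A, logs.T, rcond=None)[0].T
    for _ in range(n_iter):
        w = np.exp(2.0 * np.clip(theta @ A.T, -700 / 2, 700 / 2))  # Shat^2
        Aw = w[:, :, None] * A[None, :, :]
        G = np.einsum("vmi,mj->vij", Aw, A)
        rhs = np.einsum("vmi,vm->vi", Aw, logs)
        theta = np.linalg.solve(G, rhs[..., None])[..., 0]
    return theta


def _fit(dwi: DWISeries, order: int, n_iter: int = 2) -> TensorFitResult:
    A = _design_matrix(dwi.bvals, dwi.bvecs, order)
    M, P = A.shape
    if np.linalg.matrix_rank(A) < P:
        raise ValueError(
            "rank-deficient design: not enough distinct directions/shells")
    spatial = dwi.signal.shape[:3]
    S = np.asarray(dwi.signal, dtype=float).reshape(-1, M)
    V = S.shape[0]
    theta = np.full((V, P), np.nan)
    pos = S > 0
    allpos = pos.all(axis=1)
    valid = np.zeros(V, dtype=bool)

    if np.any(allpos):
        logs = np.log(S[allpos])
        theta[allpos] = _wlls(A, logs, n_iter)
        valid[allpos] = True

    # voxels with non-positive signals: delete those rows voxel-wise
    for v in np.flatnonzero(~allpos):
        keep = pos[v]
        if keep.sum() < P:
            continue
        Av = A[keep]
        if np.linalg.matrix_rank(Av) < P:
            continue
        theta[v] = _wlls(Av, np.log(S[v, keep])[None, :], n_iter)[0]
        valid[v] = True

    s0 = np.exp(theta[:, 0])
    dt = theta[:, 1:7]
    if order == 4:
        # fitted quartic coefficients V(n) = Dbar^2 W(n)
        md = np.mean(dt[:, :3], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            kt = theta[:, 7:22] / (md**2)[:, None]
        kt[md <= 0] = np.nan
    else:
        kt = np.zeros((V, 15))
    return TensorFitResult(
        s0=s0.reshape(spatial),
        dt=dt.reshape(spatial + (6,)),
        kt=kt.reshape(spatial + (15,)),
        valid=valid.reshape(spatial),
    )


def fit_wlls_dki(dwi: DWISeries, n_iter: int = 2) -> TensorFitResult:
    """Unconstrained WLLS fit of the 22-parameter DKI model."""
    if dwi.n_volumes < 22:
        raise ValueError("DKI needs at least 22 volumes")
    return _fit(dwi, order=4, n_iter=n_iter)


def fit_dti(dwi: DWISeries, n_iter: int = 2, b_max: float = 1050.0) -> TensorFitResult:
    """7-parameter DTI WLLS fit restricted to the b = 0 and b = 1000 shells."""
    sub = dwi.subset(dwi.shells <= b_max)
    if sub.n_volumes < 7:
        raise ValueError("DTI needs at least 7 volumes at b <= 1000")
    return _fit(sub, order=2, n_iter=n_iter)


# scalar maps ---------------------------------------------------------------


def _eig(fit: TensorFitResult) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and eigenvectors; v1 z-component >= 0."""
    D = dt_to_tensor(np.nan_to_num(fit.dt, nan=0.0))
    evals, evecs = np.linalg.eigh(D)       # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]               # columns: v1, v2, v3
    sign = np.where(evecs[..., 2, 0] < 0, -1.0, 1.0)
    evecs = evecs * sign[..., None, None]
    bad = ~fit.valid
    evals[bad] = np.nan
    return evals, evecs


def dti_metrics(fit: TensorFitResult) -> dict[str, np.ndarray]:
    """MD, AD, RD, FA from the diffusion tensor.

    AD = lambda_1; RD = (lambda_2 + lambda_3)/2 — the exact circle average
    of the quadratic form D(n) over the plane transverse to v1.
    """
    evals, _ = _eig(fit)
    md = np.mean(evals, axis=-1)
    ad = evals[..., 0]
    rd = 0.5 * (evals[..., 1] + evals[..., 2])
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.sum((evals - md[..., None]) ** 2, axis=-1)
        den = np.sum(evals**2, axis=-1)
        fa = np.sqrt(1.5 * num / den)
    return {"md": md, "ad": ad, "rd": rd, "fa": fa}


def kurtosis_metrics_W(fit: TensorFitResult) -> dict[str, np.ndarray]:
    """Mean/axial/radial kurtosis in the W (cumulant) convention.

    MW is the full trace W_iikk / 5, exact and integral-free.  AW = W(v1).
    RW is the analytic circle average in the transverse plane:
    (3/8)(W(v2) + W(v3)) + (3/4) W[v2 v2 v3 v3].
    """
    kt = np.nan_to_num(fit.kt, nan=0.0)
    mw = (kt[..., 0] + kt[..., 1] + kt[..., 2]
          + 2.0 * (kt[..., 9] + kt[..., 10] + kt[..., 11])) / 5.0
    Wfull = kt_to_tensor(kt)
    _, evecs = _eig(fit)
    v1 = evecs[..., :, 0]
    v2 = evecs[..., :, 1]
    v3 = evecs[..., :, 2]

    def wform(a, b, c, d):
        return np.einsum("...ijkl,...i,...j,...k,...l->...", Wfull, a, b, c, d)

    aw = wform(v1, v1, v1, v1)
    rw = (3.0 / 8.0) * (wform(v2, v2, v2, v2) + wform(v3, v3, v3, v3)) \
        + (3.0 / 4.0) * wform(v2, v2, v3, v3)
    bad = ~fit.valid | np.isnan(fit.kt).any(axis=-1)
    return {"mw": np.where(bad, np.nan, mw),
            "aw": np.where(bad, np.nan, aw),
            "rw": np.where(bad, np.nan, rw)}


def kurtosis_metrics_K(fit: TensorFitResult, n_sphere: int = 10000,
                       n_circle: int = 3600,
                       chunk: int = 256) -> dict[str, np.ndarray]:
    """Mean/axial/radial kurtosis in the K (directional) convention.

    MK is the spherical average of Dbar^2 W(n)/D(n)^2 over a deterministic
    Fibonacci point set; AK = Dbar^2 W(v1)/lambda_1^2; RK is the circle
    average of the same integrand in the transverse plane.  Voxels where
    D is not positive-definite are returned NaN.
    """
    spatial = fit.dt.shape[:-1]
    dt = np.nan_to_num(fit.dt, nan=0.0).reshape(-1, 6)
    kt = np.nan_to_num(fit.kt, nan=0.0).reshape(-1, 15)
    evals, evecs = _eig(fit)
    evals = evals.reshape(-1, 3)
    evecs = evecs.reshape(-1, 3, 3)
    V = dt.shape[0]
    md = np.mean(dt[:, :3], axis=1)

    nodes = fibonacci_sphere(n_sphere)
    A2 = quadratic_form_design(nodes)       # (n, 6)
    A4 = quartic_form_design(nodes)         # (n, 15)
    theta = np.linspace(0.0, 2.0 * np.pi, n_circle, endpoint=False)
    cth, sth = np.cos(theta), np.sin(theta)

    mk = np.empty(V)
    rk = np.empty(V)
    for lo in range(0, V, chunk):
        hi = min(lo + chunk, V)
        Dn = dt[lo:hi] @ A2.T               # (v, n)
        Wn = kt[lo:hi] @ A4.T
        with np.errstate(divide="ignore", invalid="ignore"):
            mk[lo:hi] = (md[lo:hi]**2) * np.mean(Wn / Dn**2, axis=1)
        # circle nodes in the transverse plane, per voxel
        v2 = evecs[lo:hi, :, 1]
        v3 = evecs[lo:hi, :, 2]
        nc = cth[None, :, None] * v2[:, None, :] + sth[None, :, None] * v3[:, None, :]
        flat = nc.reshape(-1, 3)
        Dc = np.einsum("vc,vc->v", quadratic_form_design(flat),
                       np.repeat(dt[lo:hi], n_circle, axis=0))
        Wc = np.einsum("vc,vc->v", quartic_form_design(flat),
                       np.repeat(kt[lo:hi], n_circle, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            rk[lo:hi] = (md[lo:hi]**2) * np.mean(
                (Wc / Dc**2).reshape(hi - lo, n_circle), axis=1)

    v1 = evecs[:, :, 0]
    Wv1 = np.einsum("vc,vc->v", quartic_form_design(v1), kt)
    with np.errstate(divide="ignore", invalid="ignore"):
        ak = md**2 * Wv1 / evals.reshape(-1, 3)[:, 0] ** 2

    bad = (~fit.valid.ravel()) | (np.min(evals, axis=1) <= 0)
    for m in (mk, ak, rk):
        m[bad] = np.nan
    return {"mk": mk.reshape(spatial), "ak": ak.reshape(spatial),
            "rk": rk.reshape(spatial)}


def count_outliers(kmap: np.ndarray, mask: np.ndarray,
                   lo: float = -1.0, hi: float = 10.0) -> float:
    """Percentage of in-mask voxels with kurtosis < lo or > hi.

    Bounds are strict (boundary values are retained); NaN voxels count as
    outliers.  The same rule excludes voxels before ROI means.
    """
    kmap = np.asarray(kmap)
    mask = np.asarray(mask, dtype=bool)
    if kmap.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    vals = kmap[mask]
    out = np.isnan(vals) | (vals < lo) | (vals > hi)
    return float(100.0 * out.mean())


def compute_parameter_maps(dwi: DWISeries, model: str = "dki",
                           with_k: bool = True,
                           n_iter: int = 2) -> dict[str, np.ndarray]:
    """Convenience wrapper: fit and derive all scalar maps.

    ``model="dti"`` fits only b <= 1000 and returns the DTI family;
    ``model="dki"`` adds the W-convention (and optionally K-convention)
    kurtosis maps.
    """
    if model == "dti":
        fit = fit_dti(dwi, n_iter=n_iter)
        return dti_metrics(fit)
    fit = fit_wlls_dki(dwi, n_iter=n_iter)
    maps = dti_metrics(fit)
    maps.update(kurtosis_metrics_W(fit))
    if with_k:
        maps.update(kurtosis_metrics_K(fit))
    return maps
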