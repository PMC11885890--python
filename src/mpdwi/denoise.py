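"""Volume-level denoising pipelines.

Three processing arms are supported:

* ``none`` — identity (baseline arm for comparisons);
* ``magnitude`` — MPPCA on magnitude data with adaptive 3-D patches,
  symmetric MP thresholding and singular-value shrinkage;
* ``complex`` — two-pass denoising of complex data: the smooth shot-to-shot
  phase is first estimated by low-rank denoising of the complex images with
  2-D sliding patches, the data are phase-unwound (multiplied by the
  conjugate phase so the signal becomes real and the noise zero-mean
  Gaussian), and the real part is then denoised with the magnitude
  machinery.  The second pass removes the Rician noise floor, so its output
  may legitimately contain negative values; they are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from tqdm.auto import tqdm

from .patching import PatchConfig, select_adaptive_patch
from .rmt import denoise_matrix
from .series import DWISeries

__all__ = [
    "DenoiseResult",
    "denoise_none",
    "denoise_magnitude",
    "estimate_smooth_phase",
    "unwind_phase",
    "denoise_complex",
]


@dataclass
class DenoiseResult:
    """Denoised volume plus per-voxel noise level and retained rank.

    ``sigma_map`` is the noise standard deviation per channel of the data
    fitted in the (final) denoising pass: the Rician channel sigma for the
    magnitude arm, the real-channel sigma for the complex arm.
    """

    denoised: np.ndarray
    sigma_map: np.ndarray
    rank_map: np.ndarray
    method: str


def denoise_none(dwi: DWISeries) -> DenoiseResult:
    """Identity arm: untouched signal, empty sigma and rank maps."""
    shape = dwi.signal.shape[:3]
    return DenoiseResult(
        denoised=dwi.signal.copy(),
        sigma_map=np.zeros(shape),
        rank_map=np.zeros(shape, dtype=int),
        method="none",
    )


def _denoise_volume(signal: np.ndarray, cfg: PatchConfig, shrink: bool,
                    scale: str = "M") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding adaptive-patch MPPCA over a real-valued 4-D array.

    Each voxel takes its denoised value from the patch in which it is the
    center (moving patch, no overlap averaging).
    """
    X, Y, Z, M = signal.shape
    out = np.empty_like(signal, dtype=float)
    sigma_map = np.zeros((X, Y, Z))
    rank_map = np.zeros((X, Y, Z), dtype=int)
    for x in tqdm(range(X), desc="denoise", leave=False, disable=None):
        for y in range(Y):
            for z in range(Z):
                patch = select_adaptive_patch(signal, (x, y, z), cfg)
                idx = patch.members
                mat = signal[idx[:, 0], idx[:, 1], idx[:, 2], :].T  # M x N
                den, fit = denoise_matrix(mat, shrink=shrink, scale=scale)
                out[x, y, z] = den[:, 0]        # center is selection index 0
                sigma_map[x, y, z] = fit.sigma
                rank_map[x, y, z] = fit.p
    return out, sigma_map, rank_map


def denoise_magnitude(dwi: DWISeries, cfg: PatchConfig | None = None,
                      shrink: bool = True, scale: str = "M") -> DenoiseResult:
    """MPPCA denoising of magnitude (or real-valued) data."""
    if dwi.n_volumes < 8:
        raise ValueError("need at least 8 volumes for a stable MP fit")
    cfg = cfg or PatchConfig()
    den, sigma_map, rank_map = _denoise_volume(
        np.asarray(dwi.signal, dtype=float), cfg, shrink, scale)
    return DenoiseResult(den, sigma_map, rank_map, method="magnitude")


def estimate_smooth_phase(dwi: DWISeries, kernel: int = 15,
                          stride: int = 1) -> np.ndarray:
    """Estimate the smooth shot-to-shot phase by complex low-rank denoising.

    For every slice the complex images ``magnitude * exp(i phase)`` are
    processed with a ``kernel x kernel`` 2-D box patch (matrix M x kernel^2,
    symmetric thresholding, no shrinkage); the phase estimate at a voxel is
    the angle of its low-rank reconstruction.  Wrapped phase maps are never
    filtered directly — the angle is taken only after denoising the complex
    signal, which avoids 2-pi wrap artifacts.

    ``stride`` > 1 tiles the slice with non-overlapping windows (each window
    writes its full block) for speed; the default slides the window with
    center write-back, matching the signal pass.
    """
    if dwi.phase is None:
        raise ValueError(
            "series has no phase volume; use the magnitude pipeline instead")
    C = dwi.complex_signal()
    X, Y, Z, M = C.shape
    half = kernel // 2
    phi = np.empty((X, Y, Z, M))
    for z in tqdm(range(Z), desc="phase", leave=False, disable=None):
        sl = C[:, :, z]                       # (X, Y, M)
        if stride > 1:
            # tile edges: the last block absorbs any remainder thinner than
            # half a kernel so every patch matrix keeps >= 2 columns
            xstarts = [x for x in range(0, X, kernel)
                       if X - x >= kernel // 2 or x == 0]
            ystarts = [y for y in range(0, Y, kernel)
                       if Y - y >= kernel // 2 or y == 0]
            for i, x0 in enumerate(xstarts):
                for j, y0 in enumerate(ystarts):
                    xe = xstarts[i + 1] if i + 1 < len(xstarts) else X
                    ye = ystarts[j + 1] if j + 1 < len(ystarts) else Y
                    xs = slice(x0, xe)
                    ys = slice(y0, ye)
                    blk = sl[xs, ys]
                    mat = blk.reshape(-1, M).T
                    den, _ = denoise_matrix(mat, shrink=False)
                    phi[xs, ys, z] = np.angle(den.T.reshape(blk.shape))
        else:
            for x in range(X):
                xs = slice(max(x - half, 0), min(x + half + 1, X))
                for y in range(Y):
                    ys = slice(max(y - half, 0), min(y + half + 1, Y))
                    blk = sl[xs, ys]
                    mat = blk.reshape(-1, M).T  # M x (window voxels)
                    den, _ = denoise_matrix(mat, shrink=False)
                    ci = (x - xs.start) * blk.shape[1] + (y - ys.start)
                    phi[x, y, z] = np.angle(den[:, ci])
    return phi


def unwind_phase(dwi: DWISeries, phi_dn: np.ndarray) -> DWISeries:
    """Remove the estimated phase; return the real-valued series.

    ``S_real = Re(S_complex * exp(-i phi_dn))``.  With an accurate phase
    estimate the signal is rotated onto the real axis and the imaginary part
    carries only noise, which is discarded.
    """
    if dwi.phase is None:
        raise ValueError("series has no phase volume")
    phi_dn = np.asarray(phi_dn)
    if phi_dn.shape != dwi.signal.shape:
        raise ValueError("phi_dn must match the signal shape")
    real = np.real(dwi.complex_signal() * np.exp(-1j * phi_dn))
    return DWISeries(signal=real, bvals=dwi.bvals, bvecs=dwi.bvecs,
                     phase=None, voxel_size=dwi.voxel_size, affine=dwi.affine)


def denoise_complex(dwi: DWISeries, cfg: PatchConfig | None = None,
                    shrink: bool = True, scale: str = "M",
                    phase_kernel: int = 15,
                    phase_stride: int = 1) -> DenoiseResult:
    """Two-pass complex denoising: phase estimation, unwinding, real denoise.

    The phase pass uses 2-D box patches and the signal pass 3-D adaptive
    patches, deliberately different constructions so the two passes do not
    reuse the same linear subspaces.  The reported sigma map refers to the
    real channel (1/sqrt(2) of the complex-magnitude channel sigma).
    """
    phi_dn = estimate_smooth_phase(dwi, kernel=phase_kernel, stride=phase_stride)
    real = unwind_phase(dwi, phi_dn)
    res = denoise_magnitude(real, cfg=cfg, shrink=shrink, scale=scale)
    res.method = "complex"
    return res
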