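"""Core in-memory container for a diffusion-weighted series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DWISeries", "cluster_shells", "B0_TOLERANCE", "SHELL_TOLERANCE"]

# b-values within this of each other belong to one shell; b < B0_TOLERANCE is b=0
SHELL_TOLERANCE = 50.0
B0_TOLERANCE = 50.0


def cluster_shells(bvals: np.ndarray, tol: float = SHELL_TOLERANCE) -> np.ndarray:
    """Assign a representative shell b-value to every volume.

    b-values are grouped greedily in ascending order: a new shell starts when
    the gap to the previous value exceeds ``tol``.  Values below ``tol`` map
    to shell 0.  Returns an array of shell b-values (one per volume), where
    the representative is the rounded mean of the members.
    """
    b = np.asarray(bvals, dtype=float)
    order = np.argsort(b)
    shells = np.empty_like(b)
    start = 0
    bs = b[order]
    for i in range(1, b.size + 1):
        if i == b.size or bs[i] - bs[i - 1] > tol:
            rep = float(np.round(np.mean(bs[start:i])))
            if bs[start:i].max() < tol:
                rep = 0.0
            shells[order[start:i]] = rep
            start = i
    return shells


@dataclass
class DWISeries:
    """4-D diffusion-weighted signal with its gradient table.

    Attributes
    ----------
    signal : (X, Y, Z, M) ndarray
        Magnitude or real-valued signal in scanner units.
    bvals : (M,) ndarray, s/mm^2.
    bvecs : (M, 3) ndarray, unit gradient directions (arbitrary for b=0).
    phase : optional (X, Y, Z, M) ndarray, radians.
    voxel_size : mm triplet.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    phase: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (X, Y, Z, M)")
        m = self.signal.shape[3]
        if self.bvals.size != m:
            raise ValueError(f"bvals has {self.bvals.size} entries, image has {m} volumes")
        if self.bvecs.shape != (m, 3):
            raise ValueError("bvecs must have shape (M, 3)")
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if self.phase.shape != self.signal.shape:
                raise ValueError("phase must match the signal shape")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def shells(self) -> np.ndarray:
        """Representative shell b-value per volume."""
        return cluster_shells(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shells == 0.0

    def shell_mask(self, b: float, tol: float = SHELL_TOLERANCE) -> np.ndarray:
        return np.abs(self.shells - b) <= tol

    def subset(self, mask: np.ndarray) -> "DWISeries":
        """New series restricted to the volumes selected by ``mask``."""
        mask = np.asarray(mask)
        return replace(
            self,
            signal=self.signal[..., mask],
            bvals=self.bvals[mask],
            bvecs=self.bvecs[mask],
            phase=None if self.phase is None else self.phase[..., mask],
        )

    def complex_signal(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("series has no phase; complex data unavailable")
        return self.signal * np.exp(1j * self.phase)
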