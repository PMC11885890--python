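"""Adaptive, anatomy-shaped patch selection.

Instead of a fixed cube around each voxel, the N voxels entering a patch
matrix are chosen inside a bounding box by the joint space/signal distance

    w(r, r0) = |r - r0|^alpha * ||S(r) - S(r0)||^beta

(Euclidean norms over 3-D space and over the M measurements).  With beta >
alpha the selection prefers voxels whose signals resemble the center voxel,
so the noise-free patch matrix stays closer to low rank.  With beta = 0 the
rule degenerates to the classical nearest-neighbour cubic patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchConfig", "Patch", "signal_distance", "select_adaptive_patch"]


@dataclass(frozen=True)
class PatchConfig:
    """Patch-selection parameters.

    alpha, beta : spatial and signal exponents (defaults 1 and 2).
    box_radius : half-width of the cubic bounding box (default 3, a 7x7x7 box).
    n_select : voxels kept per patch (default 100).
    """

    alpha: float = 1.0
    beta: float = 2.0
    box_radius: int = 3
    n_select: int = 100

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.box_radius < 1:
            raise ValueError("box_radius must be >= 1")
        side = 2 * self.box_radius + 1
        if not (1 <= self.n_select <= side**3):
            raise ValueError("n_select must be in [1, box voxel count]")


@dataclass(frozen=True)
class Patch:
    center: tuple[int, int, int]
    members: np.ndarray      # (n, 3) voxel indices, selection order
    weights: np.ndarray      # (n,) the w values, non-decreasing


def signal_distance(r: np.ndarray, r0: np.ndarray, s_r: np.ndarray,
                    s_r0: np.ndarray, cfg: PatchConfig) -> float:
    """Joint space/signal distance between one voxel and the patch center."""
    s_r = np.asarray(s_r, dtype=float)
    s_r0 = np.asarray(s_r0, dtype=float)
    if s_r.shape != s_r0.shape:
        raise ValueError("signal vectors must have the same length")
    dr = np.linalg.norm(np.asarray(r, dtype=float) - np.asarray(r0, dtype=float))
    ds = np.linalg.norm(s_r - s_r0)
    return float(dr**cfg.alpha * ds**cfg.beta)


def select_adaptive_patch(volume4d: np.ndarray, r0: tuple[int, int, int],
                          cfg: PatchConfig) -> Patch:
    """Pick the ``n_select`` most similar voxels inside the clipped box.

    The bounding box is clipped at the volume boundary (never padded), and
    ties in ``w`` are broken by spatial distance then lexicographic index so
    the selection is deterministic.  The center voxel has ``w = 0`` and is
    always included.
    """
    vol = np.asarray(volume4d)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D volume (X, Y, Z, M)")
    if min(vol.shape[:3]) < 2:
        raise ValueError("volume must be at least 2x2x2")
    x0, y0, z0 = (int(c) for c in r0)
    shape = vol.shape[:3]
    if not (0 <= x0 < shape[0] and 0 <= y0 < shape[1] and 0 <= z0 < shape[2]):
        raise ValueError("center voxel outside the volume")

    R = cfg.box_radius
    xs = slice(max(x0 - R, 0), min(x0 + R + 1, shape[0]))
    ys = slice(max(y0 - R, 0), min(y0 + R + 1, shape[1]))
    zs = slice(max(z0 - R, 0), min(z0 + R + 1, shape[2]))
    sub = vol[xs, ys, zs]                       # (bx, by, bz, M)
    bx, by, bz = sub.shape[:3]

    gx, gy, gz = np.meshgrid(np.arange(xs.start, xs.stop),
                             np.arange(ys.start, ys.stop),
                             np.arange(zs.start, zs.stop), indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    sig = sub.reshape(bx * by * bz, -1).astype(float)
    s0 = vol[x0, y0, z0].astype(float)
    ds2 = np.sum((sig - s0) ** 2, axis=1)
    dr2 = np.sum((coords - np.array([x0, y0, z0])) ** 2, axis=1).astype(float)
    w = dr2 ** (cfg.alpha / 2.0) * ds2 ** (cfg.beta / 2.0)

    lex = (coords[:, 2] + shape[2] * (coords[:, 1] + shape[1] * coords[:, 0]))
    order = np.lexsort((lex, dr2, w))
    n = min(cfg.n_select, coords.shape[0])
    sel = order[:n]
    return Patch(center=(x0, y0, z0), members=coords[sel], weights=w[sel])
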