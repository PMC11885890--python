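import numpy as np
import pytest

from mpdwi import (DWISeries, PhantomSpec, denoise_magnitude, make_phantom,
                   simulate_scan_rescan)

# Phantom sizes are reduced from the 40x40x12 default to keep the suite fast
# while preserving the features the assertions need (an interior homogeneous
# WM slab of >= 1000 voxels for the scan-rescan pair, all four tissue types).


@pytest.fixture(scope="session")
def phantom_small():
    """Noiseless multi-shell phantom on a small grid (exact model member)."""
    return make_phantom(PhantomSpec(grid=(14, 14, 8)), "P92")


@pytest.fixture(scope="session")
def scan_rescan_pair():
    """Seeded scan-rescan pair: b0-SNR 13, smooth phase, 1080-voxel WM slab."""
    spec = PhantomSpec(grid=(24, 24, 10), snr_b0=13.0)
    phantom, repeats = simulate_scan_rescan(spec, "P92", n_repeats=2, seed=1)
    return phantom, repeats


@pytest.fixture(scope="session")
def denoised_pair(scan_rescan_pair):
    """Magnitude-MPPCA denoised version of the scan-rescan pair."""
    _, repeats = scan_rescan_pair
    out = []
    for rep in repeats:
        res = denoise_magnitude(rep)
        out.append((res, DWISeries(signal=res.denoised, bvals=rep.bvals,
                                   bvecs=rep.bvecs)))
    return out


def rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from the QR decomposition of a Gaussian."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
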