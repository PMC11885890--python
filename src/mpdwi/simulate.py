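"""Synthetic multi-shell scan-rescan phantoms with known ground truth.

The generator emulates a two-shell clinical brain protocol (b = 0, 1000,
2000 s/mm^2) on a block phantom containing a large homogeneous
single-fiber white-matter region, a fiber-crossing region, a gray-matter
region, and a CSF region whose isotropic diffusivity of 3 um^2/ms leaves
essentially no signal (~e^-6 of S0) at b = 2000 — the zero-signal pool used
for Rayleigh noise-floor estimation.  Signals follow the DKI cumulant model
exactly, so a noiseless phantom is an exact member of the fitted model and
the generating tensors are recoverable to numerical precision.

Noise is additive complex Gaussian: independent per-channel deviates on the
real and imaginary parts of S * exp(i phi), with a smooth per-volume
quadratic phase across each slice emulating shot-to-shot phase variation.
The stored magnitude is then Rician-distributed, with the b0 white-matter
SNR set by ``snr_b0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .dki import TensorFitResult, dti_metrics, kurtosis_metrics_W, kt_to_tensor
from .series import DWISeries

__all__ = [
    "ProtocolSpec",
    "PhantomSpec",
    "Phantom",
    "get_protocol",
    "make_phantom",
    "add_complex_noise",
    "simulate_scan_rescan",
]

PROTOCOLS = {
    # name -> list of (b-value s/mm^2, n directions)
    "P92": [(0.0, 5), (1000.0, 20), (2000.0, 40)],
    "P127": [(0.0, 5), (1000.0, 15), (2000.0, 30)],
    "S127": [(0.0, 5), (1000.0, 15), (2000.0, 30)],
}


def _load_directions(n: int) -> np.ndarray:
    """Fixed electrostatic-repulsion direction set shipped with the package."""
    ref = resources.files("mpdwi.data").joinpath(f"dirs{n:03d}.txt")
    with ref.open("r") as fh:
        return np.loadtxt(fh)


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition protocol: shells and their gradient directions."""

    name: str
    bvals: np.ndarray
    bvecs: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.bvals.size


def get_protocol(name: str) -> ProtocolSpec:
    if name not in PROTOCOLS:
        raise ValueError(f"unknown protocol {name!r}; options: {sorted(PROTOCOLS)}")
    bvals, bvecs = [], []
    for b, n in PROTOCOLS[name]:
        if b == 0:
            bvals.extend([0.0] * n)
            bvecs.append(np.zeros((n, 3)))
        else:
            bvals.extend([b] * n)
            bvecs.append(_load_directions(n))
    return ProtocolSpec(name=name, bvals=np.array(bvals),
                        bvecs=np.concatenate(bvecs, axis=0))


# ground-truth tensors ------------------------------------------------------


def _axial_kt(aw: float, rw: float, mw: float) -> np.ndarray:
    """Axially-symmetric (about z) kurtosis tensor with the given metrics."""
    kt = np.zeros(15)
    kt[2] = aw                       # Wzzzz = W(z) = AW
    kt[0] = kt[1] = rw               # transverse isotropy: Wxxxx = Wyyyy = RW
    kt[9] = rw / 3.0                 # Wxxyy
    # remaining trace freedom: MW = (Wxxxx+Wyyyy+Wzzzz + 2(Wxxyy+Wxxzz+Wyyzz))/5
    wxxzz = (5.0 * mw - 2.0 * rw - aw - 2.0 * rw / 3.0) / 4.0
    kt[10] = kt[11] = wxxzz
    return kt


def _iso_kt(w0: float) -> np.ndarray:
    """Isotropic kurtosis tensor: W(n) = w0 in every direction."""
    kt = np.zeros(15)
    kt[0] = kt[1] = kt[2] = w0
    kt[9] = kt[10] = kt[11] = w0 / 3.0
    return kt


def _rotate_kt(kt: np.ndarray, R: np.ndarray) -> np.ndarray:
    from .dki import KT_IDX
    W = kt_to_tensor(kt)
    Wr = np.einsum("ai,bj,ck,dl,ijkl->abcd", R, R, R, R, W)
    return np.array([Wr[idx] for idx in KT_IDX])


_ROT_ZX = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
_ROT_ZY = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])

# region label -> (S0, dt6 [um^2/ms], kt15)
_WM_KT = _axial_kt(aw=0.6, rw=1.3, mw=0.9)
# 60/40 crossing keeps the principal eigenvalue non-degenerate so the
# ground-truth axial/radial projections are well defined
_CROSS_DT = 0.6 * np.array([2.0, 0.5, 0.5, 0, 0, 0.0]) \
    + 0.4 * np.array([0.5, 2.0, 0.5, 0, 0, 0.0])
_CROSS_KT = 0.6 * _rotate_kt(_WM_KT, _ROT_ZX) + 0.4 * _rotate_kt(_WM_KT, _ROT_ZY)

REGION_PARAMS = {
    "wm": (1000.0, np.array([0.5, 0.5, 2.0, 0, 0, 0.0]), _WM_KT),
    "wm_crossing": (1000.0, _CROSS_DT, _CROSS_KT),
    "gm": (1000.0, np.array([0.8, 0.8, 0.8, 0, 0, 0.0]), _iso_kt(0.6)),
    "csf": (1000.0, np.array([3.0, 3.0, 3.0, 0, 0, 0.0]), np.zeros(15)),
}
REGION_LABELS = {"background": 0, "wm": 1, "wm_crossing": 2, "gm": 3, "csf": 4}


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry and acquisition conditions.

    grid : 3-D dimensions; a 2-voxel air border surrounds the tissue block
    and the interior is split along x into WM-fiber (45%), WM-crossing
    (15%), GM (20%) and CSF (20%) slabs.  The default grid leaves a
    homogeneous single-fiber WM region of several thousand voxels.
    snr_b0 : target b=0 SNR in WM (per-channel noise sigma = S0_wm/snr_b0).
    phase_amp : scale (radians) of the random smooth per-volume phase.
    """

    grid: tuple[int, int, int] = (40, 40, 12)
    snr_b0: float = 13.1
    phase_amp: float = 1.0
    border: int = 2
    fractions: tuple[float, float, float] = (0.45, 0.15, 0.20)  # wm, crossing, gm

    def __post_init__(self) -> None:
        if min(self.grid) <= 2 * self.border:
            raise ValueError("grid too small for the air border")
        if self.snr_b0 <= 0:
            raise ValueError("snr_b0 must be > 0")


@dataclass
class Phantom:
    """Noiseless series plus labels, region masks and true parameter maps."""

    series: DWISeries
    labels: np.ndarray
    masks: dict[str, np.ndarray]
    truth: dict[str, np.ndarray]
    spec: PhantomSpec
    protocol: ProtocolSpec
    truth_fit: TensorFitResult = field(repr=False, default=None)


def _region_labels(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = spec.grid
    b = spec.border
    labels = np.zeros(spec.grid, dtype=int)
    xw = X - 2 * b
    f_wm, f_cross, f_gm = spec.fractions
    e1 = b + int(round(f_wm * xw))
    e2 = e1 + int(round(f_cross * xw))
    e3 = e2 + int(round(f_gm * xw))
    labels[b:e1, b:Y - b, b:Z - b] = REGION_LABELS["wm"]
    labels[e1:e2, b:Y - b, b:Z - b] = REGION_LABELS["wm_crossing"]
    labels[e2:e3, b:Y - b, b:Z - b] = REGION_LABELS["gm"]
    labels[e3:X - b, b:Y - b, b:Z - b] = REGION_LABELS["csf"]
    return labels


def make_phantom(spec: PhantomSpec | None = None,
                 protocol: ProtocolSpec | str = "P92") -> Phantom:
    """Build the noiseless phantom and its analytic ground-truth maps."""
    spec = spec or PhantomSpec()
    if isinstance(protocol, str):
        protocol = get_protocol(protocol)
    labels = _region_labels(spec)
    X, Y, Z = spec.grid
    M = protocol.n_volumes

    from .dki import quadratic_form_design, quartic_form_design
    b = protocol.bvals / 1000.0                     # ms/um^2
    Dn_design = quadratic_form_design(protocol.bvecs)   # (M, 6)
    Wn_design = quartic_form_design(protocol.bvecs)     # (M, 15)

    signal = np.zeros((X, Y, Z, M))
    s0_map = np.zeros((X, Y, Z))
    dt_map = np.zeros((X, Y, Z, 6))
    kt_map = np.zeros((X, Y, Z, 15))
    for name, lab in REGION_LABELS.items():
        if name == "background":
            continue
        s0, dt6, kt15 = REGION_PARAMS[name]
        if s0 < 0:
            raise ValueError("unphysical region: negative S0")
        Dn = Dn_design @ dt6
        Wn = Wn_design @ kt15
        md = np.mean(dt6[:3])
        s = s0 * np.exp(-b * Dn + (b**2 / 6.0) * md**2 * Wn)
        m = labels == lab
        signal[m] = s
        s0_map[m] = s0
        dt_map[m] = dt6
        kt_map[m] = kt15

    series = DWISeries(signal=signal, bvals=protocol.bvals,
                       bvecs=protocol.bvecs)
    masks = {name: labels == lab for name, lab in REGION_LABELS.items()}
    truth_fit = TensorFitResult(s0=s0_map, dt=dt_map, kt=kt_map,
                                valid=labels > 0)
    truth = dti_metrics(truth_fit)
    truth.update(kurtosis_metrics_W(truth_fit))
    return Phantom(series=series, labels=labels, masks=masks, truth=truth,
                   spec=spec, protocol=protocol, truth_fit=truth_fit)


def _smooth_phase(shape: tuple[int, int, int], m: int, amp: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-volume, per-slice random 2-D quadratic phase (radians)."""
    X, Y, Z = shape
    u = np.linspace(-1.0, 1.0, X)[:, None]
    v = np.linspace(-1.0, 1.0, Y)[None, :]
    basis = np.stack([np.ones((X, Y)), u * np.ones_like(v),
                      v * np.ones_like(u), u**2 * np.ones_like(v),
                      u * v, v**2 * np.ones_like(u)], axis=-1)  # (X, Y, 6)
    coef = rng.normal(0.0, amp, size=(Z, m, 6))
    coef[:, :, 0] = rng.uniform(-np.pi, np.pi, size=(Z, m))
    return np.einsum("xyc,zmc->xyzm", basis, coef)


def add_complex_noise(series: DWISeries, snr_b0: float = 13.1,
                      phase_amp: float = 1.0,
                      seed: int | np.random.SeedSequence = 0,
                      s0_ref: float | None = None) -> DWISeries:
    """Add smooth phase and complex Gaussian noise; return magnitude+phase.

    Per-channel noise sigma is ``s0_ref / snr_b0`` with ``s0_ref`` the
    reference b=0 tissue signal (the phantom's S0 = 1000 by default).  With
    snr_b0 = inf the output equals the noiseless input with the clean phase.
    """
    if snr_b0 <= 0:
        raise ValueError("snr_b0 must be > 0")
    rng = np.random.default_rng(seed)
    shape = series.signal.shape
    phi = _smooth_phase(shape[:3], shape[3], phase_amp, rng)
    cplx = series.signal * np.exp(1j * phi)
    if np.isfinite(snr_b0):
        if s0_ref is None:
            s0_ref = float(np.max(series.signal))
        sigma = s0_ref / snr_b0
        cplx = cplx + sigma * (rng.standard_normal(shape)
                               + 1j * rng.standard_normal(shape))
    return DWISeries(signal=np.abs(cplx), bvals=series.bvals,
                     bvecs=series.bvecs, phase=np.angle(cplx),
                     voxel_size=series.voxel_size, affine=series.affine)


def simulate_scan_rescan(spec: PhantomSpec | None = None,
                         protocol: ProtocolSpec | str = "P92",
                         n_repeats: int = 2,
                         seed: int = 0) -> tuple[Phantom, list[DWISeries]]:
    """Scan-rescan series: shared ground truth, independent noise and phase.

    Per-repeat seeds are derived deterministically from the master seed, so
    the whole experiment is reproducible from ``(spec, protocol, seed)``.
    """
    if n_repeats < 2:
        raise ValueError("need n_repeats >= 2")
    spec = spec or PhantomSpec()
    phantom = make_phantom(spec, protocol)
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    repeats = [add_complex_noise(phantom.series, snr_b0=spec.snr_b0,
                                 phase_amp=spec.phase_amp, seed=c)
               for c in children]
    return phantom, repeats
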