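"""Forward model and per-pixel fit for polarization-dependent imaging contrast.

X-ray linear dichroism of apatite makes the ratio image at linear
polarization angle ``chi`` depend on the local c-axis orientation through
a Malus-law response

    R(chi) = A + B * cos^2(gamma) * cos^2(chi - c')

with a dimensionless baseline ``A`` and calibration amplitude ``B``.
A polarization series (19 angles, 0..90 in 5-degree steps) therefore
carries enough information to recover the orientation at every pixel:
rewriting the response as a second harmonic in chi,

    R(chi) = m0 + m1*cos(2*chi) + m2*sin(2*chi),

gives c' = atan2(m2, m1)/2 and an amplitude sqrt(m1^2 + m2^2)
= B*cos^2(gamma)/2 from which gamma follows.  The fit is an exact linear
least-squares problem -- no iteration, no initialization sensitivity.

Organic sheath pixels are non-dichroic: their ratio series is flat, the
fitted amplitude falls below the mask threshold, and they are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import fold_c_prime

__all__ = [
    "DichroismParams",
    "PolarizationStack",
    "PICMap",
    "default_polarization_angles",
    "dichroic_ratio",
    "simulate_stack",
    "fit_pixel",
    "build_pic_map",
]


def default_polarization_angles() -> np.ndarray:
    """The standard acquisition series: 0, 5, ..., 90 degrees (19 angles)."""
    return np.arange(0.0, 95.0, 5.0)


@dataclass(frozen=True)
class DichroismParams:
    """Calibration of the dichroic response.

    baseline_a : ratio value with no dichroic modulation (> 0).
    amplitude_b : full modulation depth for an in-plane axis (> 0).
    noise_sigma : relative sd of multiplicative Gaussian noise on ratios.
    mask_amplitude_threshold : fraction of the full second-harmonic
        amplitude (B/2) below which a fitted pixel is rejected as
        non-dichroic (sheath / axis along the beam).
    """

    baseline_a: float = 1.0
    amplitude_b: float = 1.0
    noise_sigma: float = 0.0
    mask_amplitude_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_a <= 0 or self.amplitude_b <= 0:
            raise ValueError("baseline_a and amplitude_b must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 < self.mask_amplitude_threshold < 1.0):
            raise ValueError("mask_amplitude_threshold must lie in (0, 1)")


@dataclass
class PICMap:
    """Per-pixel c-axis orientation field with validity mask.

    c_prime_deg, gamma_deg : 2D float arrays (degrees).
    mask : 2D bool array; True = dichroic mineral pixel with a valid
        orientation, False = organic sheath / rejected fit.
    pixel_size_nm : physical pixel size (60 nm for survey maps, 22 nm for
        the high-resolution ones).
    residual_rms : optional per-pixel fit residual plane (QC).
    """

    c_prime_deg: np.ndarray
    gamma_deg: np.ndarray
    mask: np.ndarray
    pixel_size_nm: float = 60.0
    residual_rms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c_prime_deg = np.asarray(self.c_prime_deg, dtype=float)
        self.gamma_deg = np.asarray(self.gamma_deg, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.c_prime_deg.shape == self.gamma_deg.shape == self.mask.shape):
            raise ValueError("c_prime_deg, gamma_deg and mask must be congruent")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.c_prime_deg.shape


@dataclass
class PolarizationStack:
    """A stack of ratio images, one per polarization angle."""

    angles_deg: np.ndarray
    ratio_images: np.ndarray  # (n_angles, H, W), strictly positive
    pixel_size_nm: float = 60.0

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.ratio_images = np.asarray(self.ratio_images, dtype=float)
        if self.ratio_images.ndim != 3 or self.ratio_images.shape[0] != len(self.angles_deg):
            raise ValueError("need exactly one image per polarization angle")
        if np.any(self.ratio_images <= 0):
            raise ValueError("ratio values must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratio_images.shape[1:]


def dichroic_ratio(chi_deg, c_prime_deg, gamma_deg, params: DichroismParams):
    """Noise-free dichroic ratio at polarization angle ``chi_deg``.

    Period 180 degrees in chi; independent of chi when gamma = 90 (axis
    along the beam, no dichroism).  Broadcasts over array inputs.
    """
    chi = np.deg2rad(np.asarray(chi_deg, dtype=float))
    cp = np.deg2rad(np.asarray(c_prime_deg, dtype=float))
    g = np.deg2rad(np.asarray(gamma_deg, dtype=float))
    out = params.baseline_a + params.amplitude_b * np.cos(g) ** 2 * np.cos(chi - cp) ** 2
    return float(out) if np.ndim(out) == 0 else out


def simulate_stack(
    pic_map: PICMap,
    params: DichroismParams,
    seed: int | None = None,
    angles_deg: np.ndarray | None = None,
) -> PolarizationStack:
    """Forward-simulate a polarization ratio stack from an orientation field.

    Each pixel's noiseless response is multiplied by (1 + eps) with
    eps ~ Normal(0, noise_sigma), seeded and reproducible.  Masked pixels
    are non-dichroic and emit the flat baseline ``A`` (plus noise).
    """
    if angles_deg is None:
        angles_deg = default_polarization_angles()
    angles_deg = np.asarray(angles_deg, dtype=float)
    chi = angles_deg[:, None, None]
    clean = dichroic_ratio(chi, pic_map.c_prime_deg[None], pic_map.gamma_deg[None], params)
    clean = np.where(pic_map.mask[None], clean, params.baseline_a)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + rng.normal(0.0, params.noise_sigma, size=clean.shape))
    return PolarizationStack(angles_deg, clean, pic_map.pixel_size_nm)


def _harmonic_coeffs(values: np.ndarray, angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve R(chi) = m0 + m1 cos2chi + m2 sin2chi by linear least squares.

    values : (n_angles, ...) ratio data.  Returns (coeffs (3, ...), rms (...)).
    """
    two_chi = 2.0 * np.deg2rad(angles_deg)
    design = np.column_stack([np.ones_like(two_chi), np.cos(two_chi), np.sin(two_chi)])
    flat = values.reshape(values.shape[0], -1)
    coeffs, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ coeffs
    rms = np.sqrt(np.mean(resid**2, axis=0))
    tail = values.shape[1:]
    return coeffs.reshape((3,) + tail), rms.reshape(tail)


def fit_pixel(
    values,
    angles_deg,
    params: DichroismParams,
    *,
    calibration_rtol: float = 1e-3,
):
    """Fit one pixel's polarization series.

    Returns ``(c_prime_deg, gamma_deg, amplitude, residual_rms, valid)``.
    ``valid`` is False when the fitted second-harmonic amplitude falls
    below ``mask_amplitude_threshold * B/2`` (non-dichroic pixel).  An
    amplitude exceeding the calibrated maximum B/2 beyond tolerance raises,
    as it indicates a wrong calibration constant.
    """
    values = np.asarray(values, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if values.shape[0] != angles_deg.shape[0] or values.shape[0] < 3:
        raise ValueError("need at least 3 samples with matching angles")
    coeffs, rms = _harmonic_coeffs(values[:, None], angles_deg)
    m0, m1, m2 = (float(c[0]) for c in coeffs)
    amplitude = float(np.hypot(m1, m2))
    half_b = params.amplitude_b / 2.0
    # under multiplicative noise the fitted amplitude fluctuates above B/2
    calibration_rtol = max(calibration_rtol, 20.0 * params.noise_sigma)
    if amplitude > half_b * (1.0 + calibration_rtol):
        raise ValueError(
            f"fitted amplitude {amplitude:.4g} exceeds calibration B/2 = {half_b:.4g}"
        )
    if amplitude < params.mask_amplitude_threshold * half_b:
        return np.nan, np.nan, amplitude, float(rms[0]), False
    c_prime = fold_c_prime(np.degrees(0.5 * np.arctan2(m2, m1)))
    cos_g = np.sqrt(np.clip(amplitude / half_b, 0.0, 1.0))
    gamma = float(np.degrees(np.arccos(cos_g)))
    return float(c_prime), gamma, amplitude, float(rms[0]), True


def build_pic_map(
    stack: PolarizationStack,
    params: DichroismParams,
    *,
    calibration_rtol: float = 1e-3,
) -> PICMap:
    """Fit every pixel of a polarization stack into a PIC map.

    Vectorised version of :func:`fit_pixel`; rejected pixels are masked and
    carry nan angles.  The per-pixel residual RMS is attached for QC.
    """
    coeffs, rms = _harmonic_coeffs(stack.ratio_images, stack.angles_deg)
    m1, m2 = coeffs[1], coeffs[2]
    amplitude = np.hypot(m1, m2)
    half_b = params.amplitude_b / 2.0
    calibration_rtol = max(calibration_rtol, 20.0 * params.noise_sigma)
    if np.any(amplitude > half_b * (1.0 + calibration_rtol)):
        raise ValueError("fitted amplitude exceeds calibration B/2: wrong amplitude_b?")
    valid = amplitude >= params.mask_amplitude_threshold * half_b
    c_prime = fold_c_prime(np.degrees(0.5 * np.arctan2(m2, m1)))
    gamma = np.degrees(np.arccos(np.sqrt(np.clip(amplitude / half_b, 0.0, 1.0))))
    c_prime = np.where(valid, c_prime, np.nan)
    gamma = np.where(valid, gamma, np.nan)
    return PICMap(c_prime, gamma, valid, stack.pixel_size_nm, residual_rms=rms)
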