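"""Conversions between c-axis orientation angles, display colors, and directors.

The apatite c-axis is a *director*: an unsigned axis, so a direction and its
antipode encode the same physical orientation.  Per-pixel orientation is
parameterised by two angles:

``c_prime_deg``
    The in-polarization-plane component of the c-axis, measured from
    vertical, in ``[-90, +90)`` degrees.  Displayed as hue: cyan is a
    vertical axis (0 deg), green +30, yellow +60, blue -30, magenta -60.
``gamma_deg``
    The off-polarization-plane component in ``[0, 90]`` degrees.
    Displayed as brightness: full color is in-plane, black means the axis
    points straight into the beam (90 deg off-plane).

All public functions accept scalars or numpy arrays of degrees and
broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CAxisOrientation",
    "HSBColor",
    "angles_to_director",
    "angular_distance",
    "director_distance",
    "angles_to_hsb",
    "hsb_to_angles",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "fold_c_prime",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class CAxisOrientation:
    """A single c-axis orientation (in-plane angle c', off-plane angle gamma)."""

    c_prime_deg: float
    gamma_deg: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.c_prime_deg < 90.0):
            raise ValueError(f"c_prime_deg {self.c_prime_deg} outside [-90, 90)")
        if not (0.0 <= self.gamma_deg <= 90.0):
            raise ValueError(f"gamma_deg {self.gamma_deg} outside [0, 90]")

    def director(self) -> np.ndarray:
        return angles_to_director(self.c_prime_deg, self.gamma_deg)


@dataclass(frozen=True)
class HSBColor:
    """Hue/saturation/brightness color. Hue in degrees [0, 360); S, B in [0, 1]."""

    hue_deg: float
    saturation: float
    brightness: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_deg < 360.0):
            raise ValueError(f"hue_deg {self.hue_deg} outside [0, 360)")
        if not (0.0 <= self.saturation <= 1.0) or not (0.0 <= self.brightness <= 1.0):
            raise ValueError("saturation and brightness must lie in [0, 1]")


def fold_c_prime(c_prime_deg):
    """Fold an in-plane angle into the director range [-90, +90)."""
    return np.mod(np.asarray(c_prime_deg, dtype=float) + 90.0, 180.0) - 90.0


def angles_to_director(c_prime_deg, gamma_deg) -> np.ndarray:
    """Unit director (u, w, v) for orientation angles in degrees.

    Components: u = in-plane horizontal, w = off-plane toward the beam,
    v = in-plane vertical.  The result has unit norm; stacking axis is the
    last axis, so array inputs of shape ``s`` give shape ``s + (3,)``.
    """
    cp = np.deg2rad(np.asarray(c_prime_deg, dtype=float))
    g = np.deg2rad(np.asarray(gamma_deg, dtype=float))
    u = np.cos(g) * np.sin(cp)
    w = np.sin(g)
    v = np.cos(g) * np.cos(cp)
    return np.stack(np.broadcast_arrays(u, w, v), axis=-1)


def _check_unit(d: np.ndarray, tol: float) -> None:
    norms = np.linalg.norm(d, axis=-1)
    if not np.allclose(norms, 1.0, atol=tol):
        raise ValueError("director is not unit norm within tolerance")


def angular_distance(a, b, *, tol: float = 1e-6):
    """Angle in degrees between two directors, in [0, 90].

    Sign-invariant (d and -d are the same axis) and symmetric.  Inputs are
    (..., 3) arrays of unit vectors; raises ``ValueError`` if a norm
    deviates from 1 by more than ``tol``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_unit(a, tol)
    _check_unit(b, tol)
    dot = np.abs(np.sum(a * b, axis=-1))
    ang = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
    return float(ang) if np.ndim(ang) == 0 else ang


def director_distance(c_prime_a, gamma_a, c_prime_b, gamma_b):
    """Angular distance between orientations given directly as angle pairs."""
    return angular_distance(
        angles_to_director(c_prime_a, gamma_a),
        angles_to_director(c_prime_b, gamma_b),
    )


def angles_to_hsb(c_prime_deg, gamma_deg):
    """Encode orientation angles as (hue_deg, saturation, brightness).

    hue = (2 * (90 - c')) mod 360 -- the unique linear 180->360 degree wheel
    consistent with the printed legend (cyan 0, green +30, yellow +60,
    blue -30, magenta -60).  Brightness falls linearly with the off-plane
    angle: 1 - gamma/90, so a pixel with its axis along the beam is black.
    """
    cp = np.asarray(c_prime_deg, dtype=float)
    g = np.asarray(gamma_deg, dtype=float)
    hue = np.mod(2.0 * (90.0 - cp), 360.0)
    sat = np.ones_like(hue)
    bri = 1.0 - g / 90.0
    return hue, sat, bri


def hsb_to_angles(hue_deg, brightness):
    """Invert :func:`angles_to_hsb`.  Brightness 0 carries no orientation.

    Returns (c_prime_deg, gamma_deg).  For array input, pixels with
    brightness exactly 0 yield nan angles; a scalar brightness of 0 raises.
    """
    hue = np.asarray(hue_deg, dtype=float)
    bri = np.asarray(brightness, dtype=float)
    if np.ndim(bri) == 0 and bri == 0.0:
        raise ValueError("brightness 0: masked pixel, no orientation recoverable")
    cp = fold_c_prime(90.0 - hue / 2.0)
    g = 90.0 * (1.0 - bri)
    masked = bri == 0.0
    if np.any(masked):
        cp = np.where(masked, np.nan, cp)
        g = np.where(masked, np.nan, g)
    if np.ndim(cp) == 0:
        return float(cp), float(g)
    return cp, g


def rgb_to_hsb(rgb):
    """Standard hexcone RGB -> HSB on 8-bit channels.

    ``rgb`` is (..., 3) with channels in [0, 255].  Returns
    (hue_deg in [0, 360), saturation in [0, 1], brightness in [0, 1]).
    Hue of an achromatic pixel is reported as 0.
    """
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("RGB channels must lie in [0, 255]")
    r, g, b = rgb[..., 0] / 255.0, rgb[..., 1] / 255.0, rgb[..., 2] / 255.0
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
        rc = (maxc - r) / np.where(delta > 0, delta, 1.0)
        gc = (maxc - g) / np.where(delta > 0, delta, 1.0)
        bc = (maxc - b) / np.where(delta > 0, delta, 1.0)
    hue = np.where(
        delta == 0,
        0.0,
        np.where(
            maxc == r,
            bc - gc,
            np.where(maxc == g, 2.0 + rc - bc, 4.0 + gc - rc),
        ),
    )
    hue = np.mod(hue * 60.0, 360.0)
    if np.ndim(hue) == 0:
        return float(hue), float(sat), float(maxc)
    return hue, sat, maxc


def hsb_to_rgb(hue_deg, saturation, brightness):
    """Standard hexcone HSB -> 8-bit RGB; inverse of :func:`rgb_to_hsb`.

    Round trips within the 1-unit channel quantization.  Returns a (..., 3)
    uint8 array (or a length-3 array for scalar input).
    """
    h = np.asarray(hue_deg, dtype=float)
    s = np.asarray(saturation, dtype=float)
    v = np.asarray(brightness, dtype=float)
    if np.any(h < 0) or np.any(h >= 360) or np.any(s < 0) or np.any(s > 1) or np.any(v < 0) or np.any(v > 1):
        raise ValueError("HSB components out of range")
    h6 = h / 60.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack(np.broadcast_arrays(r, g, b), axis=-1)
    return np.round(rgb * 255.0).astype(np.uint8)
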