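"""Fracture and elasticity calculations for apatite bi-crystals.

Covers the analysis mathematics around bi-crystal fracture simulations:

* fracture energy (critical energy release rate G_c) by integrating a
  stress-strain curve and normalising by the gauge length, and its
  conversion to mode-I toughness K_IC = sqrt(G_c * E) (plane stress);
* the discrete mis-orientation angles theta that keep a bi-crystal
  interface periodic along z, l_x * sin(theta) = a_z * n, with the apatite
  lattice length a_z = 6.86 Angstrom;
* hexagonal elastic stiffness tensors in contracted (Voigt) notation and
  their rotation about the out-of-plane y-axis (Bond transformation), used
  to assign per-layer properties in layered crack models;
* exponential fits to crack-tip strain profiles; and the mastication
  pressure estimate (chewing force over cusp area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StressStrainCurve",
    "ElasticTensor",
    "BiCrystalGeometry",
    "StrainProfileFit",
    "StrainFitError",
    "A_Z_ANGSTROM",
    "critical_energy_release_rate",
    "fracture_toughness",
    "periodic_misorientation_angle",
    "infer_lx",
    "hexagonal_tensor",
    "rotation_matrix_y",
    "bond_matrix",
    "rotate_elastic_tensor",
    "layer_tensors",
    "fit_strain_profile",
    "mastication_pressure",
]

#: Hydroxyapatite lattice length along z, in Angstrom.
A_Z_ANGSTROM = 6.86


@dataclass
class StressStrainCurve:
    """A tensile stress-strain record: strain (ascending), stress in GPa,
    and the specimen gauge length along the loading axis in nm."""

    strain: np.ndarray
    stress_gpa: np.ndarray
    gauge_length_nm: float

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_gpa = np.asarray(self.stress_gpa, dtype=float)
        if self.strain.shape != self.stress_gpa.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be 1D arrays of equal length")
        if self.strain[0] < 0 or np.any(np.diff(self.strain) < 0):
            raise ValueError("strain must be ascending and start at >= 0")
        if self.gauge_length_nm <= 0:
            raise ValueError("gauge_length_nm must be positive")


@dataclass(frozen=True)
class ElasticTensor:
    """6x6 symmetric stiffness matrix in contracted (Voigt) notation, GPa.

    Voigt order 11, 22, 33, 23, 13, 12.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (6, 6):
            raise ValueError("stiffness matrix must be 6x6")
        if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
            raise ValueError("stiffness matrix must be symmetric")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    def is_positive_definite(self) -> bool:
        return bool(np.all(np.linalg.eigvalsh(self.matrix) > 0))


@dataclass(frozen=True)
class BiCrystalGeometry:
    """Bi-crystal periodicity geometry: crystal length l_x and lattice
    length a_z (both Angstrom), plus the top-crystal mis-orientation."""

    l_x_angstrom: float
    a_z_angstrom: float = A_Z_ANGSTROM
    theta_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.l_x_angstrom <= 0 or self.a_z_angstrom <= 0:
            raise ValueError("lengths must be positive")
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError("theta_deg must lie in [0, 90]")


@dataclass(frozen=True)
class StrainProfileFit:
    """Parameters of strain(y) = p * exp(-q * y) + r and the fit residual."""

    p: float
    q: float  # 1/nm
    r: float
    residual_rms: float


class StrainFitError(RuntimeError):
    """Raised when the exponential strain-profile fit fails to converge."""


def critical_energy_release_rate(curve: StressStrainCurve, eps_max: float = 0.2) -> float:
    """Fracture energy G_c in J/m^2 from a stress-strain curve.

    G_c = L_z * integral_0^eps_max sigma d(eps), trapezoidal, i.e. the
    external work to break the specimen per unit created crack area when
    the crack spans the full cross-section (1 GPa*nm = 1 J/m^2).  The
    curve must cover [0, eps_max]; stress is linearly interpolated at the
    upper limit.
    """
    eps, sig = curve.strain, curve.stress_gpa
    if eps[-1] < eps_max:
        raise ValueError(f"curve ends at strain {eps[-1]}, below eps_max={eps_max}")
    sig_end = np.interp(eps_max, eps, sig)
    keep = eps < eps_max
    e = np.append(eps[keep], eps_max)
    s = np.append(sig[keep], sig_end)
    work_gpa = np.trapezoid(s, e)
    return float(curve.gauge_length_nm * work_gpa)  # GPa*nm == J/m^2


def fracture_toughness(g_c_j_m2: float, youngs_modulus_pa: float = 133.3e9) -> float:
    """Mode-I toughness K_IC in MPa*m^0.5 from G_c (J/m^2) and E (Pa).

    Plane-stress relation K = sqrt(G * E); with the default apatite modulus
    E = 133.3 GPa, G_c = 5.87 J/m^2 gives 0.88 MPa*m^0.5.
    """
    if g_c_j_m2 < 0 or youngs_modulus_pa <= 0:
        raise ValueError("G_c must be >= 0 and E > 0")
    return float(np.sqrt(g_c_j_m2 * youngs_modulus_pa) / 1e6)


def periodic_misorientation_angle(g: BiCrystalGeometry, n: int) -> float:
    """Mis-orientation angle (degrees) keeping the interface z-periodic.

    Solves l_x * sin(theta) = a_z * n for theta; only discrete angles admit
    a periodic bi-crystal, which is why the simulations use 14.1, 29.2 and
    47.0 degrees.  Raises when n * a_z exceeds l_x (no solution).
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    s = n * g.a_z_angstrom / g.l_x_angstrom
    if s > 1.0:
        raise ValueError(f"n*a_z = {n * g.a_z_angstrom} exceeds l_x = {g.l_x_angstrom}: no periodic solution")
    return float(np.degrees(np.arcsin(s)))


def infer_lx(theta_deg: float, n: int = 1, a_z_angstrom: float = A_Z_ANGSTROM) -> float:
    """Crystal length l_x (Angstrom) implied by a known periodic angle."""
    if not (0.0 < theta_deg <= 90.0):
        raise ValueError("theta_deg must lie in (0, 90]")
    return float(n * a_z_angstrom / np.sin(np.radians(theta_deg)))


def hexagonal_tensor(c11: float, c12: float, c13: float, c33: float, c44: float) -> ElasticTensor:
    """Hexagonal stiffness matrix (unique axis 3) from its five constants.

    C22 = C11, C23 = C13, C55 = C44 and C66 = (C11 - C12)/2 by symmetry.
    Rejects constants that do not give a positive-definite matrix.
    """
    c66 = (c11 - c12) / 2.0
    m = np.array(
        [
            [c11, c12, c13, 0, 0, 0],
            [c12, c11, c13, 0, 0, 0],
            [c13, c13, c33, 0, 0, 0],
            [0, 0, 0, c44, 0, 0],
            [0, 0, 0, 0, c44, 0],
            [0, 0, 0, 0, 0, c66],
        ],
        dtype=float,
    )
    t = ElasticTensor(m)
    if not t.is_positive_definite():
        raise ValueError("elastic constants do not give a positive-definite stiffness")
    return t


def rotation_matrix_y(theta_deg: float) -> np.ndarray:
    """Right-handed rotation about the out-of-plane y-axis."""
    c, s = np.cos(np.radians(theta_deg)), np.sin(np.radians(theta_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def bond_matrix(r: np.ndarray) -> np.ndarray:
    """6x6 Bond stress-transformation matrix for a 3x3 rotation ``r``.

    With Voigt order (11, 22, 33, 23, 13, 12), a stiffness transforms as
    C' = M C M^T.
    """
    m = np.empty((6, 6))
    idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    for a, (i, j) in enumerate(idx):
        for b, (k, l) in enumerate(idx):
            if b < 3:
                m[a, b] = r[i, k] * r[j, k]
            else:
                m[a, b] = r[i, k] * r[j, l] + r[i, l] * r[j, k]
    return m


def rotate_elastic_tensor(c: ElasticTensor, theta_deg: float) -> ElasticTensor:
    """Rotate a stiffness tensor about the y-axis by ``theta_deg``.

    Contracted-notation congruence (Bond) transform, C' = M C M^T; exactly
    equivalent to the full 4th-order transformation
    C'_ijkl = R_ia R_jb R_kc R_ld C_abcd.  Symmetry and the eigenvalue
    spectrum (hence strain energy) are preserved.
    """
    m = bond_matrix(rotation_matrix_y(theta_deg))
    out = m @ c.matrix @ m.T
    return ElasticTensor((out + out.T) / 2.0)


def layer_tensors(c0: ElasticTensor, delta_theta_deg: float, n_layers: int = 10) -> list[ElasticTensor]:
    """Per-layer stiffnesses for a layered model: layer i rotated by i*delta.

    Emulates assigning each of the (default 10) layers its own orientation,
    theta_i = i * delta_theta.
    """
    return [rotate_elastic_tensor(c0, i * delta_theta_deg) for i in range(n_layers)]


def fit_strain_profile(y_nm, strain) -> StrainProfileFit:
    """Fit strain(y) = p * exp(-q * y) + r to a crack-tip strain profile.

    Deterministic initialization: r0 = min(strain), p0 = max - min, q0 from
    the log-slope between the first point and the point where the excess
    strain has decayed most.  Needs at least 4 points; raises
    :class:`StrainFitError` on non-convergence.
    """
    y = np.asarray(y_nm, dtype=float)
    e = np.asarray(strain, dtype=float)
    if y.shape != e.shape or y.ndim != 1:
        raise ValueError("y_nm and strain must be 1D arrays of equal length")
    if y.size < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter profile")
    order = np.argsort(y)
    y, e = y[order], e[order]
    r0 = float(e.min())
    p0 = float(e.max() - e.min())
    span = y[-1] - y[0]
    q0 = 1.0 / span if span > 0 else 1.0
    if p0 > 0:
        excess = e - r0 + 1e-12 * max(1.0, p0)
        k = int(np.argmax(e))
        j = int(np.argmin(excess))
        if y[j] != y[k] and excess[k] > 0:
            slope = (np.log(excess[k]) - np.log(excess[j])) / (y[j] - y[k])
            if slope > 0:
                q0 = slope
    try:
        popt, _ = curve_fit(
            lambda yy, p, q, r: p * np.exp(-q * yy) + r,
            y,
            e,
            p0=[p0, q0, r0],
            maxfev=10000,
        )
    except RuntimeError as err:
        raise StrainFitError(f"exponential strain fit did not converge: {err}") from err
    p, q, r = (float(v) for v in popt)
    resid = e - (p * np.exp(-q * y) + r)
    return StrainProfileFit(p, q, r, float(np.sqrt(np.mean(resid**2))))


def mastication_pressure(force_n: float, area_mm2: float) -> float:
    """Pressure in GPa from a chewing force (N) over a cusp area (mm^2).

    1000 N over 1 mm^2 is 1 GPa, the canonical mastication estimate.
    """
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return float(force_n / area_mm2 / 1000.0)  # N/mm^2 = MPa -> GPa
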