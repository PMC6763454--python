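"""Bi-crystal fracture and elasticity calculations: fracture energy and
toughness, the periodic mis-orientation angle set, layered tensor rotation,
a crack-tip strain-profile fit, and the mastication pressure estimate.
"""

import numpy as np

from enamelpic import (
    A_Z_ANGSTROM,
    BiCrystalGeometry,
    StressStrainCurve,
    critical_energy_release_rate,
    fit_strain_profile,
    fracture_toughness,
    hexagonal_tensor,
    infer_lx,
    layer_tensors,
    mastication_pressure,
    periodic_misorientation_angle,
)

# --- fracture energy from a stress-strain curve --------------------------
# a toy triangular tensile record: linear to 6 GPa at strain 0.12, then failure
curve = StressStrainCurve(
    strain=np.array([0.0, 0.12, 0.121, 0.2]),
    stress_gpa=np.array([0.0, 6.0, 0.0, 0.0]),
    gauge_length_nm=16.0,
)
g_c = critical_energy_release_rate(curve)
k_ic = fracture_toughness(g_c, 133.3e9)
print(f"G_c = {g_c:.2f} J/m^2  ->  K_IC = {k_ic:.2f} MPa m^0.5 (E = 133.3 GPa)")
print(f"published co-oriented bi-crystal: G_c = 5.87 J/m^2 -> "
      f"K_IC = {fracture_toughness(5.87, 133.3e9):.2f} MPa m^0.5")

# --- the discrete periodic mis-orientation angles ------------------------
l_x = infer_lx(14.1, 1, A_Z_ANGSTROM)
geo = BiCrystalGeometry(l_x)
angles = [14.1] + [periodic_misorientation_angle(geo, n) for n in (2, 3)]
print(f"l_x = {l_x:.2f} A; periodic angles: "
      + ", ".join(f"{a:.1f}°" for a in angles))

# --- per-layer stiffness for a 10-layer rotated-crystal model ------------
c0 = hexagonal_tensor(c11=140.0, c12=45.0, c13=50.0, c33=170.0, c44=40.0)
layers = layer_tensors(c0, delta_theta_deg=14.1)
print(f"layer 0 C11 = {layers[0].matrix[0, 0]:.1f} GPa, "
      f"layer 9 (126.9°) C11 = {layers[9].matrix[0, 0]:.1f} GPa")

# --- crack-tip strain decay ----------------------------------------------
y = np.linspace(0.0, 30.0, 16)  # nm above the crack tip
strain = 0.08 * np.exp(-0.15 * y) + 0.005
fit = fit_strain_profile(y, strain)
print(f"strain(y) = {fit.p:.3f} exp(-{fit.q:.3f} y) + {fit.r:.3f}  "
      f"(rms {fit.residual_rms:.1e})")

# --- mastication pressure -------------------------------------------------
print(f"1000 N on 1 mm^2 cusp: {mastication_pressure(1000, 1):.2f} GPa; "
      f"770 N max bite: {mastication_pressure(770, 1):.2f} GPa")
# The GPa-scale contact pressure is what sinters abutting apatite crystals
# and loads the mis-oriented interfaces that deflect cracks.
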