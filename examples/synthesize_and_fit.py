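"""Generate a synthetic enamel field, image it through the dichroism model,
and fit the orientations back — the full forward/inverse loop.

The synthetic field plays the role of the real sample; the 19-angle
polarization ratio stack is what a beamline would record; the per-pixel
harmonic fit is how a PIC map is computed from it.
"""

import numpy as np

from enamelpic import (
    DichroismParams,
    EnamelConfig,
    build_pic_map,
    fold_c_prime,
    generate_field,
    simulate_stack,
)

truth = generate_field(EnamelConfig(image_shape=(192, 192), seed=1))
print(f"ground truth: {truth.pic_map.shape} px, {len(truth.rod_spreads_deg)} rods, "
      f"{int((~truth.pic_map.mask).sum())} sheath px")

params = DichroismParams(noise_sigma=0.01)  # 1% multiplicative ratio noise
stack = simulate_stack(truth.pic_map, params, seed=1)
print(f"simulated stack: {stack.ratio_images.shape[0]} polarization angles "
      f"({stack.angles_deg[0]:.0f}..{stack.angles_deg[-1]:.0f} deg)")

fitted = build_pic_map(stack, params)
both = fitted.mask & truth.pic_map.mask
err = np.abs(fold_c_prime(fitted.c_prime_deg[both] - truth.pic_map.c_prime_deg[both]))
err = np.minimum(err, 180.0 - err)
print(f"fitted {int(both.sum())} pixels; median |c' error| = {np.median(err):.3f} deg, "
      f"95th pct = {np.percentile(err, 95):.2f} deg")
# Sub-degree recovery means the in-plane c-axis angle survives realistic
# ratio noise; pixels whose axis points into the beam lose dichroic
# contrast and are masked rather than mis-fitted.
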