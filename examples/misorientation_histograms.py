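"""Neighbor mis-orientation histograms at doubling strides on the default
synthetic field — the statistic that distinguishes gradual intra-rod
orientation drift from abrupt rod-interrod boundaries.
"""

import numpy as np

from enamelpic import (
    EnamelConfig,
    angle_at_frequency,
    generate_field,
    multiscale_histograms,
    neighbor_distances,
)

truth = generate_field(EnamelConfig(seed=0))
pic = truth.pic_map

hists = multiscale_histograms(pic)
level = max(1, round(hists[1].n_pairs / 1000))  # ~0.1% of stride-1 pairs
print(f"{'stride':>6} {'pairs':>8} {'modal bin':>10} {'tail angle @' + str(level):>14}")
for s, h in sorted(hists.items()):
    if h.n_pairs == 0:
        continue
    modal = h.bin_centers[int(np.argmax(h.counts))]
    tail = angle_at_frequency(h, level)
    print(f"{s:>6} {h.n_pairs:>8} {modal:>9.2f}° {tail:>13.2f}°")

within = neighbor_distances(pic, 1, region=truth.rod_labels > 0)
print(f"\nwithin-rod adjacent pairs < 30°: {100 * np.mean(within < 30):.1f}%")
for label, spread in sorted(truth.rod_spreads_deg.items()):
    print(f"rod {label}: realized c-axis spread {spread:.1f}°")
# The modal adjacent-pixel distance sits near 1° while the tail angle grows
# with stride: orientations change gradually pixel-to-pixel but accumulate
# 30-90° of spread within each rod, the signature of real enamel maps.
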