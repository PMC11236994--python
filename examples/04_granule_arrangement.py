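"""Classify germ-granule E/P/Z contact arrangements from rendered images.

Generates a 210-granule cohort with composition 32% / 48% / 20%
(EP_only / EPZ / multiE_P), renders each granule into three noisy
channels, segments the foci, and re-derives the category percentages
from the contact graph.
"""

import egranule as eg

cohort = eg.make_granule_cohort(n=210, weights=(0.32, 0.48, 0.20), seed=0)
calls = []
correct = 0
for i, scene in enumerate(cohort):
    images, truth_graph = eg.simulate_foci_image(scene.layout, noise_sd=50.0, seed=100 + i)
    call = eg.arrangement_from_images(images, threshold=350.0)
    calls.append(call)
    correct += call.category == scene.category

pct = eg.category_percentages(calls)
print(f"re-classified {len(calls)} granules; {100 * correct / len(calls):.1f}% match truth")
for cat in ("EP_only", "EPZ", "multiE_P", "other"):
    print(f"  {cat:9s}: {pct[cat]:5.1f}%")
# EP_only = one E granule touching the P granule but no Z granule;
# EPZ = the E granule bridges both P and Z; multiE_P = two or more
# E granules docked on one P granule.

# the same contact test backs ROI colocalization workflows:
images, _ = eg.simulate_foci_image(cohort[0].layout, noise_sd=50.0, seed=1)
import numpy as np
mask = np.ones_like(images["P"], dtype=bool)
r = eg.pearson_coloc(images["P"], images["E"], mask)
print(f"\nwhole-field Pearson R between the P and E channels: {r:.2f}")
print("(distinct, adjacent compartments give low R; identical channels give 1)")
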