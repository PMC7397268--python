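"""Build one barrel head and inspect its geometry.

Heads are ordered: each stave's position across the 597 mm disc fixes both
its in-circle area (its weight in the head OTR) and the minimum length it
must have — maximal at the centre, shrinking toward the rim.
"""

import numpy as np

import otrcooper as oc

rng = np.random.default_rng(2)
pool = oc.generate_staves(oc.class_population_model("head", "L"), 25, rng)
target = oc.CLASS_MEAN_OTR[("head", "L")]

config = oc.GAConfig(target_otr=target, procedures=dict(oc.HEAD_PROCEDURES),
                     max_generations=5000, tolerance=1e-6)
head, trace = oc.ga_construct(pool, "head", config, rng=rng)

layout = oc.layout_head(head)
print(f"{len(head)}-stave head, OTR {oc.element_otr(head):.7f} hPa/h "
      f"(target {target}, error {abs(oc.element_otr(head) - target):.2e})")
print(f"disc coverage {layout.total_area_m2:.5f} m^2 (pi*R^2 = 0.27992 m^2)")
print("position  width   length  required  area share")
for i, s in enumerate(head):
    ratio = oc.head_ratios(layout)[i]
    print(f"   {i}      {s.width:5.1f}   {s.length:5.0f}   {layout.required_lengths[i]:6.1f}"
          f"    {100 * ratio:.3f}%")
# The centre stave must span the full 597 mm diameter; the printed area
# shares sum to ~12.61% of the whole barrel surface for one head.
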