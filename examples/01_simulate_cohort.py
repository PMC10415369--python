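"""Generate a synthetic GMD cohort and inspect its group structure.

The `paper_like` preset encodes a step-wise gradient of grey-matter-density
reductions: a psychosis-wide shared deficit plus a strong, spatially
extensive B1-specific pattern, a small B2-specific pattern, and only a weak
effect in B3.
"""

import numpy as np

from gmdclassify import cohort_spec, generate_cohort

spec = cohort_spec(preset="paper_like", grid_dims=(16, 16, 16), seed=0)
cohort = generate_cohort(spec)

print(f"subjects: {len(cohort.subject_ids)}")
print(cohort.subjects["biotype"].value_counts().to_string())

flat = cohort.images.reshape(cohort.images.shape[0], -1)
support = spec.specific_effects["B1"].support
for group in ("B1", "B2", "B3", "CON"):
    sel = (cohort.subjects["biotype"] == group).to_numpy()
    mean_gmd = flat[sel][:, support].mean()
    print(f"mean GMD over the B1-specific region, {group}: {mean_gmd:.4f}")

# B1 sits lowest (baseline 0.5 minus its specific reduction); the other
# groups hover near baseline there, because the region is B1-specific.
print(f"configured B1-specific reduction depth: {spec.specific_effects['B1'].magnitude}")
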