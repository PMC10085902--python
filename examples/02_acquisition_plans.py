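"""Build the transect and scatter SEM acquisition plans.

Prints the image-count ladder of both strategies: 10/20/40/80 images
for quarter/half/full/double transects along the membrane diameter, and
8/16/32/69 images for eighth/quarter/half/full scatter layouts spread
over the whole disc.
"""

from diatomtest import (
    MembraneSpec, SCATTER_LEVELS, TRANSECT_LEVELS,
    make_scatter_plan, make_transect_plan,
)

spec = MembraneSpec()
print("strategy  level    images  sampled mm^2  % of membrane")
for level in TRANSECT_LEVELS:
    p = make_transect_plan(spec, level)
    print(f"transect  {level:<8} {p.n_images:>5}  {p.sampled_area_mm2:>11.2f}"
          f"  {100 * p.sampled_area_mm2 / spec.area_mm2:>12.1f}")
for level in SCATTER_LEVELS:
    p = make_scatter_plan(spec, level)
    print(f"scatter   {level:<8} {p.n_images:>5}  {p.sampled_area_mm2:>11.2f}"
          f"  {100 * p.sampled_area_mm2 / spec.area_mm2:>12.1f}")
# Even the largest plan images only a few percent of the membrane --
# whole-membrane abundance always rests on extrapolation.
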