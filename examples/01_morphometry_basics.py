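"""Measure Genant heights and the height loss ratio on a synthetic vertebra.

Builds a single 15 mm vertebral body with a wedge deformity targeting one
third height loss, measures the three column heights from the emitted mask,
and grades the result.
"""

from spinemorph import PhantomSpec, DeformityClass, VertebraMask, analyze_mask, generate_spine

spec = PhantomSpec(
    n_vertebrae=1,
    base_posterior_height_mm=15.0,
    deformity_plan=((0, DeformityClass.WEDGE, 1 / 3),),
    seed=0,
)
labels, truth = generate_spine(spec)

record = analyze_mask(VertebraMask(labels == 1, truth.pixel_spacing_mm, "L1"))
print(f"anterior  height: {record.ha_mm:5.1f} mm")
print(f"middle    height: {record.hm_mm:5.1f} mm")
print(f"posterior height: {record.hp_mm:5.1f} mm")
print(f"height loss ratio: {record.hlr:.1%}  ->  grade: {record.grade}")

# A 5 mm anterior loss on this 15 mm body is a 33% ratio (moderate VCF);
# the same 5 mm loss on a 25 mm body would only be 20% and grade normal —
# the size dependence that limits ratio-based reading.
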