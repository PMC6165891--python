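"""Inter-rater agreement before and after lesion correction.

Simulates ten tracers of the same lesion (boundary jitter plus
tracer-specific healthy-WM inclusions), computes all 45 pairwise Dice
coefficients, corrects every tracing, and recomputes.  Correction
removes the WM-intensity disagreement voxels, so mean pairwise Dice
rises.
"""

from lesionkit import correct_lesion, normalize_intensity, pairwise_dice, segment_white_matter
from lesionkit.metrics import overlap_heatmap
from lesionkit.phantoms import PhantomSpec, make_head_phantom, make_tracer_variants

ph = make_head_phantom(PhantomSpec(seed=4))
t1n = normalize_intensity(ph["t1"])
wm = segment_white_matter(t1n, ph["brain_truth"])
healthy_wm = wm.with_data(((wm.data > 0) & ~(ph["lesion_truth"].data > 0)).astype(float))

tracings = make_tracer_variants(ph["lesion_truth"], 10, 0.5, seed=5, sprinkle_region=healthy_wm)
before = pairwise_dice(tracings)
corrected = [correct_lesion(t1n, wm, t, 5.0).corrected_mask for t in tracings]
after = pairwise_dice(corrected)

print(f"tracers: {len(tracings)}  pairs: {before.pair_values.size}")
print(f"mean pairwise Dice, no correction:   {before.mean_dc:.3f} +/- {before.sem:.3f} (SEM)")
print(f"mean pairwise Dice, after correction: {after.mean_dc:.3f} +/- {after.sem:.3f} (SEM)")

heat = overlap_heatmap(corrected)
print(f"heat-map peak agreement: {int(heat.data.max())}/10 tracers at the lesion core")

# The corrected tracings agree more closely: the intensity window removes
# exactly the healthy-white-matter voxels on which tracers disagreed.
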