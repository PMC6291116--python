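"""Watching the level-set energy decrease.

Builds the probability maps and distance images for a small synthetic
scene, evolves the two level-set fields, and prints the energy breakdown
every 50 iterations: E_p (negative log-likelihood of the four phases), E_d
(weighted color-distance), and the contour-length terms.
"""
from plasmaseg import (
    LevelSetParams,
    assign_weights,
    contrast_stretch,
    default_scene_spec,
    distance_images,
    distance_table_from_model,
    evolve,
    fit_model_from_truth,
    generate_scene,
    init_phis,
    probability_maps,
    remove_unstained,
    to_channel_stack,
)

spec = default_scene_spec(shape=(128, 128), n_single=4, cluster_sizes=(2,), n_unstained=1)
train = generate_scene(spec, seed=99)
model = fit_model_from_truth(*train)

img, truth = generate_scene(spec, seed=7)
stretched = contrast_stretch(img)
stack = to_channel_stack(stretched)
cleaned = remove_unstained(stack, stretched, bg_color=model.region_rgb_mean("background"))
stack = to_channel_stack(cleaned)

weights = assign_weights(distance_table_from_model(model))
pmaps = probability_maps(stack, model, weights)
dimgs = distance_images(stack, model, weights)

state = init_phis((128, 128), radius=5, spacing=15)
state = evolve(state, pmaps, dimgs, LevelSetParams(n_iter=300, tol=0.0))

print(f"{'iter':>5} {'E_total':>14} {'E_p':>12} {'E_d':>14} {'len1':>8} {'len2':>8}")
for row in state.energy_log[::50]:
    print(
        f"{row['iteration']:>5} {row['E']:>14.4g} {row['E_p']:>12.4g}"
        f" {row['E_d']:>14.4g} {row['length1']:>8.1f} {row['length2']:>8.1f}"
    )
print(
    "\nThe total decreases between re-initializations; the periodic reset to"
    "\nsigned distance (every 20 iterations) can bump it, after which descent"
    "\nresumes.  The distance term dominates and drives the fields toward the"
    "\nstained-cell boundaries."
)
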