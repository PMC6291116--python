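"""Channel weighting from region separability.

Loads the reference Bhattacharyya distance table measured on stained
bone-marrow smears and applies the threshold rules that decide which color
channels may represent each region in the level-set energies: a channel is
admitted for a region only when it separates that region from both of its
competitors (threshold 1 for the two plasma-cell regions, 3 for background
and unstained cells), and the admitted weight is the larger of the two
distances.
"""
from plasmaseg import CHANNEL_NAMES, REGION_NAMES, assign_weights
from plasmaseg.reference import REFERENCE_DISTANCES

weights = assign_weights(REFERENCE_DISTANCES, t_pc=1.0, t_bg=3.0)

header = f"{'channel':>8} " + " ".join(f"{r:>11}" for r in REGION_NAMES)
print(header)
for ch in CHANNEL_NAMES:
    row = " ".join(f"{weights.weight(ch, r):11.2f}" for r in REGION_NAMES)
    print(f"{ch:>8} {row}")

print(
    "\nNonzero cells are the channels each region's probability map and"
    "\ndistance image are built from; e.g. the nucleus is carried by B, H, V"
    "\n(weight = the stronger of its separations from cytoplasm and background)."
)
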