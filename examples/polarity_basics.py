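"""The polarity index at its geometric extremes.

CL = center of mass of the measured channel, CC = cell centroid, CB =
vector from CC to the bead center.  The index is the scalar projection of
CL onto CB divided by |CB|: +1 when the channel mass sits at the bead,
−1 at the mirror point, 0 when centered.
"""

from synquant import SceneConfig, make_bead_scene, polarity_index

for label, offset in [
    ("at bead center ", (0.0, 5.0)),
    ("mirror of bead ", (0.0, -5.0)),
    ("at cell center ", (0.0, 0.0)),
]:
    cfg = SceneConfig(
        lamp_positions_um=(offset,),
        n_lysosome_puncta=1,
        noise=(0.0, 0.0),
        blur_sigma_um=0.0,
        seed=0,
    )
    stack, truth = make_bead_scene(cfg)
    geom = polarity_index(
        stack, "LAMP", None, truth.true_bead_center,
        cell_center_um=truth.true_cell_center,
    )
    print(f"channel mass {label} -> polarity index {geom.index:+.6f}")

print("\nThe bounds ±1 correspond to fully polarized / anti-polarized cells.")
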