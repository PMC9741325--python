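"""Antigen-extraction readout: percent OVA lost from the bead.

A time-0 bead population (full retention) sets the reference; beads
rendered with half retention should read ~50 % extracted.
"""

import numpy as np

from synquant import (
    SceneConfig,
    antigen_remaining,
    bead_total_intensity,
    make_bead_scene,
    synapse_disk,
)

N = 10
ref = []
for i in range(N):
    stack, truth = make_bead_scene(SceneConfig(ova_retained_fraction=1.0, seed=i))
    disk, _ = synapse_disk(stack, truth.true_bead_center, 1.5)
    ref.append(bead_total_intensity(stack, disk))
t0 = float(np.mean(ref))

for retained in (0.75, 0.5, 0.25):
    vals = []
    for i in range(N):
        stack, truth = make_bead_scene(
            SceneConfig(ova_retained_fraction=retained, seed=100 + i)
        )
        disk, _ = synapse_disk(stack, truth.true_bead_center, 1.5)
        vals.append(antigen_remaining(stack, disk, t0).percent_extracted)
    print(
        f"retained {retained:.2f} -> measured {np.mean(vals):5.1f} % extracted "
        f"(true {100 * (1 - retained):.0f} %)"
    )

print("\nMeasured extraction tracks the programmed OVA loss despite shot noise.")
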