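"""Condition-level statistics on per-cell polarity indices.

Simulates a control and a treated population of bead conjugates (the
treatment suppresses lysosome polarization), then reports mean ± SEM and
a Dunnett many-to-one comparison against the control.
"""

import numpy as np
import pandas as pd

from synquant import ComparisonDesign, SceneConfig, compare_groups, make_bead_scene, polarity_index, summarize


def population(kappa: float, label: str, n: int, seed0: int) -> pd.DataFrame:
    rows = []
    for i in range(n):
        cfg = SceneConfig(polarization_kappa=kappa, seed=seed0 + i)
        stack, truth = make_bead_scene(cfg)
        ny, nx = stack.shape_zyx[1:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        cy, cx = np.array(truth.true_cell_center) / stack.pixel_size_um
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (5.0 / stack.pixel_size_um) ** 2
        idx = polarity_index(stack, "LAMP", mask, truth.true_bead_center).index
        rows.append({"condition": label, "polarity_index": idx})
    return pd.DataFrame(rows)


records = pd.concat(
    [population(6.0, "ctrl", 12, 0), population(1.0, "treated", 12, 500)]
)
print(summarize(records, ["condition"], "polarity_index").to_string(index=False))
design = ComparisonDesign(posthoc="dunnett", reference_level="ctrl")
print(compare_groups(records, "polarity_index", design)["posthoc"].to_string(index=False))
print(
    "\nThe treated cells' weaker angular concentration lowers the polarity "
    "index; the Dunnett contrast tests that drop against the control."
)
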