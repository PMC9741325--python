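"""Render a small bead-conjugate dataset, quantify it, and print the table.

Each row is one cell/bead conjugate: recruitment fraction (share of LAMP1
fluorescence inside the 3 µm synapse disk), polarity index (−1..1, 1 =
lysosomes fully polarized toward the bead), central enrichment, bottom/top
z-ratio and LAMP1/LC3 Manders M1.
"""

import tempfile
from pathlib import Path

from synquant import SceneConfig
from synquant.pipeline import run_quantify, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "scenes"
    simulate_dataset(
        root,
        n_scenes=4,
        seed=7,
        base_config=SceneConfig(polarization_kappa=3.0),
    )
    records = run_quantify(root)

cols = ["cell_id", "recruitment_fraction", "polarity_index", "manders_m1"]
print(records[cols].to_string(index=False))
print(
    "\nPositive polarity indices: the von Mises placement (kappa=3) pulls "
    "lysosomes toward the bead, as after BCR engagement."
)
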