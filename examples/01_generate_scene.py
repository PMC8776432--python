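"""Generate a synthetic H&E scene and inspect its ground truth.

Builds one 256x256 tile (0.5 um/px) of clear-cell-like tissue with a known
vacuole fraction, then reports how the vacuole fraction moves the excess
kurtosis of the cytoplasmic hematoxylin concentration -- the quantity the
whole pipeline is built to measure.
"""

import numpy as np
from scipy.stats import kurtosis

from histokurt import SceneSpec, generate_scene

for vac in (0.1, 0.3, 0.6):
    scene = generate_scene(SceneSpec(vacuole_fraction=vac, seed=0))
    band = scene.true_concentrations[scene.cytoplasm_band, 0]
    k = kurtosis(band, fisher=True, bias=True)
    print(
        f"vacuole fraction {vac:.1f}: {scene.nuclei_labels.max()} nuclei, "
        f"cytoplasm band {scene.cytoplasm_band.sum()} px, "
        f"hematoxylin excess kurtosis {k:+.2f}"
    )

print(
    "\nMore lipid vacuoles -> a sharper near-zero spike in the cytoplasmic "
    "hematoxylin\ndistribution -> higher excess kurtosis.  Low kurtosis "
    "emulates lipid-poor,\nhigher-grade tumors."
)
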