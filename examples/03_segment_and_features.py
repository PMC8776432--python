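"""Segment nuclei, build the 4 um perinuclear rings, extract cell features.

Runs the full image stage on one synthetic tile and shows the per-cell
cytoplasm-hematoxylin kurtosis separating a vacuole-poor from a
vacuole-rich scene.
"""

import numpy as np

from histokurt import (
    SceneSpec, apply_normalization, deconvolve, estimate_stain_vectors_macenko,
    expand_perinuclear, extract_cell_features, fit_normalization,
    generate_scene, render_he, rgb_to_od, segment_nuclei, tissue_mask,
)

for vac in (0.1, 0.6):
    scene = generate_scene(SceneSpec(vacuole_fraction=vac, seed=5))
    od = rgb_to_od(render_he(scene))
    pair = deconvolve(od, estimate_stain_vectors_macenko(od))
    norm = apply_normalization(pair, fit_normalization(pair, tissue_mask(od)))

    nuclei = segment_nuclei(norm.c_h, scene.spec.mpp)
    cyto = expand_perinuclear(nuclei, expansion_um=4.0)
    cells, drops = extract_cell_features(norm, nuclei, cyto, patient_id="demo")

    kurt = [c.hC.kurtosis for c in cells]
    print(
        f"vacuole {vac:.1f}: {nuclei.n_objects} nuclei segmented "
        f"({scene.nuclei_labels.max()} true), {len(cells)} cells kept, "
        f"{len(drops)} dropped; median kurtosis_hC {np.median(kurt):+.2f}"
    )

print("\nkurtosis_hC is the per-cell excess kurtosis of hematoxylin "
      "concentration in\nthe perinuclear cytoplasm ring; vacuole-rich "
      "(clear-cell-like) tissue scores higher.")
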