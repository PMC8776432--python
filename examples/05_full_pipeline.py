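"""End to end: synthetic cohort -> tiles -> features -> survival report.

Generates 20 patients x 4 tiles in two vacuole-fraction groups, wires the
hazard to each patient's true cytoplasm kurtosis (low kurtosis = worse
prognosis), runs the full pipeline, and prints the dichotomized hazard
ratio it recovers.  Writes all outputs under ./pipeline_demo/.
"""

import json
from pathlib import Path

from histokurt import PipelineConfig, generate_cohort, run_pipeline

root = Path("pipeline_demo")
cohort = generate_cohort(root, n_patients=20, tiles_per_patient=4, seed=1)

config = PipelineConfig(
    tiles_manifest=cohort["manifest"],
    survival_table=cohort["survival"],
    output_dir=str(root / "out"),
    mpp=0.5,
    patch_size_px=128,
)
paths = run_pipeline(config)

report = json.loads(Path(paths["cutpoint"]).read_text())
print(f"cutpoint on kurtosis_hC: {report['cutpoint']:.3f} "
      f"(adjusted p = {report['adjusted_p']:.3f})")
print(f"hazard ratio, high vs low kurtosis: "
      f"{report['hazard_ratio_high_vs_low']:.3f}")
print(f"log-rank: chi2 = {report['logrank_chi2']:.2f}, "
      f"p = {report['logrank_p']:.2e} "
      f"({report['n_high']} high / {report['n_low']} low patients)")
print(f"\noutputs: {paths['patients']}, {paths['univariate']}, ...")
print("HR < 1 with small p reproduces the designed structure: patients with "
      "high\ncytoplasmic hematoxylin kurtosis (lipid-rich, clear-cell-like "
      "tumors) do better.")
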