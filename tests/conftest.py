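import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from histokurt import (
    PipelineConfig,
    SceneSpec,
    generate_cohort,
    generate_scene,
    run_pipeline,
)


def well_separated_spec(seed: int, noise_sd: float = 0.0) -> SceneSpec:
    """50 nuclei with 8 um edge-to-edge separation: unambiguous ground truth."""
    return SceneSpec(
        n_nuclei=50,
        image_height_px=384,
        image_width_px=384,
        min_separation_um=8.0,
        seed=seed,
        noise_sd=noise_sd,
    )


@pytest.fixture(scope="session")
def separated_scene():
    """One noiseless well-separated scene shared across tests."""
    return generate_scene(well_separated_spec(seed=7))


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    """A 20-patient x 4-tile synthetic cohort run end-to-end once per session.

    Low/high vacuole-fraction groups; hazard wired to each patient's true
    cytoplasm-hematoxylin kurtosis with a negative log hazard ratio, so low
    kurtosis means worse prognosis.
    """
    root = tmp_path_factory.mktemp("cohort")
    res = generate_cohort(root, n_patients=20, tiles_per_patient=4, seed=1)
    config = PipelineConfig(
        tiles_manifest=res["manifest"],
        survival_table=res["survival"],
        output_dir=str(root / "out"),
        mpp=0.5,
        patch_size_px=128,
    )
    paths = run_pipeline(config)
    return {"config": config, "paths": paths, "root": root, **res}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
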