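from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from achkit import BinaryMask, MaskLabel, PipelineConfig
from achkit.geometry import extract_tooth_instances, process_radiograph
from achkit.oracle import NoiseParams, oracle_detect
from achkit.phantom import PhantomSpec, generate_phantom

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def config() -> PipelineConfig:
    """Default pipeline config at the phantom calibration of 0.1 mm/px."""
    return PipelineConfig(mm_per_px=0.1)


def make_rect_tooth(x0, x1, y0, y1, shape=(80, 80)):
    """A rectangular ToothInstance for unit tests."""
    grid = np.zeros(shape, dtype=bool)
    grid[y0:y1 + 1, x0:x1 + 1] = True
    return extract_tooth_instances(BinaryMask(grid, MaskLabel.TEETH), 1)[0]


def run_phantom_pipeline(seed, noise: NoiseParams | None = None, spec: PhantomSpec | None = None,
                         config: PipelineConfig | None = None):
    """Generate a phantom, detect with the oracle, run the pipeline."""
    spec = spec if spec is not None else PhantomSpec(seed=seed)
    config = config if config is not None else PipelineConfig(mm_per_px=spec.mm_per_px)
    _, truth = generate_phantom(spec)
    bundle = oracle_detect(truth, noise if noise is not None else NoiseParams(seed=seed))
    result = process_radiograph(
        bundle.landmarks_a,
        bundle.landmarks_b,
        bundle.teeth_mask_1,
        bundle.teeth_mask_2,
        bundle.abcl_mask,
        config.calibration,
        config,
        image_id=truth.image_id,
    )
    return truth, result
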