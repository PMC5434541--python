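import numpy as np
import pandas as pd
import pytest

import mcttrack as m
from mcttrack.detect import DetectParams, concat_detections, detect_particles
from mcttrack.preprocess import subtract_background_frame


@pytest.fixture(scope="session")
def small_params():
    """A quick sheep-like phantom: quarter-size field, short run."""
    return m.sheep_preset(shape=(256, 256), n_frames=20, n_particles=8, seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return m.generate_phantom(small_params)


def run_detection(result, threshold_k=5.0):
    """Static-reference subtraction + detection over a phantom result."""
    model = m.build_background(
        result.sequence, mode="static_reference", reference=result.background
    )
    params = DetectParams.for_bead(
        103.0, result.sequence.pixel_size_um, threshold_k=threshold_k
    )
    parts = [
        detect_particles(subtract_background_frame(f, model), params, frame_index=i)
        for i, f in enumerate(result.sequence)
    ]
    return concat_detections(parts)


def truth_as_detections(truth_positions):
    """Turn exact ground-truth positions into a detection table (noise-free
    input for testing the linker in isolation)."""
    df = truth_positions.rename(columns={"particle_id": "truth_id"}).copy()
    out = pd.DataFrame({
        "frame_index": df["frame_index"].astype(int),
        "x_px": df["x_px"],
        "y_px": df["y_px"],
        "area_px2": 32.0,
        "contrast": 0.2,
    })
    return out
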