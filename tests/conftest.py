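import numpy as np
import pytest

from fixscene.geometry import DEFAULT_GEOMETRY, ScreenGeometry


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisefree_trace(geometry):
    """Noise-free synthetic gaze trace with ground-truth events."""
    from fixscene import synth

    return synth.make_gaze_trace(150, seed=3, jitter_sd_deg=0.0,
                                 blink_rate_per_min=0.0, geometry=geometry)


@pytest.fixture(scope="session")
def detected_noisefree(noisefree_trace, geometry):
    """Saccades/fixations detected on the noise-free trace."""
    from fixscene import gaze as gz

    trace, truth = noisefree_trace
    vel = gz.compute_velocity(trace, geometry)
    saccades = gz.detect_saccades(trace, vel, geometry,
                                  floor_threshold=30.0)
    blinks, dropouts = gz.detect_blinks(trace)
    fixations = gz.detect_fixations(trace, saccades, blinks, dropouts)
    return {"trace": trace, "truth": truth, "velocity": vel,
            "saccades": saccades, "fixations": fixations,
            "blinks": blinks, "dropouts": dropouts}
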