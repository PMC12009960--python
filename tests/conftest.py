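import numpy as np
import pytest

from synspread.geometry import DeviceGeometry
from synspread.segment import SegmentationParams
from synspread.synth import NoiseModel, SynthConfig

# coarse calibration used throughout the suite to keep fields small
PX = 0.65


@pytest.fixture()
def geometry():
    return DeviceGeometry(pixel_size=PX)


@pytest.fixture()
def small_cfg():
    """A compact field (166 µm) with the default study conditions."""
    return SynthConfig(seed=11, field_size_um=(166.4, 166.4), pixel_size_um=PX)


@pytest.fixture()
def noise_free_cfg():
    return SynthConfig(
        seed=11,
        field_size_um=(332.8, 332.8),
        pixel_size_um=PX,
        noise=NoiseModel.noise_free(),
    )


@pytest.fixture()
def manual_params():
    """Manual thresholds matched to the generator's intensity scale."""
    return {
        "psyn": SegmentationParams(threshold_method="manual", manual_level=1200.0),
        "tubulin": SegmentationParams(threshold_method="manual", manual_level=150.0),
        "cfse": SegmentationParams(threshold_method="manual", manual_level=150.0),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
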