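import numpy as np
import pytest

from gelquant import synthgel
from gelquant.gelimage import GelImage


@pytest.fixture(scope="session")
def calibration_gel(tmp_path_factory):
    """Rendered serial-dilution gel (5 calibration lanes + one unknown +
    marker), with its spec, truth table and image path."""
    spec = synthgel.make_calibration_gel(extra_sample_masses=(0.7,), seed=11)
    out = tmp_path_factory.mktemp("calgel")
    path = out / "gel.tif"
    image, truth = synthgel.write_gel(spec, path)
    return {"spec": spec, "image": image, "truth": truth, "path": path}


@pytest.fixture(scope="session")
def degradation_gel(tmp_path_factory):
    spec = synthgel.make_degradation_gel(seed=3)
    out = tmp_path_factory.mktemp("deggel")
    path = out / "gel.tif"
    image, truth = synthgel.write_gel(spec, path)
    return {"spec": spec, "image": image, "truth": truth, "path": path}


def lanes_config(spec):
    """Explicit lane declarations for a synthetic gel's run config."""
    return [
        {
            "lane_id": ln.lane_id,
            "col_start": ln.col_start,
            "col_end": ln.col_end,
            "role": ln.role,
        }
        for ln in spec.lanes
    ]


def signal_image(signal, bit_depth=16):
    """Wrap a raw non-negative array as a GelImage for unit tests."""
    return GelImage(signal=np.asarray(signal, dtype=float), bit_depth=bit_depth)
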