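import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from metlab.synthetic_data import make_demo_panel  # noqa: E402
from metlab.tables_io import SampleSheet  # noqa: E402


@pytest.fixture(scope="session")
def demo_panel():
    return make_demo_panel()


@pytest.fixture()
def nist_style_sheet():
    """12 replicates in two batches (4 + 8), the reference-material design."""
    rows = []
    order = {"B1": 0, "B2": 0}
    for i in range(1, 5):
        order["B1"] += 1
        rows.append(("nist_b1_%02d" % i, "sample", order["B1"], "B1"))
    for i in range(1, 9):
        order["B2"] += 1
        rows.append(("nist_b2_%02d" % i, "sample", order["B2"], "B2"))
    frame = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "role": role,
                "injection_order": o,
                "batch_id": b,
                "tissue": "plasma",
                "replicate_group": sid,
                "dilution_factor": 5.0,
            }
            for sid, role, o, b in rows
        ]
    )
    return SampleSheet(frame)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180913)
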