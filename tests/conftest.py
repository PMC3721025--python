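import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from ventflow.io_model import OtuTable, SampleMetadata
from ventflow.synth import make_scenario

logging.getLogger("ventflow").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_scenario():
    """One default two-region scenario shared across tests (seed fixed)."""
    return make_scenario(seed=20130724)


@pytest.fixture(scope="session")
def default_subtraction(default_scenario):
    from ventflow.enrichment import subtract_background

    sc = default_scenario
    vent_sets, frame = subtract_background(sc.table, sc.metadata)
    return vent_sets, frame


@pytest.fixture
def tiny_table():
    """2 samples x 3 OTUs, hand-checkable."""
    return OtuTable(
        pd.DataFrame(
            [[5, 0, 1], [2, 2, 0]],
            index=["S1", "S2"],
            columns=["OtuA", "OtuB", "OtuC"],
        )
    )


@pytest.fixture
def paired_region_meta():
    """Minimal one-region metadata: one off-axis + two vent samples."""
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["V1", "V2", "OA"],
                "region": ["EPR", "EPR", "EPR"],
                "habitat": ["diffuse_flow", "diffuse_flow", "off_axis"],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
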