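import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from marrownet.data_io import AnnotationMap, ConcentrationTable
from marrownet.panels import AMINO, LIPID, OTHER

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(values: dict, patients, compartments=("BM", "PB"), days=(0,)) -> ConcentrationTable:
    """Build a small concentration table; values[metabolite] is a flat list
    ordered patient-major, then compartment, then day."""
    index = pd.MultiIndex.from_tuples(
        [(p, c, d) for p in patients for c in compartments for d in days],
        names=["patient_id", "compartment", "day"],
    )
    return ConcentrationTable(pd.DataFrame(values, index=index, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_table():
    """3 patients × BM/PB at day 0, 3 metabolites, one missing cell."""
    return make_table(
        {
            "choline": [30, 20, 28, 21, np.nan, 19],
            "alanine": [350, 340, 360, 345, 355, 338],
            "lactate": [2400, 2300, 2500, 2350, 2450, 2320],
        },
        patients=["p1", "p2", "p3"],
    )


@pytest.fixture
def three_class_annotation():
    return AnnotationMap({"choline": LIPID, "alanine": AMINO, "lactate": OTHER})
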