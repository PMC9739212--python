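"""Shared fixtures: the printed activity table of the tetrahydroquinoline
series and session-scoped synthetic study sets."""

import numpy as np
import pytest

from study_constants import ACTIVITY_TABLE, STUDY_KINDS

from qsarfield.dataset import CompoundRecord
from qsarfield.pipeline import run_pipeline
from qsarfield.synthetic import SyntheticConfig, generate_set


@pytest.fixture(scope="session")
def activity_records() -> list[CompoundRecord]:
    return [
        CompoundRecord(id=str(no), ic50_uM=ic50, role="test" if is_test else "training")
        for no, ic50, _, is_test in ACTIVITY_TABLE
    ]


@pytest.fixture(scope="session")
def study_set():
    """Synthetic 40-compound series at the study conditions (seed 1)."""
    return generate_set(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def study_result(study_set):
    """Pipeline fit of the study set with the selected field kinds."""
    return run_pipeline(
        study_set.molecules, study_set.records, kinds=STUDY_KINDS, grid=study_set.grid
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
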