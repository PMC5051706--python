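import numpy as np
import pytest

from elastoconcord import (
    GeneratorConfig,
    PopulationLabel,
    add_standardized_columns,
    apply_applicability,
    derive_populations,
    generate_frame,
)


def analysis_ready(config: GeneratorConfig):
    """Generate a cohort frame with statuses and standardized columns."""
    frame = apply_applicability(generate_frame(config))
    return add_standardized_columns(frame)


@pytest.fixture(scope="session")
def study_frame():
    """One study-sized cohort at the default scenario, analysis-ready."""
    return analysis_ready(GeneratorConfig(n=2251, seed=20160))


@pytest.fixture(scope="session")
def study_populations(study_frame):
    return derive_populations(study_frame)


@pytest.fixture(scope="session")
def concordance_frame(study_frame, study_populations):
    return study_frame[
        study_frame["id"].isin(study_populations[PopulationLabel.CONCORDANCE])
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(99)
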