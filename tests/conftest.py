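import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from iohdef import default_registry, pipeline, synthetic
from iohdef.signal import MAPGrid

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


def make_grid(values, patient_id="p"):
    values = np.asarray(values, dtype=float)
    return MAPGrid(
        patient_id=patient_id,
        start_s=0.0,
        values=values,
        anesthesia_duration_min=(values.size - 1) * 15.0 / 60.0,
    )


@pytest.fixture(scope="session")
def registry24():
    return default_registry("tables_24")


@pytest.fixture(scope="session")
def worked_grid():
    """The hand-checkable 8-tick MAP grid used in the worked examples."""
    return make_grid([80.0, 80.0, 70.0, 65.0, 62.0, 62.0, 66.0, 75.0])


@pytest.fixture(scope="session")
def cleaning_fixture():
    """60-sample hand-built record: one constructed violator per rule."""
    series, expected = pipeline.reference_cleaning_series()
    return series, expected


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort with artifacts (n=150)."""
    return synthetic.generate_cohort(synthetic.TruthConfig(n_patients=150, seed=42))


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free cohort for pipeline self-consistency checks (n=100)."""
    return synthetic.generate_cohort(
        synthetic.TruthConfig(n_patients=100, seed=17, artifact_rate=0.0)
    )


@pytest.fixture(scope="session")
def random_grid_corpus():
    """Random integer-valued MAP grids (ties on purpose) for oracle checks."""
    rng = np.random.default_rng(2024)
    grids = []
    for _ in range(400):
        n = int(rng.integers(8, 201))
        vals = rng.integers(40, 101, size=n).astype(float)
        grids.append(vals)
    return grids
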