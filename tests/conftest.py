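import numpy as np
import pytest

from trajmine.config import RunConfig
from trajmine.cohort import build_cohort
from trajmine.data_model import default_class_map
from trajmine.pipeline import build_sequences_for_cohort
from trajmine.synthetic_data import default_archetypes, generate_cohort


@pytest.fixture(scope="session")
def class_map():
    return default_class_map()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def small_run(config):
    """A 120-patient synthetic cohort run through cohort and sequence stages."""
    syn = generate_cohort(120, seed=11)
    cohort, attrition = build_cohort(
        syn.prescriptions, syn.diagnoses, syn.patients, syn.class_map, config
    )
    sequences = build_sequences_for_cohort(cohort, syn.prescriptions, syn.class_map, config)
    return {"syn": syn, "cohort": cohort, "attrition": attrition, "sequences": sequences}


@pytest.fixture(scope="session")
def recovery_run(config):
    """The n=400 recovery cohort: full pipeline inputs shared across tests."""
    syn = generate_cohort(400, seed=1)
    cohort, _ = build_cohort(
        syn.prescriptions, syn.diagnoses, syn.patients, syn.class_map, config
    )
    sequences = build_sequences_for_cohort(cohort, syn.prescriptions, syn.class_map, config)
    truth = syn.truth.set_index("patient_id")["archetype"]
    labels_true = np.array([truth[s.patient_id] for s in sequences])
    return {"syn": syn, "cohort": cohort, "sequences": sequences, "truth": labels_true}
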