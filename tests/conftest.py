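from datetime import date

import pytest
from hypothesis import settings

import rxcohort as rx

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_patient(pid="P1", sex="F", birth=date(2000, 1, 1),
                 entry=date(2008, 1, 1)):
    return rx.Patient(pid, sex, birth, entry)


def make_rx(pid="P1", fill=date(2010, 3, 1), atc="N06AB03", units=30.0,
            upd=1.0, ddd=30.0, formulation="solid", prescriber="GP"):
    return rx.PrescriptionRecord(pid, fill, atc, units, upd, ddd,
                                 formulation, prescriber)


@pytest.fixture
def tiny_dataset():
    """One clean fluoxetine starter plus a non-user."""
    patients = [make_patient("P1"), make_patient("P2", sex="M")]
    fills = [make_rx("P1"),
             make_rx("P1", fill=date(2010, 3, 29)),
             make_rx("P2", atc="N02BE01", ddd=10.0)]
    return rx.dataset_from_records(patients, fills)


@pytest.fixture(scope="session")
def sim_default():
    """Mid-sized simulation shared by recovery tests."""
    cfg = rx.default_config(seed=101, n_patients=1000)
    dataset, truth = rx.simulate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def pipeline_default(sim_default):
    _, dataset, _ = sim_default
    return rx.run_pipeline(dataset)
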