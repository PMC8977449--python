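import numpy as np
import pytest

from painnma import Scenario, generate, load_fixture
from painnma.nma_engine import ModelSpec
from painnma.trial_data import ArmOutcome, NetworkDataset, OutcomeRecord, Study, Treatment


@pytest.fixture(scope="session")
def fixture_ds():
    return load_fixture()


@pytest.fixture(scope="session")
def two_treatment_ds():
    """Six placebo-controlled trials of one drug, continuous outcome."""
    sc = Scenario(
        n_treatments=2,
        geometry="star",
        trials_per_edge=6,
        d={"drug01": -0.6},
        tau=0.15,
        arm_size=(30, 80),
        seed=3,
    )
    return generate(sc)


@pytest.fixture(scope="session")
def triangle_ds():
    sc = Scenario(
        n_treatments=3,
        geometry="triangle",
        trials_per_edge=2,
        d={"drug01": -0.5, "drug02": -0.2},
        tau=0.1,
        arm_size=(40, 80),
        seed=5,
    )
    return generate(sc)


@pytest.fixture(scope="session")
def star_ds():
    sc = Scenario(
        n_treatments=4,
        geometry="star",
        trials_per_edge=2,
        d={"drug01": -0.4, "drug02": -0.2, "drug03": 0.1},
        tau=0.1,
        arm_size=(30, 60),
        seed=9,
    )
    return generate(sc)


@pytest.fixture
def quick_spec():
    """Reduced MCMC settings for unit tests (scaled down from 3x50k/100k)."""
    return ModelSpec(burn_in=800, samples=2400, seed=17)


def make_continuous_study(study_id, arms, outcome_id="pain4w", followup=4.0):
    """arms: list of (treatment, n, mean_change, sd)."""
    outcomes = {
        t: ArmOutcome(kind="continuous", n=n, mean_change=m, sd=sd)
        for t, n, m, sd in arms
    }
    return Study(
        study_id=study_id,
        arms=tuple(sorted((t, n) for t, n, _, _ in arms)),
        records=(
            OutcomeRecord(outcome_id=outcome_id, followup_weeks=followup, arm_outcomes=outcomes),
        ),
    )


def make_dataset(studies, reference="placebo"):
    used = sorted({t for s in studies for t in s.treatment_ids})
    ref = reference if reference in used else used[0]
    return NetworkDataset(
        treatments=tuple(Treatment(id=t, is_reference=(t == ref)) for t in used),
        studies=tuple(studies),
        reference=ref,
    )
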