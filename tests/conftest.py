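import dataclasses

import pytest

from exvivopharm import classify, ihc, synthetic


@pytest.fixture(scope="session")
def clinical_cases():
    return classify.load_clinical_fixture()


@pytest.fixture()
def default_cohort():
    return synthetic.generate_cohort(synthetic.CohortParams(seed=7))


def cohort_trajectories(cohort):
    """Group cohort observations into MarkerTrajectory objects."""
    grouped = {}
    for obs in cohort.observations:
        grouped.setdefault((obs.case_id, obs.marker, obs.arm), []).append(obs)
    return {key: ihc.MarkerTrajectory.from_observations(v) for key, v in grouped.items()}


def classify_cohort(cohort):
    """Run the full scoring + classification chain; returns case_id -> call."""
    trajs = cohort_trajectories(cohort)
    calls = {}
    for case in cohort.cases:
        doxo = ihc.normalize_to_baseline(trajs[(case.case_id, "Ki67", "doxo")])
        veh = ihc.normalize_to_baseline(trajs[(case.case_id, "Ki67", "vehicle")])
        rel = classify.relative_ki67(doxo, veh)
        calls[case.case_id] = classify.classify_response(rel)
    return calls


def with_true_labels(cohort):
    """Synthetic cases with the hidden class written into doxo_class."""
    truth = cohort.reveal_all()
    return [dataclasses.replace(c, doxo_class=truth[c.case_id]) for c in cohort.cases]
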