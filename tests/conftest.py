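import pytest

from dietrisk import assess, generate_ffq_population, generate_residue_survey, paper_like_scenario


@pytest.fixture(scope="session")
def scenario():
    return paper_like_scenario(seed=1)


@pytest.fixture(scope="session")
def survey_samples(scenario):
    samples = []
    for i, com in enumerate(sorted(scenario.commodities)):
        samples.extend(generate_residue_survey(scenario, com, seed=i))
    return samples


@pytest.fixture(scope="session")
def ffq_records(scenario):
    return generate_ffq_population(scenario)


@pytest.fixture(scope="session")
def assessment(survey_samples, ffq_records):
    return assess(survey_samples, ffq_records)
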