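import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")

from agestage.cohort import Cohort, IndividualRecord, write_life_history
from agestage.simulate import (
    FecundityModel,
    GeneratorConfig,
    discretized_gamma,
    discretized_normal,
)


def make_toy_cohort() -> Cohort:
    """Four-individual hand fixture: two females, one male, one pre-adult
    death.  Every life-table quantity is enumerable by hand."""
    f1 = IndividualRecord(
        "F1",
        ("egg", "larva", "larva", "pupa", "female", "female", "female"),
        (0, 0, 0, 0, 0, 4, 2),
    )
    f2 = IndividualRecord(
        "F2", ("egg", "larva", "larva", "pupa", "female", "female"), (0, 0, 0, 0, 3, 0)
    )
    m1 = IndividualRecord(
        "M1", ("egg", "larva", "larva", "larva", "pupa", "male", "male"), (0,) * 7
    )
    d1 = IndividualRecord("D1", ("egg", "larva", "larva"), (0, 0, 0))
    return Cohort((f1, f2, m1, d1), label="toy")


@pytest.fixture
def toy_cohort() -> Cohort:
    return make_toy_cohort()


@pytest.fixture
def toy_csv(tmp_path, toy_cohort):
    path = tmp_path / "toy.csv"
    write_life_history(toy_cohort, path)
    return path


def mini_config(label: str = "mini", fecundity_mean: float = 20.0) -> GeneratorConfig:
    """A fast, small-support config for property tests (short stages, modest
    fecundity) -- keeps X_max ~ 25 d so hundreds of cohorts fit in seconds."""
    return GeneratorConfig(
        label=label,
        stage_durations={
            "egg": discretized_normal(2.0, 0.7),
            "larva": discretized_normal(4.0, 1.2),
            "pupa": discretized_normal(3.0, 1.0),
        },
        stage_survival={"egg": 0.9, "larva": 0.8, "pupa": 0.9},
        female_longevity=discretized_normal(8.0, 2.0),
        male_longevity=discretized_normal(6.0, 2.0),
        fecundity=FecundityModel(
            total=discretized_gamma(fecundity_mean, 8.0),
            apop=discretized_normal(1.0, 1.0, minimum=0),
            oviposition_days=discretized_normal(4.0, 1.5),
        ),
    )


@pytest.fixture
def small_config() -> GeneratorConfig:
    return mini_config()
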