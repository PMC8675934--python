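import pytest

from commstack import GeneratorConfig, ModelSpec, generate_dataset

#: Forest sizes used by the evaluation-protocol tests (library defaults are
#: larger; these are the documented protocol sizes).
RF_EVAL = ModelSpec("rf", n_estimators=80, max_samples=0.25, max_features=1.0)
RF_STAGE1 = ModelSpec("rf", n_estimators=80, max_depth=6, max_samples=0.25,
                      max_features=1.0)
RF_SMALL = ModelSpec("rf", n_estimators=30, max_features=1.0)


def small_config(**overrides) -> GeneratorConfig:
    """A reduced survey: 2 plots x 16 subplots x 3 years x 6 species."""
    base = dict(n_plots=2, grid=(4, 4), n_years=None, n_species=6,
                years=(2015, 2016, 2017), precipitation=(530.0, 625.0, 384.0))
    base.pop("n_years")
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_table():
    table, truth = generate_dataset(small_config(), seed=7)
    return table, truth


@pytest.fixture(scope="session")
def default_table():
    """One realisation of the full calibrated survey (1620 communities)."""
    table, truth = generate_dataset(seed=1)
    return table, truth
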