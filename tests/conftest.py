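import numpy as np
import pytest

import plankform as pf
from plankform.cascade import ForestConfig
from plankform.evaluate import PipelineConfig, SplitSpec, repeat_evaluation

#: Split protocol shared by the repeated-evaluation fixtures (same seed =>
#: identical splits across pipeline variants, enabling paired comparisons).
EVAL_SPLITS = SplitSpec(train_fraction=0.8, n_repetitions=50, seed=7)


@pytest.fixture(scope="session")
def default_config():
    return pf.default_config(seed=0)


@pytest.fixture(scope="session")
def default_table(default_config):
    """19 subjects x 7 techniques, stable-window features + engineered maxima."""
    trials = pf.generate_dataset(default_config)
    table = pf.build_feature_table(trials)
    return pf.add_max_features(table, pf.reference_max_feature_specs())


@pytest.fixture(scope="session")
def small_table():
    """5 subjects per technique — fast variant for fitting-path tests."""
    cfg = pf.default_config(n_subjects_per_technique=5, seed=3)
    table = pf.build_feature_table(pf.generate_dataset(cfg))
    return pf.add_max_features(table, pf.reference_max_feature_specs())


@pytest.fixture(scope="session")
def small_forest():
    return ForestConfig(n_estimators=50)


@pytest.fixture(scope="session")
def default_report(default_table):
    """Full-protocol evaluation of the default pipeline on default data."""
    return repeat_evaluation(default_table, PipelineConfig(), EVAL_SPLITS)


@pytest.fixture(scope="session")
def nofilter_report(default_table):
    """Same data and splits as default_report, aberrance filters disabled."""
    return repeat_evaluation(
        default_table, PipelineConfig(filter_specs=None), EVAL_SPLITS
    )


@pytest.fixture(scope="session")
def separated_table():
    """Data where every deviation sits >= 4 combined SDs from PC."""
    cfg = pf.default_config(seed=0, hd_overlap=False)
    table = pf.build_feature_table(pf.generate_dataset(cfg))
    return pf.add_max_features(table, pf.reference_max_feature_specs())


@pytest.fixture(scope="session")
def separated_report(separated_table):
    return repeat_evaluation(separated_table, PipelineConfig(), EVAL_SPLITS)


@pytest.fixture(scope="session")
def fitted_model(default_table):
    """One cascade fitted on the full default table (reference order)."""
    return PipelineConfig(forest=ForestConfig(n_estimators=200)).fit(default_table, 17)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
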