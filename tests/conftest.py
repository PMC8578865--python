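import numpy as np
import pandas as pd
import pytest

from neuroindex import AnalysisConfig, GeneratorConfig, TrialDataset, run_all
from neuroindex.simulate import simulate_bundle

BUNDLE_SEED = 1  # fixed study seed for all default-bundle tests


def make_frame(rows):
    """Build a measurement frame from (sid, trial, arm, day, h, q, p, b) tuples."""
    return pd.DataFrame(
        rows,
        columns=["subject_id", "trial", "arm", "day", "hamd24", "qids_sr16",
                 "phq9", "bdnf_pg_ml"],
    )


@pytest.fixture
def tiny_frame():
    """Two subjects x three visits, fully observed."""
    rows = []
    for sid, h in (("S01", 26), ("S02", 30)):
        for day, drop in ((0, 0), (4, 5), (28, 15)):
            rows.append((sid, "trial2", "yueju", day, h - drop, 12, 10,
                         18000.0 + 100 * day))
    return make_frame(rows)


@pytest.fixture
def tiny_csv(tmp_path, tiny_frame):
    path = tmp_path / "trial.csv"
    tiny_frame.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return simulate_bundle(default_config)


@pytest.fixture(scope="session")
def default_report(default_bundle):
    return run_all(
        default_bundle["trial1"], default_bundle["trial2"],
        default_bundle["controls"], AnalysisConfig(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
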