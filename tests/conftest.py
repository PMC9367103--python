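import warnings

import numpy as np
import pandas as pd
import pytest

from subclonepulse.pipeline import RunConfig, run_pipeline
from subclonepulse.simdata import SimConfig


def make_observations(rows):
    """Build a minimal call-ready observation table from (id, alt, ref) triples."""
    return pd.DataFrame(
        [dict(mutation_id=m, alt_reads=a, ref_reads=r) for m, a, r in rows]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """One shared end-to-end pipeline run on a simulated six-patient cohort."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = RunConfig(simulate=SimConfig(n_patients=6), seed=11, out_dir=str(out))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)
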