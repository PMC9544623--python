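import numpy as np
import pandas as pd
import pytest

import cropstab as cs
from cropstab import model, pipeline


@pytest.fixture(scope="session")
def small_ds():
    """5 publications x 3 comparisons x 2 effects, shared controls present."""
    return cs.small_fixture(seed=7)


@pytest.fixture(scope="session")
def tiny_ds():
    """Minimal dataset: one effect per comparison, no shared controls."""
    cfg = cs.GeneratorConfig(
        n_publications=6, comparisons_per_publication=(2, 2),
        effects_per_comparison=(1, 1), treatments_per_control=1, seed=11)
    return cs.generate_summary_dataset(cfg)


def null_fit(ds, response="lnCVR", method="REML", **fit_kw):
    """Intercept-only multilevel fit of a contrast effect size."""
    cfg = pipeline.SuiteConfig()
    y, S, levels, tab = pipeline._contrast_inputs(ds, response, cfg)
    X = pd.DataFrame({"intercept": np.ones(len(y))})
    return model.fit(y, X, S, levels, method=method, **fit_kw), tab


@pytest.fixture(scope="session")
def small_cvr0(small_ds):
    fit, _ = null_fit(small_ds)
    return fit
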