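import numpy as np
import pytest

from gridvote.core_io import ExpressionDataset, RunConfig
from gridvote.synthetic_data import EndpointSpec, make_reduced_suite
from gridvote.driver import run_suite

#: seeds of the replicated reduced-scale suite experiment (fixed up front)
SUITE_SEEDS = tuple(range(1, 21))


def make_ds(values, labels=None, batches=None, code="T", role="training",
            sample_prefix="s", feature_prefix="f"):
    """Small-dataset builder for tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionDataset(
        sample_ids=[f"{sample_prefix}{i:03d}" for i in range(n)],
        feature_ids=[f"{feature_prefix}{j:03d}" for j in range(p)],
        values=values,
        labels=None if labels is None else np.asarray(labels),
        batches=batches if batches is None else list(batches),
        endpoint_code=code,
        role=role,
    )


def tiny_spec(code="D", seed=0, **kw):
    """Quick separable endpoint for pipeline-level unit tests."""
    defaults = dict(
        code=code, train_n=60, train_pn_ratio=1.0, validation_n=40,
        validation_pn_ratio=1.0, n_features=60, n_informative=10,
        effect_size=1.5, seed=seed,
    )
    defaults.update(kw)
    return EndpointSpec(**defaults)


def tiny_cfg(seed=0, **kw):
    defaults = dict(feature_step=5, feature_max=20, knn_k_grid=(1, 3, 5),
                    cv_folds=3, cv_repeats=2, seed=seed)
    defaults.update(kw)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def suite_reports():
    """Twenty seeded reduced-scale suite runs (shared across tests)."""
    return {
        seed: run_suite(RunConfig.reduced(seed=seed),
                        make_reduced_suite(seed=seed))
        for seed in SUITE_SEEDS
    }
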