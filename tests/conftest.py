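import dataclasses

import numpy as np
import pytest

from dentalcbr.case_model import CaseEncoder
from dentalcbr.synthetic_data import default_paper_like_config, generate_casebase


@pytest.fixture(scope="session")
def small_casebase():
    """400 study-like cases with known cluster labels (shared, read-only)."""
    cfg = default_paper_like_config(3, n_cases=400)
    return generate_casebase(cfg)


@pytest.fixture(scope="session")
def small_encoder(small_casebase):
    cb, _ = small_casebase
    return CaseEncoder.fit(cb)


@pytest.fixture()
def two_cluster_config():
    """Two-cluster variant of the study-like generator (weights 0.3/0.7)."""

    def make(seed, n_cases, weights=(0.3, 0.7)):
        base = default_paper_like_config(seed, n_cases=n_cases)
        return dataclasses.replace(
            base,
            n_clusters=2,
            cluster_weights=np.asarray(weights, dtype=float),
            cat_tables={k: v[:2] for k, v in base.cat_tables.items()},
            composite_prob=base.composite_prob[:2],
            age_mean=base.age_mean[:2],
            age_sd=base.age_sd[:2],
            prior_gap_mean=base.prior_gap_mean[:2],
            prior_gap_sd=base.prior_gap_sd[:2],
            prior_longevity_mean=base.prior_longevity_mean[:2],
            prior_longevity_sd=base.prior_longevity_sd[:2],
            longevity_mean=base.longevity_mean[:2],
            longevity_sd=base.longevity_sd[:2],
        )

    return make
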