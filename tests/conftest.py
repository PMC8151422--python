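import dataclasses

import pytest

from lv1rm import GroupParams, default_config, noiseless_variant


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def tiny_config(base_config):
    """Default conditions shrunk to 4 athletes per group for fast tests."""
    groups = {
        g: {ex: dataclasses.replace(p, n_athletes=4)
            for ex, p in per_ex.items()}
        for g, per_ex in base_config.groups.items()
    }
    return dataclasses.replace(base_config, groups=groups)


@pytest.fixture(scope="session")
def ideal_config(base_config):
    """Noiseless cohort whose individual MVTs equal the reference MVTs."""
    return noiseless_variant(base_config, n_per_group=4)


@pytest.fixture
def bench_params():
    return GroupParams(
        group_label="young", n_athletes=20,
        true_1rm_mean=100.0, true_1rm_sd=15.0,
        v20_mean=1.50, v20_sd=0.08,
        mvt_ind_mean=0.17, mvt_ind_sd=0.04,
        rep_noise_sd=0.03, flatten_prob=0.0, flatten_strength=0.8,
    )
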