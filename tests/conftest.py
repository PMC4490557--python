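import numpy as np
import pytest

import ribofret as rf
from ribofret.synthetic import (AcquisitionParams, ConditionPreset,
                                KineticScheme, PhotophysicsParams)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_state_scheme():
    """XL-like 0.6/0.4 scheme with the tabulated stalled-intermediate rates."""
    return KineticScheme(
        state_names=("0.6", "0.4"),
        fret_mean=np.array([0.56, 0.40]),
        fret_sd=np.array([0.08, 0.09]),
        rate_matrix=np.array([[0.0, 7.9], [1.2, 0.0]]),
        start_probs=np.array([1.0, 0.0]),
    )


@pytest.fixture(scope="session")
def noiseless_photophysics():
    return PhotophysicsParams(bleach_rate_donor=0.0, bleach_rate_acceptor=0.0,
                              bleedthrough=0.0, noise_sd=0.0)


def make_noiseless_scheme(names, means, rates, start=None):
    k = len(names)
    q = np.zeros((k, k))
    for (a, b), r in rates.items():
        q[names.index(a), names.index(b)] = r
    return KineticScheme(state_names=tuple(names),
                         fret_mean=np.asarray(means, float),
                         fret_sd=np.zeros(k),
                         rate_matrix=q,
                         start_probs=start)


@pytest.fixture(scope="session")
def pre_dataset():
    """Small PRE-condition dataset shared by read-only tests."""
    return rf.generate_dataset("PRE", 40, seed=7)


@pytest.fixture(scope="session")
def xl_analysis():
    """A full analysis of a moderate XL dataset, shared by read-only tests."""
    ds = rf.generate_dataset("XL", 120, seed=11)
    res = rf.analyze(ds.raw_traces(), rf.PipelineConfig(k_max=3, seed=5),
                     condition="XL")
    return ds, res
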