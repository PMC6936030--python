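import pytest

from pseusite import SignalSpec, simulate_dataset

# Strong planted signal: G enrichment at several positions flanking the
# central U, mimicking the multi-position guanine enrichment seen around
# genuine Ψ sites.  With four positions at P(G)=0.9 vs uniform background
# the Bayes-optimal accuracy is ≈0.95, so a working pipeline has room to
# clear a 0.9 recovery bound.
STRONG_BIASES = ((13, "G", 0.9), (14, "G", 0.9), (16, "G", 0.9), (18, "G", 0.9))

# Single-position signal (Bayes optimum 0.825): used where the question
# is *where* the signal is, not how well it can be classified.
SINGLE_BIAS = ((16, "G", 0.9),)


@pytest.fixture(scope="session")
def signal_dataset():
    return simulate_dataset(SignalSpec(window_length=21, n_positive=150,
                                       n_negative=150, biases=STRONG_BIASES,
                                       seed=11))


@pytest.fixture(scope="session")
def single_signal_dataset():
    return simulate_dataset(SignalSpec(window_length=21, n_positive=200,
                                       n_negative=200, biases=SINGLE_BIAS,
                                       seed=13))


@pytest.fixture(scope="session")
def null_dataset():
    return simulate_dataset(SignalSpec(window_length=21, n_positive=150,
                                       n_negative=150, seed=12))
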