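import pytest

from calyxstp import (
    KO_PARAMS,
    RECOVERY_INTERVALS_S,
    WT_PARAMS,
    NoiseSpec,
    StimulusProtocol,
    generate_dataset,
)

FIT_FREQUENCIES_HZ = (100.0, 200.0, 600.0)


@pytest.fixture(scope="session")
def wt_params():
    return WT_PARAMS


@pytest.fixture(scope="session")
def ko_params():
    return KO_PARAMS


@pytest.fixture(scope="session")
def fit_protocols():
    """Canonical fitting protocols: 100/200/600 Hz trains + 100 Hz recovery."""
    protos = [
        StimulusProtocol.regular_train(f, 800.0) for f in FIT_FREQUENCIES_HZ
    ]
    protos.append(
        StimulusProtocol.train_with_recovery(
            100.0, 800.0, [1000.0 * d for d in RECOVERY_INTERVALS_S]
        )
    )
    return protos


NOISELESS = NoiseSpec(amp_cv=0.0, cell_param_cv=0.0, n_cells=1, n_repeats=1, seed=0)


@pytest.fixture(scope="session")
def wt_noiseless_dataset(fit_protocols):
    dataset, _ = generate_dataset(WT_PARAMS, fit_protocols, NOISELESS)
    return dataset


@pytest.fixture(scope="session")
def ko_noiseless_dataset(fit_protocols):
    dataset, _ = generate_dataset(KO_PARAMS, fit_protocols, NOISELESS)
    return dataset
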