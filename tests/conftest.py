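import numpy as np
import pytest

import kernelfc as kfc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_subject():
    """Reduced strong-coupling subject (20 trials/class) for fast unit tests."""
    spec = kfc.strong_coupling_spec(seed=5, trials_per_class=20)
    return kfc.generate(spec)


@pytest.fixture(scope="session")
def small_segments(small_subject):
    epochs, _ = small_subject
    windower = kfc.FilterBankWindower(
        fs=epochs.fs, bank=kfc.strong_coupling_bank(), tau=1.0, overlap=0.75
    ).fit(epochs.data)
    return windower.transform_epochs(epochs)


@pytest.fixture(scope="session")
def preset_subject():
    """Full strong-coupling preset subject (100 trials/class), seed 1."""
    spec = kfc.strong_coupling_spec(seed=1)
    return kfc.generate(spec)


@pytest.fixture(scope="session")
def preset_gfc_features(preset_subject):
    """Vectorized Gaussian-kernel features of the full preset subject."""
    epochs, truth = preset_subject
    bank = kfc.strong_coupling_bank()
    window = kfc.WindowSpec(tau=1.0, overlap=0.75)
    windower = kfc.FilterBankWindower(
        fs=epochs.fs, bank=bank, tau=window.tau, overlap=window.overlap
    ).fit(epochs.data)
    seg = windower.transform_epochs(epochs)
    sigma = kfc.median_sigma(seg)
    X, index_map = kfc.vectorize(kfc.connectivity_tensor(seg, "gfc", sigma))
    truth_cols = kfc.resolve_truth(truth, bank, window)
    return {
        "X": X,
        "y": epochs.labels,
        "index_map": index_map,
        "truth_cols": truth_cols,
        "epochs": epochs,
    }


def random_segments(rng, r=3, b=2, w=2, c=4, length=64, fs=64.0):
    """Ad-hoc TFSegments filled with Gaussian noise (for oracle tests)."""
    values = rng.standard_normal((r, b, w, c, length))
    return kfc.TFSegments(
        values=values,
        fs=fs,
        bands=tuple((4.0 * (i + 1), 4.0 * (i + 2)) for i in range(b)),
        window_starts=np.arange(w) * (length // 4),
        tau=length / fs,
    )
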