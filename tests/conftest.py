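import numpy as np
import pytest

import metaspectra as ms

#: repo-standard seed for deterministic simulation fixtures
SIM_SEED = 0


@pytest.fixture(scope="session")
def default_dataset():
    """Default simulated study: spectra plus ground truth."""
    config = ms.SimulationConfig(seed=SIM_SEED)
    spectra, truth = ms.generate_dataset(config)
    return config, spectra, truth


@pytest.fixture(scope="session")
def clustered_dataset(default_dataset):
    """Quality-filtered and clustered default simulation (shared: read-only)."""
    config, spectra, truth = default_dataset
    kept, rejected = ms.quality_filter(spectra)
    clusters = ms.cluster_spectra(kept)
    return config, kept, rejected, clusters, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_spectrum(spectrum_id, mz, intensity, precursor_mz=500.0, charge=2,
                  sample_id="S"):
    """Hand-build a spectrum from parallel m/z / intensity sequences."""
    return ms.Spectrum(
        spectrum_id=spectrum_id,
        sample_id=sample_id,
        precursor_mz=precursor_mz,
        charge=charge,
        peaks=[ms.Peak(m, i) for m, i in zip(mz, intensity)],
    )


def random_spectra(rng, n, n_peaks=30):
    """Random valid spectra for round-trip / property tests."""
    out = []
    for i in range(n):
        k = int(rng.integers(5, n_peaks))
        mz = np.sort(rng.uniform(100, 1400, size=k))
        intensity = rng.uniform(1, 1e5, size=k)
        out.append(
            make_spectrum(
                f"rand{i}", mz, intensity,
                precursor_mz=float(rng.uniform(300, 1500)),
                charge=int(rng.integers(1, 4)),
                sample_id=f"S{i % 3}",
            )
        )
    return out
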