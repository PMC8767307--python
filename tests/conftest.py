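import numpy as np
import pandas as pd
import pytest

from auscon.signal_io import Spectrogram, SpectrogramDataset


def make_spectrogram(n_bins=16, n_frames=40, pad_left=0, pad_right=0, seed=0,
                     fill=None):
    """Random-valued spectrogram with an explicit padded region.

    Data cells are drawn away from zero so 'masked' cells are unambiguous.
    """
    rng = np.random.default_rng(seed)
    values = np.zeros((n_bins, n_frames))
    data = slice(pad_left, n_frames - pad_right)
    if fill is None:
        values[:, data] = rng.normal(-40.0, 8.0, size=(n_bins, n_frames - pad_left - pad_right))
    else:
        values[:, data] = fill
    return Spectrogram(values=values, pad_left=pad_left, pad_right=pad_right)


@pytest.fixture
def padded_spec():
    return make_spectrogram(n_bins=16, n_frames=40, pad_left=5, pad_right=7, seed=3)


def toy_metadata(rows):
    """rows: list of (recording_id, patient_id, age_band, sex, location, label)."""
    return pd.DataFrame(rows, columns=["recording_id", "patient_id", "age_band",
                                       "sex", "location", "label"])


def toy_dataset(meta, n_bins=8, n_frames=20, seed=0):
    specs = [make_spectrogram(n_bins, n_frames, seed=seed + i)
             for i in range(len(meta))]
    return SpectrogramDataset(spectrograms=specs, metadata=meta)


@pytest.fixture(scope="session")
def bench_dataset():
    """Small synthetic cohort shared by the slower pipeline tests."""
    from auscon.synthetic import CohortSpec, make_benchmark_dataset

    return make_benchmark_dataset(CohortSpec(n_patients=40, seed=7))
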