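"""Audio and metadata I/O, spectrogram standardization, demographic imputation.

Heart and lung sound recordings arrive as PCM WAV files of widely varying
duration, with a per-recording metadata table (patient, age band, sex,
auscultation location, optional diagnosis label).  This module turns each
recording into a log-power mel spectrogram, standardizes all spectrograms to
a common frame count by center crop/pad at the 75th-quantile length, and
imputes missing demographics by chained categorical regression.

The non-padded ("data") region of a standardized spectrogram is tracked
explicitly because downstream augmentation must never touch the padding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import stft

LOCATIONS = (
    "trachea",
    "anterior left",
    "anterior right",
    "posterior left",
    "posterior right",
    "lateral left",
    "lateral right",
)
AGE_BANDS = ("adult", "child")
SEXES = ("female", "male")
LABELS = ("normal", "abnormal")

METADATA_COLUMNS = ("recording_id", "patient_id", "age_band", "sex", "location", "label")

# dB floor for log-power cells; keeps all-zero signals finite and uniform
LOG_FLOOR_DB = -100.0


@dataclass(frozen=True)
class AudioRecording:
    """A single auscultation recording tied to a patient."""

    recording_id: str
    patient_id: str
    waveform: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=np.float64)
        if wf.ndim != 1 or wf.size < 1:
            raise ValueError("waveform must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "waveform", wf)


@dataclass(frozen=True)
class Spectrogram:
    """Log-power time-frequency grid with an explicit non-padded region.

    ``values`` is (n_freq_bins, n_frames_total); frames outside
    ``[pad_left, n_frames_total - pad_right)`` are exactly zero.
    """

    values: np.ndarray
    pad_left: int = 0
    pad_right: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (freq x time)")
        if self.pad_left < 0 or self.pad_right < 0:
            raise ValueError("padding counts must be non-negative")
        if self.pad_left + self.pad_right >= v.shape[1]:
            raise ValueError("padding must leave at least one data frame")
        object.__setattr__(self, "values", v)

    @property
    def n_frames_total(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def data_slice(self) -> slice:
        return slice(self.pad_left, self.n_frames_total - self.pad_right)

    @property
    def n_data_frames(self) -> int:
        return self.n_frames_total - self.pad_left - self.pad_right

    @property
    def data(self) -> np.ndarray:
        """View of the non-padded frames."""
        return self.values[:, self.data_slice]


@dataclass(frozen=True)
class PatientMetadata:
    patient_id: str
    age_band: str | None = None
    sex: str | None = None
    location: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.location is not None and self.location not in LOCATIONS:
            raise ValueError(
                f"location {self.location!r} not in the 7-value set {LOCATIONS}"
            )


@dataclass(frozen=True)
class StandardizationRule:
    """Target frame count derived from a cohort length quantile."""

    target_frames: int
    quantile: float = 0.75

    def __post_init__(self) -> None:
        if self.target_frames < 1:
            raise ValueError("target_frames must be >= 1")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT + mel parameters. Defaults: 25 ms window, 10 ms hop, 64 mel bands."""

    window_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 64
    fmin: float = 0.0
    fmax: float | None = None

    def window_samples(self, sample_rate: int) -> int:
        return max(int(round(self.window_ms * sample_rate / 1000.0)), 1)

    def hop_samples(self, sample_rate: int) -> int:
        hop = max(int(round(self.hop_ms * sample_rate / 1000.0)), 1)
        win = self.window_samples(sample_rate)
        if hop > win:
            raise ValueError(f"hop ({hop}) must not exceed window ({win}) samples")
        return hop


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft_bins: int, sample_rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_fft_bins), rows sum-normalized."""
    if fmax is None:
        fmax = sample_rate / 2.0
    freqs = np.linspace(0.0, sample_rate / 2.0, n_fft_bins)
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, n_fft_bins))
    for i in range(n_mels):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    norm = fb.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return fb / norm


def compute_spectrogram(recording: AudioRecording,
                        config: SpectrogramConfig | None = None) -> Spectrogram:
    """Log-power mel spectrogram of a recording; no padding recorded.

    Deterministic for fixed input and config.  Power below the floor is
    clipped so an all-zero waveform yields a uniform floor-valued grid.
    """
    config = config or SpectrogramConfig()
    sr = recording.sample_rate
    win = config.window_samples(sr)
    hop = config.hop_samples(sr)
    if recording.waveform.size < win:
        raise ValueError(
            f"waveform has {recording.waveform.size} samples but one analysis "
            f"window needs at least {win}"
        )
    _, _, Z = stft(recording.waveform, fs=sr, nperseg=win, noverlap=win - hop,
                   boundary=None, padded=False)
    power = np.abs(Z) ** 2
    fb = mel_filterbank(config.n_mels, power.shape[0], sr, config.fmin, config.fmax)
    mel_power = fb @ power
    log_power = 10.0 * np.log10(np.maximum(mel_power, 10.0 ** (LOG_FLOOR_DB / 10.0)))
    return Spectrogram(values=log_power, pad_left=0, pad_right=0)


def normalize_per_recording(spec: Spectrogram, eps: float = 1e-9) -> Spectrogram:
    """Z-score the data region of a spectrogram; padding stays exactly zero.

    After normalization the padding value (0) coincides with the data-region
    mean, so convolutional models see padded frames as neutral rather than
    as a bright constant band.  Removes per-recording gain offsets.
    """
    values = spec.values.copy()
    data = spec.data
    mu = data.mean()
    sd = data.std()
    values[:, spec.data_slice] = (data - mu) / (sd + eps)
    return Spectrogram(values=values, pad_left=spec.pad_left,
                       pad_right=spec.pad_right)


def fit_standardization(lengths: Sequence[int], quantile: float = 0.75) -> StandardizationRule:
    """Target frame count = interpolated quantile of lengths, rounded half-up."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("need at least one length to fit a standardization rule")
    if any(n < 1 for n in lengths):
        raise ValueError("all lengths must be >= 1")
    q = float(np.quantile(np.asarray(lengths, dtype=np.float64), quantile,
                          method="linear"))
    target = int(math.floor(q + 0.5))  # round half-up
    return StandardizationRule(target_frames=max(target, 1), quantile=quantile)


def standardize_length(spec: Spectrogram, rule: StandardizationRule) -> Spectrogram:
    """Center crop/pad a spectrogram to the rule's target frame count.

    Odd pad deficit puts the extra zero frame on the right; odd crop excess
    drops the extra frame from the right.  Existing padding is tracked through
    the crop so the data region stays exact.
    """
    target = rule.target_frames
    n = spec.n_frames_total
    if n == target:
        return spec
    if n > target:
        excess = n - target
        start = excess // 2  # drop extra frame on the right for odd excess
        stop = start + target
        new_pad_left = max(spec.pad_left - start, 0)
        new_pad_right = max(stop - (n - spec.pad_right), 0)
        return Spectrogram(values=spec.values[:, start:stop],
                           pad_left=new_pad_left, pad_right=new_pad_right)
    deficit = target - n
    add_left = deficit // 2
    add_right = deficit - add_left  # extra frame on the right
    values = np.zeros((spec.n_bins, target), dtype=spec.values.dtype)
    values[:, add_left:add_left + n] = spec.values
    return Spectrogram(values=values,
                       pad_left=spec.pad_left + add_left,
                       pad_right=spec.pad_right + add_right)


# ---------------------------------------------------------------------------
# Metadata table handling and imputation
# ---------------------------------------------------------------------------

_FIELD_VALUES = {"age_band": AGE_BANDS, "sex": SEXES, "location": LOCATIONS}


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the interchange CSV/TSV; empty fields become NA."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    missing = set(METADATA_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if df["recording_id"].duplicated().any():
        raise ValueError("recording_id values must be unique")
    return df


def save_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep="")


def impute_metadata(table: pd.DataFrame, seed: int = 0, n_sweeps: int = 5) -> pd.DataFrame:
    """Fill missing age_band / sex / location by chained categorical regression.

    Demographics (age_band, sex) are patient-level: a patient's observed value
    is broadcast to all their recordings before anything is modelled.  Each
    sweep fits one logistic (multinomial for location) regression per field on
    the currently complete rows, one-hot encoding the other two fields, and
    re-predicts the originally missing entries; 5 sweeps, fixed seed.  A
    patient with no metadata at all receives the per-field mode.  Raises if a
    field is missing for every recording.
    """
    from sklearn.linear_model import LogisticRegression

    df = table.copy().reset_index(drop=True)
    fields = ["age_band", "sex", "location"]
    for f in fields:
        if f not in df.columns:
            raise ValueError(f"metadata table lacks column {f!r}")
        df[f] = df[f].where(df[f].notna(), pd.NA)

    # broadcast patient-level demographics across that patient's recordings
    for f in ("age_band", "sex"):
        per_patient = df.groupby("patient_id")[f].agg(
            lambda s: s.dropna().iloc[0] if s.notna().any() else pd.NA)
        df[f] = df["patient_id"].map(per_patient)

    for f in fields:
        if df[f].isna().all():
            raise ValueError(f"cannot impute {f!r}: missing for every recording")

    orig_missing = {f: df[f].isna().to_numpy() for f in fields}
    modes = {f: df[f].dropna().mode().iloc[0] for f in fields}

    # patients with every field missing get the per-field mode and are final
    all_missing = np.logical_and.reduce([orig_missing[f] for f in fields])
    for f in fields:
        df.loc[all_missing, f] = modes[f]
        # initial fill for the chained sweeps
        df.loc[df[f].isna(), f] = modes[f]

    rng = np.random.default_rng(seed)
    for _ in range(n_sweeps):
        for f in fields:
            target_rows = orig_missing[f] & ~all_missing
            if not target_rows.any():
                continue
            others = [g for g in fields if g != f]
            X = pd.get_dummies(df[others]).to_numpy(dtype=np.float64)
            y = df.loc[~orig_missing[f], f]
            if y.nunique() < 2:
                df.loc[target_rows, f] = y.iloc[0]
                continue
            model = LogisticRegression(max_iter=200,
                                       random_state=int(rng.integers(2 ** 31)))
            model.fit(X[~orig_missing[f]], y)
            df.loc[target_rows, f] = model.predict(X[target_rows])

    for f in fields:
        bad = ~df[f].isin(_FIELD_VALUES[f])
        if bad.any():
            raise ValueError(f"invalid {f} values after imputation: "
                             f"{sorted(df.loc[bad, f].unique())}")
    return df


def metadata_records(df: pd.DataFrame) -> list[PatientMetadata]:
    """Row-wise view of the table as typed records (one per recording)."""
    out = []
    for _, row in df.iterrows():
        out.append(PatientMetadata(
            patient_id=str(row["patient_id"]),
            age_band=None if pd.isna(row.get("age_band")) else str(row["age_band"]),
            sex=None if pd.isna(row.get("sex")) else str(row["sex"]),
            location=None if pd.isna(row.get("location")) else str(row["location"]),
            label=None if pd.isna(row.get("label")) else str(row["label"]),
        ))
    return out


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class SpectrogramDataset:
    """Standardized spectrograms plus the per-recording metadata table.

    ``metadata`` is indexed positionally and must carry the interchange
    columns; ``spectrograms[i]`` corresponds to ``metadata.iloc[i]``.
    """

    spectrograms: list[Spectrogram]
    metadata: pd.DataFrame
    rule: StandardizationRule | None = None

    def __post_init__(self) -> None:
        if len(self.spectrograms) != len(self.metadata):
            raise ValueError("spectrogram count must match metadata rows")
        self.metadata = self.metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.spectrograms)

    @property
    def recording_ids(self) -> list[str]:
        return [str(r) for r in self.metadata["recording_id"]]

    def subset(self, indices: Sequence[int]) -> "SpectrogramDataset":
        idx = list(int(i) for i in indices)
        return SpectrogramDataset(
            spectrograms=[self.spectrograms[i] for i in idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            rule=self.rule,
        )


def read_wav(path: str | Path, recording_id: str, patient_id: str) -> AudioRecording:
    """Read a PCM WAV file into an AudioRecording (amplitude scaled to [-1, 1])."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioRecording(recording_id=recording_id, patient_id=patient_id,
                          waveform=data, sample_rate=int(sr))


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a float waveform as 16-bit PCM, clipping to [-1, 1]."""
    peak = np.max(np.abs(waveform)) if waveform.size else 0.0
    scaled = waveform / peak if peak > 1.0 else waveform
    pcm = np.round(np.clip(scaled, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path, int(sample_rate), pcm)


def load_dataset(audio_dir: str | Path, metadata_path: str | Path,
                 config: SpectrogramConfig | None = None,
                 rule: StandardizationRule | None = None,
                 quantile: float = 0.75,
                 normalize: bool = True) -> SpectrogramDataset:
    """Load WAVs named <recording_id>.wav, build standardized spectrograms."""
    audio_dir = Path(audio_dir)
    meta = load_metadata(metadata_path)
    specs = []
    for _, row in meta.iterrows():
        rec = read_wav(audio_dir / f"{row['recording_id']}.wav",
                       str(row["recording_id"]), str(row["patient_id"]))
        specs.append(compute_spectrogram(rec, config))
    if rule is None:
        rule = fit_standardization([s.n_frames_total for s in specs], quantile)
    specs = [standardize_length(s, rule) for s in specs]
    if normalize:
        specs = [normalize_per_recording(s) for s in specs]
    return SpectrogramDataset(spectrograms=specs, metadata=meta, rule=rule)


def write_manifest(dataset: SpectrogramDataset, path: str | Path) -> None:
    """JSON-lines manifest, one record per recording."""
    with open(path, "w") as fh:
        for spec, (_, row) in zip(dataset.spectrograms, dataset.metadata.iterrows()):
            rec = {k: (None if pd.isna(row.get(k)) else str(row[k]))
                   for k in METADATA_COLUMNS if k in row.index}
            rec.update(n_frames_total=spec.n_frames_total,
                       pad_left=spec.pad_left, pad_right=spec.pad_right,
                       n_bins=spec.n_bins)
            fh.write(json.dumps(rec) + "\n")
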