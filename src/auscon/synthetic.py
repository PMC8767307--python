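"""Seeded synthetic auscultation cohorts with label-correlated metadata.

The generator emulates the statistical structure the contrastive method
exploits, without attempting physiological realism:

* patient-level demographics (age band, sex) drawn independently, with a
  binary diagnosis sampled from a logistic model on those demographics, so
  metadata carries real information about the label (as age does for
  respiratory disease);
* several recordings per patient at named auscultation locations;
* waveforms built from a shared broadband "breath" noise bed, a
  patient-specific narrowband component reused across that patient's
  recordings (within-patient correlation), a location-dependent spectral
  tilt, and — for abnormal patients only — transient wideband bursts
  ("crackles") at random times whose amplitude scales with ``signal_effect``;
* right-skewed recording durations so the 75th-quantile crop/pad rule is
  exercised on both sides.

Setting ``signal_effect=0`` removes any class difference in the audio;
setting ``patient_effect=0`` removes within-patient correlation.  Everything
is deterministic given the cohort seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter

from .signal_io import (LOCATIONS, AudioRecording, SpectrogramConfig,
                        SpectrogramDataset, compute_spectrogram,
                        fit_standardization, normalize_per_recording,
                        save_metadata, standardize_length, write_wav)


@dataclass(frozen=True)
class CohortSpec:
    """Benchmark cohort parameters (see module docstring for the generative model)."""

    n_patients: int = 80
    p_child: float = 0.45
    p_female: float = 0.5
    recordings_per_patient: int | tuple[int, int] = (3, 5)
    label_intercept: float = -1.6
    beta_age: float = 2.4       # log-odds shift for children
    beta_sex: float = 0.7       # log-odds shift for female patients
    signal_effect: float = 1.0  # class-signature amplitude (0 = no class signal)
    patient_effect: float = 0.8  # within-patient shared-component amplitude
    noise_sd: float = 0.3       # white-noise amplitude
    sample_rate: int = 4000
    duration_median_s: float = 0.9
    duration_log_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_child, self.p_female):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rpp = self.recordings_per_patient
        lo = rpp if isinstance(rpp, int) else rpp[0]
        if lo < 1:
            raise ValueError("recordings_per_patient must be >= 1")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def label_probability(spec: CohortSpec, age_band: str, sex: str) -> float:
    """P(abnormal | demographics) under the cohort's logistic label model."""
    logit = (spec.label_intercept
             + spec.beta_age * (age_band == "child")
             + spec.beta_sex * (sex == "female"))
    return _sigmoid(logit)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Patient-level table: patient_id, age_band, sex, label."""
    rng = np.random.default_rng([spec.seed, 0])
    rows = []
    for p in range(spec.n_patients):
        age = "child" if rng.random() < spec.p_child else "adult"
        sex = "female" if rng.random() < spec.p_female else "male"
        prob = label_probability(spec, age, sex)
        label = "abnormal" if rng.random() < prob else "normal"
        rows.append({"patient_id": f"p{p:04d}", "age_band": age, "sex": sex,
                     "label": label})
    return pd.DataFrame(rows)


# per-location first-order spectral tilt coefficients (tilt up vs down)
_LOCATION_TILT = dict(zip(LOCATIONS, np.linspace(-0.5, 0.5, len(LOCATIONS))))


def _patient_traits(spec: CohortSpec, patient_index: int, label: str) -> dict:
    rng = np.random.default_rng([spec.seed, 1, patient_index])
    # the wheeze carrier placement is label-independent by construction;
    # only the patient's amplitude-modulation rate depends on the class
    traits = {
        "tone_hz": float(rng.uniform(180.0, 420.0)),
        "tone_amp": float(rng.uniform(0.6, 1.4)),
        "wheeze_hz": float(rng.uniform(520.0, 880.0)),
    }
    if label == "abnormal":
        traits["am_rate_hz"] = float(rng.uniform(5.0, 9.0))
    else:
        traits["am_rate_hz"] = float(rng.uniform(0.5, 2.5))
    return traits


def generate_recording(spec: CohortSpec, patient_index: int, patient_row,
                       rec_index: int) -> tuple[AudioRecording, str]:
    """One recording for a patient; deterministic per (seed, patient, index).

    Returns the recording and its auscultation location.
    """
    rng = np.random.default_rng([spec.seed, 2, patient_index, rec_index])
    sr = spec.sample_rate
    duration = spec.duration_median_s * math.exp(
        rng.normal(0.0, spec.duration_log_sigma))
    n = max(int(round(duration * sr)), sr // 4)
    t = np.arange(n) / sr

    # broadband breath bed: low-passed white noise, amplitude-modulated at
    # the patient's class-dependent rate (see below)
    traits = _patient_traits(spec, patient_index, str(patient_row["label"]))
    rate = traits["am_rate_hz"] * rng.uniform(0.9, 1.1)
    am = 1.0 + 0.85 * np.sin(2.0 * math.pi * rate * t
                             + rng.uniform(0.0, 2.0 * math.pi))
    b, a = butter(2, 350.0 / (sr / 2.0), btype="low")
    wave = lfilter(b, a, rng.normal(0.0, 1.0, size=n))
    if spec.signal_effect > 0:
        wave = wave * (1.0 + spec.signal_effect * (am - 1.0))

    # patient-specific narrowband component, shared across recordings
    phase = rng.uniform(0.0, 2.0 * math.pi)
    wave += (spec.patient_effect * traits["tone_amp"]
             * np.sin(2.0 * math.pi * (traits["tone_hz"]
                                       + rng.uniform(-60.0, 60.0)) * t + phase))

    # class signature: the amplitude-modulation rate.  The breath bed and an
    # additional "wheeze" tone share a patient-level modulation rate — a
    # fast ripple for abnormal patients, a slow drift for normal ones.  The
    # wheeze carrier frequency is drawn identically for both classes
    # (patient-specific centre, per-recording jitter), and modulation depth
    # and power are class-independent, so no fixed spectrogram cell carries
    # class information in expectation: the class lives in a temporal
    # pattern a convolutional encoder can detect but a flattened per-cell
    # linear readout cannot.
    if spec.signal_effect > 0:
        carrier = traits["wheeze_hz"] + rng.uniform(-80.0, 80.0)
        amp = spec.signal_effect * rng.uniform(0.9, 1.1)
        wave += amp * am * np.sin(2.0 * math.pi * carrier * t
                                  + rng.uniform(0.0, 2.0 * math.pi))

    wave += spec.noise_sd * rng.normal(0.0, 1.0, size=n)

    # location: random site with a mild location-specific spectral tilt
    location = LOCATIONS[int(rng.integers(len(LOCATIONS)))]
    wave = lfilter([1.0, _LOCATION_TILT[location]], [1.0], wave)

    # per-recording gain nuisance (+/- 3 dB)
    wave *= 10.0 ** (rng.uniform(-3.0, 3.0) / 20.0)
    wave /= max(np.max(np.abs(wave)), 1e-9) * 1.05  # headroom for PCM

    rec = AudioRecording(recording_id=f"p{patient_index:04d}_r{rec_index}",
                         patient_id=str(patient_row["patient_id"]),
                         waveform=wave, sample_rate=sr)
    return rec, location


def generate_recordings(spec: CohortSpec
                        ) -> tuple[list[AudioRecording], pd.DataFrame]:
    """All recordings plus the interchange metadata table."""
    cohort = generate_cohort(spec)
    rng = np.random.default_rng([spec.seed, 3])
    recs, rows = [], []
    for p, patient in cohort.iterrows():
        rpp = spec.recordings_per_patient
        k = rpp if isinstance(rpp, int) else int(rng.integers(rpp[0], rpp[1] + 1))
        for r in range(k):
            rec, location = generate_recording(spec, p, patient, r)
            recs.append(rec)
            rows.append({"recording_id": rec.recording_id,
                         "patient_id": patient["patient_id"],
                         "age_band": patient["age_band"],
                         "sex": patient["sex"],
                         "location": location,
                         "label": patient["label"]})
    return recs, pd.DataFrame(rows)


def generate_dataset(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write WAV files and metadata.csv in the interchange format."""
    out_dir = Path(out_dir)
    audio_dir = out_dir / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    recs, meta = generate_recordings(spec)
    for rec in recs:
        write_wav(audio_dir / f"{rec.recording_id}.wav", rec.waveform,
                  rec.sample_rate)
    save_metadata(meta, out_dir / "metadata.csv")
    return out_dir


def make_benchmark_dataset(spec: CohortSpec,
                           config: SpectrogramConfig | None = None,
                           quantile: float = 0.75,
                           normalize: bool = True) -> SpectrogramDataset:
    """In-memory standardized spectrogram dataset for the benchmark cohort.

    Each spectrogram is per-recording z-scored (data region only) so models
    see gain-free inputs with neutral padding.
    """
    config = config or SpectrogramConfig(n_mels=32)
    recs, meta = generate_recordings(spec)
    specs = [compute_spectrogram(r, config) for r in recs]
    rule = fit_standardization([s.n_frames_total for s in specs], quantile)
    specs = [standardize_length(s, rule) for s in specs]
    if normalize:
        specs = [normalize_per_recording(s) for s in specs]
    return SpectrogramDataset(spectrograms=specs, metadata=meta, rule=rule)


def inject_missing(meta: pd.DataFrame, fraction: float, seed: int,
                   fields: tuple[str, ...] = ("age_band", "sex", "location")
                   ) -> pd.DataFrame:
    """Blank a random ``fraction`` of entries per field (missing at random).

    Demographics are blanked patient-wise (all of a patient's rows) so the
    missingness matches the patient-level granularity of those fields.
    """
    rng = np.random.default_rng(seed)
    out = meta.copy()
    patients = out["patient_id"].unique()
    for f in fields:
        if f in ("age_band", "sex"):
            hit = patients[rng.random(len(patients)) < fraction]
            out.loc[out["patient_id"].isin(hit), f] = pd.NA
        else:
            hit = rng.random(len(out)) < fraction
            out.loc[hit, f] = pd.NA
    return out
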