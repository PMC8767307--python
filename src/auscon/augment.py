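"""Stochastic spectrogram augmentations for contrastive view generation.

Five schemes: splitting (keep a random contiguous half of the data region),
time masking, frequency masking, combined spectrogram masking, and masking
followed by splitting.  Masking zeroes a fixed number of bands (5 along time,
2 along frequency by default) placed uniformly at random strictly inside the
non-padded region; padding frames are never touched.  Band widths are
calibrated so each scheme's expected masked fraction of the data region hits
a target (50% by default), with bands placed independently so overlaps are
allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .signal_io import Spectrogram

AUGMENTATION_SCHEMES = ("split", "time_mask", "freq_mask", "spec_mask",
                        "spec_mask_split")


@dataclass(frozen=True)
class MaskSpec:
    """Band counts, widths (as fractions of the data region) and target coverage."""

    n_time_bands: int = 5
    n_freq_bands: int = 2
    time_band_width: float = 0.1
    freq_band_width: float = 0.25
    target_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.n_time_bands < 1 or self.n_freq_bands < 1:
            raise ValueError("band counts must be >= 1")
        for w in (self.time_band_width, self.freq_band_width):
            if not 0.0 <= w < 1.0:
                raise ValueError("band widths must lie in [0, 1)")
        if not 0.0 <= self.target_coverage < 1.0:
            raise ValueError("target_coverage must lie in [0, 1)")


def _band_frames(width_fraction: float, region: int) -> int:
    """Band width in cells, rounded half-up; saturation at the region is allowed."""
    b = int(math.floor(width_fraction * region + 0.5))
    if b > region:
        raise ValueError(f"band of {b} cells exceeds data region of {region}")
    return b


def _draw_band_mask(region: int, n_bands: int, band: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Boolean union of n_bands independent uniformly placed bands."""
    mask = np.zeros(region, dtype=bool)
    if band == 0:
        return mask
    starts = rng.integers(0, region - band + 1, size=n_bands)
    for s in starts:
        mask[s:s + band] = True
    return mask


def split(spec: Spectrogram, rng: np.random.Generator) -> Spectrogram:
    """Keep a uniformly random contiguous half of the data region, re-centered.

    The surviving half has floor(data/2) frames (at least 1); the output keeps
    the input's total frame count, with the half re-centered between zeros
    (odd deficit padded on the right).
    """
    region = spec.n_data_frames
    if region < 2:
        raise ValueError("split needs a data region of at least 2 frames")
    half = max(region // 2, 1)
    start = int(rng.integers(0, region - half + 1))
    data = spec.data[:, start:start + half]
    total = spec.n_frames_total
    deficit = total - half
    pad_left = deficit // 2
    values = np.zeros_like(spec.values)
    values[:, pad_left:pad_left + half] = data
    return Spectrogram(values=values, pad_left=pad_left,
                       pad_right=deficit - pad_left)


def time_mask(spec: Spectrogram, m: MaskSpec, rng: np.random.Generator) -> Spectrogram:
    """Zero n_time_bands random time bands inside the data region."""
    region = spec.n_data_frames
    if region < m.n_time_bands:
        raise ValueError("data region smaller than the number of time bands")
    band = _band_frames(m.time_band_width, region)
    mask = _draw_band_mask(region, m.n_time_bands, band, rng)
    values = spec.values.copy()
    cols = np.arange(spec.pad_left, spec.pad_left + region)[mask]
    values[:, cols] = 0.0
    return replace(spec, values=values)


def freq_mask(spec: Spectrogram, m: MaskSpec, rng: np.random.Generator) -> Spectrogram:
    """Zero n_freq_bands random frequency bands, confined to data-region frames."""
    region = spec.n_data_frames
    n_bins = spec.n_bins
    if n_bins < m.n_freq_bands:
        raise ValueError("too few frequency bins for the number of bands")
    band = _band_frames(m.freq_band_width, n_bins)
    mask = _draw_band_mask(n_bins, m.n_freq_bands, band, rng)
    values = spec.values.copy()
    values[np.ix_(np.flatnonzero(mask),
                  np.arange(spec.pad_left, spec.pad_left + region))] = 0.0
    return replace(spec, values=values)


def spec_mask(spec: Spectrogram, m: MaskSpec, rng: np.random.Generator) -> Spectrogram:
    """Time masking then frequency masking (the combined scheme)."""
    return freq_mask(time_mask(spec, m, rng), m, rng)


def spec_mask_split(spec: Spectrogram, m: MaskSpec, rng: np.random.Generator) -> Spectrogram:
    """Combined masking followed by splitting, in that order."""
    return split(spec_mask(spec, m, rng), rng)


def apply_scheme(name: str, spec: Spectrogram, m: MaskSpec,
                 rng: np.random.Generator) -> Spectrogram:
    if name == "split":
        return split(spec, rng)
    if name == "time_mask":
        return time_mask(spec, m, rng)
    if name == "freq_mask":
        return freq_mask(spec, m, rng)
    if name == "spec_mask":
        return spec_mask(spec, m, rng)
    if name == "spec_mask_split":
        return spec_mask_split(spec, m, rng)
    raise ValueError(f"unknown augmentation scheme {name!r}; "
                     f"choose from {AUGMENTATION_SCHEMES}")


# ---------------------------------------------------------------------------
# Coverage calibration
# ---------------------------------------------------------------------------

def expected_coverage(width: float, n_bands: int, grid: int = 4001) -> float:
    """Expected union coverage of n_bands iid bands of fractional ``width``.

    Continuous model on [0, 1]: each band start is uniform on [0, 1 - width],
    so edge cells are covered less often than interior ones.  Computed by
    numerical integration of 1 - (1 - p(x))^n over cell positions x.
    """
    if width <= 0.0:
        return 0.0
    if width >= 1.0:
        return 1.0
    x = np.linspace(0.0, 1.0, grid)
    # probability one band covers x: measure of starts in [x-width, x] ∩ [0, 1-width]
    cover = (np.minimum(x, 1.0 - width) - np.maximum(x - width, 0.0)) / (1.0 - width)
    cover = np.clip(cover, 0.0, 1.0)
    return float(np.trapezoid(1.0 - (1.0 - cover) ** n_bands, x))


def _solve_width(target: float, n_bands: int) -> float:
    if target <= 0.0:
        return 0.0
    max_cov = expected_coverage(1.0 - 1e-9, n_bands)
    if target >= max_cov:
        raise ValueError(
            f"target coverage {target} not achievable with {n_bands} band(s)")
    return float(brentq(lambda w: expected_coverage(w, n_bands) - target,
                        1e-12, 1.0 - 1e-9, xtol=1e-10))


def calibrate_band_widths(m: MaskSpec, scheme: str) -> MaskSpec:
    """Return a MaskSpec whose widths hit ``target_coverage`` in expectation.

    For time-only and freq-only masking the axis width solves the union
    coverage equation directly.  For the combined scheme the two axes share a
    per-axis target t with t + f - t*f = target and t = f, i.e.
    t = 1 - sqrt(1 - target); each axis width is then calibrated to t.
    """
    target = m.target_coverage
    if scheme == "time":
        return replace(m, time_band_width=_solve_width(target, m.n_time_bands))
    if scheme == "freq":
        return replace(m, freq_band_width=_solve_width(target, m.n_freq_bands))
    if scheme == "spec":
        axis_target = 1.0 - math.sqrt(1.0 - target)
        return replace(m,
                       time_band_width=_solve_width(axis_target, m.n_time_bands),
                       freq_band_width=_solve_width(axis_target, m.n_freq_bands))
    raise ValueError(f"scheme must be one of 'time', 'freq', 'spec'; got {scheme!r}")


def masked_fraction(original: Spectrogram, augmented: Spectrogram) -> float:
    """Fraction of the original's data-region cells zeroed by masking."""
    orig = original.data
    aug = augmented.values[:, original.data_slice]
    newly_zero = (aug == 0.0) & (orig != 0.0)
    nonzero = int((orig != 0.0).sum())
    if nonzero == 0:
        return 0.0
    return float(newly_zero.sum()) / nonzero
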