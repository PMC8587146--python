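"""Windowed time- and frequency-domain feature extraction.

Seven time-domain statistics and eight frequency-domain features are
computed per channel per window, 15 columns per channel and 75 for the full
five-channel inventory.  Column names follow ``{signal}.{time|freq}.{feature}``.

Conventions that matter downstream:

* the one-sided amplitude spectrum is normalized so the DC bin equals the
  window's time-domain mean (``|X_0|/N``; other bins ``2|X_k|/N``, with the
  Nyquist bin of an even-length window not doubled);
* for accelerometer channels gravity makes the DC bin the global spectral
  maximum, so the peak feature is the *second max* (the largest non-DC
  amplitude when DC dominates, otherwise the second-largest overall) and
  the dominant frequency is that bin's frequency;
* for bio-signals (ECG, PPG) the peak feature is the plain global maximum
  and the dominant frequency its bin;
* crossing counts use one rule everywhere: strict sign changes between
  consecutive values, a zero adopting the previous nonzero sign;
* all standard deviations are population (``ddof=0``) standard deviations;
* spectral ties are broken toward the lowest frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import WindowSet
from .types import CHANNEL_ORDER

ACC_CHANNELS = ("ACC-X", "ACC-Y", "ACC-Z")


@dataclass
class Spectrum:
    """One-sided amplitude spectrum; ``frequencies_hz[0]`` is the DC bin."""

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray


def crossing_count(x: np.ndarray) -> int:
    """Count strict sign changes between consecutive samples.

    A zero sample adopts the most recent nonzero sign (leading zeros carry
    no sign and cannot produce a crossing).
    """
    s = np.sign(np.asarray(x, dtype=np.float64))
    nz = s != 0
    if not nz.any():
        return 0
    # forward-fill signs over zeros
    idx = np.where(nz, np.arange(s.size), -1)
    idx = np.maximum.accumulate(idx)
    valid = idx >= 0
    filled = s[idx[valid]]
    return int(np.count_nonzero(np.diff(filled) != 0))


def time_domain_features(samples: np.ndarray) -> dict[str, float]:
    """The seven time-domain statistics of one window block."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("time-domain features require at least 2 samples")
    mean = float(np.mean(x))
    return {
        "mean": mean,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
        "std": float(np.std(x)),
        "zero_crossings": float(crossing_count(x)),
        "mean_crossings": float(crossing_count(x - mean)),
    }


def amplitude_spectrum(samples: np.ndarray, rate_hz: float) -> Spectrum:
    """One-sided FFT amplitude spectrum with mean-preserving normalization."""
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("spectrum requires at least 2 samples")
    amp = np.abs(np.fft.rfft(x)) / n
    amp[1:] *= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0  # Nyquist bin appears once; do not double it
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return Spectrum(frequencies_hz=freqs, amplitudes=amp)


def frequency_domain_features(spectrum: Spectrum, kind: str) -> dict[str, float]:
    """The eight frequency-domain features of one spectrum.

    ``kind`` is ``"ACC"`` (second-max convention) or ``"BIO"`` (global-max
    convention).  Statistics run over all bins including DC.
    """
    if kind not in ("ACC", "BIO"):
        raise ValueError(f"kind must be 'ACC' or 'BIO', got {kind!r}")
    amp = np.asarray(spectrum.amplitudes, dtype=np.float64)
    freqs = np.asarray(spectrum.frequencies_hz, dtype=np.float64)
    if amp.size < 3:
        raise ValueError("frequency features require at least 3 spectral bins")

    out = {
        "mean": float(np.mean(amp)),
        "min": float(np.min(amp)),
        "std": float(np.std(amp)),
        "median": float(np.median(amp)),
        "mean_crossings": float(crossing_count(amp - np.mean(amp))),
        "dc_component": float(amp[0]),
    }

    # np.argmax returns the first occurrence, i.e. the lowest-frequency bin
    # among ties — the documented tie rule.
    i_max = int(np.argmax(amp))
    if kind == "BIO":
        out["max"] = float(amp[i_max])
        out["dominant_frequency"] = float(freqs[i_max])
        return out

    if i_max == 0:
        # DC (gravity) is the global maximum: peak over the non-DC bins
        i_second = 1 + int(np.argmax(amp[1:]))
    else:
        masked = amp.copy()
        masked[i_max] = -np.inf
        i_second = int(np.argmax(masked))
    out["second_max"] = float(amp[i_second])
    out["dominant_frequency"] = float(freqs[i_second])
    return out


def channel_kind(channel: str) -> str:
    return "ACC" if channel in ACC_CHANNELS else "BIO"


def window_features(blocks: dict[str, np.ndarray], rates: dict[str, float]) -> dict[str, float]:
    """All 75 named features of one window (15 per channel)."""
    row: dict[str, float] = {}
    for ch in CHANNEL_ORDER:
        if ch not in blocks:
            raise ValueError(f"window is missing channel {ch}")
        block = blocks[ch]
        for name, value in time_domain_features(block).items():
            row[f"{ch}.time.{name}"] = value
        spec = amplitude_spectrum(block, rates[ch])
        for name, value in frequency_domain_features(spec, channel_kind(ch)).items():
            row[f"{ch}.freq.{name}"] = value
    return row


def build_feature_matrix(windows: WindowSet, subject_id: str | None = None) -> pd.DataFrame:
    """Assemble the windows × features matrix for one subject.

    Row order follows window order; each row carries ``window_id`` and
    ``activity`` (plus ``subject_id`` when given) ahead of the 75 feature
    columns.
    """
    rows = []
    for w in windows:
        wid = f"{subject_id}.w{w.window_id:04d}" if subject_id else f"w{w.window_id:04d}"
        row: dict[str, object] = {"window_id": wid, "activity": w.activity}
        if subject_id is not None:
            row["subject_id"] = subject_id
        row.update(window_features(w.blocks, windows.channel_rates))
        rows.append(row)
    if not rows:
        meta = ["window_id", "activity"] + (["subject_id"] if subject_id else [])
        return pd.DataFrame(columns=meta)
    cols = list(rows[0].keys())
    return pd.DataFrame(rows, columns=cols)
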