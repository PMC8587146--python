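"""Core containers shared across the pipeline.

A recording session is a :class:`SubjectRecord`: a fixed inventory of five
uniformly sampled channels (triaxial wrist accelerometer at 32 Hz, wrist PPG
at 64 Hz, chest ECG at 700 Hz) plus an activity label track.  Label intervals
are half-open ``[start_s, end_s)`` in seconds from recording start; sample
``i`` of a channel occurs at time ``i / rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five studied activities, in the fixed alphabetical order used for
#: integer label coding throughout the package.
ACTIVITIES: tuple[str, ...] = ("cycling", "sitting", "stairs", "table_soccer", "walking")

#: Native sampling rate of each channel in Hz, as recorded by the devices.
CHANNEL_RATES: dict[str, float] = {
    "ACC-X": 32.0,
    "ACC-Y": 32.0,
    "ACC-Z": 32.0,
    "PPG": 64.0,
    "ECG": 700.0,
}

#: Canonical channel order for feature-matrix column layout.
CHANNEL_ORDER: tuple[str, ...] = ("ACC-X", "ACC-Y", "ACC-Z", "ECG", "PPG")

CHANNEL_NAMES = frozenset(CHANNEL_RATES)


@dataclass
class ChannelSeries:
    """One uniformly sampled signal.

    Parameters
    ----------
    name
        Channel name, one of ``ACC-X/Y/Z``, ``PPG``, ``ECG``.
    rate_hz
        Sampling rate in Hz, strictly positive.
    samples
        Sample values; coerced to a float64 array and checked finite.
    """

    name: str
    rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel name {self.name!r}")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.name}: non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


def validate_labels(intervals: list[tuple[float, float, str]], duration_s: float | None = None) -> None:
    """Check that label intervals are well formed.

    Intervals must satisfy ``start < end``, be sorted, non-overlapping and
    (when ``duration_s`` is given) lie within the recording span.  Raises
    ``ValueError`` naming the offending row(s).
    """
    for i, (start, end, activity) in enumerate(intervals):
        if not start < end:
            raise ValueError(f"label row {i}: start_s {start} must be < end_s {end}")
        if start < 0:
            raise ValueError(f"label row {i}: negative start_s {start}")
        if duration_s is not None and end > duration_s + 1e-6:
            raise ValueError(
                f"label row {i}: end_s {end} exceeds recording duration {duration_s:.6f}"
            )
    for i in range(1, len(intervals)):
        if intervals[i][0] < intervals[i - 1][1]:
            raise ValueError(
                f"label rows {i - 1} and {i} overlap: "
                f"{intervals[i - 1][:2]} vs {intervals[i][:2]}"
            )


@dataclass
class SubjectRecord:
    """A subject's channel set, activity label track and identifier."""

    subject_id: str
    channels: dict[str, ChannelSeries]
    labels: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = CHANNEL_NAMES - set(self.channels)
        if missing:
            raise ValueError(f"missing channel(s): {', '.join(sorted(missing))}")
        extra = set(self.channels) - CHANNEL_NAMES
        if extra:
            raise ValueError(f"unexpected channel(s): {', '.join(sorted(extra))}")
        durations = [ch.duration_s for ch in self.channels.values()]
        # channel streams may disagree by at most one sample period of the
        # slowest channel (32 Hz)
        if max(durations) - min(durations) > 1.0 / 32.0 + 1e-9:
            raise ValueError(
                f"channel durations differ by more than one sample period: {durations}"
            )
        validate_labels(self.labels, duration_s=max(durations))

    @property
    def duration_s(self) -> float:
        return min(ch.duration_s for ch in self.channels.values())
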