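"""Up-sampling and label-pure windowing across multi-rate channels.

The 32 Hz wrist accelerometer is brought to the PPG's 64 Hz by pairwise
averaging: each original sample is kept and the midpoint of every
consecutive pair is inserted after it (the final inserted slot, which has
no successor, repeats the last sample).  The 700 Hz chest ECG is left
untouched.

Windowing then tiles each label interval from its start in non-overlapping
steps of the window length; a tail window that would cross the interval end
is discarded, so every window is label-pure by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ACTIVITIES, ChannelSeries, SubjectRecord

#: Channels up-sampled to 64 Hz before windowing.
UPSAMPLE_TARGETS = ("ACC-X", "ACC-Y", "ACC-Z")


def upsample_by_pairwise_average(samples: np.ndarray, rate_hz: float | None = None) -> np.ndarray:
    """Double a signal's rate by inserting consecutive-pair averages.

    Output length is exactly twice the input length: even indices carry the
    original samples, odd index ``2i + 1`` carries ``(x[i] + x[i+1]) / 2``,
    and the final odd slot repeats the last sample.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot up-sample an empty sequence")
    out = np.empty(2 * x.size, dtype=np.float64)
    out[0::2] = x
    out[1:-1:2] = 0.5 * (x[:-1] + x[1:])
    out[-1] = x[-1]
    return out


def upsample_record(record: SubjectRecord) -> SubjectRecord:
    """Return a copy with ACC channels up-sampled 32 → 64 Hz."""
    channels = {}
    for name, ch in record.channels.items():
        if name in UPSAMPLE_TARGETS and ch.rate_hz == 32.0:
            channels[name] = ChannelSeries(name, 64.0, upsample_by_pairwise_average(ch.samples))
        else:
            channels[name] = ch
    out = SubjectRecord.__new__(SubjectRecord)
    out.subject_id = record.subject_id
    out.channels = channels
    out.labels = list(record.labels)
    return out


@dataclass
class Window:
    """One label-pure segment: aligned per-channel sample blocks."""

    window_id: int
    activity: str
    start_s: float
    blocks: dict[str, np.ndarray]


@dataclass
class WindowSet:
    """An ordered collection of uniform-duration windows."""

    window_seconds: float
    channel_rates: dict[str, float]
    windows: list[Window] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def extract_windows(
    record: SubjectRecord,
    window_seconds: float = 7.0,
    allowed_activities: tuple[str, ...] = ACTIVITIES,
) -> WindowSet:
    """Cut non-overlapping, label-pure windows from an up-sampled record.

    Expects ACC channels already at 64 Hz.  Windows tile each label interval
    from its start; tails shorter than ``window_seconds`` are dropped, as are
    intervals whose activity is not in ``allowed_activities``.  A window too
    long for every interval yields an empty WindowSet (not an error).
    """
    if not window_seconds > 0:
        raise ValueError("window_seconds must be > 0")
    for name in UPSAMPLE_TARGETS:
        if record.channels[name].rate_hz != 64.0:
            raise ValueError(
                f"channel {name} is at {record.channels[name].rate_hz} Hz; "
                "up-sample to 64 Hz before windowing (see upsample_record)"
            )

    rates = {name: ch.rate_hz for name, ch in record.channels.items()}
    block_len = {name: int(round(window_seconds * r)) for name, r in rates.items()}

    ws = WindowSet(window_seconds=window_seconds, channel_rates=rates)
    wid = 0
    for start, end, activity in record.labels:
        if activity not in allowed_activities:
            continue
        k = 0
        while start + (k + 1) * window_seconds <= end + 1e-9:
            w_start = start + k * window_seconds
            blocks = {}
            ok = True
            for name, ch in record.channels.items():
                i0 = int(round(w_start * ch.rate_hz))
                i1 = i0 + block_len[name]
                if i1 > len(ch.samples):
                    ok = False
                    break
                blocks[name] = ch.samples[i0:i1]
            if ok:
                ws.windows.append(Window(wid, activity, w_start, blocks))
                wid += 1
            k += 1
    return ws
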