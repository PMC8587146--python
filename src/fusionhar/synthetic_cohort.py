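"""Synthetic multi-subject ACC/ECG/PPG cohort generator.

Generates labeled wearable-sensor recordings with the statistical structure
the downstream analysis assumes: a wrist triaxial accelerometer (32 Hz)
carrying a constant 1 g gravity component plus activity-dependent motion
sinusoids, a chest ECG (700 Hz) as a train of Gaussian-shaped R peaks whose
rate follows the activity's heart-rate signature, and a wrist PPG (64 Hz)
pulse wave at the same heart rate corrupted by motion artifacts proportional
to instantaneous acceleration magnitude.

The default activity profiles encode the qualitative premises the analysis
probes: walking and stair climbing share overlapping motion spectra and
amplitudes (hard to tell apart from the accelerometer alone) but differ in
mean heart rate by 25 bpm; sitting has near-zero motion and the lowest heart
rate.  Waveforms are stylized rather than physiological — the pipeline
consumes only windowed statistics, so Gaussian R peaks and a two-harmonic
pulse wave carry all the information the features can see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_rng, derive_seed
from .types import ChannelSeries, SubjectRecord

#: Resting heart rate anchoring the exertion model, in bpm.  A subject's
#: rate for an activity is ``rest + offset + (profile_mean - rest) / fitness``.
REST_BPM = 65.0

# Gravity direction (unit vector, in g) per activity: wrist orientation
# differs between postures; walking and stairs are deliberately close.
_ORIENTATIONS = {
    "sitting": (0.10, 0.20, 0.97),
    "walking": (0.30, 0.60, 0.74),
    "stairs": (0.34, 0.56, 0.75),
    "table_soccer": (0.55, 0.45, 0.70),
    "cycling": (0.70, 0.40, 0.59),
}

_ECG_SIGMA_S = 0.02  # R-peak Gaussian width
_ECG_NOISE_SD = 0.03
_PPG_NOISE_SD = 0.05
# Motion-artifact mix: a small deterministic tone at the motion fundamental
# plus dominant motion-modulated broadband noise (artifacts scramble the
# pulse rather than copying the accelerometer into the PPG).  Motion also
# degrades optical coupling, shrinking the cardiac pulse itself.
_ARTIFACT_TONE = 0.1
_ARTIFACT_NOISE_MAX = 1.2  # broadband artifact sd at full saturation
_ARTIFACT_KNEE = 0.08  # rms motion (g) at which artifact noise saturates
_PERFUSION_LOSS = 12.0  # pulse amplitude gain = 1 / (1 + loss * rms motion)
_HARMONIC_FRACTION = 0.35  # second-harmonic amplitude relative to fundamental
_CADENCE_JITTER_SD = 0.045  # per-subject relative spread of motion fundamentals


@dataclass(frozen=True)
class ActivityProfile:
    """Generative parameters for one activity.

    ``artifact_coupling`` is the dimensionless gain converting instantaneous
    dynamic acceleration magnitude (in g) into additive PPG corruption.
    """

    activity_name: str
    motion_fundamental_hz: float
    motion_amplitude_g: tuple[float, float, float]
    motion_noise_sd_g: float
    heart_rate_mean_bpm: float
    heart_rate_sd_bpm: float
    artifact_coupling: float

    def __post_init__(self) -> None:
        if self.motion_fundamental_hz < 0:
            raise ValueError("motion_fundamental_hz must be >= 0")
        if not 40.0 <= self.heart_rate_mean_bpm <= 220.0:
            raise ValueError("heart_rate_mean_bpm must lie in [40, 220]")
        if self.heart_rate_sd_bpm < 0 or self.motion_noise_sd_g < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiological and biomechanical modifiers."""

    subject_id: str
    baseline_hr_offset_bpm: float = 0.0
    motion_amplitude_scale: float = 1.0
    fitness_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.motion_amplitude_scale <= 0:
            raise ValueError("motion_amplitude_scale must be > 0")
        if self.fitness_factor <= 0:
            raise ValueError("fitness_factor must be > 0")


Protocol = list[tuple[str, float]]


def default_profiles() -> dict[str, ActivityProfile]:
    """Activity profiles for the five studied activities.

    Designed orderings: sitting has the minimum heart rate and near-zero
    motion; walking and stairs have fundamentals 0.1 Hz apart with similar
    per-axis amplitudes but heart rates 25 bpm apart.
    """
    return {
        "sitting": ActivityProfile(
            "sitting", 0.0, (0.01, 0.01, 0.01), 0.02, 65.0, 3.0, 0.5
        ),
        "walking": ActivityProfile(
            "walking", 1.9, (0.22, 0.40, 0.32), 0.08, 95.0, 5.0, 0.8
        ),
        "stairs": ActivityProfile(
            "stairs", 2.05, (0.25, 0.45, 0.35), 0.08, 120.0, 7.0, 0.8
        ),
        "table_soccer": ActivityProfile(
            "table_soccer", 2.8, (0.30, 0.20, 0.35), 0.15, 82.0, 6.0, 0.8
        ),
        "cycling": ActivityProfile(
            "cycling", 1.2, (0.12, 0.18, 0.15), 0.06, 108.0, 6.0, 0.8
        ),
    }


def default_protocol(per_activity_s: float = 120.0) -> Protocol:
    """One contiguous bout of each studied activity (default 120 s each)."""
    order = ("sitting", "stairs", "table_soccer", "cycling", "walking")
    return [(a, float(per_activity_s)) for a in order]


def _validate_protocol(protocol: Protocol, profiles: dict[str, ActivityProfile]) -> None:
    if not protocol:
        raise ValueError("protocol must be non-empty")
    for activity, dur in protocol:
        if activity not in profiles:
            raise ValueError(f"unknown activity in protocol: {activity!r}")
        if not dur > 0:
            raise ValueError(f"protocol duration for {activity!r} must be > 0")


def _subject_hr(profile: ActivityProfile, params: SubjectParams) -> float:
    hr = (
        REST_BPM
        + params.baseline_hr_offset_bpm
        + (profile.heart_rate_mean_bpm - REST_BPM) / params.fitness_factor
    )
    return float(np.clip(hr, 40.0, 220.0))


def _motion_axes(
    t: np.ndarray,
    profile: ActivityProfile,
    params: SubjectParams,
    freq_hz: float,
    phases: np.ndarray,
) -> np.ndarray:
    """Noise-free dynamic acceleration (3, len(t)) for one segment, in g."""
    out = np.empty((3, t.size))
    for ax in range(3):
        amp = profile.motion_amplitude_g[ax] * params.motion_amplitude_scale
        out[ax] = amp * np.sin(2 * np.pi * freq_hz * t + phases[ax]) + (
            _HARMONIC_FRACTION * amp * np.sin(4 * np.pi * freq_hz * t + phases[3 + ax])
        )
    return out


def simulate_subject(
    params: SubjectParams,
    protocol: Protocol,
    profiles: dict[str, ActivityProfile] | None = None,
    seed: int = 0,
) -> SubjectRecord:
    """Simulate one subject's five-channel recording for a protocol.

    Identical ``(params, protocol, profiles, seed)`` yield a bit-identical
    record.  Raises ``ValueError`` for an unknown activity in the protocol.
    """
    profiles = profiles if profiles is not None else default_profiles()
    _validate_protocol(protocol, profiles)
    rng = derive_rng(seed)

    # subject-level draws: characteristic cadence and wrist orientation per
    # activity (drawn in fixed alphabetical order for reproducibility)
    cadence: dict[str, float] = {}
    orientation: dict[str, np.ndarray] = {}
    for activity in sorted(profiles):
        cadence[activity] = 1.0 + _CADENCE_JITTER_SD * rng.standard_normal()
        g = np.asarray(_ORIENTATIONS.get(activity, (0.0, 0.0, 1.0)), dtype=float)
        g = g + 0.05 * rng.standard_normal(3)
        orientation[activity] = g / np.linalg.norm(g)

    acc = [[], [], []]  # per-axis 32 Hz blocks
    ppg_blocks = []
    labels: list[tuple[float, float, str]] = []

    total_s = sum(d for _, d in protocol)
    n_ecg_total = int(round(total_s * 700.0))
    ecg = np.zeros(n_ecg_total)

    t0 = 0.0
    ppg_phase = 0.0
    next_beat_s = 0.0
    for activity, dur in protocol:
        profile = profiles[activity]
        freq = profile.motion_fundamental_hz * cadence[activity]
        hr = _subject_hr(profile, params)
        labels.append((t0, t0 + dur, activity))

        phases = rng.uniform(0, 2 * np.pi, size=6)

        # --- accelerometer at 32 Hz ---
        n32 = int(round(dur * 32.0))
        t32 = t0 + np.arange(n32) / 32.0
        motion32 = _motion_axes(t32 - t0, profile, params, freq, phases)
        for ax in range(3):
            acc[ax].append(
                orientation[activity][ax]
                + motion32[ax]
                + rng.normal(0.0, profile.motion_noise_sd_g, n32)
            )

        # --- ECG at 700 Hz: Gaussian R-peak train, per-beat RR jitter ---
        seg_end = t0 + dur
        while next_beat_s < seg_end:
            hr_beat = float(np.clip(rng.normal(hr, profile.heart_rate_sd_bpm), 40.0, 220.0))
            center = next_beat_s
            lo = max(0, int((center - 5 * _ECG_SIGMA_S) * 700.0))
            hi = min(n_ecg_total, int((center + 5 * _ECG_SIGMA_S) * 700.0) + 1)
            if lo < hi:
                tt = np.arange(lo, hi) / 700.0
                ecg[lo:hi] += np.exp(-0.5 * ((tt - center) / _ECG_SIGMA_S) ** 2)
            next_beat_s += 60.0 / hr_beat

        # --- PPG at 64 Hz: two-harmonic pulse wave + motion artifact ---
        n64 = int(round(dur * 64.0))
        t64 = t0 + np.arange(n64) / 64.0
        # slowly varying instantaneous HR (control point every ~5 s)
        n_cp = max(2, int(np.ceil(dur / 5.0)) + 1)
        cp_t = np.linspace(0.0, dur, n_cp)
        cp_v = rng.normal(hr, profile.heart_rate_sd_bpm, n_cp)
        hr_t = np.interp(t64 - t0, cp_t, cp_v)
        phase = ppg_phase + np.cumsum(hr_t / 60.0) / 64.0
        ppg_phase = float(phase[-1]) if n64 else ppg_phase
        pulse = np.sin(2 * np.pi * phase) + 0.3 * np.sin(4 * np.pi * phase)
        motion64 = _motion_axes(t64 - t0, profile, params, freq, phases)
        acc_mag = np.sqrt((motion64**2).sum(axis=0))
        rms_mag = float(np.sqrt(np.mean(acc_mag**2)))
        pulse *= 1.0 / (1.0 + _PERFUSION_LOSS * rms_mag)
        noise_sd = _ARTIFACT_NOISE_MAX * np.tanh(rms_mag / _ARTIFACT_KNEE)
        artifact = profile.artifact_coupling * (
            _ARTIFACT_TONE * acc_mag + noise_sd * rng.standard_normal(n64)
        )
        ppg_blocks.append(pulse + artifact + rng.normal(0.0, _PPG_NOISE_SD, n64))

        t0 = seg_end

    ecg += rng.normal(0.0, _ECG_NOISE_SD, n_ecg_total)

    channels = {
        "ACC-X": ChannelSeries("ACC-X", 32.0, np.concatenate(acc[0])),
        "ACC-Y": ChannelSeries("ACC-Y", 32.0, np.concatenate(acc[1])),
        "ACC-Z": ChannelSeries("ACC-Z", 32.0, np.concatenate(acc[2])),
        "PPG": ChannelSeries("PPG", 64.0, np.concatenate(ppg_blocks)),
        "ECG": ChannelSeries("ECG", 700.0, ecg),
    }
    return SubjectRecord(subject_id=params.subject_id, channels=channels, labels=labels)


def draw_subject_params(n_subjects: int, seed: int) -> list[SubjectParams]:
    """Draw per-subject parameters from the configured population ranges.

    Heart-rate offsets are Gaussian (sd 6 bpm); amplitude scale and fitness
    are lognormal around 1 (sd 0.18 and 0.12 on the log scale).
    """
    rng = derive_rng(seed, 0)
    out = []
    for i in range(n_subjects):
        out.append(
            SubjectParams(
                subject_id=f"S{i + 1:02d}",
                baseline_hr_offset_bpm=float(rng.normal(0.0, 4.0)),
                motion_amplitude_scale=float(np.clip(np.exp(rng.normal(0.0, 0.12)), 0.5, 2.0)),
                fitness_factor=float(np.exp(rng.normal(0.0, 0.10))),
            )
        )
    return out


def simulate_cohort(
    n_subjects: int,
    protocol: Protocol | None = None,
    profiles: dict[str, ActivityProfile] | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate a cohort of mutually distinct subjects.

    Requires ``n_subjects >= 2`` (leave-one-subject-out evaluation is
    undefined for a single subject).  Per-subject seeds derive from the
    master seed, so the cohort is a pure function of ``(inputs, seed)``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (LOSO requires at least two subjects)")
    protocol = protocol if protocol is not None else default_protocol()
    profiles = profiles if profiles is not None else default_profiles()
    params = draw_subject_params(n_subjects, seed)
    return [
        simulate_subject(p, protocol, profiles, seed=derive_seed(seed, 1, i))
        for i, p in enumerate(params)
    ]
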