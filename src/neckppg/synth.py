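"""Synthetic neck-PPG cohort generator.

The human protocol this emulates: 140 s recordings at 75 Hz per subject —
one control (spontaneous breathing), one slow-breathing and one
breath-hold recording with three 20-30 s episodes each, and ten artifact
recordings where 20 s corruption bursts alternate with spontaneous
breathing.

The signal model is a quasi-periodic train of pulse templates placed at
jittered beat intervals, with the per-beat amplitude modulated by
respiration, slow baseline wander and white sensor noise.  During
breath-hold episodes the respiratory amplitude modulation collapses and
beat-interval variability shrinks; artifact bursts superimpose
subtype-specific corruption at a configurable artifact-to-pulse power
ratio.  This is a discriminative test harness, not a hemodynamic model:
it is designed so that envelope, variance and spectral features separate
the classes, which is the property the downstream classifiers exploit.

Annotations returned alongside each recording are exact generator truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    ARTIFACT_SUBTYPES,
    AnnotationSegment,
    Cohort,
    Recording,
    ValidationError,
)

#: Recordings per subject: control, slow_breathing, breath_hold, 10 artifacts.
SCENARIO_SEQUENCE = (
    ["control", "slow_breathing", "breath_hold"]
    + [f"artifact_{ARTIFACT_SUBTYPES[i % len(ARTIFACT_SUBTYPES)]}" for i in range(10)]
)


@dataclass
class SynthConfig:
    """Cohort-generation conditions.

    Defaults mirror the experimental protocol being emulated (140 s at
    75 Hz, 13 recordings per subject) with effect sizes chosen so classes
    are separable but not trivially noiseless: 30% respiratory amplitude
    modulation collapsing to 2% during breath-holds, and artifact bursts
    at +6 dB over the local pulse power.
    """

    n_subjects: int = 12
    fs: float = 75.0
    duration: float = 140.0
    heart_rate_range: tuple[float, float] = (55.0, 90.0)
    resp_rate_range: tuple[float, float] = (0.15, 0.35)
    resp_mod_depth: float = 0.3
    apnea_mod_depth: float = 0.02
    artifact_snr_db: float = 6.0
    noise_std: float = 0.02
    beat_jitter_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        for name in ("heart_rate_range", "resp_rate_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be a non-degenerate interval")
        if not self.apnea_mod_depth < self.resp_mod_depth:
            raise ValidationError("apnea_mod_depth must be < resp_mod_depth")


@dataclass
class SubjectParams:
    """Per-subject physiology drawn once (subject identity for LOSO)."""

    subject_id: str
    heart_rate: float        # bpm
    resp_rate: float         # Hz
    rise_time: float         # s, onset-to-systolic-peak
    pulse_width_frac: float  # template width as fraction of beat interval
    notch_depth: float       # dicrotic bump relative height
    amplitude: float         # overall pulse amplitude (a.u.)
    rng_seed: int = 0


def make_pulse_template(
    rise_time: float, width: float, notch_depth: float, fs: float
) -> np.ndarray:
    """Build a single peak-normalized PPG pulse waveform.

    The template starts at 0, rises (half-cosine) to its global maximum 1
    at ``round(rise_time*fs)``, decays back toward 0, and carries a
    secondary dicrotic bump of relative height ``notch_depth`` after the
    systolic peak.  Length is ``round(width*fs)`` samples.
    """
    if not 0 < rise_time < width:
        raise ValidationError("require 0 < rise_time < width")
    if not 0 <= notch_depth < 1:
        raise ValidationError("notch_depth must be in [0, 1)")
    n = int(round(width * fs))
    p = int(round(rise_time * fs))
    p = max(1, min(p, n - 2))
    wave = np.zeros(n)
    i = np.arange(n)
    # systolic upstroke and downstroke
    rise = i <= p
    wave[rise] = 0.5 * (1 - np.cos(np.pi * i[rise] / p))
    fall_end = p + max(2, int(round(0.5 * (n - p))))
    fall = (i > p) & (i <= fall_end)
    wave[fall] = 0.5 * (1 + np.cos(np.pi * (i[fall] - p) / (fall_end - p)))
    if notch_depth > 0:
        center = p + int(round(0.72 * (n - p)))
        half = max(1, int(round(0.14 * (n - p))))
        sel = np.abs(i - center) <= half
        wave[sel] += notch_depth * 0.5 * (1 + np.cos(np.pi * (i[sel] - center) / half))
    return wave


def _episode_starts(rng: np.random.Generator, duration: float) -> list[tuple[float, float]]:
    """Three 20-30 s episodes, one per recording third.

    The protocol places the breathing manoeuvres at three separate
    moments of the recording; anchoring one episode inside each third
    (with >= 4 s spontaneous-breathing margins) also guarantees that
    every segment of the recording-thirds partition contains both apnea
    and normal windows.
    """
    episodes = []
    third = duration / 3.0
    for k in range(3):
        length = rng.uniform(20.0, 30.0)
        start = k * third + rng.uniform(4.0, third - length - 4.0)
        episodes.append((start, start + length))
    return episodes


def _artifact_waveform(
    rng: np.random.Generator, subtype: str, n: int, fs: float
) -> np.ndarray:
    """Schematic corruption waveform for one artifact burst (unit-power)."""
    t = np.arange(n) / fs
    if subtype in ("talking", "coughing", "fast_breathing"):
        # band-limited noise burst with irregular amplitude bursts
        x = rng.standard_normal(n)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [1.0, 10.0], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
        gate = 0.4 + np.abs(np.sin(2 * np.pi * rng.uniform(0.3, 1.2) * t + rng.uniform(0, 6)))
        x = x * gate
    elif subtype in ("head_movement", "body_movement", "swallowing"):
        # step / ramp excursions at random change points
        x = np.zeros(n)
        n_steps = rng.integers(3, 7)
        points = np.sort(rng.integers(0, n, size=n_steps))
        level = 0.0
        prev = 0
        for pt in points:
            x[prev:pt] = level
            level = rng.uniform(-2.0, 2.0)
            prev = pt
        x[prev:] = level
        ramp = np.linspace(0, rng.uniform(-1, 1), n)
        x = x + ramp + 0.3 * rng.standard_normal(n)
    else:  # yawning, sensor_rubbing: large low-frequency oscillation
        f = rng.uniform(0.3, 0.9)
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 6))
        x = x * (1 + 0.5 * np.sin(2 * np.pi * 0.1 * t))
        x = x + 0.2 * rng.standard_normal(n)
    power = float(np.mean(x**2))
    return x / np.sqrt(power) if power > 0 else x


def synth_recording(
    cfg: SynthConfig,
    subject: SubjectParams,
    scenario: str,
    recording_id: str | None = None,
    variant: int = 0,
) -> tuple[Recording, list[AnnotationSegment]]:
    """Generate one annotated 140 s recording for a given scenario.

    ``breath_hold`` and ``slow_breathing`` place three 20-30 s episodes
    (annotated ``apnea`` / ``slow_breathing``); ``artifact_<subtype>``
    corrupts the fixed alternating bursts [20,40), [60,80), [100,120) s at
    ``cfg.artifact_snr_db`` over the local pulse power.  Unannotated time
    is implicitly ``normal``.
    """
    known = {"control", "slow_breathing", "breath_hold"}
    is_artifact = scenario.startswith("artifact_")
    if scenario not in known and not is_artifact:
        raise ValidationError(f"unknown scenario {scenario!r}")
    if is_artifact and scenario[len("artifact_"):] not in ARTIFACT_SUBTYPES:
        raise ValidationError(f"unknown artifact subtype in {scenario!r}")

    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=cfg.seed,
            spawn_key=(subject.rng_seed, SCENARIO_KEYS[scenario], variant),
        )
    )
    fs, duration = cfg.fs, cfg.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    annotations: list[AnnotationSegment] = []
    episodes: list[tuple[float, float]] = []
    if scenario == "breath_hold":
        episodes = _episode_starts(rng, duration)
        annotations = [AnnotationSegment(a, b, "apnea") for a, b in episodes]
    elif scenario == "slow_breathing":
        episodes = _episode_starts(rng, duration)
        annotations = [AnnotationSegment(a, b, "slow_breathing") for a, b in episodes]
    elif is_artifact:
        episodes = [(20.0, 40.0), (60.0, 80.0), (100.0, 120.0)]
        subtype = scenario[len("artifact_"):]
        annotations = [AnnotationSegment(a, b, scenario) for a, b in episodes]

    def in_episode(time: float) -> bool:
        return any(a <= time < b for a, b in episodes)

    # --- pulse train with respiratory amplitude modulation -------------
    base_interval = 60.0 / subject.heart_rate
    width = subject.pulse_width_frac * base_interval
    template = make_pulse_template(
        min(subject.rise_time, 0.45 * width), width, subject.notch_depth, fs
    )
    signal = np.zeros(n)
    resp_phase = 0.0
    beat_t = float(rng.uniform(0, base_interval / 2))
    prev_t = 0.0
    while beat_t < duration:
        dt = beat_t - prev_t
        f_resp = subject.resp_rate
        depth = cfg.resp_mod_depth
        if scenario == "slow_breathing" and in_episode(beat_t):
            f_resp = subject.resp_rate / 2.0
        if scenario == "breath_hold" and in_episode(beat_t):
            depth = cfg.apnea_mod_depth
        resp_phase += 2 * np.pi * f_resp * dt
        amp = subject.amplitude * (1 + depth * np.sin(resp_phase))
        start = int(round(beat_t * fs))
        seg = template[: n - start]
        if seg.size:
            signal[start : start + seg.size] += amp * seg
        jitter_cv = cfg.beat_jitter_cv
        if scenario == "breath_hold" and in_episode(beat_t):
            jitter_cv *= 0.3  # steadier rhythm during breath-hold
        jitter = rng.lognormal(mean=0.0, sigma=jitter_cv)
        prev_t = beat_t
        beat_t += base_interval * jitter

    # slow baseline wander + sensor noise
    signal += 0.05 * subject.amplitude * np.sin(
        2 * np.pi * rng.uniform(0.04, 0.09) * t + rng.uniform(0, 6)
    )
    signal += cfg.noise_std * rng.standard_normal(n)

    # --- artifact bursts ------------------------------------------------
    if is_artifact:
        subtype = scenario[len("artifact_"):]
        gain = 10.0 ** (cfg.artifact_snr_db / 10.0)
        for a, b in episodes:
            i0, i1 = int(round(a * fs)), int(round(b * fs))
            clean_power = float(np.mean(signal[i0:i1] ** 2))
            burst = _artifact_waveform(rng, subtype, i1 - i0, fs)
            signal[i0:i1] += np.sqrt(gain * clean_power) * burst

    rec = Recording(
        subject_id=subject.subject_id,
        recording_id=recording_id or f"{subject.subject_id}_{scenario}",
        scenario=scenario,
        fs=fs,
        samples=signal,
    )
    return rec, annotations


#: Stable per-scenario spawn keys so streams are independent per recording.
SCENARIO_KEYS = {s: i for i, s in enumerate(
    ["control", "slow_breathing", "breath_hold"]
    + [f"artifact_{sub}" for sub in ARTIFACT_SUBTYPES]
)}


def draw_subject_params(cfg: SynthConfig, index: int) -> SubjectParams:
    """Sample one subject's physiology from the cohort ranges."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1000 + index,))
    )
    return SubjectParams(
        subject_id=f"S{index:02d}",
        heart_rate=float(rng.uniform(*cfg.heart_rate_range)),
        resp_rate=float(rng.uniform(*cfg.resp_rate_range)),
        rise_time=float(rng.uniform(0.12, 0.18)),
        pulse_width_frac=float(rng.uniform(0.75, 0.9)),
        notch_depth=float(rng.uniform(0.08, 0.3)),
        amplitude=float(rng.uniform(0.8, 1.2)),
        rng_seed=index,
    )


def synth_cohort(cfg: SynthConfig) -> Cohort:
    """Generate the full cohort: 13 recordings per subject.

    Per subject: 1 control + 1 slow_breathing + 1 breath_hold + 10
    artifact recordings cycling the 8 subtypes.  Fully reproducible from
    ``cfg.seed``.
    """
    recordings: list[Recording] = []
    annotations: dict[str, list[AnnotationSegment]] = {}
    for idx in range(cfg.n_subjects):
        subject = draw_subject_params(cfg, idx)
        for r, scenario in enumerate(SCENARIO_SEQUENCE):
            rid = f"{subject.subject_id}_r{r:02d}"
            # 10 artifact recordings cycle 8 subtypes: the two repeated
            # subtypes get variant=1 so their noise streams differ
            variant = 1 if r >= 11 else 0
            rec, segs = synth_recording(
                cfg, subject, scenario, recording_id=rid, variant=variant
            )
            recordings.append(rec)
            annotations[rid] = segs
    return Cohort(recordings=recordings, annotations=annotations)
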