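"""Synthetic multi-wavelength PPG cohorts with known ground truth.

The generator emulates a wrist-worn reflective PPG experiment: a long
relaxed baseline followed by two 2-minute physical stressors (Cold Pressor
and Hand Grip, delivered in random order) separated by 5-minute recoveries.
Sympathetic arousal is modelled through its cutaneous vasoconstriction
signature: during a stressor epoch the per-beat pulsatile (AC) amplitude
drops and its beat-to-beat variability shrinks.

Every subject is rendered as a train of smooth two-lobed pulses (systolic
plus dicrotic wrapped-Gaussian lobes in beat phase) whose inter-beat
intervals and amplitudes follow AR(1) processes, plus per-wavelength gain,
baseline wander and additive sensor noise. The exact beat-level truth
(peak/onset times, IBIs, AC amplitudes) is returned alongside the record so
every downstream stage can be scored without real data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CHANNELS, EventSchedule, PpgRecord

# Two-lobe pulse template in beat phase [0, 1): a broad systolic lobe and a
# smaller, narrower dicrotic lobe. Wrapped (von Mises) lobes keep the
# waveform periodic and continuous across beat boundaries and give the
# pre-systolic minimum a well-defined curvature.
_SYS_PHASE = 0.30
_SYS_KAPPA = 0.8
_DIC_PHASE = 0.62
_DIC_KAPPA = 4.0
_DIC_WEIGHT = 0.15


def pulse_template(phase: np.ndarray) -> np.ndarray:
    """Normalized pulse waveform on beat phase in [0, 1): min 0, max 1."""
    def lobe(mu: float, kappa: float) -> np.ndarray:
        return np.exp(kappa * (np.cos(2 * np.pi * (phase - mu)) - 1.0))

    w = lobe(_SYS_PHASE, _SYS_KAPPA) + _DIC_WEIGHT * lobe(_DIC_PHASE, _DIC_KAPPA)
    return (w - _TEMPLATE_MIN) / (_TEMPLATE_MAX - _TEMPLATE_MIN)


def _template_extrema() -> tuple[float, float]:
    phi = np.linspace(0.0, 1.0, 20001, endpoint=False)
    w = (np.exp(_SYS_KAPPA * (np.cos(2 * np.pi * (phi - _SYS_PHASE)) - 1.0))
         + _DIC_WEIGHT * np.exp(_DIC_KAPPA * (np.cos(2 * np.pi * (phi - _DIC_PHASE)) - 1.0)))
    return float(w.min()), float(w.max())


_TEMPLATE_MIN, _TEMPLATE_MAX = _template_extrema()


@dataclass
class Protocol:
    """Stressor protocol geometry, in seconds."""

    baseline_s: float = 600.0
    stressor_s: float = 120.0
    recovery_s: float = 300.0

    @property
    def duration_s(self) -> float:
        return self.baseline_s + 2 * (self.stressor_s + self.recovery_s)


@dataclass
class SimConfig:
    """Cohort simulation parameters (defaults are the study conditions)."""

    n_subjects: int = 32
    fs: float = 100.0
    heart_rate_mean: float = 70.0        # bpm, cohort mean
    heart_rate_sd: float = 4.0           # bpm, beat-to-beat sd (~50 ms IBI sd)
    subject_hr_sd: float = 6.0           # bpm, between-subject sd
    ibi_ar1: float = 0.4                 # AR(1) coefficient of the IBI series
    pulse_amplitude: float = 1.3         # mean AC amplitude before channel gain
    amplitude_sd: float = 0.30           # beat-to-beat AC sd before gain
    amplitude_ar1: float = 0.6
    # white beat-level amplitude jitter (residual micro-vasomotor and
    # measurement variability); unlike the AR component it is NOT damped
    # during stressor epochs, mirroring the irregularity floor real AC
    # series keep under vasoconstriction
    amplitude_jitter_sd: float = 0.12
    subject_amplitude_cv: float = 0.15   # between-subject amplitude spread
    channel_gains: dict = field(default_factory=lambda: {
        "green": 1.00, "blue": 0.75, "ir": 0.52, "red": 0.52})
    noise_sd: dict = field(default_factory=lambda: {
        "green": 0.05, "blue": 0.05, "ir": 0.05, "red": 0.06})
    dc_level: float = 4.0
    wander_amplitude: float = 0.5
    wander_freq: float = 0.05            # Hz
    stressor_ac_drop: float = 0.2        # fractional AC-mean reduction in stressor
    stressor_regularity_gain: float = 0.5  # fractional AC-innovation-sd reduction
    protocol: Protocol = field(default_factory=Protocol)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (50.0 <= self.heart_rate_mean <= 180.0):
            raise ValueError(
                f"heart_rate_mean {self.heart_rate_mean} bpm outside the "
                "physiological 50-180 bpm band")
        if self.heart_rate_sd < 0 or self.subject_hr_sd < 0:
            raise ValueError("heart-rate spreads must be non-negative")
        for name in ("ibi_ar1", "amplitude_ar1", "stressor_ac_drop",
                     "stressor_regularity_gain"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1)")
        for ch in CHANNELS:
            if ch not in self.channel_gains or ch not in self.noise_sd:
                raise ValueError(f"missing channel parameters for {ch!r}")


@dataclass
class GroundTruth:
    """Beat-level truth for one simulated subject.

    AC truth is defined on the unit-gain clean pulsatile signal: per beat,
    rendered peak value minus the preceding rendered onset value. Channel k
    sees these amplitudes scaled by its gain.
    """

    true_peak_times: np.ndarray
    true_onset_times: np.ndarray
    true_ibi_series: np.ndarray
    true_ac_series: np.ndarray
    event_schedule: EventSchedule
    clean_pulsatile: np.ndarray

    def validate(self) -> None:
        if np.any(np.diff(self.true_peak_times) <= 0):
            raise ValueError("peak times not strictly increasing")
        if np.any(np.diff(self.true_onset_times) <= 0):
            raise ValueError("onset times not strictly increasing")
        if len(self.true_onset_times) != len(self.true_peak_times) - 1:
            raise ValueError("expected one onset between each peak pair")
        # alternation: onset k lies between peak k and peak k+1
        if not np.all((self.true_onset_times > self.true_peak_times[:-1])
                      & (self.true_onset_times < self.true_peak_times[1:])):
            raise ValueError("peaks and onsets do not alternate")
        if np.any(self.true_ac_series <= 0):
            raise ValueError("ground-truth AC must be positive")


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # Counter-based substream: subject i's stream is independent of cohort
    # size, so growing the cohort never reshuffles earlier subjects.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def _make_schedule(protocol: Protocol, rng: np.random.Generator) -> EventSchedule:
    order = list(rng.permutation(["CP", "HG"]))
    t = protocol.baseline_s
    epochs = []
    for label in order:
        epochs.append((label, t, t + protocol.stressor_s))
        t += protocol.stressor_s + protocol.recovery_s
    return EventSchedule(epochs)


def _in_stressor(t: float, schedule: EventSchedule) -> bool:
    return any(onset <= t < end for _, onset, end in schedule.epochs)


def generate_subject(config: SimConfig, subject_index: int) -> tuple[PpgRecord, GroundTruth]:
    """Simulate one subject; deterministic given ``(config.seed, subject_index)``."""
    config.validate()
    if subject_index < 0 or subject_index >= max(config.n_subjects, 1):
        raise ValueError("subject_index out of range for this config")
    rng = _subject_rng(config.seed, subject_index)

    protocol = config.protocol
    duration = protocol.duration_s
    n = int(round(duration * config.fs))
    t_axis = np.arange(n) / config.fs

    schedule = _make_schedule(protocol, rng)

    # Subject-level physiology.
    hr_subject = float(np.clip(
        config.heart_rate_mean + config.subject_hr_sd * rng.standard_normal(),
        52.0, 175.0))
    ibi_mean = 60.0 / hr_subject
    ibi_sd = config.heart_rate_sd * 60.0 / hr_subject ** 2  # delta method, bpm -> s
    amp_scale = float(np.exp(config.subject_amplitude_cv * rng.standard_normal()))
    amp_mean_base = config.pulse_amplitude * amp_scale
    amp_sd_base = config.amplitude_sd * amp_scale

    # Beat-by-beat AR(1) IBI and amplitude series.
    phi_i, phi_a = config.ibi_ar1, config.amplitude_ar1
    ibi_innov = ibi_sd * math.sqrt(max(1.0 - phi_i ** 2, 0.0))
    onsets = []          # beat start times (template phase 0)
    ibis = []
    amps = []
    t_beat = float(rng.uniform(0.0, ibi_mean))
    ibi_prev = ibi_mean
    amp_prev = amp_mean_base
    mu_prev = amp_mean_base
    while True:
        ibi = ibi_mean + phi_i * (ibi_prev - ibi_mean) + ibi_innov * rng.standard_normal()
        ibi = float(np.clip(ibi, 60.0 / 180.0, 60.0 / 50.0))
        if t_beat + ibi > duration:  # only fully rendered beats enter the train
            break
        stress = _in_stressor(t_beat, schedule)
        mu = amp_mean_base * (1.0 - config.stressor_ac_drop) if stress else amp_mean_base
        sd = amp_sd_base * (1.0 - config.stressor_regularity_gain) if stress else amp_sd_base
        innov = sd * math.sqrt(max(1.0 - phi_a ** 2, 0.0))
        amp = mu + phi_a * (amp_prev - mu_prev) + innov * rng.standard_normal()
        amp = float(max(amp, 0.5 * mu))
        jitter = (config.amplitude_jitter_sd * amp_scale
                  * rng.standard_normal())
        # Floor at 50% of the regime mean: clean recordings do not show
        # near-zero beats, and it keeps every true beat above the
        # detector's 30%-of-median false-peak height criterion even after
        # low-pass attenuation of short-IBI beats.
        rendered = float(max(amp + jitter, 0.5 * mu))
        onsets.append(t_beat)
        ibis.append(ibi)
        amps.append(rendered)
        t_beat += ibi
        ibi_prev, amp_prev, mu_prev = ibi, amp, mu

    # Render the clean unit-gain pulsatile signal beat by beat.
    clean = np.zeros(n)
    for t0, ibi, amp in zip(onsets, ibis, amps):
        i0 = int(math.ceil(t0 * config.fs))
        i1 = min(int(math.ceil((t0 + ibi) * config.fs)), n)
        if i1 <= i0:
            continue
        phase = (t_axis[i0:i1] - t0) / ibi
        clean[i0:i1] = amp * pulse_template(phase)

    # Beat-level truth from the rendered signal itself.
    peak_idx = []
    for t0, ibi in zip(onsets, ibis):
        i0 = int(math.ceil(t0 * config.fs))
        i1 = min(int(math.ceil((t0 + ibi) * config.fs)), n)
        if i1 - i0 < 3:
            continue
        peak_idx.append(i0 + int(np.argmax(clean[i0:i1])))
    peak_idx = np.asarray(peak_idx, dtype=int)
    onset_idx = np.array([p0 + 1 + int(np.argmin(clean[p0 + 1:p1]))
                          for p0, p1 in zip(peak_idx[:-1], peak_idx[1:])], dtype=int)
    true_ac = clean[peak_idx[1:]] - clean[onset_idx]

    truth = GroundTruth(
        true_peak_times=peak_idx / config.fs,
        true_onset_times=onset_idx / config.fs,
        true_ibi_series=np.asarray(ibis),
        true_ac_series=true_ac,
        event_schedule=schedule,
        clean_pulsatile=clean,
    )
    truth.validate()

    data = {"time": t_axis}
    for ch in CHANNELS:
        wander_phase = rng.uniform(0.0, 2 * np.pi)
        noise = config.noise_sd[ch] * rng.standard_normal(n)
        data[ch] = (config.dc_level
                    + config.channel_gains[ch] * clean
                    + config.wander_amplitude
                    * np.sin(2 * np.pi * config.wander_freq * t_axis + wander_phase)
                    + noise)
    record = PpgRecord(fs=config.fs, data=pd.DataFrame(data),
                       subject_id=f"s{subject_index:03d}")
    return record, truth


def generate_cohort(config: SimConfig) -> list[tuple[PpgRecord, GroundTruth]]:
    """Simulate ``config.n_subjects`` independent subjects."""
    config.validate()
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def config_with_snr(config: SimConfig, snr_db: float) -> SimConfig:
    """Return a copy of ``config`` whose additive noise gives the requested
    per-channel SNR (pulsatile RMS power over noise power, in dB)."""
    clean_cfg = replace(config, noise_sd={ch: 0.0 for ch in CHANNELS},
                        wander_amplitude=0.0)
    _, truth = generate_subject(clean_cfg, 0)
    rms = float(np.sqrt(np.mean((truth.clean_pulsatile
                                 - truth.clean_pulsatile.mean()) ** 2)))
    factor = 10.0 ** (-snr_db / 20.0)
    noise = {ch: config.channel_gains[ch] * rms * factor for ch in CHANNELS}
    return replace(config, noise_sd=noise)
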