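"""Synthetic EEG cohorts with controllable ERN/CRA structure.

The generator emulates the study conditions every downstream stage assumes:
a 32-channel 10-20 montage sampled at 500 Hz, 48 trials per subject (18
short-window failure trials eliciting an ERN, 4 unpredictable catch trials,
26 long-window success trials eliciting a CRA), event-related templates whose
ERN-minus-CRA difference at Fz peaks at -5.9 uV near 208 ms and +5.7 uV near
340 ms with a central scalp topography, 1/f background noise with optional
10 Hz alpha bump and 50 Hz line interference, and ~6 % trial attrition.

Event-related peaks are Gaussian bumps, so every extremum is analytically
known; peak amplitudes are parameterised as the value observed *at Fz* (the
electrode all downstream statistics read), and the spatial projection
scales other channels by their topographic gain relative to Fz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ernbci.io_core import (
    CHANNELS_32,
    EventList,
    Recording,
    ValidationError,
    condition_for_duration,
    standard_montage,
    window_n_samples,
)

logger = logging.getLogger("ernbci")

FS_RAW = 500.0          # acquisition rate (Hz)
EPOCH_WINDOW_MS = (-100.0, 800.0)

#: great-circle angle of Fz from the vertex (radians); the topographic
#: Gaussian width is chosen so the gain at Fz is exactly 0.9.
_FZ_ANGLE = np.deg2rad(36.0)
TOPO_SIGMA_RAD = _FZ_ANGLE / np.sqrt(2.0 * np.log(1.0 / 0.9))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class ProtocolSpec:
    """Trial schedule of one recording session.

    Durations: short trials draw from U(2, 4) s and force failure (ERN),
    catch trials from U(9, 10) s, long trials are fixed 15 s successes (CRA).
    Segment timings cover the fixation cross, exercise video, 3-2-1 timer and
    the post-trial gap.
    """

    n_trials: int = 48
    n_short: int = 18
    n_catch: int = 4
    n_long: int = 26
    short_band_s: tuple[float, float] = (2.0, 4.0)
    catch_band_s: tuple[float, float] = (9.0, 10.0)
    long_duration_s: float = 15.0
    fixation_s: float = 1.0
    video_s: float = 3.0
    timer_s: float = 3.0
    post_s: float = 1.5
    lead_in_s: float = 2.0
    fs: float = FS_RAW
    seed: int | None = 0

    def validate(self) -> None:
        if self.n_short + self.n_catch + self.n_long != self.n_trials:
            raise ValidationError(
                f"trial counts {self.n_short}+{self.n_catch}+{self.n_long} "
                f"!= n_trials={self.n_trials}"
            )
        if min(self.n_trials, self.fs) <= 0:
            raise ValidationError("n_trials and fs must be positive")


@dataclass
class TemplateSpec:
    """Event-related waveform model for both conditions.

    ``peaks``: per condition, a list of (latency_ms, amplitude_uv, fwhm_ms)
    Gaussian bumps; amplitudes are the values observed at Fz.  The scalp
    topography is a Gaussian in great-circle distance from ``center`` with
    width ``topo_sigma_rad`` (gain 1 at the center, 0.9 at Fz by default).
    """

    peaks: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {
            "ERN": [(208.0, -7.9, 80.0), (340.0, 3.7, 80.0)],
            "CRA": [(208.0, -2.0, 80.0), (340.0, -2.0, 80.0)],
        }
    )
    center: str = "Cz"
    topo_sigma_rad: float = TOPO_SIGMA_RAD

    def topography(self, channels=CHANNELS_32) -> dict[str, float]:
        """Per-channel gain in [0, 1], maximal at the central electrodes."""
        pos = standard_montage()
        c = pos[self.center]
        gains = {}
        for ch in channels:
            angle = np.arccos(np.clip(np.dot(pos[ch], c), -1.0, 1.0))
            gains[ch] = float(np.exp(-(angle ** 2) / (2 * self.topo_sigma_rad ** 2)))
        return gains


@dataclass
class NoiseSpec:
    """Background-EEG stand-in: 1/f^alpha noise, alpha bump, line noise."""

    pink_exponent: float = 1.0
    rms_uv: float = 10.0
    alpha_gain: float = 1.0          # multiplicative bump at 10 Hz
    alpha_width_hz: float = 2.0
    line_50hz_uv: float = 0.0        # amplitude of 50 Hz interference
    seed: int | None = 0

    def validate(self) -> None:
        if self.rms_uv < 0:
            raise ValidationError("rms_uv must be non-negative")


@dataclass
class SubjectSpec:
    """Between-subject variability and trial attrition."""

    subject_id: str = "S01"
    amplitude_scale: float | None = None   # None: draw mean-one lognormal
    sigma_amp: float = 0.75
    latency_jitter_sd_ms: float = 10.0
    attrition_rate: float = 0.06
    seed: int | None = 0

    def validate(self) -> None:
        if self.amplitude_scale is not None and self.amplitude_scale <= 0:
            raise ValidationError("amplitude_scale must be positive")
        if not 0 <= self.attrition_rate < 1:
            raise ValidationError("attrition_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def generate_protocol(spec: ProtocolSpec | None = None,
                      rng=None) -> EventList:
    """Randomised 48-trial schedule with condition assigned by duration band.

    Each trial contributes three markers: ``trial_start`` (fixation onset),
    ``go`` (movement cue) and ``times_up`` (allotted window expires; the
    anchor for all ERP analyses).
    """
    spec = spec or ProtocolSpec()
    spec.validate()
    rng = _as_rng(spec.seed if rng is None else rng)

    durations = np.concatenate([
        rng.uniform(*spec.short_band_s, size=spec.n_short),
        rng.uniform(*spec.catch_band_s, size=spec.n_catch),
        np.full(spec.n_long, spec.long_duration_s),
    ])
    rng.shuffle(durations)

    rows = []
    t = spec.lead_in_s
    for trial_id, dur in enumerate(durations):
        cond = condition_for_duration(dur)
        if cond is None:
            raise ValidationError(f"duration {dur} s falls outside all bands")
        t_go = t + spec.fixation_s + spec.video_s + spec.timer_s
        t_up = t_go + dur
        for code, tt in [("trial_start", t), ("go", t_go), ("times_up", t_up)]:
            rows.append({
                "onset_sample": int(round(tt * spec.fs)),
                "code": code,
                "trial_id": trial_id,
                "condition": cond,
                "given_duration_s": float(dur),
                "excluded": False,
            })
        t = t_up + spec.post_s
    events = EventList(pd.DataFrame(rows))
    logger.info("generate_protocol: %d trials (%d ERN / %d catch / %d CRA)",
                spec.n_trials, spec.n_short, spec.n_catch, spec.n_long)
    return events


def render_template(spec: TemplateSpec, condition: str, fs: float,
                    channel: str = "Fz",
                    window_ms: tuple[float, float] = EPOCH_WINDOW_MS) -> np.ndarray:
    """Single-channel template over the half-open epoch window.

    ``condition`` may be ``"ERN"``, ``"CRA"`` or ``"diff"`` (ERN minus CRA).
    The waveform is the sum of Gaussian bumps scaled by the channel's
    topographic gain relative to Fz, so Fz reproduces the stated amplitudes.
    """
    if condition == "diff":
        return (render_template(spec, "ERN", fs, channel, window_ms)
                - render_template(spec, "CRA", fs, channel, window_ms))
    if condition not in spec.peaks:
        raise ValidationError(f"unknown condition {condition!r}")
    n = window_n_samples(*window_ms, fs)
    t = window_ms[0] + np.arange(n) * 1000.0 / fs
    wave = np.zeros(n)
    for latency, amplitude, fwhm in spec.peaks[condition]:
        if fwhm <= 0:
            raise ValidationError(f"FWHM must be positive, got {fwhm}")
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        wave += amplitude * np.exp(-((t - latency) ** 2) / (2 * sigma ** 2))
    gains = spec.topography()
    return wave * gains[channel] / gains["Fz"]


def synth_background(spec: NoiseSpec, n_samples: int, n_channels: int,
                     fs: float = FS_RAW, rng=None) -> np.ndarray:
    """Background noise matrix of shape (n_samples, n_channels).

    White Gaussian noise is spectrally shaped to power ~ 1/f^alpha (with an
    optional alpha-band bump) in the frequency domain, scaled per channel to
    the exact target RMS, then 50 Hz line interference is added if requested.
    Channels are independent.
    """
    spec.validate()
    if n_samples <= 0 or n_channels <= 0:
        raise ValidationError("n_samples and n_channels must be positive")
    rng = _as_rng(spec.seed if rng is None else rng)
    if spec.rms_uv == 0 and spec.line_50hz_uv == 0:
        return np.zeros((n_samples, n_channels))

    out = np.zeros((n_samples, n_channels))
    if spec.rms_uv > 0:
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shape = np.zeros_like(freqs)
        nz = freqs > 0
        shape[nz] = freqs[nz] ** (-spec.pink_exponent / 2.0)
        shape[nz] *= 1.0 + spec.alpha_gain * np.exp(
            -((freqs[nz] - 10.0) ** 2) / (2 * spec.alpha_width_hz ** 2))
        white = rng.standard_normal((n_samples, n_channels))
        spectrum = np.fft.rfft(white, axis=0) * shape[:, None]
        pink = np.fft.irfft(spectrum, n=n_samples, axis=0)
        rms = np.sqrt(np.mean(pink ** 2, axis=0))
        out = pink / rms * spec.rms_uv
    if spec.line_50hz_uv > 0:
        t = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi, size=n_channels)
        out = out + spec.line_50hz_uv * np.sin(
            2 * np.pi * 50.0 * t[:, None] + phase[None, :])
    return out


def _draw_amplitude_scale(spec: SubjectSpec, rng) -> float:
    if spec.amplitude_scale is not None:
        return spec.amplitude_scale
    # mean-one lognormal: E[scale] = 1 regardless of sigma_amp
    return float(rng.lognormal(-spec.sigma_amp ** 2 / 2.0, spec.sigma_amp))


def assemble_subject(protocol: ProtocolSpec | None = None,
                     template: TemplateSpec | None = None,
                     noise: NoiseSpec | None = None,
                     subject: SubjectSpec | None = None,
                     ) -> tuple[Recording, EventList]:
    """One subject's continuous recording plus its event table.

    At every ERN-trial ``times_up`` onset the ERN template (scaled by the
    subject's amplitude factor, latency-jittered, projected through the scalp
    topography) is added to the background; the CRA template at CRA onsets;
    nothing at catch trials.  Attrition flags ~6 % of trials as excluded
    without deleting them.
    """
    protocol = protocol or ProtocolSpec()
    template = template or TemplateSpec()
    noise = noise or NoiseSpec()
    subject = subject or SubjectSpec()
    subject.validate()

    events = generate_protocol(protocol)
    fs = protocol.fs
    tail = int(round((abs(EPOCH_WINDOW_MS[1]) / 1000.0 + 2.0) * fs))
    n_samples = int(events.table["onset_sample"].max()) + tail
    n_channels = len(CHANNELS_32)

    data = synth_background(noise, n_samples, n_channels, fs=fs)

    srng = _as_rng(subject.seed)
    scale = _draw_amplitude_scale(subject, srng)
    gains = template.topography()
    gain_vec = np.array([gains[ch] for ch in CHANNELS_32]) / gains["Fz"]

    n_epoch = window_n_samples(*EPOCH_WINDOW_MS, fs)
    offset0 = int(round(EPOCH_WINDOW_MS[0] / 1000.0 * fs))
    waveforms = {c: render_template(template, c, fs) for c in ("ERN", "CRA")}

    anchors = events.table[(events.table["code"] == "times_up")
                           & (events.table["condition"] != "catch")]
    for _, row in anchors.iterrows():
        jitter = srng.normal(0.0, subject.latency_jitter_sd_ms) \
            if subject.latency_jitter_sd_ms > 0 else 0.0
        start = int(row["onset_sample"]) + offset0 + int(round(jitter / 1000.0 * fs))
        if start < 0 or start + n_epoch > n_samples:
            raise ValidationError("recording too short for the trial schedule")
        wave = waveforms[row["condition"]]
        data[start:start + n_epoch] += scale * np.outer(wave, gain_vec)

    table = events.table.copy()
    trial_ids = table["trial_id"].unique()
    dropped = trial_ids[srng.random(len(trial_ids)) < subject.attrition_rate]
    table.loc[table["trial_id"].isin(dropped), "excluded"] = True
    events = EventList(table)

    recording = Recording(data=data, fs=fs, channels=list(CHANNELS_32))
    logger.info("assemble_subject %s: %d samples, amplitude scale %.3f, "
                "%d trials flagged by attrition",
                subject.subject_id, n_samples, scale, len(dropped))
    return recording, events


def iter_cohort(n_subjects: int = 11, master_seed: int = 42,
                protocol: ProtocolSpec | None = None,
                template: TemplateSpec | None = None,
                noise: NoiseSpec | None = None,
                subject: SubjectSpec | None = None):
    """Yield per-subject ``(Recording, EventList)`` pairs one at a time.

    Per-subject seeds are derived deterministically from the master seed, so
    subject k is identical whether the cohort is streamed or materialised.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    protocol = protocol or ProtocolSpec()
    template = template or TemplateSpec()
    noise = noise or NoiseSpec()
    subject = subject or SubjectSpec()

    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    for i, child in enumerate(children):
        s_proto, s_noise, s_subj = (int(x) for x in
                                    child.generate_state(3) % (2 ** 31))
        yield assemble_subject(
            replace(protocol, seed=s_proto),
            template,
            replace(noise, seed=s_noise),
            replace(subject, subject_id=f"S{i + 1:02d}", seed=s_subj),
        )


def make_cohort(n_subjects: int = 11, master_seed: int = 42,
                protocol: ProtocolSpec | None = None,
                template: TemplateSpec | None = None,
                noise: NoiseSpec | None = None,
                subject: SubjectSpec | None = None,
                ) -> list[tuple[Recording, EventList]]:
    """Deterministic cohort: per-subject seeds derived from the master seed."""
    return list(iter_cohort(n_subjects, master_seed, protocol, template,
                            noise, subject))


# ---------------------------------------------------------------------------
# Fast path for statistical simulation studies
# ---------------------------------------------------------------------------


def subject_average_waveforms(n_subjects: int = 11,
                              n_ern: int = 16, n_cra: int = 25,
                              fs: float = 250.0,
                              window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
                              template: TemplateSpec | None = None,
                              noise: NoiseSpec | None = None,
                              subject: SubjectSpec | None = None,
                              effect: bool = True,
                              rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Subject-averaged Fz waveforms for simulation studies.

    Simulates single-trial Fz epochs directly (template + spectrally shaped
    noise, epoch-mean subtracted) and returns per-subject ERN and CRA
    averages of shape ``(n_subjects, n_samples)``.  With ``effect=False`` no
    template is added (null cohorts).  This is the light-weight path used by
    error-rate and power studies, where simulating and filtering hundreds of
    full 32-channel recordings would be pointless: the statistics consume
    only the Fz subject averages.
    """
    template = template or TemplateSpec()
    noise = noise or NoiseSpec()
    subject = subject or SubjectSpec()
    rng = _as_rng(rng)
    n = window_n_samples(*window_ms, fs)
    ern = np.empty((n_subjects, n))
    cra = np.empty((n_subjects, n))
    for s in range(n_subjects):
        scale = _draw_amplitude_scale(subject, rng)
        for cond, n_trials, out in (("ERN", n_ern, ern), ("CRA", n_cra, cra)):
            eps = synth_background(replace(noise, seed=None), n, n_trials,
                                   fs=fs, rng=rng).T
            if effect:
                base = render_template(template, cond, fs, window_ms=window_ms)
                if subject.latency_jitter_sd_ms > 0:
                    shifts = np.round(rng.normal(
                        0.0, subject.latency_jitter_sd_ms, n_trials)
                        / 1000.0 * fs).astype(int)
                    for i, sh in enumerate(shifts):
                        eps[i] += scale * np.roll(base, sh)
                else:
                    eps += scale * base
            eps -= eps.mean(axis=1, keepdims=True)
            out[s] = eps.mean(axis=0)
    return ern, cra
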