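"""Continuous-data conditioning and epoching.

Stage order mirrors the analysis pipeline: zero-phase band-pass filter,
channel rejection, downsampling, epoching with whole-epoch mean subtraction,
amplitude-threshold epoch rejection, and interpolation of rejected channels.
Artifact handling is deliberately automatic (robust-variance channel
rejection plus amplitude-threshold epoch rejection); component-based
artifact removal is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from mne.filter import filter_data, notch_filter

from ernbci.io_core import (
    DataQualityError,
    EpochSet,
    EventList,
    Recording,
    ValidationError,
    window_n_samples,
)

logger = logging.getLogger("ernbci")


@dataclass
class PreprocConfig:
    """All tunable preprocessing constants.

    The FIR is a zero-phase windowed-sinc (Hamming) design with a 0.1 Hz
    transition at the low edge and 10 Hz at the high edge.
    """

    band_hz: tuple[float, float] = (0.1, 50.0)
    l_trans_hz: float = 0.1
    h_trans_hz: float = 10.0
    notch_hz: float = 50.0
    target_fs: float = 250.0
    channel_reject_z: float = 3.0
    max_channel_reject_frac: float = 0.25
    epoch_reject_uv: float = 100.0
    analysis_window_ms: tuple[float, float] = (-100.0, 800.0)
    classify_window_ms: tuple[float, float] = (0.0, 500.0)
    interp_neighbors: int = 4


def bandpass_zero_phase(recording: Recording,
                        band_hz: tuple[float, float] = (0.1, 50.0),
                        l_trans_hz: float = 0.1,
                        h_trans_hz: float = 10.0) -> Recording:
    """Zero-phase FIR band-pass; no group delay by construction."""
    low, high = band_hz
    nyq = recording.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValidationError(f"band {band_hz} outside (0, {nyq}) Hz")
    filtered = filter_data(
        np.ascontiguousarray(recording.data.T), recording.fs, low, high,
        l_trans_bandwidth=l_trans_hz, h_trans_bandwidth=h_trans_hz,
        method="fir", phase="zero", fir_window="hamming", fir_design="firwin",
        verbose="error",
    )
    logger.info("bandpass_zero_phase: %.2g-%.2g Hz on %s", low, high,
                recording.data.shape)
    return recording.copy_with(data=filtered.T)


def notch_50(recording: Recording, notch_hz: float = 50.0) -> Recording:
    """Zero-phase notch at the mains frequency."""
    filtered = notch_filter(
        np.ascontiguousarray(recording.data.T), recording.fs, notch_hz,
        method="fir", phase="zero", verbose="error",
    )
    logger.info("notch_50: %g Hz", notch_hz)
    return recording.copy_with(data=filtered.T)


def reject_channels(recording: Recording, z_thresh: float = 3.0,
                    max_frac: float = 0.25) -> tuple[Recording, list[str]]:
    """Flag channels whose robust z-score of log-variance is extreme.

    Robust z uses the median and 1.4826*MAD across channels.  Refuses to
    remove more than ``max_frac`` of the channels (that points at a
    recording-level problem, not at individual electrodes).
    """
    if recording.n_channels < 8:
        raise ValidationError("channel rejection needs >= 8 channels")
    variances = recording.data.var(axis=0)
    if np.all(variances == 0):
        raise DataQualityError("all channels are flat")
    if np.any(variances == 0):
        logvar = np.full_like(variances, -np.inf)
        nz = variances > 0
        logvar[nz] = np.log(variances[nz])
    else:
        logvar = np.log(variances)
    med = np.median(logvar)
    mad = np.median(np.abs(logvar - med))
    scale = 1.4826 * mad
    if scale == 0:
        z = np.where(logvar == med, 0.0, np.inf * np.sign(logvar - med))
    else:
        z = (logvar - med) / scale
    bad = [ch for ch, zz in zip(recording.channels, z)
           if not np.isfinite(zz) or abs(zz) > z_thresh]
    if len(bad) > max_frac * recording.n_channels:
        raise DataQualityError(
            f"{len(bad)}/{recording.n_channels} channels rejected "
            f"(limit {max_frac:.0%}): {bad}"
        )
    keep = [i for i, ch in enumerate(recording.channels) if ch not in bad]
    logger.info("reject_channels: flagged %s", bad or "none")
    reduced = recording.copy_with(
        data=recording.data[:, keep],
        channels=[recording.channels[i] for i in keep],
    )
    return reduced, bad


def downsample(recording: Recording, target_fs: float = 250.0) -> Recording:
    """Anti-aliased decimation to an integer divisor of the sampling rate."""
    ratio = recording.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValidationError(
            f"target_fs {target_fs} is not an integer divisor of {recording.fs}"
        )
    q = int(round(ratio))
    if q == 1:
        return recording.copy_with()
    decimated = scipy.signal.decimate(recording.data, q, axis=0,
                                      ftype="fir", zero_phase=True)
    logger.info("downsample: %g -> %g Hz", recording.fs, target_fs)
    return recording.copy_with(data=decimated, fs=target_fs)


def epoch(recording: Recording, events: EventList,
          window_ms: tuple[float, float] = (-100.0, 800.0),
          anchor: str = "times_up",
          conditions: tuple[str, ...] = ("ERN", "CRA"),
          demean: bool = True,
          subject_id: str = "") -> EpochSet:
    """Cut fixed-length epochs around the anchor events.

    Catch and attrition-flagged trials are excluded; the per-epoch,
    per-channel mean is subtracted (whole-epoch mean, not a pre-stimulus
    baseline).  Anchors too close to the record edge are dropped with a
    warning.
    """
    fs = recording.fs
    n = window_n_samples(*window_ms, fs)
    offset = int(round(window_ms[0] / 1000.0 * fs))
    anchors = events.anchors(code=anchor, conditions=conditions)

    chunks, labels = [], []
    for _, row in anchors.iterrows():
        start = int(row["onset_sample"]) + offset
        if start < 0 or start + n > recording.n_samples:
            warnings.warn(
                f"trial {row['trial_id']}: anchor too close to record edge; dropped",
                stacklevel=2)
            continue
        chunk = recording.data[start:start + n].T.copy()   # (ch, samples)
        if demean:
            chunk -= chunk.mean(axis=1, keepdims=True)
        chunks.append(chunk)
        labels.append(row["condition"])
    if not chunks:
        raise DataQualityError("no usable epochs")
    logger.info("epoch: %d epochs of %d samples (%s)", len(chunks), n, window_ms)
    return EpochSet(np.stack(chunks), window_ms[0], window_ms[1], fs,
                    np.array(labels), list(recording.channels), subject_id,
                    recording.positions)


def rescale_events(events: EventList, fs_from: float, fs_to: float) -> EventList:
    """Convert onset samples between sampling rates (after downsampling)."""
    table = events.table.copy()
    table["onset_sample"] = np.round(
        table["onset_sample"] * fs_to / fs_from).astype(np.int64)
    return EventList(table)


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop epochs containing any sample beyond the amplitude threshold."""
    if threshold_uv <= 0:
        raise ValidationError("threshold must be positive")
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    keep = peak <= threshold_uv
    n_removed = int((~keep).sum())
    if not keep.any():
        raise DataQualityError("amplitude threshold removed every epoch")
    logger.info("reject_epochs: removed %d of %d", n_removed, epochs.n_epochs)
    return EpochSet(epochs.epochs[keep], epochs.t0_ms, epochs.t1_ms, epochs.fs,
                    epochs.labels[keep], list(epochs.channels),
                    epochs.subject_id, epochs.positions)


def _idw_weights(target: str, surviving: list[str],
                 positions: dict[str, np.ndarray], k: int = 4) -> tuple[list[int], np.ndarray]:
    if len(surviving) < 3:
        raise ValidationError("interpolation needs >= 3 surviving neighbors")
    p0 = positions[target]
    dists = np.array([np.linalg.norm(positions[ch] - p0) for ch in surviving])
    order = np.argsort(dists)[: min(k, len(surviving))]
    d = dists[order]
    if np.any(d == 0):
        w = (d == 0).astype(float)
    else:
        w = 1.0 / d
    return list(order), w / w.sum()


def interpolate_channels(obj, rejected: list[str],
                         positions: dict[str, np.ndarray] | None = None,
                         k: int = 4):
    """Reconstruct rejected channels by inverse-distance weighting.

    Each rejected channel becomes the IDW mean of its ``k`` nearest surviving
    electrodes.  Works on a :class:`Recording` (channels = columns) or an
    :class:`EpochSet` (channels = axis 1).  Returns the object with the
    channels restored (in standard montage order where possible) plus the
    list of reconstructed labels.
    """
    if not rejected:
        return obj, []
    positions = positions or obj.positions
    surviving = list(obj.channels)
    overlap = set(rejected) & set(surviving)
    if overlap:
        raise ValidationError(f"channels {sorted(overlap)} are not rejected")

    recon = {}
    for ch in rejected:
        idx, w = _idw_weights(ch, surviving, positions, k)
        if isinstance(obj, Recording):
            recon[ch] = obj.data[:, idx] @ w
        else:
            recon[ch] = np.tensordot(obj.epochs[:, idx, :], w, axes=([1], [0]))

    from ernbci.io_core import CHANNELS_32
    union = surviving + [ch for ch in rejected if ch not in surviving]
    ordered = [ch for ch in CHANNELS_32 if ch in union]
    ordered += [ch for ch in union if ch not in ordered]

    def column(ch):
        if ch in surviving:
            i = surviving.index(ch)
            return obj.data[:, i] if isinstance(obj, Recording) \
                else obj.epochs[:, i, :]
        return recon[ch]

    logger.info("interpolate_channels: reconstructed %s", rejected)
    if isinstance(obj, Recording):
        data = np.stack([column(ch) for ch in ordered], axis=1)
        return obj.copy_with(data=data, channels=ordered), list(rejected)
    stacked = np.stack([column(ch) for ch in ordered], axis=1)
    return EpochSet(stacked, obj.t0_ms, obj.t1_ms, obj.fs, obj.labels,
                    ordered, obj.subject_id, obj.positions), list(rejected)


# ---------------------------------------------------------------------------
# Composed pipeline
# ---------------------------------------------------------------------------


def preprocess_continuous(recording: Recording, config: PreprocConfig | None = None,
                          apply_notch: bool = False,
                          ) -> tuple[Recording, EventList | None, list[str]]:
    """Filter, reject channels, downsample and re-interpolate continuously.

    Returns the conditioned recording and the rejected-channel labels.  The
    acquisition chain already applies a mains notch, so ``apply_notch``
    defaults to off.
    """
    config = config or PreprocConfig()
    rec = bandpass_zero_phase(recording, config.band_hz,
                              config.l_trans_hz, config.h_trans_hz)
    if apply_notch:
        rec = notch_50(rec, config.notch_hz)
    rec, rejected = reject_channels(rec, config.channel_reject_z,
                                    config.max_channel_reject_frac)
    rec = downsample(rec, config.target_fs)
    if rejected:
        rec, _ = interpolate_channels(rec, rejected, k=config.interp_neighbors)
    return rec, None, rejected


def preprocess_subject(recording: Recording, events: EventList,
                       config: PreprocConfig | None = None,
                       window: str = "analysis",
                       subject_id: str = "") -> EpochSet:
    """Full per-subject path from raw recording to clean epochs."""
    config = config or PreprocConfig()
    rec, _, rejected = preprocess_continuous(recording, config)
    ev = rescale_events(events, recording.fs, rec.fs)
    window_ms = (config.analysis_window_ms if window == "analysis"
                 else config.classify_window_ms)
    eps = epoch(rec, ev, window_ms, subject_id=subject_id)
    eps = reject_epochs(eps, config.epoch_reject_uv)
    return eps
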