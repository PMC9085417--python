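"""Shared data model, standard-format I/O, montage and logging.

Conventions used throughout the package:

* sample indices are 0-based;
* epoch windows are half-open ``[t0, t1)`` in milliseconds, so an epoch from
  -100 to 800 ms at 250 Hz spans exactly 225 samples;
* potentials are microvolts, stored time-major (one column per channel).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ernbci")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


class DataQualityError(RuntimeError):
    """Data is formally valid but unusable (e.g. all channels rejected)."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

#: The 32-channel recording montage (10-20 system, right-mastoid reference).
CHANNELS_32 = [
    "FP1", "FP2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "Oz",
]

# Idealised spherical 10-20 coordinates: (inclination from vertex in degrees,
# azimuth in degrees measured from the anterior midline, positive toward the
# right ear).  Exact left/right mirror symmetry by construction; Cz at vertex.
_MONTAGE_ANGLES = {
    "FP1": (72, -18), "FP2": (72, 18),
    "AF3": (59, -28), "AF4": (59, 28),
    "F7": (72, -54), "F3": (48, -40), "Fz": (36, 0), "F4": (48, 40),
    "F8": (72, 54),
    "FC5": (60, -69), "FC1": (25, -45), "FC2": (25, 45), "FC6": (60, 69),
    "T7": (72, -90), "C3": (36, -90), "Cz": (0, 0), "C4": (36, 90),
    "T8": (72, 90),
    "CP5": (60, -111), "CP1": (25, -135), "CP2": (25, 135), "CP6": (60, 111),
    "P7": (72, -126), "P3": (48, -140), "Pz": (36, 180), "P4": (48, 140),
    "P8": (72, 126),
    "PO7": (72, -144), "PO3": (59, -152), "PO4": (59, 152), "PO8": (72, 144),
    "Oz": (72, 180),
}


def standard_montage() -> dict[str, np.ndarray]:
    """Unit-sphere 3-D electrode positions for the 32-channel 10-20 montage.

    Coordinate frame: +x right, +y anterior, +z up; Cz at ``(0, 0, 1)``.
    Homologous pairs (e.g. F3/F4) are exact mirror images in x.
    """
    positions = {}
    for label, (incl, azim) in _MONTAGE_ANGLES.items():
        th = np.deg2rad(incl)
        ph = np.deg2rad(azim)
        positions[label] = np.array(
            [np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)]
        )
    return positions


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Potentials in microvolts, time-major.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered channel labels, one per data column.
    positions : dict
        3-D unit-sphere electrode position per label.
    reference : str
        Label of the reference electrode (``M2`` = right mastoid).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    positions: dict[str, np.ndarray] = field(default_factory=standard_montage)
    reference: str = "M2"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.channels) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.channels)} labels for {self.data.shape[1]} columns"
            )
        missing = [c for c in self.channels if c not in self.positions]
        if missing:
            raise ValidationError(f"channels without montage position: {missing}")
        if not np.isfinite(self.data).all():
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, data: np.ndarray | None = None, fs: float | None = None,
                  channels: list[str] | None = None) -> "Recording":
        return Recording(
            data=self.data.copy() if data is None else data,
            fs=self.fs if fs is None else fs,
            channels=list(self.channels) if channels is None else channels,
            positions=self.positions,
            reference=self.reference,
        )


EVENT_CODES = ("trial_start", "go", "times_up")
CONDITIONS = ("ERN", "CRA", "catch")

#: allotted-duration bands (seconds) that define the trial condition
DURATION_BANDS = {"ERN": (2.0, 4.0), "catch": (9.0, 10.0), "CRA": (14.0, 16.0)}

_EVENT_COLUMNS = ["onset_sample", "code", "trial_id", "condition",
                  "given_duration_s", "excluded"]


def condition_for_duration(duration_s: float) -> str | None:
    """Map an allotted completion window to its trial condition band.

    Short windows (2-4 s) force failure (ERN), long ones (~15 s) guarantee
    success (CRA), intermediate ones (9-10 s) are unpredictable catch trials.
    """
    for cond, (lo, hi) in DURATION_BANDS.items():
        if lo <= duration_s <= hi:
            return cond
    return None


@dataclass
class EventList:
    """Timestamped experiment markers as a validated table.

    ``table`` columns: onset_sample (int), code (trial_start | go | times_up),
    trial_id (int), condition (ERN | CRA | catch), given_duration_s (float),
    excluded (bool; attrition flag -- excluded trials are kept in the table so
    counts stay auditable).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        required = [c for c in _EVENT_COLUMNS if c != "excluded"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        if "excluded" not in df.columns:
            df = df.assign(excluded=False)
        df = df[_EVENT_COLUMNS].copy()
        df["onset_sample"] = df["onset_sample"].astype(np.int64)
        df["trial_id"] = df["trial_id"].astype(np.int64)
        df["given_duration_s"] = df["given_duration_s"].astype(float)
        df["excluded"] = df["excluded"].astype(bool)
        self.table = df.sort_values("onset_sample", kind="stable").reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.table
        bad_code = df.loc[~df["code"].isin(EVENT_CODES)]
        if len(bad_code):
            raise ValidationError(
                f"unknown event code(s) in rows {bad_code.index.tolist()}: "
                f"{sorted(bad_code['code'].unique())}"
            )
        bad_cond = df.loc[~df["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            raise ValidationError(
                f"unknown condition(s) in rows {bad_cond.index.tolist()}"
            )
        for trial_id, grp in df.groupby("trial_id"):
            onsets = grp["onset_sample"].to_numpy()
            if not (np.diff(onsets) > 0).all():
                raise ValidationError(
                    f"trial {trial_id}: onsets not strictly increasing"
                )
            if (grp["code"] == "times_up").sum() != 1:
                raise ValidationError(
                    f"trial {trial_id}: expected exactly one times_up event"
                )
            cond = grp["condition"].iloc[0]
            if grp["condition"].nunique() != 1:
                raise ValidationError(f"trial {trial_id}: inconsistent condition")
            dur = float(grp["given_duration_s"].iloc[0])
            expected = condition_for_duration(dur)
            if expected != cond:
                raise ValidationError(
                    f"trial {trial_id}: duration {dur} s is in the "
                    f"{expected!r} band but condition is {cond!r}"
                )

    @property
    def n_trials(self) -> int:
        return self.table["trial_id"].nunique()

    def anchors(self, code: str = "times_up", conditions=("ERN", "CRA"),
                include_excluded: bool = False) -> pd.DataFrame:
        """Rows for the given marker code, filtered to usable conditions."""
        df = self.table
        sel = (df["code"] == code) & df["condition"].isin(conditions)
        if not include_excluded:
            sel &= ~df["excluded"]
        return df.loc[sel].reset_index(drop=True)


@dataclass
class EpochSet:
    """Stacked fixed-length epochs (trial x channel x sample)."""

    epochs: np.ndarray
    t0_ms: float
    t1_ms: float
    fs: float
    labels: np.ndarray          # condition per epoch
    channels: list[str]
    subject_id: str = ""
    positions: dict[str, np.ndarray] = field(default_factory=standard_montage)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be 3-D (trial x channel x sample)")
        n_expected = window_n_samples(self.t0_ms, self.t1_ms, self.fs)
        if self.epochs.shape[2] != n_expected:
            raise ValidationError(
                f"epoch length {self.epochs.shape[2]} != "
                f"{n_expected} samples for [{self.t0_ms}, {self.t1_ms}) ms at "
                f"{self.fs} Hz"
            )
        if self.epochs.shape[0] != len(self.labels):
            raise ValidationError("one label per epoch required")
        if self.epochs.shape[1] != len(self.channels):
            raise ValidationError("one channel label per epoch row required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.epochs.shape[2]
        return self.t0_ms + np.arange(n) * 1000.0 / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None

    def select(self, condition: str) -> "EpochSet":
        mask = self.labels == condition
        return EpochSet(self.epochs[mask], self.t0_ms, self.t1_ms, self.fs,
                        self.labels[mask], list(self.channels),
                        self.subject_id, self.positions)


def window_n_samples(t0_ms: float, t1_ms: float, fs: float) -> int:
    """Length in samples of the half-open window [t0, t1) ms at rate fs."""
    return int(round((t1_ms - t0_ms) / 1000.0 * fs))


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

EDF_PHYSICAL_RANGE_UV = 200.0   # default physical range: +/-200 uV
_EDF_DIG_MIN, _EDF_DIG_MAX = -32767, 32767


def _pad(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path, physical_range_uv: float = EDF_PHYSICAL_RANGE_UV) -> None:
    """Write a recording as a plain EDF file (16-bit, 1-second data records).

    Samples are clipped to ``+/-physical_range_uv`` and quantised to 16 bits.
    If the recording length is not a whole number of seconds the final data
    record is zero-padded; the true sample count is stashed in the reserved
    header field so :func:`read_edf` can trim the padding.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_samples, n_channels = recording.data.shape
    if n_channels > 9999:
        raise ValidationError("channel count exceeds EDF limits")
    n_records = int(np.ceil(n_samples / fs)) if n_samples else 0

    phys_min, phys_max = -physical_range_uv, physical_range_uv
    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    clipped = np.clip(recording.data, phys_min, phys_max)
    digital = np.round((clipped - phys_min) / scale + _EDF_DIG_MIN).astype("<i2")
    pad_rows = n_records * fs - n_samples
    if pad_rows:
        zero_dig = int(round((0.0 - phys_min) / scale + _EDF_DIG_MIN))
        digital = np.vstack([digital, np.full((pad_rows, n_channels), zero_dig, "<i2")])

    header = io.BytesIO()
    header.write(_pad("0", 8))
    header.write(_pad("X X X X", 80))
    header.write(_pad(f"Startdate 01-JAN-2000 ref={recording.reference}", 80))
    header.write(_pad("01.01.00", 8))
    header.write(_pad("00.00.00", 8))
    header.write(_pad(256 * (1 + n_channels), 8))
    header.write(_pad(f"nsamp={n_samples}", 44))
    header.write(_pad(n_records, 8))
    header.write(_pad(1, 8))
    header.write(_pad(n_channels, 4))
    for width, values in [
        (16, recording.channels),
        (80, [""] * n_channels),
        (8, ["uV"] * n_channels),
        (8, [f"{phys_min:g}"] * n_channels),
        (8, [f"{phys_max:g}"] * n_channels),
        (8, [str(_EDF_DIG_MIN)] * n_channels),
        (8, [str(_EDF_DIG_MAX)] * n_channels),
        (80, [""] * n_channels),
        (8, [str(fs)] * n_channels),
        (32, [""] * n_channels),
    ]:
        for v in values:
            header.write(_pad(v, width))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        # record-major layout: per record, each signal's samples contiguously
        for rec in range(n_records):
            chunk = digital[rec * fs:(rec + 1) * fs]     # (fs, n_channels)
            fh.write(chunk.T.tobytes())
    logger.info("write_edf: %s (%d ch, %d samples @ %d Hz)",
                path.name, n_channels, n_samples, fs)


def _ascii_field(raw: bytes, offset: int, width: int) -> str:
    return raw[offset:offset + width].decode("ascii", errors="replace").strip()


def read_edf(path, positions: dict[str, np.ndarray] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    All signals must share one sampling rate (EEG-only files); files with
    mixed rates are rejected as unsupported.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path.name}: truncated EDF header")
    try:
        n_header = int(_ascii_field(raw, 184, 8))
        n_records = int(_ascii_field(raw, 236, 8))
        record_dur = float(_ascii_field(raw, 244, 8))
        n_channels = int(_ascii_field(raw, 252, 4))
    except ValueError as exc:
        raise FormatError(f"{path.name}: malformed EDF header ({exc})") from exc
    if n_channels <= 0 or n_header != 256 * (1 + n_channels):
        raise FormatError(f"{path.name}: inconsistent EDF header sizes")
    if len(raw) < n_header:
        raise FormatError(f"{path.name}: truncated EDF signal headers")

    def signal_fields(offset: int, width: int) -> list[str]:
        base = 256 + offset * n_channels
        return [_ascii_field(raw, base + i * width, width) for i in range(n_channels)]

    labels = signal_fields(0, 16)
    try:
        phys_min = np.array([float(v) for v in signal_fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in signal_fields(16 + 80 + 16, 8)])
        dig_min = np.array([float(v) for v in signal_fields(16 + 80 + 24, 8)])
        dig_max = np.array([float(v) for v in signal_fields(16 + 80 + 32, 8)])
        samp_per_rec = [int(v) for v in signal_fields(216, 8)]
    except ValueError as exc:
        raise FormatError(f"{path.name}: malformed EDF signal header ({exc})") from exc
    if len(set(samp_per_rec)) != 1:
        raise FormatError(f"{path.name}: mixed sampling rates are unsupported")
    spr = samp_per_rec[0]
    fs = spr / record_dur

    expected = n_header + n_records * n_channels * spr * 2
    if len(raw) < expected:
        raise FormatError(
            f"{path.name}: truncated data section "
            f"({len(raw)} bytes, expected {expected})"
        )
    flat = np.frombuffer(raw, dtype="<i2", offset=n_header,
                         count=n_records * n_channels * spr)
    data_dig = flat.reshape(n_records, n_channels, spr)
    data_dig = np.transpose(data_dig, (0, 2, 1)).reshape(n_records * spr, n_channels)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data_dig - dig_min) * scale + phys_min

    reserved = _ascii_field(raw, 192, 44)
    if reserved.startswith("nsamp="):
        try:
            data = data[: int(reserved[6:])]
        except ValueError:
            pass
    rec_id = _ascii_field(raw, 88, 80)
    reference = "M2"
    for token in rec_id.split():
        if token.startswith("ref="):
            reference = token[4:]

    if positions is None:
        montage = standard_montage()
        unknown = [l for l in labels if l not in montage]
        if unknown:
            raise FormatError(
                f"{path.name}: no montage position for channel(s) {unknown}; "
                "pass explicit positions"
            )
        positions = montage
    logger.info("read_edf: %s (%d ch, %d samples @ %g Hz)",
                path.name, n_channels, data.shape[0], fs)
    return Recording(data=data, fs=fs, channels=labels,
                     positions=positions, reference=reference)


# ---------------------------------------------------------------------------
# Event-table I/O
# ---------------------------------------------------------------------------


def write_events(events: EventList, path) -> None:
    """Write an event table as tab-delimited text (lossless round-trip)."""
    events.table.to_csv(path, sep="\t", index=False)
    logger.info("write_events: %s (%d rows)", Path(path).name, len(events.table))


def read_events(path) -> EventList:
    """Read a tab-delimited event table and validate it row by row."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"code": str, "condition": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            _EVENT_COLUMNS,
            [np.int64, str, np.int64, str, float, bool])})
    return EventList(df)


def validate_pair(recording: Recording, events: EventList) -> list[str]:
    """Cross-check a recording against its event table; return problem list."""
    problems = []
    last = events.table["onset_sample"].max() if len(events.table) else -1
    if last >= recording.n_samples:
        problems.append(
            f"event onset {last} beyond recording end ({recording.n_samples})"
        )
    if len(events.table) and events.table["onset_sample"].min() < 0:
        problems.append("negative event onset")
    return problems
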