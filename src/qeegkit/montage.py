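"""Recording I/O, filtering and montage derivations.

A scalp EEG acquired referentially on the 19-electrode 10–20 set is read from
EDF or a plain text matrix, band-pass filtered, optionally reduced to
artifact-free segments, and re-derived either as the clinical double-banana
bipolar montage (18 channels, anode minus cathode) or as the average-reference
(AVG) montage.

Units are microvolts throughout. Sign convention for bipolar channels is
``V(anode) - V(cathode)`` in the label order as printed (``Fp1-F3`` means
``V(Fp1) - V(F3)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import (
    DurationError,
    FormatError,
    MontageError,
    ParameterError,
    ValidationError,
)

#: The 19 scalp electrodes of the 10–20 system, classical nomenclature
#: (T3/T4 temporal, T5/T6 posterior temporal).
TEN_TWENTY: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Modern (T7/T8/P7/P8) aliases accepted on input, mapped to classical names.
_ALIASES = {"t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6"}

#: Double-banana derivation: two parasagittal chains, two temporal chains and
#: the midline, each channel ``(anode, cathode)``.
DOUBLE_BANANA: tuple[tuple[str, str], ...] = (
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fz", "Cz"), ("Cz", "Pz"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
)


def bipolar_label(anode: str, cathode: str) -> str:
    return f"{anode}-{cathode}"


def normalize_label(label: str) -> str:
    """Map a channel label onto the classical 10–20 name, or raise."""
    key = label.strip().lower().replace("eeg", "").strip(" -_")
    canon = {name.lower(): name for name in TEN_TWENTY}
    if key in canon:
        return canon[key]
    if key in _ALIASES:
        return _ALIASES[key]
    raise MontageError(f"unknown electrode label: {label!r}")


def _unit_positions() -> dict[str, np.ndarray]:
    """Unit-sphere 10–20 coordinates from the standard montage."""
    import mne

    std = mne.channels.make_standard_montage("standard_1020")
    pos = std.get_positions()["ch_pos"]
    modern = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}
    out = {}
    for name in TEN_TWENTY:
        p = np.asarray(pos[modern.get(name, name)], dtype=float)
        out[name] = p / np.linalg.norm(p)
    return out


def geodesic_midpoint(a: str, b: str) -> np.ndarray:
    """Midpoint of the great-circle arc between two electrodes (unit sphere).

    Used only for reporting channel placement; no numeric analysis depends
    on scalp geometry.
    """
    pos = _unit_positions()
    mid = pos[normalize_label(a)] + pos[normalize_label(b)]
    return mid / np.linalg.norm(mid)


@dataclass
class Recording:
    """Referential multichannel EEG.

    Parameters
    ----------
    subject_id : str
    fs : float
        Sampling rate in Hz.
    electrodes : list of str
        Ordered 10–20 labels, one per data row.
    data : ndarray, shape (n_electrodes, n_samples)
        Voltages in µV.
    segments : list of (int, int)
        Retained artifact-free stretches as half-open sample index ranges.
        Analysis windows never straddle a segment boundary.
    """

    subject_id: str
    fs: float
    electrodes: list[str]
    data: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.electrodes):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows for "
                f"{len(self.electrodes)} electrode labels"
            )
        if not self.segments:
            self.segments = [(0, self.data.shape[1])]
        prev_end = 0
        for start, end in self.segments:
            if not (0 <= start < end <= self.data.shape[1]):
                raise ValidationError(f"segment {(start, end)} out of bounds")
            if start < prev_end:
                raise ValidationError("segments overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.electrodes.index(normalize_label(label))]


@dataclass
class BipolarRecord:
    """Double-banana derivation of a :class:`Recording`."""

    subject_id: str
    fs: float
    channels: list[tuple[str, str]]
    data: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not self.segments:
            self.segments = [(0, self.data.shape[1])]

    @property
    def labels(self) -> list[str]:
        return [bipolar_label(a, c) for a, c in self.channels]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def midpoints(self) -> dict[str, np.ndarray]:
        """Scalp placement of each channel: geodesic midpoint of its pair."""
        return {bipolar_label(a, c): geodesic_midpoint(a, c)
                for a, c in self.channels}


# ---------------------------------------------------------------------------
# Reading and writing


def _require_electrodes(labels: list[str], required=TEN_TWENTY) -> None:
    missing = [e for e in required if e not in labels]
    if missing:
        raise MontageError("missing required electrodes: " + ", ".join(missing))


def read_recording(path: str | Path, format: str | None = None,
                   subject_id: str | None = None) -> Recording:
    """Read a referential recording from EDF or a text matrix.

    The text dialect is tab-separated with a header row of channel labels and
    one column per channel. EDF voltages are converted to µV.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "text-matrix"
    if subject_id is None:
        subject_id = path.stem
    if format == "edf":
        return _read_edf(path, subject_id)
    if format == "text-matrix":
        return _read_text(path, subject_id)
    raise FormatError(f"unknown format {format!r}")


def _read_edf(path: Path, subject_id: str) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad files
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    labels = []
    for name in raw.ch_names:
        try:
            labels.append(normalize_label(name))
        except MontageError:
            labels.append(None)  # non-EEG channel, dropped below
    keep = [i for i, lab in enumerate(labels) if lab is not None]
    kept_labels = [labels[i] for i in keep]
    _require_electrodes(kept_labels)
    data = raw.get_data(picks=keep) * 1e6  # volts -> µV
    return Recording(subject_id, float(raw.info["sfreq"]), kept_labels, data)


def _read_text(path: Path, subject_id: str, fs: float = 512.0) -> Recording:
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        matrix = np.loadtxt(path, skiprows=1, delimiter="\t", ndmin=2)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse text matrix {path}: {exc}") from exc
    # header may carry the sampling rate as "# fs=512" in the first cell
    if header and header[0].startswith("#"):
        token = header[0].lstrip("# ").strip()
        if token.startswith("fs="):
            fs = float(token[3:])
        header = header[1:]
        matrix = matrix[:, 1:] if matrix.shape[1] == len(header) + 1 else matrix
    labels = [normalize_label(h) for h in header]
    _require_electrodes(labels)
    if matrix.shape[1] != len(labels):
        raise FormatError(
            f"{matrix.shape[1]} columns for {len(labels)} header labels")
    return Recording(subject_id, fs, labels, matrix.T.copy())


def write_text_matrix(rec: Recording, path: str | Path) -> None:
    """Write the tab-separated text dialect read by :func:`read_recording`."""
    header = "\t".join([f"# fs={rec.fs:g}"] + list(rec.electrodes))
    body = np.column_stack([np.zeros(rec.n_samples), rec.data.T])
    np.savetxt(path, body, delimiter="\t", header=header, comments="",
               fmt="%.6f")


# ---------------------------------------------------------------------------
# Preprocessing


def concat_segments(rec: Recording, keep: list[tuple[float, float]],
                    min_duration_s: float = 120.0,
                    allow_short: bool = False) -> Recording:
    """Concatenate artifact-free chunks given in seconds.

    The chunk boundaries are recorded as segment boundaries so later
    windowing never places a window across a splice (a splice would create
    spurious broadband power).
    """
    pieces, segments, cursor = [], [], 0
    for start_s, end_s in keep:
        i0, i1 = int(round(start_s * rec.fs)), int(round(end_s * rec.fs))
        if not (0 <= i0 < i1 <= rec.n_samples):
            raise ParameterError(f"chunk {(start_s, end_s)} s out of bounds")
        pieces.append(rec.data[:, i0:i1])
        segments.append((cursor, cursor + (i1 - i0)))
        cursor += i1 - i0
    total_s = cursor / rec.fs
    if total_s < min_duration_s and not allow_short:
        raise DurationError(
            f"retained duration {total_s:.1f} s is below the "
            f"{min_duration_s:.0f} s minimum (set allow_short to override)")
    return Recording(rec.subject_id, rec.fs, list(rec.electrodes),
                     np.concatenate(pieces, axis=1), segments)


def bandpass(rec: Recording, low: float = 0.5, high: float = 30.0,
             order: int = 6, zero_phase: bool = True) -> Recording:
    """Butterworth band-pass, zero-phase (forward–backward) by default.

    Defaults follow routine clinical qEEG practice: sixth order, 0.5–30 Hz.
    Zero-phase application avoids the phase distortion that would corrupt
    cross-correlation lag estimates.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ParameterError(
            f"corner frequencies ({low}, {high}) invalid for fs={rec.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    out = np.empty_like(rec.data)
    for start, end in rec.segments:
        chunk = rec.data[:, start:end]
        if zero_phase:
            out[:, start:end] = signal.sosfiltfilt(sos, chunk, axis=1)
        else:
            out[:, start:end] = signal.sosfilt(sos, chunk, axis=1)
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# Montages


def to_bipolar(rec: Recording) -> BipolarRecord:
    """Derive the 18-channel double-banana montage, anode minus cathode."""
    _require_electrodes(rec.electrodes,
                        sorted({e for pair in DOUBLE_BANANA for e in pair}))
    rows = [rec.channel(a) - rec.channel(c) for a, c in DOUBLE_BANANA]
    return BipolarRecord(rec.subject_id, rec.fs, list(DOUBLE_BANANA),
                         np.asarray(rows), list(rec.segments))


def to_avg(rec: Recording) -> Recording:
    """Average-reference montage: each electrode minus the scalp mean."""
    if len(rec.electrodes) < 2:
        raise MontageError("average reference needs at least 2 electrodes")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))
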