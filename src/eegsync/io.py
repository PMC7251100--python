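"""Reading, preprocessing and windowing of multichannel EEG.

Signals are held in a :class:`Recording` (channels x samples, microvolts).
EDF files are read through :mod:`mne`; a minimal 16-bit EDF writer is
provided so synthetic fixtures can round-trip through the same path real
scalp-EEG data (e.g. the CHB-MIT database) would take.  Seizure annotations
come either from a two-column CSV (``onset,offset`` in seconds) or from
CHB-MIT-style summary text files.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SeizureInterval",
    "Recording",
    "WindowPlan",
    "read_edf",
    "write_edf",
    "read_csv_recording",
    "write_csv_recording",
    "read_annotations",
    "write_annotations",
    "preprocess",
    "normalize_range",
    "segment",
]


@dataclass(frozen=True)
class SeizureInterval:
    """A marked seizure epoch, in seconds from recording start."""

    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValueError(
                f"invalid seizure interval: need 0 <= onset < offset, "
                f"got onset={self.onset}, offset={self.offset}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def contains(self, t: float) -> bool:
        return self.onset <= t <= self.offset


@dataclass
class Recording:
    """Multichannel signal with sampling rate, labels and annotations.

    ``data`` is channels x samples in microvolts (or arbitrary units for
    simulated state trajectories).
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    start_time: float = 0.0
    annotations: list[SeizureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("number of labels must match number of channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw)
        return out


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout: length and hop in seconds.

    ``hop=None`` means non-overlapping windows (hop = length).  Sample
    ranges are 0-based and half-open; window times are reported at the
    window *end*.
    """

    length: float
    hop: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"window length must be positive, got {self.length}")
        if self.hop is not None and self.hop <= 0:
            raise ValueError(f"hop must be positive, got {self.hop}")

    @property
    def effective_hop(self) -> float:
        return self.length if self.hop is None else self.hop

    def n_samples(self, fs: float) -> int:
        w = self.length * fs
        if abs(w - round(w)) > 1e-9:
            raise ValueError(
                f"window length {self.length}s is not a whole number of samples "
                f"at fs={fs} Hz"
            )
        return int(round(w))

    def indices(self, n_total: int, fs: float) -> Iterator[tuple[int, int, int]]:
        """Yield (window index, start sample, end sample) pairs.

        Windows lie entirely inside the recording; a trailing partial
        window is dropped.
        """
        w = self.n_samples(fs)
        hop = self.effective_hop * fs
        if abs(hop - round(hop)) > 1e-9:
            raise ValueError(f"hop {self.effective_hop}s is not a whole number of samples")
        hop = int(round(hop))
        k = 0
        start = 0
        while start + w <= n_total:
            yield k, start, start + w
            k += 1
            start += hop


# ---------------------------------------------------------------------------
# EDF I/O


def _edf_signal_headers(path: str | Path) -> tuple[int, float, list[dict]]:
    """Peek at the EDF header: (n_records, record_duration, per-signal dicts).

    Only the handful of fields needed to validate sampling-rate uniformity
    are decoded; full signal decoding is delegated to mne.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii").strip() or -1)
        rec_dur = float(hdr[244:252].decode("ascii").strip() or 1.0)
        ns = int(hdr[252:256].decode("ascii").strip())
        sig = fh.read(ns * 256)
        fields = []
        # EDF signal-header layout: ns consecutive arrays of fixed-width fields
        offs = 0
        labels = [sig[offs + i * 16 : offs + (i + 1) * 16].decode("ascii").strip() for i in range(ns)]
        offs = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        nsamp = [int(sig[offs + i * 8 : offs + (i + 1) * 8].decode("ascii").strip()) for i in range(ns)]
        for lab, n in zip(labels, nsamp):
            fields.append({"label": lab, "n_samples_per_record": n})
    return n_records, rec_dur, fields


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in microvolts).

    Raises if signal channels do not share one sampling rate (EDF
    annotation channels are ignored for this check).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_records, rec_dur, sig_hdrs = _edf_signal_headers(path)
    data_hdrs = [h for h in sig_hdrs if h["label"] != "EDF Annotations"]
    rates = {h["n_samples_per_record"] / rec_dur for h in data_hdrs}
    if len(rates) > 1:
        per_ch = ", ".join(
            f"{h['label']}={h['n_samples_per_record'] / rec_dur:g} Hz" for h in data_hdrs
        )
        raise ValueError(f"{path.name}: mixed sampling rates across channels ({per_ch})")

    import mne  # deferred: import is slow and only needed for EDF paths

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a standard 16-bit EDF file (1-second records).

    The physical range is set per channel from the data; quantization is
    therefore one part in 2^16 of each channel's peak-to-peak range.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_full = rec.n_samples // spr
    if n_full == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_full * spr]
    ns = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    now = _dt.datetime(2000, 1, 1)
    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_full), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    sig_hdr = b"".join(
        [
            b"".join(pad(lab, 16) for lab in rec.labels),
            b"".join(pad("", 80) for _ in range(ns)),
            b"".join(pad("uV", 8) for _ in range(ns)),
            b"".join(pad(f"{v:.8g}"[:8], 8) for v in pmin),
            b"".join(pad(f"{v:.8g}"[:8], 8) for v in pmax),
            b"".join(pad(str(dmin), 8) for _ in range(ns)),
            b"".join(pad(str(dmax), 8) for _ in range(ns)),
            b"".join(pad("", 80) for _ in range(ns)),
            b"".join(pad(str(spr), 8) for _ in range(ns)),
            b"".join(pad("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(sig_hdr)
        for r in range(n_full):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# CSV recordings (exact round trip for fixtures)


def write_csv_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV: a ``# fs=...`` comment line then one column
    per channel (exact round trip, unlike 16-bit EDF)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        writer = csv.writer(fh)
        writer.writerow(rec.labels)
        for row in rec.data.T:
            writer.writerow([repr(float(v)) for v in row])


def read_csv_recording(path: str | Path) -> Recording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        m = re.match(r"#\s*fs\s*=\s*([0-9.eE+-]+)", first)
        if not m:
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(m.group(1))
        reader = csv.reader(fh)
        labels = next(reader)
        rows = [[float(v) for v in row] for row in reader if row]
    return Recording(data=np.asarray(rows).T, fs=fs, labels=labels)


# ---------------------------------------------------------------------------
# Annotations

_CHB_START = re.compile(r"Seizure(?:\s+\d+)?\s+Start\s+Time\s*:\s*([0-9.]+)\s*sec", re.I)
_CHB_END = re.compile(r"Seizure(?:\s+\d+)?\s+End\s+Time\s*:\s*([0-9.]+)\s*sec", re.I)


def read_annotations(
    path: str | Path,
    dialect: str = "auto",
    on_overlap: str = "merge",
) -> list[SeizureInterval]:
    """Read seizure annotations.

    Parameters
    ----------
    dialect : {"auto", "csv", "chbmit"}
        ``csv`` expects ``onset,offset`` rows (an ``onset,offset`` header
        line is optional); ``chbmit`` parses summary-text files with
        ``Seizure Start/End Time: N seconds`` lines.  ``auto`` picks by
        file extension (.txt -> chbmit, otherwise csv).
    on_overlap : {"merge", "error"}
        What to do with overlapping intervals.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "chbmit" if path.suffix.lower() == ".txt" else "csv"
    if dialect not in {"csv", "chbmit"}:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")

    intervals: list[SeizureInterval] = []
    if dialect == "csv":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split(",")]
                if parts[0].lower() in {"onset", "onset_s"}:
                    continue  # header
                onset, offset = float(parts[0]), float(parts[1])
                intervals.append(SeizureInterval(onset, offset))
    else:
        text = Path(path).read_text()
        starts = [float(m) for m in _CHB_START.findall(text)]
        ends = [float(m) for m in _CHB_END.findall(text)]
        if len(starts) != len(ends):
            raise ValueError(f"{path}: unmatched seizure start/end marks")
        intervals = [SeizureInterval(a, b) for a, b in zip(starts, ends)]

    intervals.sort(key=lambda s: s.onset)
    merged: list[SeizureInterval] = []
    for iv in intervals:
        if merged and iv.onset < merged[-1].offset:
            if on_overlap == "error":
                raise ValueError(
                    f"overlapping annotations: {merged[-1]} and {iv}"
                )
            last = merged.pop()
            merged.append(SeizureInterval(last.onset, max(last.offset, iv.offset)))
        else:
            merged.append(iv)
    return merged


def write_annotations(intervals: Sequence[SeizureInterval], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("onset,offset\n")
        for iv in intervals:
            fh.write(f"{iv.onset!r},{iv.offset!r}\n")


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess(
    rec: Recording,
    band_lo: float = 1.0,
    band_hi: float = 50.0,
    rereference: bool = True,
    remove_baseline: bool = True,
    order: int = 4,
) -> Recording:
    """Baseline removal, average re-reference and zero-phase band-pass.

    The band-pass is a 4th-order Butterworth applied forward-backward
    (zero phase).  Channel means are removed first; the channel-average
    signal is then subtracted from every sample (common average
    reference), so each sample column sums to zero.
    """
    if not (0 < band_lo < band_hi):
        raise ValueError(f"need 0 < band_lo < band_hi, got [{band_lo}, {band_hi}]")
    if band_hi >= rec.fs / 2:
        raise ValueError(
            f"band_hi={band_hi} Hz is at or above Nyquist ({rec.fs / 2} Hz)"
        )
    data = rec.data.copy()
    if remove_baseline:
        data -= data.mean(axis=1, keepdims=True)
    if rereference:
        data -= data.mean(axis=0, keepdims=True)
    sos = _sig.butter(order, [band_lo, band_hi], btype="bandpass", fs=rec.fs, output="sos")
    data = _sig.sosfiltfilt(sos, data, axis=1)
    return rec.copy_with(data=data)


def normalize_range(rec: Recording, mode: str = "per_channel") -> Recording:
    """Scale the recording into [-1, 1] by max absolute value.

    ``per_channel`` scales each channel by its own peak over the whole
    recording (keeps low-amplitude channels informative); ``global`` uses
    one scale for the whole recording.  All-zero channels are left as
    zeros with a warning.
    """
    if mode not in {"per_channel", "global"}:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    data = rec.data.copy()
    if mode == "global":
        peak = np.abs(data).max()
        if peak == 0:
            warnings.warn("all-zero recording left unnormalized")
            return rec.copy_with(data=data)
        return rec.copy_with(data=data / peak)
    peaks = np.abs(data).max(axis=1)
    zero = peaks == 0
    if zero.any():
        warnings.warn(
            f"all-zero channels left unnormalized: "
            f"{[rec.labels[i] for i in np.flatnonzero(zero)]}"
        )
    peaks[zero] = 1.0
    return rec.copy_with(data=data / peaks[:, None])


def segment(rec: Recording, plan: WindowPlan) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(t_k, window)`` pairs; ``t_k`` is the window end time in
    seconds from recording start and ``window`` is channels x samples."""
    w = plan.n_samples(rec.fs)
    for _, start, end in plan.indices(rec.n_samples, rec.fs):
        t_k = rec.start_time + end / rec.fs
        yield t_k, rec.data[:, start:end]
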