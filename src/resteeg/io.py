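"""Recording data model, file readers/writers, and signal conditioning.

Recordings hold multichannel EEG in microvolts (channels x samples) with a
sampling rate and ordered channel names.  Reading BrainVision and EDF files
is delegated to :mod:`mne`; minimal EDF (16-bit) and BrainVision writers are
provided so that synthetic fixtures can be materialised without extra
dependencies.

Signal conditioning covers exactly what the analysis assumes: zero-phase
band-pass filtering, polyphase resampling, average re-referencing, and
segmentation into non-overlapping epochs.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("N", "A+P-", "A+P+")


class FormatError(ValueError):
    """A file failed to parse under its declared standard."""


@dataclass
class Recording:
    """One subject's multichannel EEG.

    Attributes
    ----------
    subject_id : str
        Subject identifier.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Ordered, unique channel names.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    group : str or None
        Risk-group label (``"N"``, ``"A+P-"``, ``"A+P+"``); supplied from a
        participants table, not from EEG headers.
    """

    subject_id: str
    fs: float
    channels: list[str]
    data: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} "
                f"rows but {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate channel names")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs cut from one recording."""

    epochs: list[np.ndarray]
    epoch_len_s: float
    source: str

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError("epochs differ in shape")


# ---------------------------------------------------------------------------
# Readers (mne-backed)
# ---------------------------------------------------------------------------

def read_recording(path, fmt: str | None = None, subject_id: str | None = None) -> Recording:
    """Read an EEG file into a :class:`Recording` (data in microvolts).

    Parameters
    ----------
    path : path-like
        ``.vhdr`` (BrainVision) or ``.edf`` file.
    fmt : {"brainvision", "edf"}, optional
        Inferred from the suffix when omitted.
    subject_id : str, optional
        Defaults to the file stem.  The group label is left unset; join it
        from a participants table with :func:`read_participants`.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    try:
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except ValueError:
        raise
    except Exception as exc:  # mne raises various types for corrupt files
        raise FormatError(f"could not parse {path.name} as {fmt}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        subject_id=subject_id or path.stem,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        data=data_uv,
    )


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > n:
        raise ValueError(f"field {text!r} exceeds {n} bytes")
    return b.ljust(n)


def write_edf(rec: Recording, path) -> Path:
    """Write a 16-bit EDF file.

    Uses 1-second data records when the duration is a whole number of
    seconds, otherwise a single record spanning the recording.  Physical
    scaling is per-channel (symmetric around zero), so the round-trip error
    is bounded by the 16-bit quantisation step.
    """
    path = Path(path).with_suffix(".edf")
    fs, n_samp, ns = rec.fs, rec.n_samples, rec.n_channels
    if n_samp % int(fs) == 0 and fs == int(fs):
        n_records, spr, rec_dur = n_samp // int(fs), int(fs), 1.0
    else:
        n_records, spr, rec_dur = 1, n_samp, n_samp / fs
    dur_str = f"{rec_dur:.6g}"
    if len(dur_str) > 8:
        raise ValueError("record duration does not fit the EDF header field")

    pmax_raw = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    # encode with the values as printed in the header, so reader and writer
    # agree exactly on the affine digital->physical map
    pmax = np.array([float(f"{p:.6g}"[:8]) for p in 1.0001 * pmax_raw])
    slope = 2.0 * pmax / 65535.0
    digital = np.clip(
        np.round((rec.data - (-pmax[:, None])) / slope[:, None]) - 32768,
        -32768, 32767,
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(rec.subject_id, 80),
        _pad("Startdate 01-JAN-2000", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad(dur_str, 8),
        _pad(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_pad(ch[:16], 16) for ch in rec.channels),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad("uV", 8) for _ in range(ns)),
        b"".join(_pad(f"{-p:.6g}"[:8], 8) for p in pmax),
        b"".join(_pad(f"{p:.6g}"[:8], 8) for p in pmax),
        b"".join(_pad("-32768", 8) for _ in range(ns)),
        b"".join(_pad("32767", 8) for _ in range(ns)),
        b"".join(_pad("", 80) for _ in range(ns)),
        b"".join(_pad(str(spr), 8) for _ in range(ns)),
        b"".join(_pad("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within each record
    return path


def write_brainvision(rec: Recording, stem, binary_format: str = "IEEE_FLOAT_32") -> Path:
    """Write a BrainVision triplet (``.vhdr``/``.vmrk``/``.eeg``).

    ``binary_format`` is ``IEEE_FLOAT_32`` (lossless) or ``INT_16``
    (quantised with a per-channel resolution).  Returns the ``.vhdr`` path.
    """
    stem = Path(stem)
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise ValueError(f"unsupported binary format {binary_format!r}")

    if binary_format == "IEEE_FLOAT_32":
        res = np.ones(rec.n_channels)
        payload = rec.data.T.astype("<f4")  # multiplexed: sample-major
    else:
        res = np.maximum(np.abs(rec.data).max(axis=1), 1e-6) / 32767.0
        payload = np.clip(
            np.round(rec.data / res[:, None]), -32768, 32767
        ).astype("<i2").T
    ch_lines = "\n".join(
        f"Ch{i + 1}={ch},,{res[i]:.10g},µV"
        for i, ch in enumerate(rec.channels)
    )
    vhdr_text = f"""Brain Vision Data Exchange Header File Version 1.0
; Written by resteeg fixture writer

[Common Infos]
Codepage=UTF-8
DataFile={eeg.name}
MarkerFile={vmrk.name}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={rec.n_channels}
SamplingInterval={1e6 / rec.fs:.10g}

[Binary Infos]
BinaryFormat={binary_format}

[Channel Infos]
{ch_lines}
"""
    vmrk_text = f"""Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={eeg.name}

[Marker Infos]
Mk1=New Segment,,1,1,0,0
"""
    vhdr.write_text(vhdr_text, encoding="utf-8")
    vmrk.write_text(vmrk_text, encoding="utf-8")
    eeg.write_bytes(payload.tobytes())
    return vhdr


# ---------------------------------------------------------------------------
# Participants table (BIDS-style sidecar)
# ---------------------------------------------------------------------------

def read_participants(path) -> dict[str, str]:
    """Read a ``participants.tsv`` (columns ``participant_id``, ``group``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("participant_id", "group"):
        if col not in df.columns:
            raise FormatError(f"participants table lacks column {col!r}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}")
    return dict(zip(df["participant_id"], df["group"]))


def write_participants(groups: dict[str, str], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"participant_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)
    return path


def attach_groups(recordings: list[Recording], table: dict[str, str]) -> None:
    """Set ``rec.group`` from a participants mapping, in place."""
    for rec in recordings:
        if rec.subject_id not in table:
            raise KeyError(f"subject {rec.subject_id!r} missing from participants table")
        rec.group = table[rec.subject_id]


# ---------------------------------------------------------------------------
# Signal conditioning
# ---------------------------------------------------------------------------

def bandpass_and_resample(rec: Recording, lo: float, hi: float, fs_out: float) -> Recording:
    """Zero-phase FIR band-pass followed by polyphase resampling.

    The transition bandwidths follow the firwin defaults (25 % of the cutoff,
    bounded to stay above 2 Hz for the upper edge).  ``hi`` must lie below
    the output Nyquist frequency.
    """
    import mne

    if not (0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    if hi >= fs_out / 2:
        raise ValueError(
            f"upper cutoff {hi} Hz is not below the output Nyquist ({fs_out / 2} Hz)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = mne.filter.filter_data(
            rec.data, sfreq=rec.fs, l_freq=lo if lo > 0 else None, h_freq=hi,
            phase="zero", fir_design="firwin", verbose="error",
        )
    frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
    from scipy.signal import resample_poly

    out = resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return Recording(rec.subject_id, fs_out, list(rec.channels), out, rec.group)


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous channel mean (common average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(rec.subject_id, rec.fs, list(rec.channels), data, rec.group)


def segment(rec: Recording, epoch_len_s: float) -> EpochSet:
    """Cut into non-overlapping epochs; trailing partial samples are dropped."""
    n_per = epoch_len_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch length times sampling rate must be an integer")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3g} s shorter than one "
            f"{epoch_len_s:.3g} s epoch"
        )
    epochs = [
        rec.data[:, i * n_per:(i + 1) * n_per].copy() for i in range(n_epochs)
    ]
    return EpochSet(epochs, epoch_len_s, rec.subject_id)
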