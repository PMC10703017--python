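"""Reading and writing EEG recordings (EDF and HDF5).

EDF reading is delegated to :mod:`mne`.  Writing uses a compact EDF+
serializer implemented here (16-bit samples, one-second data records),
whose output is verified against mne's independent reader in the test
suite.  HDF5 is the lossless mirror format and additionally stores the
ground-truth artifact intervals that EDF cannot carry.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np

from .synth import EEGRecording


class FormatError(ValueError):
    """Raised when an EEG file cannot be read or written."""


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as EDF (µV, 16-bit).

    Data records are one second long; a trailing partial second is dropped.
    The subject id and class label are stored in the patient/recording
    identification fields.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per record per signal
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels
    data = rec.data[:, : n_records * spr]

    # physical range per channel, printed then re-parsed so the scaling used
    # for quantization matches what a reader will recover from the header
    phys_min_s, phys_max_s = [], []
    for ch in range(nch):
        m = float(np.max(np.abs(data[ch])))
        m = max(m, 1e-6)
        s = f"{m:.6g}"[:8]
        phys_max_s.append(s)
        phys_min_s.append(f"-{s}"[:8])
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(rec.subject_id, 80)
    header += _edf_field(f"label={rec.label}", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (nch + 1)), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)
    header += _edf_field(str(nch), 4)

    def sig_fields(values: list[str], width: int) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    header += sig_fields(rec.channel_names, 16)
    header += sig_fields([""] * nch, 80)
    header += sig_fields(["uV"] * nch, 8)
    header += sig_fields(phys_min_s, 8)
    header += sig_fields(phys_max_s, 8)
    header += sig_fields([str(dig_min)] * nch, 8)
    header += sig_fields([str(dig_max)] * nch, 8)
    header += sig_fields([""] * nch, 80)
    header += sig_fields([str(spr)] * nch, 8)
    header += sig_fields([""] * nch, 32)

    digital = np.empty((nch, n_records * spr), dtype="<i2")
    for ch in range(nch):
        pmin, pmax = float(phys_min_s[ch]), float(phys_max_s[ch])
        scale = (dig_max - dig_min) / (pmax - pmin)
        d = np.round((data[ch] - pmin) * scale + dig_min)
        digital[ch] = np.clip(d, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major layout: for each second, each signal's block
        blocks = digital.reshape(nch, n_records, spr)
        for r in range(n_records):
            fh.write(blocks[:, r, :].tobytes())


def read_edf(path: str | Path, subject_id: str | None = None,
             label: int | None = None) -> EEGRecording:
    """Read an EDF/BDF file via mne; data returned in µV."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of ValueError/OSError subtypes
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    # patient (bytes 8..88) and recording (88..168) identification fields
    with open(path, "rb") as fh:
        header = fh.read(168)
    patient = header[8:88].decode("ascii", errors="replace").strip()
    recording = header[88:168].decode("ascii", errors="replace").strip()
    if subject_id is None:
        subject_id = patient or path.stem
    if label is None:
        m = re.search(r"label=(\d+)", recording)
        label = int(m.group(1)) if m else 0
    return EEGRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names),
                        subject_id=subject_id, label=int(label))


def write_hdf5(rec: EEGRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["label"] = rec.label
        f.create_dataset("channel_names",
                         data=np.array(rec.channel_names, dtype="S16"))
        truth = np.array(rec.artifact_truth, dtype=np.int64).reshape(-1, 2)
        f.create_dataset("artifact_truth", data=truth)


def read_hdf5(path: str | Path) -> EEGRecording:
    try:
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            names = [n.decode() for n in f["channel_names"][()]]
            truth = [tuple(int(v) for v in row) for row in f["artifact_truth"][()]]
            return EEGRecording(data=data, fs=float(f.attrs["fs"]),
                                channel_names=names,
                                subject_id=str(f.attrs["subject_id"]),
                                label=int(f.attrs["label"]),
                                artifact_truth=truth)
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read HDF5 file {path}: {exc}") from exc


_FORMATS = {".edf": "edf", ".bdf": "edf", ".h5": "hdf5", ".hdf5": "hdf5"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = path.suffix.lower()
    if ext not in _FORMATS:
        raise FormatError(f"cannot infer format of {path} (extension {ext!r})")
    return _FORMATS[ext]


def write_eeg(rec: EEGRecording, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        write_edf(rec, path)
    else:
        write_hdf5(rec, path)


def read_eeg(path: str | Path, fmt: str | None = None, *,
             subject_id: str | None = None, label: int | None = None) -> EEGRecording:
    """Read an EEG recording from EDF/BDF or HDF5.

    ``subject_id``/``label`` override what the file header carries (e.g. when
    a manifest supplies them).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        return read_edf(path, subject_id=subject_id, label=label)
    rec = read_hdf5(path)
    if subject_id is not None:
        rec.subject_id = subject_id
    if label is not None:
        rec.label = label
    return rec
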