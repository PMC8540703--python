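"""Fragment exchange formats and optional clinical-format readers.

Three interchange routes for :class:`~drowsyindex.band_features.EegFragment`:

* a columnar CSV dialect (``time, F3..O2, stage``) — human-readable, exact;
* a compact NPZ binary container — exact, fast;
* 16-bit EDF and WFDB-style (.hea + format-16 .dat) records — lossy
  (int16 quantization), for interoperability with polysomnography tools.
  EDF reading goes through :mod:`mne`; the EDF writer and the WFDB
  reader/writer are minimal self-contained implementations of those
  simple formats.

Channel selection in the clinical readers matches the six 10/20 labels
case-insensitively and tolerates common prefixes such as ``EEG F3-M2``.
"""

from __future__ import annotations

import re
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .band_features import CHANNELS, EegFragment

__all__ = [
    "fragment_to_csv",
    "fragment_from_csv",
    "fragment_to_npz",
    "fragment_from_npz",
    "write_edf",
    "read_edf",
    "write_wfdb",
    "read_wfdb",
]


def _stage_column(fragment: EegFragment) -> np.ndarray:
    t = np.arange(fragment.n_samples) / fragment.fs
    return np.where(t < fragment.stage_boundary, "W", "S1")


def fragment_to_csv(fragment: EegFragment, path) -> None:
    t = np.arange(fragment.n_samples) / fragment.fs
    df = pd.DataFrame({"time": t})
    for i, ch in enumerate(CHANNELS):
        df[ch] = fragment.samples[i]
    df["stage"] = _stage_column(fragment)
    df.to_csv(path, index=False)


def fragment_from_csv(path, subject_id: str = "") -> EegFragment:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    samples = np.vstack([df[ch].to_numpy() for ch in CHANNELS])
    stages = df["stage"].to_numpy()
    s1 = np.flatnonzero(stages == "S1")
    total = len(t) / fs
    boundary = t[s1[0]] if s1.size else total / 2
    return EegFragment(samples=samples, fs=round(fs, 6),
                       stage_boundary=float(boundary),
                       total_duration=float(round(total, 6)),
                       subject_id=subject_id or str(path))


def fragment_to_npz(fragment: EegFragment, path) -> None:
    np.savez_compressed(
        path, samples=fragment.samples, fs=fragment.fs,
        stage_boundary=fragment.stage_boundary,
        total_duration=fragment.total_duration,
        subject_id=np.array(fragment.subject_id),
    )


def fragment_from_npz(path) -> EegFragment:
    with np.load(path, allow_pickle=False) as z:
        return EegFragment(
            samples=z["samples"], fs=float(z["fs"]),
            stage_boundary=float(z["stage_boundary"]),
            total_duration=float(z["total_duration"]),
            subject_id=str(z["subject_id"]),
        )


# ---------------------------------------------------------------------------
# EDF (16-bit, standard header)

_EDF_LABEL_RE = re.compile(r"(F3|F4|C3|C4|O1|O2)", re.IGNORECASE)


def _match_channel(label: str) -> str | None:
    m = _EDF_LABEL_RE.search(label)
    return m.group(1).upper() if m else None


def write_edf(fragment: EegFragment, path) -> None:
    """Write a minimal 16-bit EDF file (1 s data records, µV units)."""
    fs = fragment.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))                      # samples per record per signal
    n_records = fragment.n_samples // spr
    ns = len(CHANNELS)

    phys_min = np.floor(fragment.samples.min(axis=1))
    phys_max = np.ceil(fragment.samples.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(fragment.subject_id or "X", 80),
        pad("synthetic", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    fields = [
        [pad(ch, 16) for ch in CHANNELS],
        [pad("AgAgCl electrode", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{phys_min[i]:g}", 8) for i in range(ns)],
        [pad(f"{phys_max[i]:g}", 8) for i in range(ns)],
        [pad(str(dig_min), 8)] * ns,
        [pad(str(dig_max), 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(spr), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    header += b"".join(b"".join(col) for col in fields)

    gains = (phys_max - phys_min) / (dig_max - dig_min)
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            block = fragment.samples[:, r * spr:(r + 1) * spr]
            dig = np.round((block - phys_min[:, None]) / gains[:, None]
                           + dig_min).astype("<i2")
            f.write(dig.tobytes())


def read_edf(path, stage_boundary: float | None = None,
             subject_id: str = "") -> EegFragment:
    """Read an EDF record via mne, selecting the six 10/20 channels.

    ``stage_boundary`` defaults to the midpoint of the record.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks: dict[str, str] = {}
    for name in raw.ch_names:
        ch = _match_channel(name)
        if ch and ch not in picks:
            picks[ch] = name
    missing = [ch for ch in CHANNELS if ch not in picks]
    if missing:
        raise ValueError(f"EDF record lacks channels {missing}")
    data = np.vstack([raw.get_data(picks=[picks[ch]])[0] for ch in CHANNELS])
    data = data * 1e6  # mne returns volts for EEG channels
    fs = float(raw.info["sfreq"])
    total = data.shape[1] / fs
    return EegFragment(samples=data, fs=fs,
                       stage_boundary=stage_boundary or total / 2,
                       total_duration=total,
                       subject_id=subject_id or Path(path).stem)


# ---------------------------------------------------------------------------
# WFDB-style (.hea + format-16 signal file)


def write_wfdb(fragment: EegFragment, record_path) -> None:
    """Write a minimal WFDB record: text header + interleaved int16 .dat."""
    record_path = Path(record_path)
    record = record_path.name
    fs = fragment.fs
    n = fragment.n_samples
    gain = 100.0  # ADC units per µV -> ±327 µV range, fine for EEG
    header = [f"{record} {len(CHANNELS)} {fs:g} {n}"]
    for ch in CHANNELS:
        header.append(f"{record}.dat 16 {gain:g}(0)/uV 16 0 0 0 0 {ch}")
    record_path.with_suffix(".hea").write_text("\n".join(header) + "\n")
    dig = np.clip(np.round(fragment.samples * gain), -32768, 32767)
    dig.astype("<i2").T.tofile(record_path.with_suffix(".dat"))


def read_wfdb(record_path, stage_boundary: float | None = None,
              subject_id: str = "") -> EegFragment:
    """Read a format-16 WFDB record, selecting the six 10/20 channels."""
    record_path = Path(record_path)
    lines = [ln for ln in
             record_path.with_suffix(".hea").read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    _, nsig, fs, n = lines[0].split()[:4]
    nsig, fs, n = int(nsig), float(fs), int(n)

    names, gains, baselines = [], [], []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        if tok[1] != "16":
            raise ValueError("only format-16 WFDB signals are supported")
        m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?(?:/(\S+))?", tok[2])
        gains.append(float(m.group(1)) if m else 200.0)
        baselines.append(int(m.group(2)) if m and m.group(2) else 0)
        names.append(tok[-1])

    dig = np.fromfile(record_path.with_suffix(".dat"), dtype="<i2")
    dig = dig.reshape(-1, nsig).T.astype(float)[:, :n]
    phys = (dig - np.array(baselines)[:, None]) / np.array(gains)[:, None]

    picks = {}
    for i, name in enumerate(names):
        ch = _match_channel(name)
        if ch and ch not in picks:
            picks[ch] = i
    missing = [ch for ch in CHANNELS if ch not in picks]
    if missing:
        raise ValueError(f"WFDB record lacks channels {missing}")
    samples = np.vstack([phys[picks[ch]] for ch in CHANNELS])
    total = samples.shape[1] / fs
    return EegFragment(samples=samples, fs=fs,
                       stage_boundary=stage_boundary or total / 2,
                       total_duration=total,
                       subject_id=subject_id or record_path.name)
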