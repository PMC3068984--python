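"""File formats: hypnogram CSV, feature CSV, NPZ and EDF recordings.

Hypnogram CSV dialect: UTF-8, comma-separated, header row
``animal_id,day,epoch_index,zt_hours,state,provenance`` with states spelled
exactly WAKE/NREMS/REMS and provenance AUTO/OVERRIDE.  Validation is strict
and fails with the offending row number.  NPZ round-trips are bit-exact;
EDF stores each channel as 16-bit integers over the declared physical
range, so a write/read round-trip is exact only up to one quantisation
step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from srsleep.features import RawRecording
from srsleep.states import (
    Hypnogram,
    PROVENANCE_AUTO,
    PROVENANCE_OVERRIDE,
    STATE_NAMES,
    VigilanceState,
)

__all__ = [
    "write_hypnogram_csv",
    "read_hypnogram_csv",
    "write_recording_npz",
    "read_recording_npz",
    "write_recording_edf",
    "read_recording_edf",
]

_PROV_NAMES = {PROVENANCE_AUTO: "AUTO", PROVENANCE_OVERRIDE: "OVERRIDE"}
_PROV_CODES = {v: k for k, v in _PROV_NAMES.items()}


def write_hypnogram_csv(hypnograms, path) -> Path:
    """Write one or more hypnograms (e.g. several days) to one CSV."""
    if isinstance(hypnograms, Hypnogram):
        hypnograms = [hypnograms]
    frames = []
    for h in hypnograms:
        frames.append(pd.DataFrame({
            "animal_id": h.animal_id,
            "day": h.day_index,
            "epoch_index": np.arange(h.n_epochs),
            "zt_hours": h.zt,
            "state": [STATE_NAMES[s] for s in h.states],
            "provenance": [_PROV_NAMES[p] for p in h.provenance],
        }))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_hypnogram_csv(path) -> list:
    """Read hypnograms from CSV; returns one Hypnogram per (animal, day).

    Any malformed state or provenance label is rejected with its row number
    (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "state": str, "provenance": str})
    required = {"animal_id", "day", "epoch_index", "zt_hours", "state", "provenance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_state = ~df["state"].isin(STATE_NAMES)
    if bad_state.any():
        row = int(df.index[bad_state][0]) + 2
        raise ValueError(f"{path}: invalid state {df.loc[row - 2, 'state']!r} at row {row}")
    bad_prov = ~df["provenance"].isin(_PROV_CODES)
    if bad_prov.any():
        row = int(df.index[bad_prov][0]) + 2
        raise ValueError(f"{path}: invalid provenance at row {row}")
    out = []
    for (animal, day), g in df.groupby(["animal_id", "day"], sort=True):
        g = g.sort_values("epoch_index")
        if not np.array_equal(g["epoch_index"].to_numpy(), np.arange(len(g))):
            raise ValueError(f"{path}: non-contiguous epoch indices for {animal} day {day}")
        out.append(Hypnogram(
            states=np.array([VigilanceState[s] for s in g["state"]], dtype=np.int8),
            zt_start=float(g["zt_hours"].iloc[0]),
            animal_id=str(animal),
            day_index=int(day),
            provenance=np.array([_PROV_CODES[p] for p in g["provenance"]], dtype=np.int8),
        ))
    return out


def write_recording_npz(recording: RawRecording, path) -> Path:
    path = Path(path)
    np.savez(
        path,
        eeg=recording.eeg,
        emg=recording.emg,
        sample_rate=recording.sample_rate,
        zt_start=recording.zt_start,
        animal_id=np.array(recording.animal_id),
        day_index=recording.day_index,
    )
    return path


def read_recording_npz(path) -> RawRecording:
    with np.load(Path(path), allow_pickle=False) as z:
        return RawRecording(
            eeg=z["eeg"], emg=z["emg"],
            sample_rate=float(z["sample_rate"]), zt_start=float(z["zt_start"]),
            animal_id=str(z["animal_id"]), day_index=int(z["day_index"]),
        )


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(recording: RawRecording, path, physical_range: float | None = None) -> Path:
    """Write the two channels as a minimal EDF file (16-bit, uV).

    One data record per second; the physical range defaults to a symmetric
    span covering the data.  Quantisation error is bounded by one step of
    (2 * range) / 65535.
    """
    sr = recording.sample_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    sr = int(round(sr))
    n = recording.n_samples
    if n % sr:
        raise ValueError("recording length must be a whole number of seconds for EDF export")
    n_records = n // sr
    chans = [("EEG", recording.eeg), ("EMG", recording.emg)]
    if physical_range is None:
        physical_range = float(max(np.abs(np.concatenate([recording.eeg, recording.emg])).max(), 1.0))
    pmin, pmax = -physical_range, physical_range
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"animal {recording.animal_id or 'X'}", 80),
        _edf_field(f"day {recording.day_index}", 80),
        _edf_field("01.01.11", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + 256 * len(chans), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(len(chans), 4),
    ])
    fields = [
        (16, [name for name, _ in chans]),
        (80, ["" for _ in chans]),
        (8, ["uV" for _ in chans]),
        (8, [f"{pmin:.8g}"[:8] for _ in chans]),
        (8, [f"{pmax:.8g}"[:8] for _ in chans]),
        (8, [dmin for _ in chans]),
        (8, [dmax for _ in chans]),
        (80, ["" for _ in chans]),
        (8, [sr for _ in chans]),
        (32, ["" for _ in chans]),
    ]
    sig_header = b"".join(
        b"".join(_edf_field(v, width) for v in values) for width, values in fields
    )
    scale = (dmax - dmin) / (pmax - pmin)
    digital = []
    for _, x in chans:
        d = np.round((np.clip(x, pmin, pmax) - pmin) * scale) + dmin
        digital.append(d.astype("<i2").reshape(n_records, sr))
    path = Path(path)
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for r in range(n_records):
            for d in digital:
                f.write(d[r].tobytes())
    return path


def read_recording_edf(path, *, zt_start: float = 0.0, expected_rate: float = 64.0) -> RawRecording:
    """Read a two-channel EDF recording via MNE (optional dependency).

    Only 64 Hz recordings are accepted; resampling is out of scope.
    """
    import mne  # local import: EDF input is optional

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if abs(raw.info["sfreq"] - expected_rate) > 1e-6:
        raise ValueError(
            f"{path}: sample rate {raw.info['sfreq']} Hz, expected {expected_rate} Hz "
            "(resampling is out of scope)"
        )
    data = raw.get_data(units="uV")
    return RawRecording(eeg=data[0], emg=data[1], sample_rate=float(raw.info["sfreq"]),
                        zt_start=zt_start)
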