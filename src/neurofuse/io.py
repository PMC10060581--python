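"""File formats: SNIRF (fNIRS, HDF5), EDF (EEG), JSON sidecars, CSV tables.

SNIRF files are written/read directly with h5py following the SNIRF v1.0
layout (continuous-wave amplitude, one measurementList entry per
channel x wavelength). EDF is written by a minimal built-in writer (EDF
is an ASCII header plus 16-bit little-endian records); ``mne`` serves as
the independent reader for round-trip checks. Events and planted ground
truth travel as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import ProbeGeometry, _electrode_positions
from .schedule import CONDITIONS, EventSchedule
from .simulate import GroundTruth, MultimodalSession


# --------------------------------------------------------------------------
# SNIRF
# --------------------------------------------------------------------------

def write_snirf(path: str | Path, session: MultimodalSession) -> None:
    """Write one session's raw fNIRS intensities as a SNIRF file."""
    geom = session.geometry
    c, w, t = session.fnirs_intensity.shape
    data = session.fnirs_intensity.reshape(c * w, t).T  # (T, M)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(session.participant))
        meta.create_dataset("MeasurementDate", data="2000-01-01")
        meta.create_dataset("MeasurementTime", data="00:00:00")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("SubjectAge", data=float(session.participant_age))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.array([0.0, 1.0 / session.fnirs_rate]))
        m = 1
        for ch, (s, d) in enumerate(geom.channel_pairs):
            for wl in range(w):
                g = d1.create_group(f"measurementList{m}")
                g.create_dataset("sourceIndex", data=s + 1)
                g.create_dataset("detectorIndex", data=d + 1)
                g.create_dataset("wavelengthIndex", data=wl + 1)
                g.create_dataset("dataType", data=1)  # CW amplitude
                g.create_dataset("dataTypeIndex", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([695.0, 830.0]))
        probe.create_dataset("sourcePos3D", data=geom.source_positions)
        probe.create_dataset("detectorPos3D", data=geom.detector_positions)
        for i, cond in enumerate(CONDITIONS, start=1):
            trials = session.schedule.by_condition(cond)
            st = nirs.create_group(f"stim{i}")
            st.create_dataset("name", data=cond)
            st.create_dataset(
                "data",
                data=np.array([[tr.onset, tr.duration, 1.0] for tr in trials]),
            )


def read_snirf(path: str | Path):
    """Read a SNIRF file written by :func:`write_snirf`.

    Returns (intensity (channels, wavelengths, T), sampling_rate,
    geometry, schedule, subject_age)."""
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        series = d1["dataTimeSeries"][()]
        time = d1["time"][()]
        if len(time) == 2:
            rate = 1.0 / time[1]
        else:
            rate = 1.0 / np.median(np.diff(time))
        ml = sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        pairs, wl_idx = [], []
        for k in ml:
            g = d1[k]
            pairs.append((int(g["sourceIndex"][()]) - 1,
                          int(g["detectorIndex"][()]) - 1))
            wl_idx.append(int(g["wavelengthIndex"][()]) - 1)
        n_wl = max(wl_idx) + 1
        n_ch = len(ml) // n_wl
        intensity = np.empty((n_ch, n_wl, series.shape[0]))
        chan_pairs = []
        for col, (pair, wl) in enumerate(zip(pairs, wl_idx)):
            ch = col // n_wl
            intensity[ch, wl] = series[:, col]
            if wl == 0:
                chan_pairs.append(pair)
        geom = ProbeGeometry(
            source_positions=f["nirs/probe/sourcePos3D"][()],
            detector_positions=f["nirs/probe/detectorPos3D"][()],
            channel_pairs=tuple(chan_pairs),
            electrode_positions=_electrode_positions(),
        )
        trials = []
        for i in range(1, 10):
            key = f"nirs/stim{i}"
            if key not in f:
                break
            name = f[key]["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            for onset, dur, _amp in f[key]["data"][()]:
                trials.append({"condition": name, "onset": float(onset),
                               "duration": float(dur)})
        age = float(f["nirs/metaDataTags/SubjectAge"][()])
    trials.sort(key=lambda r: r["onset"])
    schedule = EventSchedule.from_dicts(trials)
    return intensity, float(rate), geom, schedule, age


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str | Path, data: np.ndarray, labels: tuple[str, ...],
              sampling_rate: float, physical_unit: str = "uV") -> None:
    """Write continuous EEG (channels x time, uV) as EDF.

    One-second data records of int16 samples; the trailing partial second
    is dropped. Physical scaling is symmetric around zero and chosen from
    the data range.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samples = data.shape
    spr = int(round(sampling_rate))
    if abs(spr - sampling_rate) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    n_rec = n_samples // spr
    data = data[:, : n_rec * spr]
    phys_max = max(float(np.abs(data).max()) * 1.05, 1.0)
    dig_max = 32767
    scale = dig_max / phys_max
    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_ch), 4))
        for lab in labels:
            f.write(_pad(f"EEG {lab}", 16))
        for _ in labels:
            f.write(_pad("AgAgCl electrode", 80))
        for _ in labels:
            f.write(_pad(physical_unit, 8))
        for _ in labels:
            f.write(_pad(f"{-phys_max:.6g}"[:8], 8))
        for _ in labels:
            f.write(_pad(f"{phys_max:.6g}"[:8], 8))
        for _ in labels:
            f.write(_pad(str(-dig_max - 1), 8))
        for _ in labels:
            f.write(_pad(str(dig_max), 8))
        for _ in labels:
            f.write(_pad("", 80))
        for _ in labels:
            f.write(_pad(str(spr), 8))
        for _ in labels:
            f.write(_pad("", 32))
        digital = np.clip(np.round(data * scale), -dig_max - 1, dig_max)
        digital = digital.astype("<i2")
        # records: per second, channel-sequential
        rec = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        f.write(rec.tobytes())


def read_edf(path: str | Path):
    """Read an EDF file with mne; returns (data uV, labels, sampling rate)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(ch.replace("EEG ", "") for ch in raw.ch_names)
    data = raw.get_data() * 1e6  # mne loads EEG in volts
    return data, labels, float(raw.info["sfreq"])


# --------------------------------------------------------------------------
# JSON sidecars
# --------------------------------------------------------------------------

def write_events_json(path: str | Path, schedule: EventSchedule) -> None:
    Path(path).write_text(json.dumps(
        {"lead_in": schedule.lead_in, "trials": schedule.to_dicts()}, indent=1))


def read_events_json(path: str | Path) -> EventSchedule:
    obj = json.loads(Path(path).read_text())
    return EventSchedule.from_dicts(obj["trials"], lead_in=obj.get("lead_in", 10.0))


def write_truth_json(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        latent=np.array(d["latent"]),
        latent_fnirs=np.array(d["latent_fnirs"]),
        latent_eeg=np.array(d["latent_eeg"]),
        active_fnirs_channels=tuple(d["active_fnirs_channels"]),
        active_electrodes=tuple(d["active_electrodes"]),
        hb_gain=d["hb_gain"],
        alpha_gain=d["alpha_gain"],
        target_cross_correlation=d["target_cross_correlation"],
        planted_latent_correlation=d["planted_latent_correlation"],
    )


def save_session(out_dir: str | Path, session: MultimodalSession) -> dict:
    """Write one session's SNIRF + EDF + JSON sidecars; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = session.participant
    paths = {
        "snirf": out / f"{pid}.snirf",
        "edf": out / f"{pid}.edf",
        "events": out / f"{pid}_events.json",
        "truth": out / f"{pid}_truth.json",
    }
    write_snirf(paths["snirf"], session)
    write_edf(paths["edf"], session.eeg_signal, session.eeg_labels,
              session.eeg_rate)
    write_events_json(paths["events"], session.schedule)
    if session.truth is not None:
        write_truth_json(paths["truth"], session.truth)
    return {k: str(v) for k, v in paths.items()}


__all__ = [
    "write_snirf", "read_snirf", "write_edf", "read_edf",
    "write_events_json", "read_events_json", "write_truth_json",
    "read_truth_json", "save_session",
]
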