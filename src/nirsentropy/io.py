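"""Readers and writers: delimited-text recording dialect, SNIRF (HDF5),
event tables, tidy result tables.

The text dialect is one file per subject: ``#``-prefixed header lines
(sampling rate, wavelengths, per-channel source-detector distances,
subject metadata), then a tab-separated matrix of time x
(channel, wavelength) columns.  Events live in a sibling 3-column TSV
(label, start_s, end_s).  The SNIRF writer produces a minimal but
standard-layout HDF5 file (formatVersion, /nirs/data1 with one
measurementList entry per column, probe geometry encoding the
source-detector distances, stim groups for the phases).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import PhaseWindows, RawIntensityRecording, HemoglobinRecording
from .synthetic import CohortGroundTruth

_FLOAT_FMT = "%.10g"


def write_events_tsv(events: PhaseWindows, sampling_rate: float, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart_s\tend_s\n")
        for label, start, end in events.windows:
            fh.write(f"{label}\t{start / sampling_rate:.10g}\t{end / sampling_rate:.10g}\n")


def read_events_tsv(path, sampling_rate: float) -> PhaseWindows:
    df = pd.read_csv(path, sep="\t")
    windows = tuple(
        (str(r.label), int(round(r.start_s * sampling_rate)),
         int(round(r.end_s * sampling_rate)))
        for r in df.itertuples()
    )
    return PhaseWindows(windows)


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events.tsv")


def write_recording_text(rec: RawIntensityRecording, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# nirsentropy-raw v1\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# group_label: {rec.group_label}\n")
        fh.write(f"# sampling_rate_hz: {rec.sampling_rate:.10g}\n")
        fh.write("# wavelengths_nm: " + " ".join(f"{w:g}" for w in rec.wavelengths) + "\n")
        fh.write("# distances_cm: "
                 + " ".join(f"{d:g}" for d in rec.source_detector_distance_cm) + "\n")
        cols = ["time_s"] + [
            f"ch{ch + 1:02d}_{w:.0f}nm"
            for ch in range(rec.n_channels)
            for w in rec.wavelengths
        ]
        fh.write("\t".join(cols) + "\n")
        t = np.arange(rec.n_samples) / rec.sampling_rate
        flat = rec.intensities.reshape(rec.n_channels * len(rec.wavelengths),
                                       rec.n_samples)
        block = np.vstack([t, flat]).T
        np.savetxt(fh, block, fmt=_FLOAT_FMT, delimiter="\t")
    write_events_tsv(rec.events, rec.sampling_rate, _events_path(path))
    return path


def _parse_header(path) -> tuple[dict, list[str], np.ndarray]:
    meta, header = {}, None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# ") and ":" in line:
                key, _, val = line[2:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.startswith("#"):
                continue
            elif header is None:
                header = line.split("\t")
            else:
                rows.append(line)
    if header is None:
        raise ValueError(f"{path}: no column header found")
    data = np.loadtxt(rows, delimiter="\t", ndmin=2)
    return meta, header, data


def read_recording_text(path) -> RawIntensityRecording:
    path = Path(path)
    meta, header, data = _parse_header(path)
    fs = float(meta["sampling_rate_hz"])
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"].split())
    distances = np.array([float(d) for d in meta["distances_cm"].split()])
    n_ch = len(distances)
    inten = data[:, 1:].T.reshape(n_ch, len(wavelengths), -1)
    events = read_events_tsv(_events_path(path), fs)
    return RawIntensityRecording(
        intensities=inten,
        wavelengths=wavelengths,
        sampling_rate=fs,
        source_detector_distance_cm=distances,
        events=events,
        subject_id=meta["subject_id"],
        group_label=int(meta["group_label"]),
    )


def write_hemoglobin_text(hb: HemoglobinRecording, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# nirsentropy-hb v1\n")
        fh.write(f"# subject_id: {hb.subject_id}\n")
        fh.write(f"# group_label: {hb.group_label}\n")
        fh.write(f"# sampling_rate_hz: {hb.sampling_rate:.10g}\n")
        fh.write(f"# cbsi_applied: {int(hb.cbsi_applied)}\n")
        fh.write("# history: " + " | ".join(hb.history) + "\n")
        cols = ["time_s"] + [
            f"ch{ch + 1:02d}_{name}"
            for ch in range(hb.n_channels)
            for name in ("o2hb", "hhb")
        ]
        fh.write("\t".join(cols) + "\n")
        t = np.arange(hb.n_samples) / hb.sampling_rate
        inter = np.empty((2 * hb.n_channels, hb.n_samples))
        inter[0::2] = hb.o2hb
        inter[1::2] = hb.hhb
        np.savetxt(fh, np.vstack([t, inter]).T, fmt=_FLOAT_FMT, delimiter="\t")
    write_events_tsv(hb.events, hb.sampling_rate, _events_path(path))
    return path


def read_hemoglobin_text(path) -> HemoglobinRecording:
    path = Path(path)
    meta, header, data = _parse_header(path)
    fs = float(meta["sampling_rate_hz"])
    series = data[:, 1:].T
    o2hb, hhb = series[0::2], series[1::2]
    history = tuple(s for s in meta.get("history", "").split(" | ") if s)
    return HemoglobinRecording(
        o2hb=o2hb,
        hhb=hhb,
        sampling_rate=fs,
        events=read_events_tsv(_events_path(path), fs),
        subject_id=meta["subject_id"],
        group_label=int(meta["group_label"]),
        cbsi_applied=bool(int(meta.get("cbsi_applied", "0"))),
        history=history,
    )


# ---------------------------------------------------------------- SNIRF

def write_recording_snirf(rec: RawIntensityRecording, path) -> Path:
    """Minimal SNIRF-layout HDF5 file (one source-detector pair per channel)."""
    path = Path(path)
    n_ch, n_wl, n_t = rec.intensities.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("GroupLabel", data=str(rec.group_label))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        src = np.zeros((n_ch, 3))
        det = np.zeros((n_ch, 3))
        src[:, 0] = 10.0 * np.arange(n_ch)
        det[:, 0] = src[:, 0] + rec.source_detector_distance_cm
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)
        data = nirs.create_group("data1")
        flat = rec.intensities.reshape(n_ch * n_wl, n_t)
        data.create_dataset("dataTimeSeries", data=flat.T)
        data.create_dataset("time", data=np.arange(n_t) / rec.sampling_rate)
        k = 0
        for ch in range(n_ch):
            for wl in range(n_wl):
                ml = data.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1
        for j, (label, start, end) in enumerate(rec.events.windows):
            stim = nirs.create_group(f"stim{j + 1}")
            stim.create_dataset("name", data=label)
            onset = start / rec.sampling_rate
            dur = (end - start) / rec.sampling_rate
            stim.create_dataset("data", data=np.array([[onset, dur, 1.0]]))
    return path


def read_recording_snirf(path) -> RawIntensityRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        ts = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        src = np.asarray(nirs["probe/sourcePos3D"])
        det = np.asarray(nirs["probe/detectorPos3D"])
        ml_keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        n_wl = len(wavelengths)
        n_ch = len(ml_keys) // n_wl
        inten = np.empty((n_ch, n_wl, ts.shape[0]))
        for col, key in enumerate(ml_keys):
            ml = data[key]
            ch = int(np.asarray(ml["sourceIndex"])) - 1
            wl = int(np.asarray(ml["wavelengthIndex"])) - 1
            inten[ch, wl] = ts[:, col]
        distances = np.linalg.norm(det - src, axis=1)
        stim_keys = sorted(
            (k for k in nirs.keys() if k.startswith("stim")),
            key=lambda k: int(k[len("stim"):]),
        )
        windows = []
        for key in stim_keys:
            stim = nirs[key]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            onset, dur, _ = np.asarray(stim["data"])[0]
            windows.append((str(name), int(round(onset * fs)),
                            int(round((onset + dur) * fs))))
        windows.sort(key=lambda w: w[1])
        subject = nirs["metaDataTags/SubjectID"][()]
        if isinstance(subject, bytes):
            subject = subject.decode()
        group = nirs["metaDataTags/GroupLabel"][()]
        if isinstance(group, bytes):
            group = group.decode()
    return RawIntensityRecording(
        intensities=inten,
        wavelengths=wavelengths,
        sampling_rate=fs,
        source_detector_distance_cm=distances,
        events=PhaseWindows(tuple(windows)),
        subject_id=str(subject),
        group_label=int(group),
    )


# ------------------------------------------------------------- tables

def write_tidy_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_tidy_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth: CohortGroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "affected_channels": list(truth.affected_channels),
        "complexity_effect": truth.complexity_effect,
        "noise_mix": {sid: [round(float(v), 10) for v in w]
                      for sid, w in truth.noise_mix.items()},
        "artifact_counts": {sid: [len(ev) for ev in per_ch]
                            for sid, per_ch in truth.artifacts.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
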