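"""File I/O: SNIRF recordings, event tables, cognitive scores, results tables.

Recordings travel as SNIRF (HDF5) continuous-wave files: raw detected
intensities per channel and wavelength, the optode probe with labels and
flat-grid positions, the stimulus blocks, and subject/sleep-state metadata.
The reader reconstructs the montage from the probe and measurement list,
orders channels lexicographically by (source index, detector index), and
converts intensities to optical-density change relative to each channel's
temporal mean.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .montage import (
    Montage, EventSchedule, Recording, _label_xy, intensity_to_od,
)


class SnirfFormatError(ValueError):
    """Raised when a SNIRF file cannot be interpreted as a CW recording."""


def _utf8(value) -> str:
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.ndarray):
        return _utf8(value.item() if value.shape == () else value[0])
    return str(value)


def write_snirf(recording: Recording, path: str | os.PathLike) -> None:
    """Write a recording (raw intensities) to a SNIRF v1.0 CW file."""
    if recording.raw_intensity is None:
        raise ValueError("recording has no raw intensities to store")
    mon = recording.montage
    n_t, n_ch, n_wl = recording.raw_intensity.shape
    data = recording.raw_intensity.reshape(n_t, n_ch * n_wl)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("SleepState", data=recording.sleep_state)

        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.array([0.0, 1.0 / recording.fs_hz]))
        src_index = {lab: i + 1 for i, lab in enumerate(mon.source_labels)}
        det_index = {lab: i + 1 for i, lab in enumerate(mon.detector_labels)}
        col = 0
        for ch, (s, d) in enumerate(mon.channels):
            for wl in range(n_wl):
                ml = d1.create_group(f"measurementList{col + 1}")
                ml.create_dataset("sourceIndex", data=src_index[s])
                ml.create_dataset("detectorIndex", data=det_index[d])
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths",
                             data=np.asarray(recording.wavelengths_nm, float))
        for kind, labels in (("source", mon.source_labels),
                             ("detector", mon.detector_labels)):
            xy = np.array([_label_xy(lab) for lab in labels], dtype=float)
            probe.create_dataset(f"{kind}Pos2D", data=xy)
            probe.create_dataset(
                f"{kind}Pos3D",
                data=np.column_stack([xy, np.zeros(len(labels))]),
            )
            probe.create_dataset(
                f"{kind}Labels",
                data=np.array(labels, dtype=h5py.string_dtype()),
            )

        for k, (label, onset, dur) in enumerate(recording.events.entries):
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=label)
            stim.create_dataset("data", data=np.array([[onset, dur, 1.0]]))


def read_snirf(path: str | os.PathLike) -> Recording:
    """Read a continuous-wave SNIRF file into a Recording.

    Channels are reordered lexicographically by (source index, detector
    index); intensities are converted to optical-density change relative to
    the channel's temporal mean, OD(t) = -log10(I(t)/mean(I)).
    """
    with h5py.File(path, "r") as f:
        nirs = f.get("nirs") or f.get("nirs1")
        if nirs is None:
            raise SnirfFormatError(f"{path}: no /nirs group")
        probe = nirs["probe"]
        wavelengths = np.asarray(probe["wavelengths"][()], float).ravel()
        if wavelengths.size < 2:
            raise SnirfFormatError(
                f"{path}: need two wavelengths, found {wavelengths.size}"
            )
        src_labels = tuple(_utf8(x) for x in probe["sourceLabels"][()])
        det_labels = tuple(_utf8(x) for x in probe["detectorLabels"][()])

        d1 = nirs["data1"]
        ts = np.asarray(d1["dataTimeSeries"][()], float)
        time = np.asarray(d1["time"][()], float).ravel()
        if time.size == 2:
            fs = 1.0 / time[1]
        else:
            fs = 1.0 / float(np.median(np.diff(time)))
        cols = {}
        for name in d1:
            if not name.startswith("measurementList"):
                continue
            ml = d1[name]
            if int(ml["dataType"][()]) != 1:
                raise SnirfFormatError(
                    f"{path}: {name} is not continuous-wave amplitude data"
                )
            idx = int(name[len("measurementList"):]) - 1
            cols[idx] = (int(ml["sourceIndex"][()]) - 1,
                         int(ml["detectorIndex"][()]) - 1,
                         int(ml["wavelengthIndex"][()]) - 1)
        n_wl = len({c[2] for c in cols.values()})
        if n_wl < 2:
            raise SnirfFormatError(f"{path}: only {n_wl} wavelength(s) measured")
        pairs = sorted({(s, d) for s, d, _ in cols.values()})
        channels = tuple((src_labels[s], det_labels[d]) for s, d in pairs)
        montage = Montage(src_labels, det_labels, channels)
        pair_pos = {p: i for i, p in enumerate(pairs)}
        intensity = np.full((ts.shape[0], len(pairs), n_wl), np.nan)
        for col, (s, d, w) in cols.items():
            intensity[:, pair_pos[(s, d)], w] = ts[:, col]
        if np.isnan(intensity).any():
            bad = [channels[i] for i in
                   sorted({i for i in range(len(pairs))
                           if np.isnan(intensity[:, i, :]).any()})]
            raise SnirfFormatError(
                f"{path}: channels missing a wavelength: {bad[:5]}"
            )

        entries = []
        for name in sorted((n for n in nirs if n.startswith("stim")),
                           key=lambda n: int(n[4:])):
            stim = nirs[name]
            label = _utf8(stim["name"][()])
            for onset, dur, _ in np.atleast_2d(np.asarray(stim["data"][()], float)):
                entries.append((label, float(onset), float(dur)))
        entries.sort(key=lambda e: e[1])
        meta = nirs["metaDataTags"]
        subject = _utf8(meta["SubjectID"][()]) if "SubjectID" in meta else "S01"
        sleep = (_utf8(meta["SleepState"][()])
                 if "SleepState" in meta else "before_SD")

    return Recording(
        montage=montage, fs_hz=fs, od=intensity_to_od(intensity),
        events=EventSchedule(tuple(entries)),
        wavelengths_nm=tuple(wavelengths[:2]),
        subject_id=subject, sleep_state=sleep, raw_intensity=intensity,
    )


# ---------------------------------------------------------------------------
# tabular formats


def read_events_tsv(path: str | os.PathLike) -> EventSchedule:
    """Events from a 3-column TSV: label, onset_s, duration_s."""
    df = pd.read_csv(path, sep="\t")
    need = {"label", "onset_s", "duration_s"}
    if not need.issubset(df.columns):
        raise ValueError(f"events TSV must have columns {sorted(need)}")
    entries = tuple(
        (str(r.label), float(r.onset_s), float(r.duration_s))
        for r in df.sort_values("onset_s").itertuples()
    )
    return EventSchedule(entries)


def write_events_tsv(events: EventSchedule, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [{"label": l, "onset_s": o, "duration_s": d} for l, o, d in events.entries]
    ).to_csv(path, sep="\t", index=False)


def write_scores_csv(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    """Cognitive scores CSV: subject_id, visit, PAL, RTI, RVPA (blank=missing)."""
    cols = ["subject_id", "visit", "PAL", "RTI", "RVPA"]
    scores[cols].sort_values(["subject_id", "visit"]).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_scores_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


RESULTS_COLUMNS = ["subject", "sleep_state", "task_state", "scheme",
                   "parameter", "metric", "value"]
KEY_COLUMNS = RESULTS_COLUMNS[:5]
METRIC_COLUMNS = ["avg_degree", "WD", "C_sum", "E_sum"]


def write_results_table(results, path: str | os.PathLike) -> None:
    """Deterministic TSV of per-cell metrics.

    One row per subject x sleep_state x task_state x scheme x parameter,
    with one column per metric (binary average node degree, weighted
    density, cost-integrated clustering and efficiency sums); metrics not
    produced by a scheme are left blank.
    """
    table = results.table if hasattr(results, "table") else results
    if len(table) == 0:
        header = "\t".join(KEY_COLUMNS + METRIC_COLUMNS) + "\n"
        with open(path, "w") as f:
            f.write(header)
        return
    wide = table.pivot_table(index=KEY_COLUMNS, columns="metric",
                             values="value", aggfunc="first")
    cols = [c for c in METRIC_COLUMNS if c in wide.columns] + \
        [c for c in wide.columns if c not in METRIC_COLUMNS]
    wide = wide[cols].reset_index().sort_values(KEY_COLUMNS, kind="mergesort")
    wide.to_csv(path, sep="\t", index=False, float_format="%.10g",
                lineterminator="\n")
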