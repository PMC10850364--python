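"""Readers and writers: wide delimited text, SNIRF (HDF5), cohort and map CSV.

Delimited recordings are wide text: a comment line with sampling metadata, a
header row of channel ids, then one row of samples per channel. SNIRF files
follow the HDF5 layout of the Shared Near Infrared Spectroscopy Format
(``/nirs1/data1/dataTimeSeries`` as time x channel, a ``time`` vector and a
measurementList); montage hemisphere/lobe labels ride along in metaDataTags
so layouts survive a round trip.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMap
from .exceptions import FormatError
from .montage import MontageLayout
from .recording import TimeSeriesRecording

_META_PREFIX = "# neoconn"


# --------------------------------------------------------- delimited text
def write_recording_text(rec: TimeSeriesRecording, path, delimiter: str = "\t") -> None:
    """Write a 2-D recording as wide delimited text (rows = channels)."""
    if rec.data.ndim != 2:
        raise FormatError("delimited text supports 2-D recordings only (convert OD first)")
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(
            f"{_META_PREFIX} fs={float(rec.fs)!r} modality={rec.modality} "
            f"subject={rec.subject_id}\n"
        )
        fh.write(delimiter.join(rec.channel_names) + "\n")
        for row in rec.data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def read_recording_text(
    path, delimiter: str = "\t", layout: Optional[MontageLayout] = None
) -> TimeSeriesRecording:
    """Read a wide delimited-text recording written by :func:`write_recording_text`."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_META_PREFIX):
        raise FormatError(f"{path}: missing metadata header line")
    meta = dict(
        tok.split("=", 1) for tok in lines[0][len(_META_PREFIX):].split() if "=" in tok
    )
    try:
        fs = float(meta["fs"])
        modality = meta["modality"]
    except KeyError as exc:
        raise FormatError(f"{path}: metadata line lacks {exc}") from exc
    if len(lines) < 2:
        raise FormatError(f"{path}: missing channel-id header row")
    channels = tuple(lines[1].split(delimiter))
    rows: List[List[float]] = []
    width = None
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise FormatError(
                f"{path}: row at line {lineno} has {len(fields)} fields, expected {width}"
            )
        try:
            rows.append([float(v) for v in fields])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value at line {lineno}: {exc}") from exc
    if len(rows) != len(channels):
        raise FormatError(
            f"{path}: {len(channels)} channel ids but {len(rows)} data rows"
        )
    return TimeSeriesRecording(
        np.array(rows), fs, modality, channels, layout, meta.get("subject", "")
    )


# ------------------------------------------------------------------- SNIRF
_DATATYPE_LABEL = {"HbO": "HbO", "Hbr": "HbR"}


def write_snirf(rec: TimeSeriesRecording, path) -> None:
    """Write a recording as a SNIRF (HDF5) file.

    Concentration (HbO/Hbr) and OD blocks are supported; data are stored
    time-major per the format. Layout labels go to
    ``/nirs1/metaDataTags/neoconnHemisphere|neoconnLobe``.
    """
    import h5py

    if rec.data.ndim != 2:
        raise FormatError("write OD planes as separate recordings or convert first")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        tags = nirs.create_group("metaDataTags")
        tags.create_dataset("SubjectID", data=rec.subject_id or "unknown")
        tags.create_dataset("MeasurementDate", data="unknown")
        tags.create_dataset("MeasurementTime", data="unknown")
        tags.create_dataset("LengthUnit", data="cm")
        tags.create_dataset("TimeUnit", data="s")
        tags.create_dataset("FrequencyUnit", data="Hz")
        tags.create_dataset("neoconnModality", data=rec.modality)
        tags.create_dataset(
            "neoconnChannels", data=np.array(rec.channel_names, dtype="S")
        )
        if rec.layout is not None:
            tags.create_dataset(
                "neoconnHemisphere", data=np.array(rec.layout.hemisphere, dtype="S")
            )
            tags.create_dataset(
                "neoconnLobe", data=np.array(rec.layout.lobe, dtype="S")
            )
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.data.T)  # time x channel
        data.create_dataset("time", data=np.arange(rec.n_times) / rec.fs)
        label = _DATATYPE_LABEL.get(rec.modality, rec.modality)
        for ch in range(rec.n_channels):
            ml = data.create_group(f"measurementList{ch + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=99999)  # processed
            ml.create_dataset("dataTypeLabel", data=label)
            ml.create_dataset("dataTypeIndex", data=1)


def read_snirf(path) -> TimeSeriesRecording:
    """Read a SNIRF file written by :func:`write_snirf` (amplitude/concentration block)."""
    import h5py

    with h5py.File(path, "r") as f:
        try:
            data = f["nirs1/data1/dataTimeSeries"][()].T
            time = f["nirs1/data1/time"][()]
            tags = f["nirs1/metaDataTags"]
        except KeyError as exc:
            raise FormatError(f"{path}: not a neoconn-readable SNIRF file ({exc})") from exc
        if time.size < 2:
            raise FormatError(f"{path}: time vector too short to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(time)))
        modality = (
            tags["neoconnModality"][()].decode()
            if "neoconnModality" in tags
            else "HbO"
        )
        if "neoconnChannels" in tags:
            channels = tuple(c.decode() for c in tags["neoconnChannels"][()])
        else:
            channels = tuple(f"ch{i + 1:02d}" for i in range(data.shape[0]))
        layout = None
        if "neoconnHemisphere" in tags and "neoconnLobe" in tags:
            layout = MontageLayout(
                channels,
                tuple(h.decode() for h in tags["neoconnHemisphere"][()]),
                tuple(l.decode() for l in tags["neoconnLobe"][()]),
            )
        subject = ""
        if "SubjectID" in tags:
            raw = tags["SubjectID"][()]
            subject = raw.decode() if isinstance(raw, bytes) else str(raw)
            if subject == "unknown":
                subject = ""
    return TimeSeriesRecording(data, fs, modality, channels, layout, subject)


def read_recording(path, fmt: Optional[str] = None, **kw) -> TimeSeriesRecording:
    """Dispatch on format ("snirf" or "text"; inferred from the suffix by default)."""
    path = Path(path)
    fmt = fmt or ("snirf" if path.suffix.lower() == ".snirf" else "text")
    if fmt == "snirf":
        return read_snirf(path)
    if fmt == "text":
        return read_recording_text(path, **kw)
    raise FormatError(f"unknown recording format {fmt!r}")


def write_recording(rec: TimeSeriesRecording, path, fmt: Optional[str] = None, **kw) -> None:
    path = Path(path)
    fmt = fmt or ("snirf" if path.suffix.lower() == ".snirf" else "text")
    if fmt == "snirf":
        write_snirf(rec, path)
    elif fmt == "text":
        write_recording_text(rec, path, **kw)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


# ----------------------------------------------------------- cohort tables
COHORT_COLUMNS = (
    "subject_id",
    "group",
    "ga_birth",
    "pma_scan",
    "sex",
    "gm_volume",
    "wm_volume",
)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise FormatError(f"cohort table lacks columns: {sorted(missing)}")
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: cohort CSV lacks columns: {sorted(missing)}")
    return df


# ------------------------------------------------------------ map serializers
def write_map_csv(cmap: ConnectivityMap, path) -> None:
    """Square CSV with node labels as header and index."""
    pd.DataFrame(cmap.weights, index=cmap.node_labels, columns=cmap.node_labels).to_csv(path)


def read_map_csv(path, signal_type: str = "", subject_id: str = "") -> ConnectivityMap:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: map CSV index and header disagree")
    return ConnectivityMap(df.to_numpy(float), tuple(df.columns), signal_type, subject_id)


def write_edge_list(cmap: ConnectivityMap, path, delimiter: str = "\t") -> None:
    """Upper-triangle edge list: node_i, node_j, weight."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["node_i", "node_j", "weight"])
        n = cmap.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                writer.writerow(
                    [cmap.node_labels[i], cmap.node_labels[j], repr(float(cmap.weights[i, j]))]
                )


def read_edge_list(
    path, delimiter: str = "\t", signal_type: str = "", subject_id: str = ""
) -> ConnectivityMap:
    df = pd.read_csv(path, sep=delimiter)
    if list(df.columns) != ["node_i", "node_j", "weight"]:
        raise FormatError(f"{path}: expected columns node_i, node_j, weight")
    labels = list(dict.fromkeys(df["node_i"]).keys())
    for n in df["node_j"]:
        if n not in labels:
            labels.append(n)
    idx = {n: i for i, n in enumerate(labels)}
    w = np.eye(len(labels))
    for _, row in df.iterrows():
        i, j = idx[row["node_i"]], idx[row["node_j"]]
        w[i, j] = w[j, i] = float(row["weight"])
    return ConnectivityMap(w, tuple(labels), signal_type, subject_id)
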