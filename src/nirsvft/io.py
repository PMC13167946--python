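"""File interfaces: tabular recordings, minimal SNIRF, cohort tables.

The native on-disk form is plain TSV (one file per subject x session,
metadata in ``#key=value`` header lines, one column per channel), which
round-trips exactly and diffs cleanly. A minimal SNIRF (HDF5) writer/
reader is provided for interoperability: it covers the continuous-wave
processed-HbO2 layout (/nirs/data1 with dataTimeSeries, time and a
measurementList) and nothing more.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "write_recording_tsv",
    "read_recording_tsv",
    "write_snirf",
    "read_snirf",
    "write_cohort_csv",
    "read_cohort_csv",
    "recording_filename",
]


def recording_filename(rec: Recording, ext: str = "tsv") -> str:
    return f"{rec.subject_id}_{rec.timepoint}.{ext}"


def write_recording_tsv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    header = [
        f"#subject={rec.subject_id}",
        f"#group={rec.group}",
        f"#timepoint={rec.timepoint}",
        f"#fs={rec.fs!r}",
        f"#units=mmol/L*mm",
    ]
    cols = "\t".join(["time_s"] + [f"ch{cid:02d}" for cid in rec.channel_ids])
    t = np.arange(rec.n_samples) / rec.fs
    body = np.column_stack([t, rec.data.T])
    lines = header + [cols] + [
        "\t".join(f"{v:.10g}" for v in row) for row in body
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_recording_tsv(path: str | Path) -> Recording:
    path = Path(path)
    meta: dict[str, str] = {}
    rows = []
    cols: list[str] | None = None
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif cols is None:
                cols = line.split("\t")
            else:
                rows.append([float(v) for v in line.split("\t")])
    if cols is None or not rows:
        raise ValueError(f"no data in {path}")
    arr = np.asarray(rows)
    channel_ids = tuple(int(c[2:]) for c in cols[1:])
    return Recording(
        subject_id=meta.get("subject", path.stem),
        group=meta.get("group", "control"),
        timepoint=meta.get("timepoint", "pre"),
        fs=float(meta.get("fs", "5.0")),
        channel_ids=channel_ids,
        data=arr[:, 1:].T,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# SNIRF (minimal continuous-wave processed layout)
# ---------------------------------------------------------------------------

def write_snirf(rec: Recording, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("Group", data=rec.group)
        meta.create_dataset("Timepoint", data=rec.timepoint)
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.data.T)  # time x channel
        data.create_dataset("time", data=np.arange(rec.n_samples) / rec.fs)
        for k, cid in enumerate(rec.channel_ids, start=1):
            ml = data.create_group(f"measurementList{k}")
            ml.create_dataset("sourceIndex", data=np.int32(cid))
            ml.create_dataset("detectorIndex", data=np.int32(cid))
            ml.create_dataset("dataType", data=np.int32(99999))  # processed
            ml.create_dataset("dataTypeLabel", data="HbO")
            ml.create_dataset("dataTypeIndex", data=np.int32(1))
    return path


def read_snirf(path: str | Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        data = np.asarray(f["nirs/data1/dataTimeSeries"]).T
        time = np.asarray(f["nirs/data1/time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        meta = f["nirs/metaDataTags"]

        def _s(name, default):
            if name in meta:
                v = meta[name][()]
                return v.decode() if isinstance(v, bytes) else str(v)
            return default

        n = data.shape[0]
        cids = []
        for k in range(1, n + 1):
            grp = f[f"nirs/data1/measurementList{k}"]
            cids.append(int(grp["sourceIndex"][()]))
        return Recording(
            subject_id=_s("SubjectID", Path(path).stem),
            group=_s("Group", "control"),
            timepoint=_s("Timepoint", "pre"),
            fs=round(fs, 6),
            channel_ids=tuple(cids),
            data=data,
            meta={"source": str(path)},
        )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def write_cohort_csv(scales: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    scales.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "group", "timepoint"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    return df
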