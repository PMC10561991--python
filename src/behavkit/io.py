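"""Readers and fixture writers for fly-activity file formats.

Three input shapes are supported:

* **Ethoscope-style SQLite databases** — one file per tracking machine,
  with a key/value ``METADATA`` table, a ``ROI_MAP`` table describing the
  regions of interest, and one ``ROI_<n>`` table per region holding
  timestamped position records.  Inter-frame displacement is stored
  log-quantized as the integer ``xy_dist_log10x1000`` =
  ``round(1000 * log10(displacement_px))``.
* **DAM-style monitor files** — tab-delimited text from beam-break
  activity monitors: 42 fields per row (index, date, time, status, six
  reserved fields, then 32 channel counts).
* **Generic tabular files** — anything with an id column, a time column
  and at least one behavioural variable.

The matching ``write_fixture_*`` functions emit the same dialects from
simulated data, so the readers can be exercised against files with known
ground truth.
"""

from __future__ import annotations

import math
import os
import sqlite3
from datetime import datetime

import numpy as np
import pandas as pd

from .core import BehavTable, validate_metadata

__all__ = [
    "read_ethoscope_db",
    "read_dam_file",
    "read_generic_table",
    "load_metadata_file",
    "write_fixture_ethoscope_db",
    "write_fixture_dam_file",
]

_DAM_FIELDS = 42
_DAM_CHANNELS = 32
_DAM_DATE_FMT = "%d %b %y"
# floor for the log10-quantized displacement column: the integer encoding
# cannot represent zero, so displacements are clipped here before encoding
_MIN_DISPLACEMENT = 1e-6

_T_UNIT_S = {"s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0}


# ----------------------------------------------------------------------
# ethoscope-style SQLite
def _db_tables(con: sqlite3.Connection) -> set[str]:
    rows = con.execute(
        "SELECT name FROM sqlite_master WHERE type='table'"
    ).fetchall()
    return {r[0] for r in rows}


def read_ethoscope_db(path, metadata_row: dict | None = None,
                      regions: list[int] | None = None) -> BehavTable:
    """Read an ethoscope-style single-file SQLite tracking database.

    Each region of interest becomes one specimen, with id
    ``"<machine_name>|<region>|<date_time>"``.  Time is converted from
    milliseconds to seconds, and the quantized displacement column is
    decoded as ``displacement = 10 ** (xy_dist_log10x1000 / 1000)``
    (pixels per frame).

    Parameters
    ----------
    path
        SQLite file following the ethoscope dialect.
    metadata_row
        Extra descriptor columns (genotype, treatment, ...) attached to
        every specimen from this machine.
    regions
        Optional subset of region indices to load.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        tables = _db_tables(con)
        for required in ("METADATA", "ROI_MAP"):
            if required not in tables:
                raise ValueError(f"database lacks required table {required}")
        kv = dict(con.execute("SELECT field, value FROM METADATA").fetchall())
        for key in ("machine_name", "date_time"):
            if key not in kv:
                raise ValueError(f"METADATA lacks required field {key}")
        machine = kv["machine_name"]
        date_time = kv["date_time"]
        roi_map = pd.read_sql_query("SELECT * FROM ROI_MAP", con)
        if "roi_idx" not in roi_map.columns:
            raise ValueError("ROI_MAP lacks required column roi_idx")
        roi_idx = [int(r) for r in roi_map["roi_idx"]]
        if regions is not None:
            missing = set(regions) - set(roi_idx)
            if missing:
                raise ValueError(f"regions not in ROI_MAP: {sorted(missing)}")
            roi_idx = [r for r in roi_idx if r in set(regions)]

        meta_rows, data_frames = [], []
        for region in roi_idx:
            table = f"ROI_{region}"
            if table not in tables:
                raise ValueError(f"database lacks table {table} listed in ROI_MAP")
            sid = f"{machine}|{region}|{date_time}"
            row = {"id": sid, "machine_name": machine,
                   "region_id": region, "date_time": date_time}
            if metadata_row:
                row.update(metadata_row)
            meta_rows.append(row)
            df = pd.read_sql_query(
                f'SELECT t, x, y, xy_dist_log10x1000 FROM "{table}"', con
            )
            if len(df) == 0:
                continue
            out = pd.DataFrame({
                "id": sid,
                "t": df["t"].astype(float) / 1000.0,
                "x": df["x"].astype(float),
                "y": df["y"].astype(float),
                "displacement": np.power(
                    10.0, df["xy_dist_log10x1000"].astype(float) / 1000.0
                ),
            })
            data_frames.append(out)
    finally:
        con.close()

    meta = pd.DataFrame(meta_rows)
    if data_frames:
        data = pd.concat(data_frames, ignore_index=True)
    else:
        data = pd.DataFrame(columns=["id", "t", "x", "y", "displacement"])
    return BehavTable(data, meta)


# ----------------------------------------------------------------------
# DAM-style monitor files
def read_dam_file(path, channel_map: pd.DataFrame | dict,
                  interval: float = 60.0) -> BehavTable:
    """Read a DAM-style tab-delimited beam-count monitor file.

    Parameters
    ----------
    path
        Monitor file: 42 tab-separated fields per row — reading index,
        date (``dd Mon yy``), time (``HH:MM:SS``), status code (1 =
        valid), six reserved fields, then 32 channel counts.
    channel_map
        Mapping from channel number (1-32) to specimen descriptors.
        Either a frame with a ``channel`` column plus an ``id`` column
        (and any further metadata columns), or a ``{channel: id}`` dict.
    interval
        Reading cadence in seconds; retained as metadata (``interval``
        column) for downstream count normalization.

    Rows whose status code is not 1 are dropped.  Time is seconds since
    the first valid reading.
    """
    if isinstance(channel_map, dict):
        channel_map = pd.DataFrame(
            {"channel": list(channel_map), "id": list(channel_map.values())}
        )
    if "channel" not in channel_map.columns or "id" not in channel_map.columns:
        raise ValueError("channel_map needs 'channel' and 'id' columns")

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _DAM_FIELDS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_DAM_FIELDS} "
                    f"tab-separated fields, got {len(fields)}"
                )
            status = int(fields[3])
            stamp = datetime.strptime(f"{fields[1]} {fields[2]}",
                                      f"{_DAM_DATE_FMT} %H:%M:%S")
            counts = [int(v) for v in fields[10:10 + _DAM_CHANNELS]]
            records.append((stamp, status, counts))

    meta = channel_map.copy()
    meta["channel"] = meta["channel"].astype(int)
    meta["interval"] = float(interval)
    meta = validate_metadata(meta)

    valid = [(stamp, counts) for stamp, status, counts in records if status == 1]
    if valid:
        t0 = valid[0][0]
        rows = []
        for stamp, counts in valid:
            t = (stamp - t0).total_seconds()
            for _, mrow in meta.iterrows():
                rows.append((mrow["id"], t, counts[int(mrow["channel"]) - 1]))
        data = pd.DataFrame(rows, columns=["id", "t", "counts"])
    else:
        data = pd.DataFrame(columns=["id", "t", "counts"])
    return BehavTable(data, meta)


# ----------------------------------------------------------------------
# generic tabular data
def read_generic_table(path, id_col: str, t_col: str,
                       variable_cols: list[str], t_unit: str = "s",
                       meta: pd.DataFrame | None = None) -> BehavTable:
    """Read any tabular file with an id column, a time column and variables.

    ``t_unit`` ∈ {s, ms, min, h} converts the time column to seconds.  If
    no metadata table is supplied a minimal one (ids only) is built.
    """
    if t_unit not in _T_UNIT_S:
        raise ValueError(f"t_unit must be one of {sorted(_T_UNIT_S)}")
    df = pd.read_csv(path)
    for col in [id_col, t_col, *variable_cols]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    data = pd.DataFrame({"id": df[id_col].astype(str),
                         "t": df[t_col].astype(float) * _T_UNIT_S[t_unit]})
    for col in variable_cols:
        data[col] = df[col]
    if meta is None:
        meta = pd.DataFrame({"id": pd.unique(data["id"])})
    return BehavTable(data, meta)


def load_metadata_file(path) -> pd.DataFrame:
    """Load a metadata CSV (unique ``id`` column required)."""
    try:
        meta = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty metadata file")
    return validate_metadata(meta)


# ----------------------------------------------------------------------
# fixture writers
def encode_displacement(d: np.ndarray) -> np.ndarray:
    """Quantize displacement (px) to the integer ethoscope encoding."""
    d = np.clip(np.asarray(d, dtype=float), _MIN_DISPLACEMENT, None)
    return np.round(1000.0 * np.log10(d)).astype(int)


def write_fixture_ethoscope_db(sim_output, path,
                               machine_name: str = "ETHOSCOPE_001",
                               date_time: str = "2023-06-01_09-00-00") -> None:
    """Write simulated traces as an ethoscope-dialect SQLite database.

    *sim_output* is a :class:`~behavkit.simulate.SimOutput` or any
    :class:`BehavTable` with ``x``, ``y`` and ``displacement`` columns.
    Specimens map to consecutive regions 1..n in metadata order.
    Reading the file back reproduces the simulated series up to the
    declared ms→s and log-quantization conversions.
    """
    bt = getattr(sim_output, "behav", sim_output)
    if os.path.exists(path):
        os.remove(path)
    con = sqlite3.connect(path)
    try:
        con.execute("CREATE TABLE METADATA (field TEXT, value TEXT)")
        con.executemany(
            "INSERT INTO METADATA VALUES (?, ?)",
            [("machine_name", machine_name), ("date_time", date_time)],
        )
        con.execute(
            "CREATE TABLE ROI_MAP (roi_idx INTEGER, x INTEGER, y INTEGER,"
            " w INTEGER, h INTEGER)"
        )
        for region, sid in enumerate(bt.ids, start=1):
            con.execute("INSERT INTO ROI_MAP VALUES (?, ?, ?, ?, ?)",
                        (region, 0, (region - 1) * 50, 200, 50))
            con.execute(
                f"CREATE TABLE ROI_{region} (id INTEGER PRIMARY KEY,"
                " t INTEGER, x REAL, y REAL, xy_dist_log10x1000 INTEGER)"
            )
            grp = bt.data[bt.data["id"] == sid]
            if len(grp) == 0:
                continue
            t_ms = np.round(grp["t"].to_numpy() * 1000.0).astype(np.int64)
            x = grp["x"].to_numpy() if "x" in grp else np.zeros(len(grp))
            y = grp["y"].to_numpy() if "y" in grp else np.zeros(len(grp))
            enc = encode_displacement(grp["displacement"].to_numpy())
            con.executemany(
                f"INSERT INTO ROI_{region} (t, x, y, xy_dist_log10x1000)"
                " VALUES (?, ?, ?, ?)",
                list(zip(t_ms.tolist(), x.tolist(), y.tolist(), enc.tolist())),
            )
        con.commit()
    finally:
        con.close()


def write_fixture_dam_file(sim_output, path, interval: float = 60.0,
                           start: datetime | None = None) -> pd.DataFrame:
    """Write simulated activity as a DAM-dialect monitor file.

    Per reading interval and specimen, the count is the number of moving
    bins (a beam-crossing proxy).  Specimens map to channels 1..n (max
    32); unused channels read 0.  Returns the channel map needed to read
    the file back.
    """
    bt = getattr(sim_output, "behav", sim_output)
    if len(bt.ids) > _DAM_CHANNELS:
        raise ValueError(f"DAM files carry at most {_DAM_CHANNELS} channels")
    if start is None:
        start = datetime(2023, 6, 1, 9, 0, 0)

    counts = bt.bin_time("moving", interval, "sum") if len(bt.data) else \
        pd.DataFrame(columns=["id", "t_bin", "moving"])
    grid = (np.sort(pd.unique(counts["t_bin"])) if len(counts)
            else np.array([]))
    wide = (counts.pivot(index="t_bin", columns="id", values="moving")
            .reindex(grid).fillna(0).astype(int)) if len(counts) else None

    with open(path, "w") as fh:
        for i, t_bin in enumerate(grid, start=1):
            stamp = pd.Timestamp(start) + pd.Timedelta(seconds=float(t_bin))
            row = [str(i),
                   stamp.strftime(_DAM_DATE_FMT),
                   stamp.strftime("%H:%M:%S"),
                   "1"] + ["0"] * 6
            channel_counts = [0] * _DAM_CHANNELS
            for ch, sid in enumerate(bt.ids, start=1):
                if sid in wide.columns:
                    channel_counts[ch - 1] = int(wide.loc[t_bin, sid])
            row += [str(c) for c in channel_counts]
            fh.write("\t".join(row) + "\n")

    cmap = pd.DataFrame({"channel": range(1, len(bt.ids) + 1), "id": bt.ids})
    return cmap
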