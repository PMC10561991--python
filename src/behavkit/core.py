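"""Metadata-linked behavioural tables.

The central container is :class:`BehavTable`: a long-format table of
behavioural observations (one row per specimen per timestamp) hard-linked
to a metadata table describing each specimen (genotype, treatment,
machine, region, ...).  The link is the shared ``id`` column, and every
transformation verb preserves it: a data row can never refer to a
specimen that the metadata does not know about.

Time is stored in seconds, as floats, relative to an experiment
reference (readers convert from their native units).  Windows are
half-open ``[t_min, t_max)`` and time bins are labelled by their left
edge, so consecutive bins partition time without double counting.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehavTable",
    "link_metadata",
    "validate_metadata",
    "SECONDS_PER_DAY",
]

SECONDS_PER_DAY = 86400.0

_AGGREGATORS = {"mean", "max", "sum", "median"}


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a metadata table: an ``id`` column with unique, non-empty keys.

    Returns a copy with ``id`` coerced to string.  Raises ``ValueError``
    on a missing id column, duplicate ids or empty ids.
    """
    if "id" not in meta.columns:
        raise ValueError("metadata table must have an 'id' column")
    meta = meta.copy()
    meta["id"] = meta["id"].astype(str)
    if (meta["id"].str.len() == 0).any():
        raise ValueError("metadata contains empty id values")
    dupes = meta["id"][meta["id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate metadata ids: {sorted(dupes)}")
    return meta.reset_index(drop=True)


class BehavTable:
    """Behavioural time series linked to specimen metadata.

    Parameters
    ----------
    data
        Long-format frame with at least ``id`` and ``t`` columns plus one
        or more behavioural variables.  ``t`` is seconds since the
        experiment reference.
    meta
        Metadata frame with a unique ``id`` column.  May contain ids with
        no data rows (e.g. dead-on-arrival specimens); the converse — a
        data id absent from the metadata — is an error.
    """

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame):
        meta = validate_metadata(meta)
        if "id" not in data.columns or "t" not in data.columns:
            raise ValueError("data table must have 'id' and 't' columns")
        data = data.copy()
        data["id"] = data["id"].astype(str)
        data["t"] = data["t"].astype(float)
        if len(data) and not np.isfinite(data["t"].to_numpy()).all():
            raise ValueError("non-finite t values in data")
        unknown = set(data["id"]) - set(meta["id"])
        if unknown:
            raise ValueError(
                f"data ids missing from metadata: {sorted(unknown)}"
            )
        # canonical order: ascending t within each id, ids in meta order
        order = {sid: i for i, sid in enumerate(meta["id"])}
        data = data.sort_values(
            ["id", "t"], key=lambda s: s.map(order) if s.name == "id" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        self.data = data
        self.meta = meta

    # ------------------------------------------------------------------
    # dunder conveniences
    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"BehavTable({len(self.data)} rows, "
            f"{len(self.meta)} specimens, "
            f"variables={self.variables})"
        )

    @property
    def ids(self) -> list[str]:
        return list(self.meta["id"])

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("id", "t")]

    def copy(self) -> "BehavTable":
        return BehavTable(self.data.copy(), self.meta.copy())

    # ------------------------------------------------------------------
    # transformation verbs
    def filter_by_meta(self, predicate: str | Callable[[pd.DataFrame], pd.Series]) -> "BehavTable":
        """Restrict to specimens whose metadata row matches *predicate*.

        *predicate* is either a pandas ``query`` expression over metadata
        columns (e.g. ``'genotype == "CantonS"'``) or a callable mapping
        the metadata frame to a boolean mask.  Data rows of dropped
        specimens are dropped with them; an empty result is a valid
        (empty) table, not an error.
        """
        if callable(predicate):
            mask = np.asarray(predicate(self.meta), dtype=bool)
            sub_meta = self.meta[mask]
        else:
            try:
                sub_meta = self.meta.query(predicate)
            except pd.errors.UndefinedVariableError as exc:
                raise ValueError(f"predicate references unknown column: {exc}") from exc
        keep = set(sub_meta["id"])
        sub_data = self.data[self.data["id"].isin(keep)]
        return BehavTable(sub_data.reset_index(drop=True), sub_meta.reset_index(drop=True))

    def filter_ids(self, ids: Iterable[str]) -> "BehavTable":
        """Restrict to an explicit set of specimen ids."""
        ids = set(map(str, ids))
        unknown = ids - set(self.meta["id"])
        if unknown:
            raise ValueError(f"unknown ids: {sorted(unknown)}")
        return self.filter_by_meta(lambda m: m["id"].isin(ids))

    def time_window(self, t_min: float, t_max: float) -> "BehavTable":
        """Keep data rows with ``t`` in the half-open window [t_min, t_max)."""
        if not t_min < t_max:
            raise ValueError(f"t_min ({t_min}) must be < t_max ({t_max})")
        mask = (self.data["t"] >= t_min) & (self.data["t"] < t_max)
        return BehavTable(self.data[mask].reset_index(drop=True), self.meta)

    def bin_time(
        self,
        variable: str,
        bin_size: float,
        aggregator: str = "mean",
    ) -> pd.DataFrame:
        """Aggregate *variable* into regular time bins per specimen.

        Bins are labelled by their left edge: ``t_bin = floor(t / bin_size)
        * bin_size``.  Only non-empty bins appear in the output.  Returns a
        plain frame with columns ``id, t_bin, <variable>``.
        """
        if bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if aggregator not in _AGGREGATORS:
            raise ValueError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
        if variable not in self.data.columns:
            raise ValueError(f"no such variable: {variable!r}")
        if not pd.api.types.is_numeric_dtype(self.data[variable]):
            raise ValueError(f"variable {variable!r} is not numeric")
        df = self.data[["id", "t", variable]].copy()
        df["t_bin"] = np.floor(df["t"] / bin_size) * bin_size
        out = (
            df.groupby(["id", "t_bin"], sort=True, observed=True)[variable]
            .agg(aggregator)
            .reset_index()
        )
        return out

    def to_zeitgeber(
        self,
        lights_on_reference: float,
        day_length: float = SECONDS_PER_DAY,
    ) -> "BehavTable":
        """Add a ``zt`` column: hours since lights-on, modulo the day length.

        ``zt = ((t - lights_on_reference) mod day_length) / 3600`` — always
        in ``[0, day_length / 3600)``.
        """
        if day_length <= 0:
            raise ValueError("day_length must be > 0")
        out = self.data.copy()
        zt_s = np.mod(out["t"] - lights_on_reference, day_length)
        # tiny negative offsets can round the modulo up to day_length
        zt_s = np.where(zt_s >= day_length, 0.0, zt_s)
        out["zt"] = zt_s / 3600.0
        return BehavTable(out, self.meta)

    def curate_dead(
        self,
        movement_column: str,
        immobility_span: float = SECONDS_PER_DAY,
    ) -> "BehavTable":
        """Drop trailing data of specimens that died during the recording.

        A specimen whose final run of zero movement (extending to its last
        record) spans at least *immobility_span* seconds is assumed dead at
        that run's onset; all rows from the onset are removed.  Specimens
        that lose every row stay in the metadata.
        """
        if movement_column not in self.data.columns:
            raise ValueError(f"no such column: {movement_column!r}")
        vals = self.data[movement_column].dropna().unique()
        if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            raise ValueError(f"column {movement_column!r} is not binary")

        pieces = []
        for sid, grp in self.data.groupby("id", sort=False):
            mv = grp[movement_column].to_numpy(dtype=float)
            t = grp["t"].to_numpy()
            if len(mv) == 0 or mv[-1] != 0:
                pieces.append(grp)
                continue
            nz = np.nonzero(mv != 0)[0]
            onset_idx = nz[-1] + 1 if len(nz) else 0
            span = t[-1] - t[onset_idx]
            if span >= immobility_span:
                pieces.append(grp.iloc[:onset_idx])
            else:
                pieces.append(grp)
        data = pd.concat(pieces) if pieces else self.data.iloc[:0]
        return BehavTable(data.reset_index(drop=True), self.meta)

    # ------------------------------------------------------------------
    # round-trip persistence
    def to_csv(self, data_path, meta_path) -> None:
        """Write the pair of linked tables to two CSV files."""
        self.data.to_csv(data_path, index=False)
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, data_path, meta_path) -> "BehavTable":
        return cls(pd.read_csv(data_path), pd.read_csv(meta_path))

    # ------------------------------------------------------------------
    def check_integrity(self) -> bool:
        """Referential-integrity assertion usable after any transformation."""
        return set(self.data["id"]) <= set(self.meta["id"])


def link_metadata(data_table: pd.DataFrame, meta_table: pd.DataFrame) -> BehavTable:
    """Link a raw behavioural table to its metadata by the ``id`` column.

    The metadata may be a superset of the data's ids (specimens with no
    usable recording); any data id absent from the metadata raises a
    ``ValueError`` naming the offending ids.
    """
    return BehavTable(data_table, meta_table)
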