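"""Sleep scoring and quantification for fly activity data.

The pipeline follows the field's standard operational definition:
movement is classified per short bin (default 10 s) from a velocity
proxy, and sleep is any maximal run of complete inactivity lasting at
least five minutes.  Downstream quantifications — bout statistics,
population sleep profiles with bootstrap confidence intervals,
specimen-by-time heatmap matrices and post-deprivation rebound — all
operate on the annotated movement series.

Missing bins (no observations) are conservative: they are neither
moving nor inactive and always break an inactivity run, so sleep is
never inferred across a recording gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BehavTable, SECONDS_PER_DAY

__all__ = [
    "SleepParams",
    "classify_movement",
    "sleep_annotation",
    "bout_analysis",
    "bouts_to_series",
    "sleep_profile",
    "heatmap_matrix",
    "rebound_quantification",
]


@dataclass(frozen=True)
class SleepParams:
    """Parameters of the movement/sleep classification.

    bin_s
        Width of the movement-classification bin, seconds.
    min_sleep_s
        Minimum span of complete inactivity scored as sleep ("at least
        5 min" — the comparison is inclusive, >= 300 s).  Must be an
        integer multiple of ``bin_s``.
    velocity_threshold
        A bin counts as moving if the maximum instantaneous velocity
        proxy within it exceeds this value (pixels per second).
    """

    bin_s: float = 10.0
    min_sleep_s: float = 300.0
    velocity_threshold: float = 1.0

    def __post_init__(self):
        if self.bin_s <= 0:
            raise ValueError("bin_s must be > 0")
        if self.min_sleep_s < self.bin_s:
            raise ValueError("min_sleep_s must be >= bin_s")
        ratio = self.min_sleep_s / self.bin_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("min_sleep_s must be an integer multiple of bin_s")


def classify_movement(bt: BehavTable, params: SleepParams = SleepParams(),
                      variable: str = "displacement") -> pd.DataFrame:
    """Binarize activity onto a regular per-specimen grid.

    Per bin of width ``params.bin_s``: ``moving = 1`` iff the maximum of
    *variable* (the per-frame velocity proxy) within the bin exceeds
    ``params.velocity_threshold``; bins inside the recorded span with no
    observations are NaN (missing — neither moving nor inactive).

    Returns a frame with columns ``id, t, moving`` where ``t`` is the
    bin's left edge and the grid is regular within each specimen.
    """
    if variable not in bt.data.columns:
        raise ValueError(f"no such variable: {variable!r}")
    binned = bt.bin_time(variable, params.bin_s, "max")
    pieces = []
    for sid, grp in binned.groupby("id", sort=False):
        t = grp["t_bin"].to_numpy()
        grid = np.arange(t.min(), t.max() + params.bin_s / 2, params.bin_s)
        moving = pd.Series(
            (grp[variable] > params.velocity_threshold).astype(float).to_numpy(),
            index=t,
        ).reindex(grid)
        pieces.append(pd.DataFrame({"id": sid, "t": grid,
                                    "moving": moving.to_numpy()}))
    if not pieces:
        return pd.DataFrame(columns=["id", "t", "moving"])
    return pd.concat(pieces, ignore_index=True)


def _check_regular(t: np.ndarray, bin_s: float) -> None:
    if len(t) > 1:
        steps = np.diff(t)
        if not np.allclose(steps, bin_s, rtol=0, atol=1e-6):
            raise ValueError("movement series grid is irregular")


def sleep_annotation(ms: pd.DataFrame, params: SleepParams = SleepParams()) -> pd.DataFrame:
    """Score sleep on a movement series: the five-minute inactivity rule.

    ``asleep = 1`` exactly on bins belonging to a maximal run of
    contiguous ``moving == 0`` bins whose total span is at least
    ``params.min_sleep_s`` (inclusive).  Missing (NaN) bins terminate
    runs; their ``asleep`` is NaN.
    """
    out = []
    for sid, grp in ms.groupby("id", sort=False):
        t = grp["t"].to_numpy()
        _check_regular(t, params.bin_s)
        moving = grp["moving"].to_numpy(dtype=float)
        asleep = np.full(len(moving), np.nan)
        asleep[~np.isnan(moving)] = 0.0
        # runs of moving == 0 (NaN breaks the run)
        inactive = (moving == 0.0) & ~np.isnan(moving)
        idx = 0
        n = len(inactive)
        while idx < n:
            if not inactive[idx]:
                idx += 1
                continue
            end = idx
            while end < n and inactive[end]:
                end += 1
            span = (end - idx) * params.bin_s
            if span >= params.min_sleep_s:
                asleep[idx:end] = 1.0
            idx = end
        g = grp.copy()
        g["asleep"] = asleep
        out.append(g)
    if not out:
        ms = ms.copy()
        ms["asleep"] = pd.Series(dtype=float)
        return ms
    return pd.concat(out, ignore_index=True)


def bout_analysis(series: pd.DataFrame, state_column: str,
                  bin_s: float = 10.0) -> pd.DataFrame:
    """Run-length encode per-bin labels into bouts.

    Returns a frame ``(id, state, onset_t, duration_s)`` of maximal runs;
    NaN labels form their own (missing) bouts so that per-specimen bout
    durations always sum to the covered span.  The encoding is exactly
    invertible by :func:`bouts_to_series`.
    """
    rows = []
    for sid, grp in series.groupby("id", sort=False):
        t = grp["t"].to_numpy()
        _check_regular(t, bin_s)
        labels = grp[state_column].to_numpy(dtype=float)
        n = len(labels)
        start = 0
        for i in range(1, n + 1):
            boundary = i == n or not (
                (labels[i] == labels[start])
                or (np.isnan(labels[i]) and np.isnan(labels[start]))
            )
            if boundary:
                rows.append((sid, labels[start], t[start], (i - start) * bin_s))
                start = i
    return pd.DataFrame(rows, columns=["id", "state", "onset_t", "duration_s"])


def bouts_to_series(bouts: pd.DataFrame, bin_s: float = 10.0) -> pd.DataFrame:
    """Invert :func:`bout_analysis`: expand bouts back to per-bin labels."""
    rows = []
    for sid, grp in bouts.groupby("id", sort=False):
        for _, b in grp.iterrows():
            n = int(round(b["duration_s"] / bin_s))
            t = b["onset_t"] + bin_s * np.arange(n)
            rows.append(pd.DataFrame({"id": sid, "t": t, "state": b["state"]}))
    if not rows:
        return pd.DataFrame(columns=["id", "t", "state"])
    return pd.concat(rows, ignore_index=True)


# ----------------------------------------------------------------------
# population summaries
def _bootstrap_ci(values: np.ndarray, n_boot: int, ci: float,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling specimens."""
    if len(values) == 1:
        return float(values[0]), float(values[0])
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return float(lo), float(hi)


def sleep_profile(annotated: pd.DataFrame, meta: pd.DataFrame,
                  group_by: str | None = None,
                  profile_bin_s: float = 1800.0,
                  lights_on_reference: float = 0.0,
                  day_length: float = SECONDS_PER_DAY,
                  ci: float = 0.95, n_boot: int = 1000,
                  seed: int | None = None) -> pd.DataFrame:
    """Population sleep profile by zeitgeber time with bootstrap CIs.

    Per group and ZT bin: the mean over specimens of each specimen's
    fraction of bins asleep in that ZT bin (pooled across days), with a
    seeded percentile-bootstrap confidence interval over specimens
    (specimens, not time bins, are the independent units).

    Returns ``(group, zt_bin, n, mean_fraction_asleep, ci_low, ci_high)``
    with ``zt_bin`` in hours (left edge).
    """
    rng = np.random.default_rng(seed)
    df = annotated.dropna(subset=["asleep"]).copy()
    zt_s = np.mod(df["t"] - lights_on_reference, day_length)
    df["zt_bin"] = np.floor(zt_s / profile_bin_s) * profile_bin_s / 3600.0
    if group_by is None:
        group_of = {sid: "all" for sid in meta["id"]}
    else:
        if group_by not in meta.columns:
            raise ValueError(f"no such metadata column: {group_by!r}")
        group_of = dict(zip(meta["id"], meta[group_by]))
    df["group"] = df["id"].map(group_of)

    per_spec = (df.groupby(["group", "zt_bin", "id"], observed=True)["asleep"]
                .mean().reset_index())
    rows = []
    for (grp, zb), sub in per_spec.groupby(["group", "zt_bin"], observed=True):
        vals = sub["asleep"].to_numpy()
        lo, hi = _bootstrap_ci(vals, n_boot, ci, rng)
        rows.append((grp, zb, len(vals), float(vals.mean()), lo, hi))
    return pd.DataFrame(rows, columns=["group", "zt_bin", "n",
                                       "mean_fraction_asleep",
                                       "ci_low", "ci_high"])


def heatmap_matrix(series: pd.DataFrame, meta: pd.DataFrame,
                   variable: str, bin_s: float = 1800.0) -> pd.DataFrame:
    """Specimen-by-time matrix of binned activity for heatmap display.

    Rows are specimens in metadata order, columns are time bins (left
    edge, seconds); cells are the mean of *variable* in the bin, NaN
    where a specimen has no observations (missing bins stay visibly
    distinct from zeros).
    """
    df = series.dropna(subset=[variable]).copy()
    df["t_bin"] = np.floor(df["t"] / bin_s) * bin_s
    mat = df.pivot_table(index="id", columns="t_bin", values=variable,
                         aggfunc="mean")
    mat = mat.reindex(index=pd.Index(meta["id"], name="id"))
    cols = np.sort(mat.columns.to_numpy())
    return mat.reindex(columns=cols)


def rebound_quantification(annotated: pd.DataFrame, meta: pd.DataFrame,
                           baseline_window: tuple[float, float],
                           rebound_window: tuple[float, float],
                           group_by: str | None = None,
                           bin_s: float = 10.0,
                           ci: float = 0.95, n_boot: int = 1000,
                           seed: int | None = None):
    """Quantify rebound sleep after deprivation.

    Both windows are absolute-time intervals ``[start, end)`` of equal
    span (the same clock window on a baseline day and on the
    post-deprivation day).  Per specimen, ``delta_min`` = minutes asleep
    in the rebound window minus minutes asleep in the baseline window.
    Specimens with no scored bins in either window are excluded and
    reported.

    Returns ``(per_specimen, group_summary, excluded_ids)`` where the
    summary holds the group mean delta with a seeded bootstrap CI.
    """
    b0, b1 = baseline_window
    r0, r1 = rebound_window
    if not (b0 < b1 and r0 < r1):
        raise ValueError("windows must satisfy start < end")
    if abs((b1 - b0) - (r1 - r0)) > 1e-6:
        raise ValueError("baseline and rebound windows must have equal span")

    df = annotated.dropna(subset=["asleep"])
    in_base = df[(df["t"] >= b0) & (df["t"] < b1)]
    in_reb = df[(df["t"] >= r0) & (df["t"] < r1)]
    base_min = in_base.groupby("id")["asleep"].sum() * bin_s / 60.0
    reb_min = in_reb.groupby("id")["asleep"].sum() * bin_s / 60.0

    rows, excluded = [], []
    for sid in meta["id"]:
        has_b, has_r = sid in base_min.index, sid in reb_min.index
        if not (has_b and has_r):
            if sid in set(annotated["id"]):
                excluded.append(sid)
            continue
        b, r = float(base_min[sid]), float(reb_min[sid])
        rows.append((sid, b, r, r - b))
    per_spec = pd.DataFrame(rows, columns=["id", "baseline_sleep_min",
                                           "rebound_sleep_min", "delta_min"])

    rng = np.random.default_rng(seed)
    if group_by is None:
        group_of = {sid: "all" for sid in meta["id"]}
    else:
        group_of = dict(zip(meta["id"], meta[group_by]))
    per_spec["group"] = per_spec["id"].map(group_of)
    summaries = []
    for grp, sub in per_spec.groupby("group"):
        vals = sub["delta_min"].to_numpy()
        lo, hi = _bootstrap_ci(vals, n_boot, ci, rng)
        summaries.append((grp, len(vals), float(vals.mean()), lo, hi))
    summary = pd.DataFrame(summaries, columns=["group", "n", "mean_delta_min",
                                               "ci_low", "ci_high"])
    return per_spec, summary, excluded
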