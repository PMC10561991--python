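"""Circadian rhythm analysis: chi-squared periodograms and actograms.

The period-detection statistic is the classic chi-squared periodogram
(Sokolove & Bushell): for a candidate period of P bins the series is
truncated to K = floor(N / P) complete cycles, folded into P phase
columns, and

    Q_P = K * P * sum_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

where M_h is the mean of fold column h and Mbar the grand mean over the
K*P bins used.  Under the null of no rhythm at P, Q_P is approximately
chi-squared distributed with P - 1 degrees of freedom, which supplies
the significance line.  The candidate grid holds every integer multiple
of the bin width inside the requested range (folding needs whole bins).

Actograms are the field's raster display: one row per day, conventionally
double-plotted (each row shows 48 h: day r followed by day r+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChiSquaredPeriodogram",
    "PeriodogramResults",
    "chi_squared_periodogram",
    "population_periodogram",
    "actogram_matrix",
]


def _fold_statistic(x: np.ndarray, periods_bins: np.ndarray) -> np.ndarray:
    """Q for each candidate period (in bins) of a single series."""
    q = np.empty(len(periods_bins))
    for j, P in enumerate(periods_bins):
        K = len(x) // P
        used = x[: K * P]
        grand = used.mean()
        col_means = used.reshape(K, P).mean(axis=0)
        denom = ((used - grand) ** 2).sum()
        # Q = K * sum_h (M_h - Mbar)^2 / (sample variance of the used bins)
        # with the variance written out as sum_i (x_i - Mbar)^2 / (K*P)
        q[j] = K * K * P * ((col_means - grand) ** 2).sum() / denom
    return q


@dataclass
class PeriodogramResults:
    """Fitted chi-squared periodogram of one specimen or one group.

    Attributes
    ----------
    label : specimen id or group label.
    period_h : tested periods, hours (strictly increasing grid).
    Q : chi-squared statistic per period.
    df : degrees of freedom per period (P - 1, P in bins).
    threshold : significance line per period (NaN until
        :meth:`significance` is called).
    """

    label: str
    period_h: np.ndarray
    Q: np.ndarray
    df: np.ndarray
    threshold: np.ndarray = field(default=None)
    alpha: float | None = None
    correction: str | None = None

    def __post_init__(self):
        if self.threshold is None:
            self.threshold = np.full(len(self.period_h), np.nan)

    def significance(self, alpha: float = 0.01,
                     correction: str = "bonferroni") -> "PeriodogramResults":
        """Fill the significance line from the chi-squared null.

        ``threshold(P) = chi2.ppf(1 - alpha_adj, df=P-1)`` with
        ``alpha_adj = alpha / m`` under Bonferroni correction over the m
        tested periods (``correction="none"`` uses alpha per period).
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")
        m = len(self.period_h) if correction == "bonferroni" else 1
        self.threshold = stats.chi2.ppf(1 - alpha / m, self.df)
        self.alpha = alpha
        self.correction = correction
        return self

    def peaks(self) -> list[tuple[float, float]]:
        """Significant local maxima of Q, best first.

        A peak is a grid point strictly above its neighbours (ties
        propagate: plateau ends count once) with Q above the threshold
        line.  Sorted by Q descending; exact Q ties break toward the
        shorter period.
        """
        if np.all(np.isnan(self.threshold)):
            raise ValueError("call significance() before peaks()")
        q = self.Q
        n = len(q)
        found = []
        for i in range(n):
            left = q[i - 1] if i > 0 else -np.inf
            right = q[i + 1] if i < n - 1 else -np.inf
            if q[i] >= left and q[i] >= right and q[i] > self.threshold[i]:
                if i > 0 and q[i] == q[i - 1]:
                    continue  # plateau: keep the leftmost point only
                found.append((float(self.period_h[i]), float(q[i])))
        found.sort(key=lambda pq: (-pq[1], pq[0]))
        return found

    @property
    def best_period_h(self) -> float:
        """Period of the global maximum of Q (ties toward shorter)."""
        return float(self.period_h[int(np.argmax(self.Q))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.label, "period_h": self.period_h, "Q": self.Q,
            "df": self.df, "threshold": self.threshold,
        })

    def summary(self) -> str:
        lines = [f"Chi-squared periodogram — {self.label}",
                 f"  grid: {self.period_h[0]:g}–{self.period_h[-1]:g} h, "
                 f"{len(self.period_h)} periods"]
        if self.alpha is not None:
            lines.append(f"  significance: alpha={self.alpha}, "
                         f"{self.correction} correction")
            pk = self.peaks()
            if pk:
                lines.append("  peaks (period_h, Q): "
                             + ", ".join(f"({p:g}, {q:.1f})" for p, q in pk[:3]))
            else:
                lines.append("  no significant peak")
        return "\n".join(lines)


class ChiSquaredPeriodogram:
    """Chi-squared periodogram model for one regularly binned series.

    Parameters
    ----------
    values
        Activity per bin on a regular grid (e.g. counts of moving bins
        per 30 min).
    bin_s
        Bin width, seconds.
    period_range_h
        Candidate period range in hours; the grid holds every integer
        bin multiple inside it.
    label
        Carried through to the results.
    """

    def __init__(self, values, bin_s: float = 1800.0,
                 period_range_h: tuple[float, float] = (16.0, 32.0),
                 label: str = "series"):
        x = np.asarray(values, dtype=float)
        if x.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.isnan(x).any():
            raise ValueError("values contain NaN")
        lo, hi = period_range_h
        p_min = max(2, int(np.ceil(lo * 3600.0 / bin_s)))
        p_max = int(np.floor(hi * 3600.0 / bin_s))
        if p_max < p_min:
            raise ValueError("period range holds no whole-bin period")
        if len(x) * bin_s < 2 * hi * 3600.0:
            raise ValueError(
                "series span must be at least twice the longest tested period"
            )
        if np.ptp(x) == 0:
            raise ValueError("constant series has no rhythm to test")
        self.x = x
        self.bin_s = bin_s
        self.periods_bins = np.arange(p_min, p_max + 1)
        self.label = label

    def fit(self) -> PeriodogramResults:
        """Compute Q over the candidate grid."""
        q = _fold_statistic(self.x, self.periods_bins)
        return PeriodogramResults(
            label=self.label,
            period_h=self.periods_bins * self.bin_s / 3600.0,
            Q=q,
            df=(self.periods_bins - 1).astype(float),
        )


def chi_squared_periodogram(values, bin_s: float = 1800.0,
                            period_range_h: tuple[float, float] = (16.0, 32.0),
                            label: str = "series",
                            alpha: float | None = 0.01,
                            correction: str = "bonferroni") -> PeriodogramResults:
    """One-call convenience: fit the periodogram and fill significance."""
    res = ChiSquaredPeriodogram(values, bin_s, period_range_h, label).fit()
    if alpha is not None:
        res.significance(alpha, correction)
    return res


def population_periodogram(results: list[PeriodogramResults],
                           label: str = "population") -> PeriodogramResults:
    """Average per-specimen Q curves into one population curve.

    All inputs must share the same period grid.  The chi-squared null
    does not apply to an averaged curve; the attached threshold (copied
    from the inputs when they agree) is for visual reference only.
    """
    if not results:
        raise ValueError("no periodograms to aggregate")
    grid = results[0].period_h
    for r in results[1:]:
        if not np.array_equal(r.period_h, grid):
            raise ValueError("periodograms have different period grids")
    Q = np.mean([r.Q for r in results], axis=0)
    thr = results[0].threshold
    same_thr = all(np.array_equal(r.threshold, thr, equal_nan=True)
                   for r in results)
    return PeriodogramResults(
        label=label, period_h=grid.copy(), Q=Q,
        df=results[0].df.copy(),
        threshold=thr.copy() if same_thr else np.full(len(grid), np.nan),
        alpha=results[0].alpha if same_thr else None,
        correction=results[0].correction if same_thr else None,
    )


def actogram_matrix(values, bin_s: float = 1800.0, day_length_h: float = 24.0,
                    double: bool = True) -> np.ndarray:
    """Raster of activity by day for actogram display.

    *values* is a regularly binned activity series starting at the day
    reference.  Returns a matrix with one row per day; when *double* is
    true each row holds day r followed by day r+1 (so row r's right half
    equals row r+1's left half) and the last row's right half is NaN.
    Partial days are NaN-padded.
    """
    x = np.asarray(values, dtype=float)
    per_day = int(round(day_length_h * 3600.0 / bin_s))
    if per_day <= 0:
        raise ValueError("day must span at least one bin")
    n_days = int(np.ceil(len(x) / per_day))
    padded = np.full(n_days * per_day, np.nan)
    padded[: len(x)] = x
    days = padded.reshape(n_days, per_day)
    if not double:
        return days
    out = np.full((n_days, 2 * per_day), np.nan)
    out[:, :per_day] = days
    out[:-1, per_day:] = days[1:]
    return out
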