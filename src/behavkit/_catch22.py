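"""The curated set of 22 canonical time-series features.

These are the 22 features distilled from the massive HCTSA library into
the canonical curated subset known in the field as catch22: a fixed,
named, ordered collection of statistical, information-theoretic and
nonlinear summaries that together discriminate a wide range of
time-series classes.  They are authored here from their published
definitions on top of numpy/scipy; minor numerical details (histogram
binning rules, spline versus polynomial detrending) may differ from
other implementations of the set, but the mapping series -> 22 values is
deterministic and the feature semantics are the canonical ones.

All features are computed on the z-scored series (the set's convention);
a constant series cannot be z-scored and yields NaN for every feature,
which callers treat as a per-cell failure flag.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

__all__ = ["FEATURE_NAMES", "compute_features"]

# canonical order of the curated set
FEATURE_NAMES = (
    "DN_HistogramMode_5",
    "DN_HistogramMode_10",
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "CO_HistogramAMI_even_2_5",
    "CO_trev_1_num",
    "MD_hrv_classic_pnn40",
    "SB_BinaryStats_mean_longstretch1",
    "SB_TransitionMatrix_3ac_sumdiagcov",
    "PD_PeriodicityWang_th0_01",
    "CO_Embed2_Dist_tau_d_expfit_meandiff",
    "IN_AutoMutualInfoStats_40_gaussian_fmmi",
    "FC_LocalSimple_mean1_tauresrat",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SP_Summaries_welch_rect_area_5_1",
    "SB_BinaryStats_diff_longstretch0",
    "SB_MotifThree_quantile_hh",
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1",
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1",
    "SP_Summaries_welch_rect_centroid",
    "FC_LocalSimple_mean3_stderr",
)

MIN_LENGTH = 10


# ----------------------------------------------------------------------
# shared helpers
def _acf(y: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Autocorrelation function via FFT, acf[0] = 1."""
    n = len(y)
    if max_lag is None:
        max_lag = n - 1
    f = np.fft.rfft(y - y.mean(), 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    return acov / acov[0]


def _first_zero_ac(y: np.ndarray) -> int:
    """First lag at which the ACF is <= 0 (lag N if it never is)."""
    acf = _acf(y)
    for tau in range(1, len(acf)):
        if acf[tau] <= 0:
            return tau
    return len(y)


def _longest_run(binary: np.ndarray, value: int) -> int:
    best = cur = 0
    for b in binary:
        if b == value:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def _coarse_grain_quantile(y: np.ndarray, n_symbols: int) -> np.ndarray:
    """Symbolize into equiprobable classes 0..n_symbols-1 by quantiles."""
    edges = np.quantile(y, np.linspace(0, 1, n_symbols + 1))
    edges[0] -= 1.0  # include the minimum in the first class
    return (np.searchsorted(edges, y, side="left") - 1).clip(0, n_symbols - 1)


# ----------------------------------------------------------------------
# individual features (all take the z-scored series)
def _histogram_mode(y: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(y, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    top = counts == counts.max()
    return float(centers[top].mean())


def _f1ecac(y: np.ndarray) -> float:
    """First 1/e crossing of the ACF, linearly interpolated."""
    acf = _acf(y)
    thresh = 1.0 / np.e
    for i in range(1, len(acf)):
        if acf[i] < thresh:
            return float(i - 1 + (acf[i - 1] - thresh) / (acf[i - 1] - acf[i]))
    return float(len(y))


def _first_min_ac(y: np.ndarray) -> float:
    acf = _acf(y)
    for i in range(1, len(acf) - 1):
        if acf[i] < acf[i - 1] and acf[i] < acf[i + 1]:
            return float(i)
    return float(len(y))


def _histogram_ami_even(y: np.ndarray, tau: int = 2, n_bins: int = 5) -> float:
    """Automutual information at lag tau with even-width bins."""
    a, b = y[:-tau], y[tau:]
    lo, hi = y.min() - 0.1, y.max() + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
    pij = joint / joint.sum()
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log(pij / (pi * pj))
    return float(np.nansum(terms))


def _trev_1_num(y: np.ndarray) -> float:
    return float(np.mean(np.diff(y) ** 3))


def _pnn40(y: np.ndarray) -> float:
    dy = np.abs(np.diff(y))
    return float(np.mean(dy > 0.04))


def _binarystats_mean_longstretch1(y: np.ndarray) -> float:
    return float(_longest_run((y > y.mean()).astype(int), 1))


def _binarystats_diff_longstretch0(y: np.ndarray) -> float:
    return float(_longest_run((np.diff(y) >= 0).astype(int), 0))


def _transition_matrix_3ac_sumdiagcov(y: np.ndarray) -> float:
    tau = max(_first_zero_ac(y), 1)
    ds = y[::tau]
    if len(ds) < 5:
        return np.nan
    sym = _coarse_grain_quantile(ds, 3)
    T = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        T[a, b] += 1
    T /= T.sum()
    return float(np.trace(np.cov(T, rowvar=False)))


def _periodicity_wang(y: np.ndarray, th: float = 0.01) -> float:
    """Wang's periodicity: first qualifying ACF peak after detrending."""
    n = len(y)
    # cubic-polynomial detrend stands in for the original spline detrend
    x = np.arange(n, dtype=float)
    coef = np.polynomial.polynomial.polyfit(x, y, 3)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    if np.allclose(resid.std(), 0):
        return 1.0
    acf = _acf(resid, max_lag=max(n // 3, 2))
    troughs, peaks = [], []
    for i in range(1, len(acf) - 1):
        if acf[i] < acf[i - 1] and acf[i] <= acf[i + 1]:
            troughs.append(i)
        elif acf[i] > acf[i - 1] and acf[i] >= acf[i + 1]:
            peaks.append(i)
    for p in peaks:
        earlier = [t for t in troughs if t < p]
        if not earlier:
            continue
        t = earlier[-1]
        if acf[p] - acf[t] >= th and acf[p] > 0:
            return float(p)
    return 1.0


def _embed2_dist_expfit_meandiff(y: np.ndarray) -> float:
    """Goodness of an exponential fit to successive distances in a 2-D
    time-delay embedding."""
    n = len(y)
    tau = _first_zero_ac(y)
    if tau > n // 10:
        tau = n // 10
    tau = max(tau, 1)
    a = y[: n - tau]
    b = y[tau:]
    d = np.hypot(np.diff(a), np.diff(b))
    if len(d) < 3 or d.mean() == 0:
        return np.nan
    lam = d.mean()
    n_bins = int(np.ceil(np.sqrt(len(d))))
    counts, edges = np.histogram(d, bins=n_bins)
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    expf = np.exp(-centers / lam) / lam
    return float(np.mean(np.abs(density - expf)))


def _automutual_info_gaussian_fmmi(y: np.ndarray, max_tau: int = 40) -> float:
    """First minimum of the Gaussian automutual information."""
    max_tau = min(max_tau, len(y) // 2)
    ami = []
    for tau in range(1, max_tau + 1):
        r = np.corrcoef(y[:-tau], y[tau:])[0, 1]
        r = min(abs(r), 1 - 1e-12)
        ami.append(-0.5 * np.log(1 - r ** 2))
    for i in range(1, len(ami) - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            return float(i + 1)
    return float(len(ami))


def _local_simple_mean_tauresrat(y: np.ndarray, train: int = 1) -> float:
    res = _local_mean_residuals(y, train)
    return float(_first_zero_ac(res)) / float(_first_zero_ac(y))


def _local_mean_residuals(y: np.ndarray, train: int) -> np.ndarray:
    n = len(y)
    kernel = np.ones(train) / train
    pred = np.convolve(y, kernel, mode="valid")[: n - train]
    return y[train:] - pred


def _local_simple_mean_stderr(y: np.ndarray, train: int = 3) -> float:
    res = _local_mean_residuals(y, train)
    return float(res.std(ddof=1))


def _outlier_include_mdrmd(y: np.ndarray, sign: int, inc: float = 0.01) -> float:
    """Median relative position of threshold-exceeding points, medianed
    over an increasing outlier-inclusion threshold."""
    w = y * sign
    n = len(w)
    if w.max() < inc:
        return 0.0
    thresholds = np.arange(0, w.max() + inc, inc)
    msdti3, msdti4 = [], []
    for th in thresholds:
        r = np.nonzero(w >= th)[0] + 1  # 1-based positions
        if len(r) == 0:
            break
        msdti3.append(100.0 * len(r) / n)
        msdti4.append(np.median(r) / (n / 2.0) - 1.0)
    msdti3 = np.asarray(msdti3)
    msdti4 = np.asarray(msdti4)
    keep = msdti3 > 2.0  # keep thresholds including > 2% of points
    last = np.nonzero(keep)[0]
    if len(last) == 0:
        return 0.0
    return float(np.median(msdti4[: last[-1] + 1]))


def _welch_spectrum(y: np.ndarray):
    freqs, s = _signal.periodogram(y, window="boxcar", detrend=False)
    w = 2 * np.pi * freqs
    return w[1:], s[1:]  # drop the DC bin


def _welch_area_5_1(y: np.ndarray) -> float:
    w, s = _welch_spectrum(y)
    dw = w[1] - w[0]
    k = max(len(s) // 5, 1)
    return float(s[:k].sum() * dw)


def _welch_centroid(y: np.ndarray) -> float:
    w, s = _welch_spectrum(y)
    cs = np.cumsum(s)
    half = cs[-1] / 2.0
    idx = int(np.searchsorted(cs, half))
    return float(w[min(idx, len(w) - 1)])


def _motif_three_quantile_hh(y: np.ndarray) -> float:
    sym = _coarse_grain_quantile(y, 3)
    pairs = sym[:-1] * 3 + sym[1:]
    counts = np.bincount(pairs, minlength=9).astype(float)
    p = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p)
    return float(-np.nansum(terms))


def _fluct_anal_prop_r1(y: np.ndarray, mode: str, lag: int = 1,
                        n_scales: int = 50) -> float:
    """Two-regime scaling split of a fluctuation function.

    Computes the fluctuation function F(tau) (detrended fluctuation
    analysis or rescaled-range) over ~*n_scales* log-spaced window sizes,
    fits two straight lines to log F vs log tau over every admissible
    split, and returns the proportion of scales covered by the first
    (small-scale) regime at the best split.
    """
    x = np.cumsum(y[::lag] - y[::lag].mean())
    n = len(x)
    if n < 20:
        return np.nan
    taus = np.unique(np.floor(
        np.logspace(np.log10(5), np.log10(n / 2), n_scales)).astype(int))
    taus = taus[taus >= 5]
    if len(taus) < 6:
        return np.nan
    F = np.empty(len(taus))
    t_idx = np.arange(n)
    for i, tau in enumerate(taus):
        n_win = n // tau
        vals = []
        for k in range(n_win):
            seg = x[k * tau: (k + 1) * tau]
            tt = t_idx[: tau].astype(float)
            A = np.vstack([tt, np.ones(tau)]).T
            coef, *_ = np.linalg.lstsq(A, seg, rcond=None)
            resid = seg - A @ coef
            if mode == "dfa":
                vals.append(np.mean(resid ** 2))
            else:  # rsrangefit
                vals.append((resid.max() - resid.min()) ** 2)
        F[i] = np.sqrt(np.mean(vals))
    logt, logF = np.log(taus), np.log(F)
    if not np.all(np.isfinite(logF)):
        return np.nan
    best, best_err = None, np.inf
    m = len(taus)
    for split in range(3, m - 2):
        err = 0.0
        for seg_t, seg_f in ((logt[:split], logF[:split]),
                             (logt[split - 1:], logF[split - 1:])):
            A = np.vstack([seg_t, np.ones(len(seg_t))]).T
            coef, *_ = np.linalg.lstsq(A, seg_f, rcond=None)
            err += np.mean((seg_f - A @ coef) ** 2)
        if err < best_err:
            best_err, best = err, split
    return float(best) / m


# ----------------------------------------------------------------------
_FEATURE_FUNCS = {
    "DN_HistogramMode_5": lambda y: _histogram_mode(y, 5),
    "DN_HistogramMode_10": lambda y: _histogram_mode(y, 10),
    "CO_f1ecac": _f1ecac,
    "CO_FirstMin_ac": _first_min_ac,
    "CO_HistogramAMI_even_2_5": _histogram_ami_even,
    "CO_trev_1_num": _trev_1_num,
    "MD_hrv_classic_pnn40": _pnn40,
    "SB_BinaryStats_mean_longstretch1": _binarystats_mean_longstretch1,
    "SB_TransitionMatrix_3ac_sumdiagcov": _transition_matrix_3ac_sumdiagcov,
    "PD_PeriodicityWang_th0_01": _periodicity_wang,
    "CO_Embed2_Dist_tau_d_expfit_meandiff": _embed2_dist_expfit_meandiff,
    "IN_AutoMutualInfoStats_40_gaussian_fmmi": _automutual_info_gaussian_fmmi,
    "FC_LocalSimple_mean1_tauresrat": _local_simple_mean_tauresrat,
    "DN_OutlierInclude_p_001_mdrmd": lambda y: _outlier_include_mdrmd(y, 1),
    "DN_OutlierInclude_n_001_mdrmd": lambda y: _outlier_include_mdrmd(y, -1),
    "SP_Summaries_welch_rect_area_5_1": _welch_area_5_1,
    "SB_BinaryStats_diff_longstretch0": _binarystats_diff_longstretch0,
    "SB_MotifThree_quantile_hh": _motif_three_quantile_hh,
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1":
        lambda y: _fluct_anal_prop_r1(y, "rsrangefit", lag=1),
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1":
        lambda y: _fluct_anal_prop_r1(y, "dfa", lag=2),
    "SP_Summaries_welch_rect_centroid": _welch_centroid,
    "FC_LocalSimple_mean3_stderr": _local_simple_mean_stderr,
}

assert tuple(_FEATURE_FUNCS) == FEATURE_NAMES


def compute_features(series) -> np.ndarray:
    """Map one series to the 22 curated feature values (canonical order).

    The series is z-scored first.  A constant series yields all-NaN
    (every feature flagged); individual features may yield NaN when
    their own preconditions fail (e.g. too few distances to fit).
    Series shorter than ``MIN_LENGTH`` raise ``ValueError``.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(y) < MIN_LENGTH:
        raise ValueError(f"series too short (< {MIN_LENGTH} values)")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    sd = y.std()
    if sd == 0:
        return np.full(len(FEATURE_NAMES), np.nan)
    z = (y - y.mean()) / sd
    out = np.empty(len(FEATURE_NAMES))
    for i, name in enumerate(FEATURE_NAMES):
        try:
            out[i] = _FEATURE_FUNCS[name](z)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            out[i] = np.nan
    return out
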