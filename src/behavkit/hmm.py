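"""Constrained four-state hidden Markov model of fly sleep stages.

Binary activity (inactive/moving per bin) is modelled as emissions from
four covert stages — deep sleep, light sleep, quiet awake, active awake.
The model is constrained: both sleep stages emit movement with
probability exactly zero (sleep is complete inactivity), and a
structural-zero mask on the transition matrix forbids implausible jumps
(by default deep sleep cannot wake directly into either awake stage,
and active awake cannot drop straight into deep sleep).  The mask is
user-overridable.

Training is Baum–Welch (EM) on the pooled sequences of all specimens,
with seeded random restarts; masked entries stay exactly zero at every
iteration because the expected transition counts inherit the zeros
multiplicatively.  Decoding is Viterbi (ties toward the lowest state
index), with optional posterior marginals from forward–backward.

The public surface follows the model/results convention:
``SleepStageHMM(sequences, spec).fit(...)`` returns a
:class:`SleepStageHMMResults` carrying the fitted matrices, the
per-restart log-likelihood trajectories, and the decoding and occupancy
methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SECONDS_PER_DAY

__all__ = [
    "HmmSpec",
    "default_hmm_spec",
    "SleepStageHMM",
    "SleepStageHMMResults",
    "sample_hmm",
    "split_on_missing",
    "state_occupancy",
]

STATE_LABELS = ("deep_sleep", "light_sleep", "quiet_awake", "active_awake")
OBS_LABELS = ("inactive", "moving")

_ROW_TOL = 1e-9
_PROB_FLOOR = 1e-12  # numerical floor for free (unmasked) entries


@dataclass
class HmmSpec:
    """Parameters of the constrained categorical HMM.

    Attributes
    ----------
    labels : state names, index order defines the state indices.
    startprob : initial distribution pi, length n_states.
    transmat : row-stochastic transition matrix A.
    emissionprob : row-stochastic emission matrix B over
        ``(inactive, moving)``.
    trans_mask, emis_mask : boolean masks, True where the entry is free;
        False entries are structural zeros (exactly 0, preserved by
        training).
    """

    labels: tuple[str, ...]
    startprob: np.ndarray
    transmat: np.ndarray
    emissionprob: np.ndarray
    trans_mask: np.ndarray
    emis_mask: np.ndarray

    def __post_init__(self):
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.emissionprob = np.asarray(self.emissionprob, dtype=float)
        self.trans_mask = np.asarray(self.trans_mask, dtype=bool)
        self.emis_mask = np.asarray(self.emis_mask, dtype=bool)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def validate(self) -> None:
        n = self.n_states
        if self.transmat.shape != (n, n):
            raise ValueError("transmat shape mismatch")
        if self.emissionprob.shape[0] != n:
            raise ValueError("emissionprob shape mismatch")
        for name, mat in (("transmat", self.transmat),
                          ("emissionprob", self.emissionprob)):
            if np.any(mat < 0):
                raise ValueError(f"{name} has negative entries")
            rows = mat.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > _ROW_TOL):
                raise ValueError(f"{name} rows must sum to 1 (got {rows})")
        if abs(self.startprob.sum() - 1.0) > _ROW_TOL:
            raise ValueError("startprob must sum to 1")
        if np.any(self.transmat[~self.trans_mask] != 0.0):
            raise ValueError("masked transition entries must be exactly 0")
        if np.any(self.emissionprob[~self.emis_mask] != 0.0):
            raise ValueError("masked emission entries must be exactly 0")

    def copy(self) -> "HmmSpec":
        return HmmSpec(self.labels, self.startprob.copy(),
                       self.transmat.copy(), self.emissionprob.copy(),
                       self.trans_mask.copy(), self.emis_mask.copy())

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "labels": list(self.labels),
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "emissionprob": self.emissionprob.tolist(),
            "trans_mask": self.trans_mask.astype(int).tolist(),
            "emis_mask": self.emis_mask.astype(int).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HmmSpec":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            labels=tuple(payload["labels"]),
            startprob=np.array(payload["startprob"]),
            transmat=np.array(payload["transmat"]),
            emissionprob=np.array(payload["emissionprob"]),
            trans_mask=np.array(payload["trans_mask"], dtype=bool),
            emis_mask=np.array(payload["emis_mask"], dtype=bool),
        )


def default_hmm_spec() -> HmmSpec:
    """The default constrained four-state sleep-stage template.

    The transition topology is the adjacency chain deep_sleep ↔
    light_sleep ↔ quiet_awake ↔ active_awake with self-loops, plus the
    light_sleep → active_awake shortcut (startled awakening from light
    sleep); everything else — deep_sleep→{quiet,active}_awake,
    quiet_awake→deep_sleep, active_awake→{deep_sleep, light_sleep} — is
    a structural zero.  Deep and light sleep emit ``moving`` with
    probability 0 (sleep is complete inactivity).  Besides being the
    chain the sleep-stage literature uses, this topology makes the four
    states identifiable from binary activity alone: the two awake
    states cannot trade places without paying likelihood through their
    distinct allowed transitions.  Free entries are initialized
    uniformly over the allowed entries of each row; the mask is a
    user-overridable convention, not a fitted quantity.
    """
    n = len(STATE_LABELS)
    trans_mask = np.ones((n, n), dtype=bool)
    forbid = [("deep_sleep", "quiet_awake"),
              ("deep_sleep", "active_awake"),
              ("quiet_awake", "deep_sleep"),
              ("active_awake", "deep_sleep"),
              ("active_awake", "light_sleep")]
    for a, b in forbid:
        trans_mask[STATE_LABELS.index(a), STATE_LABELS.index(b)] = False
    emis_mask = np.ones((n, 2), dtype=bool)
    emis_mask[STATE_LABELS.index("deep_sleep"), 1] = False
    emis_mask[STATE_LABELS.index("light_sleep"), 1] = False

    transmat = _uniform_over_mask(trans_mask)
    emissionprob = _uniform_over_mask(emis_mask)
    startprob = np.full(n, 1.0 / n)
    return HmmSpec(STATE_LABELS, startprob, transmat, emissionprob,
                   trans_mask, emis_mask)


def _uniform_over_mask(mask: np.ndarray) -> np.ndarray:
    out = mask.astype(float)
    return out / out.sum(axis=1, keepdims=True)


def _random_over_mask(mask: np.ndarray, rng: np.random.Generator,
                      sticky: float | None = None) -> np.ndarray:
    """Row-stochastic matrix with Dirichlet(1) weights on free entries.

    With *sticky*, that fraction of each row's mass is moved onto the
    diagonal — behavioural stages are persistent, so restarts that start
    from diagonal-dominant dynamics explore the relevant basin.
    """
    out = np.zeros(mask.shape)
    for i in range(mask.shape[0]):
        k = int(mask[i].sum())
        out[i, mask[i]] = rng.dirichlet(np.ones(k))
        if sticky is not None and mask[i, i]:
            out[i] *= (1.0 - sticky)
            out[i, i] += sticky
    return out


# ----------------------------------------------------------------------
# sequence utilities
def split_on_missing(ms: pd.DataFrame, column: str = "moving"):
    """Split a movement series into contiguous observation sequences.

    Missing (NaN) bins split sequences, so no transition is ever fitted
    across a recording gap.  Returns ``(sequences, index)`` where
    *index* maps each sequence back to ``(id, t_start)``.
    """
    seqs, index = [], []
    for sid, grp in ms.groupby("id", sort=False):
        vals = grp[column].to_numpy(dtype=float)
        t = grp["t"].to_numpy()
        isnan = np.isnan(vals)
        start = None
        for i in range(len(vals) + 1):
            if i < len(vals) and not isnan[i]:
                if start is None:
                    start = i
            else:
                if start is not None:
                    seqs.append(vals[start:i].astype(int))
                    index.append((sid, float(t[start])))
                    start = None
    return seqs, index


try:  # JIT-compiled E-step; the numpy path below is the fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _fb_sufficient_stats_py(pi, A, B, obs_flat, starts, lengths):
    """Scaled forward-backward sufficient statistics, reference path.

    Returns (loglik, xi_sum, gamma_obs, gamma0): expected transition
    counts, expected emission counts by symbol, and summed initial
    posteriors over all sequences.  loglik is NaN when some sequence is
    impossible under the parameters.
    """
    S = pi.shape[0]
    M = B.shape[1]
    loglik = 0.0
    xi_sum = np.zeros((S, S))
    gamma_obs = np.zeros((S, M))
    gamma0 = np.zeros(S)
    n_seq = len(starts)
    for q in range(n_seq):
        s0 = starts[q]
        L = lengths[q]
        o = obs_flat[s0: s0 + L]
        alpha = np.empty((L, S))
        c = np.empty(L)
        # forward pass (scaled); explicit loops keep the 4x4 products
        # free of BLAS dispatch overhead
        tot = 0.0
        for i in range(S):
            alpha[0, i] = pi[i] * B[i, o[0]]
            tot += alpha[0, i]
        if tot <= 0:
            return np.nan, xi_sum, gamma_obs, gamma0
        c[0] = tot
        for i in range(S):
            alpha[0, i] /= tot
        for t in range(1, L):
            tot = 0.0
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += alpha[t - 1, i] * A[i, j]
                acc *= B[j, o[t]]
                alpha[t, j] = acc
                tot += acc
            if tot <= 0:
                return np.nan, xi_sum, gamma_obs, gamma0
            c[t] = tot
            for j in range(S):
                alpha[t, j] /= tot
        for t in range(L):
            loglik += np.log(c[t])
        # backward pass, accumulating sufficient statistics in place
        beta = np.ones(S)
        beta_new = np.empty(S)
        for i in range(S):
            gamma_obs[i, o[L - 1]] += alpha[L - 1, i]
        for t in range(L - 2, -1, -1):
            ct1 = c[t + 1]
            for j in range(S):
                beta_new[j] = 0.0
            for i in range(S):
                ai = alpha[t, i]
                for j in range(S):
                    bb = B[j, o[t + 1]] * beta[j] / ct1
                    xi_sum[i, j] += ai * A[i, j] * bb
                    beta_new[i] += A[i, j] * bb
            for i in range(S):
                beta[i] = beta_new[i]
            for i in range(S):
                g = alpha[t, i] * beta[i]
                gamma_obs[i, o[t]] += g
                if t == 0:
                    gamma0[i] += g
        if L == 1:
            for i in range(S):
                gamma0[i] += alpha[0, i]
    return loglik, xi_sum, gamma_obs, gamma0


if _njit is not None:
    _fb_sufficient_stats = _njit(cache=False)(_fb_sufficient_stats_py)
else:  # pragma: no cover
    _fb_sufficient_stats = _fb_sufficient_stats_py


def _flatten(sequences) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
    obs_flat = np.concatenate(sequences).astype(np.int64)
    return obs_flat, starts, lengths


def _pack(sequences) -> tuple[np.ndarray, np.ndarray]:
    """Pad sequences to (n_seq, T_max) with obs 0 and return lengths."""
    lengths = np.array([len(s) for s in sequences], dtype=int)
    obs = np.zeros((len(sequences), lengths.max()), dtype=int)
    for i, s in enumerate(sequences):
        obs[i, : len(s)] = s
    return obs, lengths


def _batched_forward_backward(pi, A, B, obs, lengths):
    """Scaled forward-backward over a padded batch of sequences.

    Padded steps use unit emission likelihood; because A is
    row-stochastic this keeps their scale factors at 1 and their beta at
    1, so they contribute nothing to the log-likelihood or the
    sufficient statistics (which are masked anyway).

    Returns (loglik, gamma, xi_sum, gamma0) where gamma is (n, T, S)
    posteriors, xi_sum is the (S, S) expected transition counts summed
    over sequences and time, and gamma0 the summed initial posteriors.
    """
    n, T = obs.shape
    S = len(pi)
    active = np.arange(T)[None, :] < lengths[:, None]  # (n, T)
    be = B.T[obs]                   # (n, T, S) emission likelihoods
    be[~active] = 1.0

    alpha = np.empty((n, T, S))
    c = np.ones((n, T))
    a = pi[None, :] * be[:, 0]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0):
        raise FloatingPointError("impossible observation at t=0")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * be[:, t]
        ct = a.sum(axis=1)
        bad = (ct <= 0) & active[:, t]
        if np.any(bad):
            raise FloatingPointError(f"impossible observation at t={t}")
        ct = np.where(ct > 0, ct, 1.0)
        c[:, t] = ct
        alpha[:, t] = a / ct[:, None]
    loglik = float(np.log(c[active]).sum())

    beta = np.empty((n, T, S))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        bb = be[:, t + 1] * beta[:, t + 1]          # (n, S)
        beta[:, t] = (bb @ A.T) / c[:, t + 1, None]
        # expected transitions t -> t+1, only where t+1 is a real step
        w = active[:, t + 1].astype(float)[:, None]
        left = alpha[:, t] * w                      # (n, S)
        right = bb / c[:, t + 1, None]              # (n, S)
        xi_sum += (left.T @ right) * A

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma[~active] = 0.0
    gamma0 = gamma[:, 0].sum(axis=0)
    return loglik, gamma, xi_sum, gamma0


def _loglik_only(pi, A, B, obs, lengths) -> float:
    n, T = obs.shape
    active = np.arange(T)[None, :] < lengths[:, None]
    be = B.T[obs]
    be[~active] = 1.0
    a = pi[None, :] * be[:, 0]
    c0 = a.sum(axis=1)
    alpha = a / c0[:, None]
    ll = np.log(c0).sum()
    for t in range(1, T):
        a = (alpha @ A) * be[:, t]
        ct = a.sum(axis=1)
        ct = np.where(ct > 0, ct, 1.0)
        alpha = a / ct[:, None]
        ll += np.log(ct[active[:, t]]).sum()
    return float(ll)


# ----------------------------------------------------------------------
class SleepStageHMM:
    """Constrained categorical HMM over pooled binary activity sequences.

    Parameters
    ----------
    sequences
        Either a movement-series frame (``id, t, moving`` — NaN splits
        sequences at recording gaps) or an explicit list of 1-D integer
        arrays with values in {0, 1}.
    spec
        Template :class:`HmmSpec`; defaults to :func:`default_hmm_spec`.
        Its masks define the structural zeros, its matrices the first
        restart's initialization.
    """

    def __init__(self, sequences, spec: HmmSpec | None = None):
        if isinstance(sequences, pd.DataFrame):
            sequences, self.sequence_index = split_on_missing(sequences)
        else:
            sequences = [np.asarray(s, dtype=int) for s in sequences]
            self.sequence_index = None
        if len(sequences) == 0 or sum(len(s) for s in sequences) == 0:
            raise ValueError("no observation sequences to fit")
        for s in sequences:
            if not np.isin(s, (0, 1)).all():
                raise ValueError("observations must be binary (0/1)")
        self.sequences = sequences
        self.spec = spec.copy() if spec is not None else default_hmm_spec()

    def fit(self, n_restarts: int = 5, tol: float = 1e-6,
            max_iter: int = 1000, seed: int | None = None) -> "SleepStageHMMResults":
        """Constrained Baum–Welch with seeded random restarts.

        Restart 0 starts from the template's own matrices; the remaining
        restarts draw free entries from a Dirichlet(1) over each row's
        allowed entries, with a random fraction of transition mass moved
        to the diagonal (behavioural stages are persistent).
        Convergence: absolute log-likelihood change below *tol*.  The
        restart with the highest final log-likelihood wins (ties toward
        the lowest restart index).
        """
        rng = np.random.default_rng(seed)
        obs_flat, starts, lengths = _flatten(self.sequences)
        spec = self.spec
        histories, finals, fitted = [], [], []
        for r in range(n_restarts):
            if r == 0:
                pi = spec.startprob.copy()
                A = spec.transmat.copy()
                B = spec.emissionprob.copy()
            else:
                pi = rng.dirichlet(np.ones(spec.n_states))
                A = _random_over_mask(spec.trans_mask, rng,
                                      sticky=rng.uniform(0.5, 0.95))
                B = _random_over_mask(spec.emis_mask, rng)
            pi, A, B, history = self._em(pi, A, B, obs_flat, starts, lengths,
                                         tol, max_iter)
            histories.append(history)
            finals.append(history[-1])
            fitted.append((pi, A, B))
        best = int(np.argmax(finals))
        pi, A, B = fitted[best]
        out = spec.copy()
        out.startprob, out.transmat, out.emissionprob = pi, A, B
        out.validate()
        degenerate = bool(np.any(B[spec.emis_mask] < 1e-8))
        return SleepStageHMMResults(
            model=self, spec=out, loglik=finals[best],
            loglik_histories=histories, best_restart=best,
            degenerate_emissions=degenerate,
        )

    def _em(self, pi, A, B, obs_flat, starts, lengths, tol, max_iter):
        spec = self.spec
        history = []
        prev = -np.inf
        for _ in range(max_iter):
            ll, xi_sum, gamma_obs, gamma0 = _fb_sufficient_stats(
                pi, A, B, obs_flat, starts, lengths)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    "observation sequence impossible under current parameters")
            history.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= tol:
                break
            prev = ll
            # M-step; masked entries have zero expected counts by
            # construction (xi inherits A's zeros, B's zeros keep their
            # states' posteriors away from the masked symbol)
            pi = gamma0 / gamma0.sum()
            rowsum = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(rowsum > 0, xi_sum / np.where(rowsum > 0, rowsum, 1.0), A)
            rs = gamma_obs.sum(axis=1, keepdims=True)
            B = np.where(rs > 0, gamma_obs / np.where(rs > 0, rs, 1.0), B)
            # numerical floor on free entries (structural zeros untouched)
            A = self._floor(A, spec.trans_mask)
            B = self._floor(B, spec.emis_mask)
        return pi, A, B, history

    @staticmethod
    def _floor(mat, mask):
        out = np.where(mask, np.maximum(mat, _PROB_FLOOR), 0.0)
        return out / out.sum(axis=1, keepdims=True)


@dataclass
class SleepStageHMMResults:
    """Fitted constrained sleep-stage HMM.

    Carries the winning restart's parameters (:attr:`spec`), its final
    log-likelihood, the full per-restart log-likelihood trajectories
    (each non-decreasing — an EM guarantee worth asserting), and the
    decoding methods.
    """

    model: SleepStageHMM
    spec: HmmSpec
    loglik: float
    loglik_histories: list[list[float]]
    best_restart: int
    degenerate_emissions: bool = False

    def summary(self) -> str:
        s = self.spec
        lines = [
            "Constrained sleep-stage HMM (Baum-Welch)",
            f"  sequences: {len(self.model.sequences)}  "
            f"total bins: {sum(len(q) for q in self.model.sequences)}",
            f"  restarts: {len(self.loglik_histories)}  "
            f"best: #{self.best_restart}  loglik: {self.loglik:.2f}",
        ]
        if self.degenerate_emissions:
            lines.append("  warning: degenerate emission probabilities")
        lines.append("  transition matrix (rows sum to 1, '.' = structural 0):")
        for i, lab in enumerate(s.labels):
            cells = [
                "    ." if not s.trans_mask[i, j] else f"{s.transmat[i, j]:.3f}"
                for j in range(s.n_states)
            ]
            lines.append(f"    {lab:>13}  " + "  ".join(c.strip() for c in cells))
        lines.append("  P(moving | state):")
        for i, lab in enumerate(s.labels):
            val = "0 (structural)" if not s.emis_mask[i, 1] else \
                f"{s.emissionprob[i, 1]:.3f}"
            lines.append(f"    {lab:>13}  {val}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def decode(self, sequences=None, bin_s: float = 1.0,
               posteriors: bool = False) -> pd.DataFrame:
        """Viterbi decoding to per-bin stage labels.

        With no argument, decodes the training input (using the stored
        ``(id, t)`` index when the model was built from a movement
        series).  ``t_bin`` holds the bin onset in seconds, ``t0 + k *
        bin_s`` within each contiguous sequence.  Returns ``(id, t_bin,
        state)`` plus ``p_<label>`` posterior columns when *posteriors*
        is set.
        """
        index = None
        if sequences is None:
            seqs = self.model.sequences
            index = self.model.sequence_index
        elif isinstance(sequences, pd.DataFrame):
            seqs, index = split_on_missing(sequences)
        else:
            seqs = [np.asarray(s, dtype=int) for s in sequences]
        for s in seqs:
            if not np.isin(s, (0, 1)).all():
                raise ValueError("observations must be binary (0/1)")
        if index is None:
            index = [(f"seq_{i}", 0.0) for i in range(len(seqs))]

        spec = self.spec
        frames = []
        for (sid, t0), s in zip(index, seqs):
            path = viterbi_path(spec, s)
            df = pd.DataFrame({
                "id": sid,
                "t_bin": t0 + bin_s * np.arange(len(s), dtype=float),
                "state": [spec.labels[k] for k in path],
            })
            if posteriors:
                post = posterior_marginals(spec, s)
                for j, lab in enumerate(spec.labels):
                    df[f"p_{lab}"] = post[:, j]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# decoding primitives
def viterbi_path(spec: HmmSpec, obs: np.ndarray) -> np.ndarray:
    """Most likely state path (log-space Viterbi).

    Ties break toward the lowest state index (argmax returns the first
    maximizer and states are ordered deep → light → quiet → active).
    """
    obs = np.asarray(obs, dtype=int)
    if not np.isin(obs, (0, 1)).all():
        raise ValueError("observations must be binary (0/1)")
    with np.errstate(divide="ignore"):
        logA = np.log(spec.transmat)
        logB = np.log(spec.emissionprob)
        logpi = np.log(spec.startprob)
    T = len(obs)
    S = spec.n_states
    delta = logpi + logB[:, obs[0]]
    psi = np.zeros((T, S), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA          # (from, to)
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(S)] + logB[:, obs[t]]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def viterbi_logprob(spec: HmmSpec, obs: np.ndarray,
                    path: np.ndarray) -> float:
    """Joint log-probability of a given state path and observations."""
    with np.errstate(divide="ignore"):
        lp = np.log(spec.startprob[path[0]]) + \
            np.log(spec.emissionprob[path[0], obs[0]])
        for t in range(1, len(obs)):
            lp += np.log(spec.transmat[path[t - 1], path[t]])
            lp += np.log(spec.emissionprob[path[t], obs[t]])
    return float(lp)


def posterior_marginals(spec: HmmSpec, obs: np.ndarray) -> np.ndarray:
    """Per-bin posterior state probabilities via forward-backward."""
    obs = np.asarray(obs, dtype=int)
    ll, gamma, _, _ = _batched_forward_backward(
        spec.startprob, spec.transmat, spec.emissionprob,
        obs[None, :], np.array([len(obs)]))
    return gamma[0]


def loglikelihood(spec: HmmSpec, sequences) -> float:
    """Total log-likelihood of sequences under a spec."""
    seqs = [np.asarray(s, dtype=int) for s in sequences]
    obs, lengths = _pack(seqs)
    return _loglik_only(spec.startprob, spec.transmat, spec.emissionprob,
                        obs, lengths)


def sample_hmm(spec: HmmSpec, n_seq: int, length: int,
               seed: int | None = None):
    """Sample state and observation sequences from a spec (ground truth
    for parameter-recovery tests)."""
    rng = np.random.default_rng(seed)
    states, obs = [], []
    for _ in range(n_seq):
        z = np.empty(length, dtype=int)
        x = np.empty(length, dtype=int)
        z[0] = rng.choice(spec.n_states, p=spec.startprob)
        for t in range(1, length):
            z[t] = rng.choice(spec.n_states, p=spec.transmat[z[t - 1]])
        for t in range(length):
            x[t] = rng.choice(spec.emissionprob.shape[1],
                              p=spec.emissionprob[z[t]])
        states.append(z)
        obs.append(x)
    return states, obs


# ----------------------------------------------------------------------
def state_occupancy(decoded: pd.DataFrame, meta: pd.DataFrame | None = None,
                    bin_s: float = 1800.0, group_by: str | None = None,
                    lights_on_reference: float = 0.0,
                    day_length: float = SECONDS_PER_DAY,
                    labels=STATE_LABELS) -> pd.DataFrame:
    """Fraction of bins in each stage by zeitgeber time.

    Returns ``(group, zt_bin, state, fraction)`` with ``zt_bin`` in
    hours; per (group, zt_bin) the four fractions sum to 1.
    """
    df = decoded.copy()
    zt_s = np.mod(df["t_bin"] - lights_on_reference, day_length)
    df["zt_bin"] = np.floor(zt_s / bin_s) * bin_s / 3600.0
    if group_by is None or meta is None:
        df["group"] = "all"
    else:
        df["group"] = df["id"].map(dict(zip(meta["id"], meta[group_by])))
    counts = (df.groupby(["group", "zt_bin", "state"], observed=True)
              .size().rename("n").reset_index())
    rows = []
    for (grp, zb), sub in counts.groupby(["group", "zt_bin"], observed=True):
        total = sub["n"].sum()
        by_state = dict(zip(sub["state"], sub["n"]))
        for lab in labels:
            rows.append((grp, zb, lab, by_state.get(lab, 0) / total))
    return pd.DataFrame(rows, columns=["group", "zt_bin", "state", "fraction"])
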