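"""Ground-truth simulator of fly populations.

Each fly is a four-state Markov chain (deep sleep, light sleep, quiet
awake, active awake) whose transition matrix oscillates between a
day-like and a night-like regime:

    A(t) = (1 - w(t)) * A_day + w(t) * A_night

with a sinusoidal mixing weight w(t) in [0, 1] whose period is the
genotype's circadian period and whose phase puts the night-like regime's
peak at a configurable zeitgeber hour (default ZT 15, the early night).
Both base matrices carry the same structural zeros as the sleep-stage
HMM template.  Movement is emitted per state (sleep states never move;
quiet and active awake move with configured probabilities), displacement
is log-normal — clearly supra-threshold when moving, tiny sub-threshold
tracker jitter otherwise — and positions follow a reflected random walk
inside a rectangular region.  Mechanical sleep deprivation is modelled
by windows that force the fly into active awake with movement every bin.

Every simulation carries its ground truth (per-bin true states, true
periods, configured deep-sleep peak hour), so downstream analyses —
sleep scoring, periodograms, HMM training, feature classification — can
be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BehavTable, SECONDS_PER_DAY
from .hmm import STATE_LABELS, default_hmm_spec

__all__ = [
    "Genotype",
    "SimConfig",
    "SimOutput",
    "default_day_matrix",
    "default_night_matrix",
    "simulate_population",
    "ground_truth_occupancy",
]

_DEEP, _LIGHT, _QUIET, _ACTIVE = range(4)


def default_day_matrix() -> np.ndarray:
    """Day-regime transition matrix: little sleep, much activity."""
    return np.array([
        [0.700, 0.300, 0.000, 0.000],   # deep_sleep
        [0.005, 0.600, 0.300, 0.095],   # light_sleep
        [0.000, 0.050, 0.600, 0.350],   # quiet_awake
        [0.000, 0.000, 0.100, 0.900],   # active_awake
    ])


def default_night_matrix() -> np.ndarray:
    """Night-regime transition matrix: consolidated deep sleep."""
    return np.array([
        [0.960, 0.040, 0.000, 0.000],
        [0.050, 0.900, 0.040, 0.010],
        [0.000, 0.150, 0.750, 0.100],
        [0.000, 0.000, 0.200, 0.800],
    ])


@dataclass(frozen=True)
class Genotype:
    name: str
    period_h: float
    n_flies: int


@dataclass
class SimConfig:
    """Study conditions of a simulated experiment.

    Defaults describe a wild-type-plus-period-mutant design: three
    genotypes with circadian periods short / 24 h / long, several days
    of recording at 10-s movement bins, night-like dynamics peaking at
    ZT 15 (the configured deep-sleep peak hour), and awake-state
    movement probabilities p_quiet < p_active.
    """

    genotypes: list[Genotype] = field(default_factory=lambda: [
        Genotype("per_short", 19.0, 10),
        Genotype("CantonS", 24.0, 10),
        Genotype("per_long", 29.0, 10),
    ])
    days: float = 5.0
    bin_s: float = 10.0
    A_day: np.ndarray = field(default_factory=default_day_matrix)
    A_night: np.ndarray = field(default_factory=default_night_matrix)
    deep_peak_zt: float = 15.0
    p_quiet: float = 0.15
    p_active: float = 0.85
    move_median_px: float = 5.0
    move_sigma: float = 0.6
    rest_median_px: float = 0.005
    rest_sigma: float = 0.5
    deprivation_windows: list[tuple[float, float]] = field(default_factory=list)
    # sleep-pressure boost after each deprivation window: extra weight on
    # the night-like regime, decaying linearly over rebound_tau_h
    rebound_boost: float = 0.5
    rebound_tau_h: float = 6.0
    arena_w: float = 200.0
    arena_h: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        spec = default_hmm_spec()
        for name, A in (("A_day", self.A_day), ("A_night", self.A_night)):
            A = np.asarray(A, dtype=float)
            if A.shape != (4, 4) or np.any(A < 0):
                raise ValueError(f"{name} must be a non-negative 4x4 matrix")
            if not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if np.any(A[~spec.trans_mask] != 0.0):
                raise ValueError(f"{name} violates the structural zeros")
        if not 0 <= self.p_quiet < self.p_active <= 1:
            raise ValueError("need 0 <= p_quiet < p_active <= 1")
        if self.bin_s <= 0 or self.days <= 0:
            raise ValueError("bin_s and days must be positive")


@dataclass
class SimOutput:
    """Simulated population with its ground truth.

    ``behav`` carries id, t, x, y, displacement and moving; the
    ``true_states`` frame aligns 1:1 with the emitted bins.
    """

    behav: BehavTable
    true_states: pd.DataFrame     # (id, t, state) — ground-truth labels
    true_periods: dict[str, float]  # genotype -> period_h
    deep_peak_zt: float
    config: SimConfig


def _emission_probs(cfg: SimConfig) -> np.ndarray:
    return np.array([0.0, 0.0, cfg.p_quiet, cfg.p_active])


def simulate_population(cfg: SimConfig | None = None) -> SimOutput:
    """Sample a population of flies under the configured conditions.

    Deterministic for a fixed ``cfg.seed``.  Per fly, the state chain is
    sampled with the time-varying mixture A(t), movement from the
    state's emission probability (forced to moving/active inside
    deprivation windows), displacement from the state-appropriate
    log-normal, and x/y from a reflected random walk.
    """
    if cfg is None:
        cfg = SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_bins = int(round(cfg.days * SECONDS_PER_DAY / cfg.bin_s))
    t = cfg.bin_s * np.arange(n_bins)
    hours = t / 3600.0
    p_move_by_state = _emission_probs(cfg)

    depriv = np.zeros(n_bins, dtype=bool)
    boost = np.zeros(n_bins)
    for start, end in cfg.deprivation_windows:
        depriv |= (t >= start) & (t < end)
        if cfg.rebound_boost > 0:
            since = (t - end) / 3600.0
            boost += cfg.rebound_boost * np.clip(
                1.0 - since / cfg.rebound_tau_h, 0.0, 1.0) * (since >= 0)

    data_frames, meta_rows, state_frames = [], [], []
    true_periods = {}
    for g in cfg.genotypes:
        true_periods[g.name] = g.period_h
        n = g.n_flies
        w = 0.5 * (1.0 + np.cos(2 * np.pi * (hours - cfg.deep_peak_zt)
                                / g.period_h))
        w = np.clip(w + boost, 0.0, 1.0)
        states = np.empty((n, n_bins), dtype=np.int8)
        # burn-in draw: a uniform state pushed through the first bin's matrix
        states[:, 0] = rng.integers(0, 4, size=n)
        A0 = (1 - w[0]) * cfg.A_day + w[0] * cfg.A_night
        states[:, 0] = _sample_rows(A0[states[:, 0]], rng)
        if depriv[0]:
            states[:, 0] = _ACTIVE
        for k in range(1, n_bins):
            if depriv[k]:
                states[:, k] = _ACTIVE
                continue
            Ak = (1 - w[k]) * cfg.A_day + w[k] * cfg.A_night
            states[:, k] = _sample_rows(Ak[states[:, k - 1]], rng)

        p_move = p_move_by_state[states]
        moving = (rng.random((n, n_bins)) < p_move).astype(float)
        moving[:, depriv] = 1.0

        log_disp = np.where(
            moving > 0,
            rng.normal(np.log(cfg.move_median_px), cfg.move_sigma, (n, n_bins)),
            rng.normal(np.log(cfg.rest_median_px), cfg.rest_sigma, (n, n_bins)),
        )
        disp = np.exp(log_disp)

        angle = rng.uniform(0, 2 * np.pi, (n, n_bins))
        x = _reflected_walk(disp * np.cos(angle), cfg.arena_w, rng)
        y = _reflected_walk(disp * np.sin(angle), cfg.arena_h, rng)

        for i in range(n):
            sid = f"sim|{g.name}|{i + 1:02d}"
            meta_rows.append({"id": sid, "genotype": g.name,
                              "period_h": g.period_h, "region_id": i + 1,
                              "machine_name": "SIMULATOR"})
            data_frames.append(pd.DataFrame({
                "id": sid, "t": t, "x": x[i], "y": y[i],
                "displacement": disp[i], "moving": moving[i],
            }))
            state_frames.append(pd.DataFrame({
                "id": sid, "t": t,
                "state": np.array(STATE_LABELS)[states[i]],
            }))

    behav = BehavTable(pd.concat(data_frames, ignore_index=True),
                       pd.DataFrame(meta_rows))
    true_states = pd.concat(state_frames, ignore_index=True)
    return SimOutput(behav=behav, true_states=true_states,
                     true_periods=true_periods,
                     deep_peak_zt=cfg.deep_peak_zt, config=cfg)


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one categorical draw per row of a (n, k) probability array."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(len(prob_rows))[:, None]
    return (u > cum[:, :-1]).sum(axis=1).astype(np.int8)


def _reflected_walk(steps: np.ndarray, limit: float,
                    rng: np.random.Generator) -> np.ndarray:
    pos = np.cumsum(steps, axis=1) + rng.uniform(0, limit, (len(steps), 1))
    # reflect into [0, limit] (triangle-wave fold)
    period = 2 * limit
    pos = np.mod(pos, period)
    return np.where(pos > limit, period - pos, pos)


def ground_truth_occupancy(sim: SimOutput, bin_s: float = 1800.0,
                           group_by: str | None = None) -> pd.DataFrame:
    """State occupancy by zeitgeber time computed from the true states.

    Same shape as :func:`behavkit.hmm.state_occupancy` — the recovery
    target for decoded occupancy curves.
    """
    from .hmm import state_occupancy

    decoded_like = sim.true_states.rename(columns={"t": "t_bin"})
    return state_occupancy(decoded_like, sim.behav.meta, bin_s=bin_s,
                           group_by=group_by)
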