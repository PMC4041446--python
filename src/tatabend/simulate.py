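"""Synthetic single-molecule FRET data with fully specified ground truth.

The generator emulates the two experiment geometries of the TBP/TFB
promoter-bending assay:

* diffusing molecules in a confocal ALEX setup (photon streams with
  microsecond timestamps, 100 us excitation alternation, detection-class
  crosstalk and Poisson background), and
* surface-immobilized molecules on a TIRF camera (frame-integrated
  donor/acceptor intensities at 20-100 Hz with additive noise and
  single-step photobleaching),

plus equilibrium binding titrations and first-order complex-survival decay.
Conformational dynamics are a continuous-time Markov chain: a two-state
unbent/bent chain for the archaeal TBPs, or a linear unbent/intermediate/
fully-bent chain (no direct unbent <-> fully-bent step) for the eukaryotic
TBP/TF(II)B system.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seed and config give bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    AA,
    ACCEPTOR,
    AD,
    DA,
    DD,
    DONOR,
    PhotonStream,
    Trace,
)

TWO_STATE = "two-state"
LINEAR_THREE_STATE = "linear-three-state"

DEFAULT_BACKGROUND = {"DD": 400.0, "AD": 300.0, "AA": 300.0, "DA": 0.0}


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimulationConfig:
    """Ground truth for the synthetic experiments.

    Parameters mirror the study conditions: state proximity ratios
    (e.g. 0.25/0.49 for unbent/bent SSV promoter DNA, 0.32/0.60/0.75 for the
    eukaryotic three-state system), exponential dwell means, 100 us laser
    alternation, camera integration at 20-100 Hz, leakage/direct-excitation
    crosstalk, donor-only / acceptor-only contaminant species and
    single-step photobleaching.
    """

    n_states: int = 2
    state_E: tuple = (0.25, 0.49)
    dwell_means: tuple = (19.2, 0.18)          # s, per state
    topology: str = TWO_STATE
    leakage: float = 0.0                        # donor photons seen in red channel
    direct_exc: float = 0.0                     # acceptor directly excited at 532 nm
    background_rates: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    alternation_period_us: int = 100
    frame_period_s: float = 0.02
    total_intensity: float = 1000.0             # photons/frame (camera)
    noise_sd: float = 0.0                       # additive counts noise per channel
    e_noise_sd: float | None = None             # alternative: target sd of E(t)
    bleach_mean_time_s: float | None = None     # per fluorophore, None = no bleach
    donor_only_frac: float = 0.0
    acceptor_only_frac: float = 0.0
    # confocal burst envelope (conventions; the experiment does not pin these)
    burst_duration_median_ms: float = 1.0
    burst_duration_log_sd: float = 0.5
    burst_rate_median_per_ms: float = 50.0
    burst_rate_log_sd: float = 0.3
    mean_interburst_s: float = 0.05
    s_dual: float = 0.5                         # stoichiometry of dual-label species
    middle_branch_prob: float = 0.5             # P(2 -> 3) for the linear chain
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_states not in (1, 2, 3):
            raise InvalidConfigError("n_states must be 1, 2 or 3")
        if len(self.state_E) != self.n_states or len(self.dwell_means) != self.n_states:
            raise InvalidConfigError("state_E/dwell_means length must equal n_states")
        if not all(0.0 <= e <= 1.0 for e in self.state_E):
            raise InvalidConfigError("state_E values must lie in [0, 1]")
        if not all(t > 0 for t in self.dwell_means):
            raise InvalidConfigError("dwell means must be positive")
        if self.topology not in (TWO_STATE, LINEAR_THREE_STATE):
            raise InvalidConfigError(f"unknown topology {self.topology!r}")
        if self.topology == LINEAR_THREE_STATE and self.n_states != 3:
            raise InvalidConfigError("linear-three-state topology needs n_states=3")
        for name in ("leakage", "direct_exc", "donor_only_frac", "acceptor_only_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.donor_only_frac + self.acceptor_only_frac > 1.0:
            raise InvalidConfigError("contaminant fractions must sum to <= 1")
        if any(r < 0 for r in self.background_rates.values()):
            raise InvalidConfigError("background rates must be non-negative")
        if self.frame_period_s <= 0 or self.alternation_period_us <= 0:
            raise InvalidConfigError("frame and alternation periods must be positive")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def exit_rates(config: SimulationConfig) -> np.ndarray:
    """Per-state exit rate 1/tau (an infinite dwell mean gives rate 0)."""
    return np.array([0.0 if math.isinf(t) else 1.0 / t for t in config.dwell_means])


def transition_probs(config: SimulationConfig) -> np.ndarray:
    """Embedded-chain jump probabilities P(next state | leaving state i)."""
    k = config.n_states
    P = np.zeros((k, k))
    if k == 1:
        return P
    if config.topology == TWO_STATE or k == 2:
        P[0, 1] = P[1, 0] = 1.0
        return P
    # linear chain: terminal states jump to the middle, the middle branches
    P[0, 1] = 1.0
    P[2, 1] = 1.0
    P[1, 2] = config.middle_branch_prob
    P[1, 0] = 1.0 - config.middle_branch_prob
    return P


def stationary_distribution(config: SimulationConfig) -> np.ndarray:
    """Time-averaged state occupancy of the configured chain (analytic)."""
    rates = exit_rates(config)
    if np.any(rates == 0):
        pi = (rates == 0).astype(float)
        return pi / pi.sum()
    P = transition_probs(config)
    Q = P * rates[:, None]
    np.fill_diagonal(Q, -rates)
    # stationary: pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(config.n_states)])
    b = np.zeros(config.n_states + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def simulate_ctmc_path(config: SimulationConfig, duration_s: float, rng_seed=None):
    """Simulate one continuous-time state path covering [0, duration].

    Returns a list of ``(state, t_entry, t_exit)`` tuples with exponential
    dwells at the configured means.  For the linear three-state topology the
    event sequence contains no direct unbent <-> fully-bent steps by
    construction.  The initial state is drawn from the stationary occupancy
    so that finite paths are unbiased samples of the equilibrium.
    """
    if duration_s <= 0:
        raise InvalidConfigError("duration must be positive")
    rng = _rng(config.seed if rng_seed is None else rng_seed)
    rates = exit_rates(config)
    P = transition_probs(config)
    pi = stationary_distribution(config)
    state = int(rng.choice(config.n_states, p=pi))
    t = 0.0
    path = []
    while t < duration_s:
        rate = rates[state]
        dwell = math.inf if rate == 0 else rng.exponential(1.0 / rate)
        t_exit = min(t + dwell, duration_s)
        path.append((state, t, t_exit))
        t = t_exit
        if t >= duration_s:
            break
        state = int(rng.choice(config.n_states, p=P[state]))
    return path


def _frame_averaged_E(path, config: SimulationConfig, n_frames: int) -> np.ndarray:
    """Dwell-time-weighted average of state_E per camera frame."""
    dt = config.frame_period_s
    bounds = np.arange(n_frames + 1) * dt
    # cumulative integral of E(t) at the segment grid
    seg_start = np.array([s[1] for s in path])
    seg_end = np.array([s[2] for s in path])
    seg_E = np.array([config.state_E[s[0]] for s in path])
    cum = np.concatenate([[0.0], np.cumsum(seg_E * (seg_end - seg_start))])

    def integral(ts):
        idx = np.clip(np.searchsorted(seg_end, ts, side="left"), 0, len(path) - 1)
        frac = np.clip(ts - seg_start[idx], 0.0, seg_end[idx] - seg_start[idx])
        return cum[idx] + seg_E[idx] * frac

    F = integral(bounds)
    return np.diff(F) / dt


def simulate_camera_trace(path, config: SimulationConfig, rng_seed=None,
                          trace_id: str = "trace0") -> Trace:
    """Frame-integrate a state path into a TIRF donor/acceptor trace.

    Per frame the emitted E is the dwell-time-weighted average of the state
    proximity ratios over that frame; the acceptor channel picks up donor
    leakage and direct acceptor excitation when configured; additive
    Gaussian camera noise is applied per channel.  When a bleach mean time
    is set, acceptor and donor bleach independently at exponential times:
    after the acceptor bleach the acceptor signal falls to background and
    the donor rises to the full intensity, after the donor bleach both
    channels fall to background.
    """
    duration = path[-1][2]
    n_frames = int(math.floor(duration / config.frame_period_s + 1e-9))
    if n_frames < 1:
        raise InvalidConfigError("path shorter than one camera frame")
    rng = _rng(config.seed if rng_seed is None else rng_seed)
    e_app = _frame_averaged_E(path, config, n_frames)

    total = config.total_intensity
    i_a_true = total * e_app
    i_d_true = total * (1.0 - e_app)

    # single-step photobleaching, per fluorophore
    t_frame = (np.arange(n_frames) + 0.5) * config.frame_period_s
    bleach_meta = {}
    if config.bleach_mean_time_s is not None:
        t_bleach_a = rng.exponential(config.bleach_mean_time_s)
        t_bleach_d = rng.exponential(config.bleach_mean_time_s)
        bleach_meta = {"t_bleach_acceptor_s": t_bleach_a,
                       "t_bleach_donor_s": t_bleach_d}
        a_dead = t_frame >= t_bleach_a
        d_dead = t_frame >= t_bleach_d
        i_a_true = np.where(a_dead, 0.0, i_a_true)
        i_d_true = np.where(a_dead, total, i_d_true)  # no FRET -> full donor
        i_a_true = np.where(d_dead, 0.0, i_a_true)
        i_d_true = np.where(d_dead, 0.0, i_d_true)
        alive_a = ~a_dead & ~d_dead
    else:
        alive_a = np.ones(n_frames, dtype=bool)

    i_a = i_a_true + config.leakage * i_d_true \
        + config.direct_exc * total * alive_a
    i_d = i_d_true.copy()

    if config.e_noise_sd is not None:
        # per-channel counts noise chosen so that sd(E) ~= e_noise_sd:
        # Var(E) ~ sigma^2 ((1-E)^2 + E^2) / N^2 for additive channel noise
        e_frac = np.where(i_a + i_d > 0, i_a / np.maximum(i_a + i_d, 1e-12), 0.0)
        sigma = config.e_noise_sd * total / np.sqrt((1 - e_frac) ** 2 + e_frac ** 2)
    else:
        sigma = config.noise_sd
    if np.any(np.asarray(sigma) > 0):
        i_a = i_a + rng.normal(0.0, 1.0, n_frames) * sigma
        i_d = i_d + rng.normal(0.0, 1.0, n_frames) * sigma

    return Trace(trace_id=trace_id, frame_period_s=config.frame_period_s,
                 donor=i_d, acceptor=i_a, meta=bleach_meta)


def simulate_traces(config: SimulationConfig, n_traces: int, duration_s: float,
                    rng_seed=None):
    """Generate ``n_traces`` independent state paths and camera traces.

    Returns ``(traces, paths)`` where ``paths`` holds the ground-truth
    ``(state, t_entry, t_exit)`` segments for each trace.
    """
    rng = _rng(config.seed if rng_seed is None else rng_seed)
    traces, paths = [], []
    for i in range(n_traces):
        path = simulate_ctmc_path(config, duration_s, rng)
        trace = simulate_camera_trace(path, config, rng, trace_id=f"trace{i:04d}")
        traces.append(trace)
        paths.append(path)
    return traces, paths


def _background_photons(rate, duration_s, period_us, slot, rng):
    """Poisson background for one detection class, confined to its slot."""
    n = rng.poisson(rate * duration_s)
    half = period_us / 2.0
    n_periods = int(duration_s * 1e6 // period_us)
    if n == 0 or n_periods == 0:
        return np.empty(0)
    k = rng.integers(0, n_periods, n)
    offset = rng.uniform(0.0, half, n) + (half if slot == 1 else 0.0)
    return k * float(period_us) + offset


def simulate_photon_stream(config: SimulationConfig, n_bursts: int,
                           rng_seed=None, duration_s: float | None = None) -> PhotonStream:
    """Simulate a confocal ALEX photon stream.

    The stream is Poisson background plus ``n_bursts`` diffusion-burst
    envelopes with lognormal duration (median 1 ms) and lognormal peak rate
    (median 50 photons/ms).  Each burst is a single molecule whose
    conformational state is drawn from the stationary occupancy of the
    configured chain; detection classes follow the species' E, S, leakage
    and direct excitation, and every photon falls inside its excitation
    half-period.  Timestamps are strictly increasing integer microseconds.
    """
    if n_bursts < 0:
        raise InvalidConfigError("n_bursts must be >= 0")
    rng = _rng(config.seed if rng_seed is None else rng_seed)
    if duration_s is None:
        duration_s = max(1.0, n_bursts * config.mean_interburst_s)
    period = config.alternation_period_us
    half = period / 2.0

    times, channels = [], []

    # --- background, per detection class -----------------------------------
    for cls, slot, chan in (("DD", 0, DONOR), ("AD", 0, ACCEPTOR),
                            ("AA", 1, ACCEPTOR), ("DA", 1, DONOR)):
        rate = config.background_rates.get(cls, 0.0)
        t = _background_photons(rate, duration_s, period, slot, rng)
        times.append(t)
        channels.append(np.full(t.size, chan, dtype=np.int8))

    # --- bursts -------------------------------------------------------------
    pi = stationary_distribution(config)
    p_dual = 1.0 - config.donor_only_frac - config.acceptor_only_frac
    species = rng.choice(3, size=n_bursts,
                         p=[p_dual, config.donor_only_frac, config.acceptor_only_frac])
    for sp in species:
        dur_ms = rng.lognormal(math.log(config.burst_duration_median_ms),
                               config.burst_duration_log_sd)
        rate_ms = rng.lognormal(math.log(config.burst_rate_median_per_ms),
                                config.burst_rate_log_sd)
        dur_us = dur_ms * 1e3
        t0 = rng.uniform(0.0, max(duration_s * 1e6 - dur_us, 1.0))
        if sp == 0:       # dual-labelled molecule in one conformational state
            state = int(rng.choice(config.n_states, p=pi))
            e_true, s = config.state_E[state], config.s_dual
        elif sp == 1:     # donor-only contaminant
            e_true, s = 0.0, 1.0
        else:             # acceptor-only contaminant
            e_true, s = 0.0, 0.0
        e_app = min(1.0, e_true + config.leakage * (1.0 - e_true) + config.direct_exc)

        # thinning: donor half-periods emit at 2*rate*S, acceptor halves at
        # 2*rate*(1-S), so the burst-average rate is `rate_ms` and the
        # stoichiometry of detected photons is S
        r_max = 2.0 * rate_ms * max(s, 1.0 - s)
        n_cand = rng.poisson(r_max * dur_ms)
        if n_cand == 0:
            continue
        t_cand = t0 + rng.uniform(0.0, dur_us, n_cand)
        in_donor_half = (t_cand % period) < half
        p_keep = np.where(in_donor_half, 2.0 * rate_ms * s / r_max,
                          2.0 * rate_ms * (1.0 - s) / r_max)
        keep = rng.uniform(size=n_cand) < p_keep
        t_burst = t_cand[keep]
        donor_half = in_donor_half[keep]
        chan = np.empty(t_burst.size, dtype=np.int8)
        # donor-excitation photons split DD/AD by the apparent E
        is_ad = rng.uniform(size=t_burst.size) < e_app
        chan[donor_half] = np.where(is_ad[donor_half], ACCEPTOR, DONOR)
        chan[~donor_half] = ACCEPTOR  # acceptor excitation -> AA
        times.append(t_burst)
        channels.append(chan)

    t_all = np.concatenate(times)
    ch_all = np.concatenate(channels)
    order = np.argsort(t_all, kind="stable")
    t_all, ch_all = t_all[order], ch_all[order]
    ts = np.floor(t_all).astype(np.int64)
    if ts.size:
        # enforce strictly increasing integer clocks without dropping photons
        idx = np.arange(ts.size, dtype=np.int64)
        ts = np.maximum.accumulate(ts - idx) + idx
    slot = ((ts % period) < half).astype(np.int8)
    slot = np.where(slot == 1, 0, 1).astype(np.int8)  # first half = donor exc
    return PhotonStream(timestamps_us=ts, channel=ch_all,
                        excitation_slot=slot,
                        alternation_period_us=period, duration_s=duration_s,
                        background_rates=dict(config.background_rates))


@dataclass
class TitrationCurve:
    """Bent-DNA fraction versus protein concentration (pseudo-first-order)."""

    concentrations_nM: np.ndarray
    fraction_bent: np.ndarray
    n_per_point: int | None = None
    kd_true_nM: float | None = None

    def __post_init__(self):
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.fraction_bent = np.asarray(self.fraction_bent, dtype=float)


@dataclass
class SurvivalSeries:
    """Surviving complex fraction at the sampled chase times."""

    times_s: np.ndarray
    surviving_fraction: np.ndarray
    n_molecules: int | None = None
    lifetime_true_s: float | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)


def simulate_titration(kd_nM: float, concentrations_nM, n_per_point: int,
                       rng_seed=None) -> TitrationCurve:
    """Binomial sampling of a Langmuir isotherm f = c/(c + Kd).

    Protein is assumed in large excess over the 10 pM DNA, so free protein
    equals total protein.  ``n_per_point=None`` gives the noiseless isotherm.
    """
    if kd_nM <= 0:
        raise InvalidConfigError("Kd must be positive")
    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc < 0):
        raise InvalidConfigError("concentrations must be non-negative")
    f_true = conc / (conc + kd_nM)
    if n_per_point is None:
        frac = f_true
    else:
        rng = _rng(rng_seed)
        frac = rng.binomial(n_per_point, f_true) / n_per_point
    return TitrationCurve(conc, frac, n_per_point=n_per_point, kd_true_nM=kd_nM)


def simulate_survival(lifetime_s: float, sample_times_s, n_molecules: int | None,
                      rng_seed=None) -> SurvivalSeries:
    """Binomial sampling of first-order complex decay exp(-t/lifetime).

    ``n_molecules=None`` is the noiseless (infinite-sample) mode.
    """
    if lifetime_s <= 0:
        raise InvalidConfigError("lifetime must be positive")
    t = np.asarray(sample_times_s, dtype=float)
    p = np.exp(-t / lifetime_s)
    if n_molecules is None:
        frac = p
    else:
        rng = _rng(rng_seed)
        frac = rng.binomial(n_molecules, p) / n_molecules
    return SurvivalSeries(t, frac, n_molecules=n_molecules,
                          lifetime_true_s=lifetime_s)
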