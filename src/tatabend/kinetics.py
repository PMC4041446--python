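"""Dwell-time, transition-rate, binding and survival kinetics.

Mean dwell times come from mono-exponential fits of the per-state dwell
distributions (MLE or histogram least squares).  Transition rates under a
declared topology follow the count-based branching estimator

    k_ij = (n_ij / sum_j n_ij) / tau_i

so a state with a single exit has k = 1/tau exactly, and the middle state
of the linear three-state chain splits its exit rate by the observed
branching fractions (k_21 + k_23 = 1/tau_2).  Equilibrium binding
titrations are fitted with the pseudo-first-order Langmuir isotherm
f = c/(c + Kd), and complex survival with a mono-exponential decay.
Reported values are rounded the way the field prints them (rates to one
decimal, temperature factors to the nearest integer); full precision is
always retained on the fit objects.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import SurvivalSeries, TitrationCurve

TOPOLOGIES = {
    "two-state": [(0, 1), (1, 0)],
    "linear-three-state": [(0, 1), (1, 0), (1, 2), (2, 1)],
}


@dataclass
class DwellFit:
    """Mono-exponential dwell-time fit for one state."""

    state: int
    tau_s: float
    se_s: float
    method: str
    n_dwells: int


def fit_exponential(dwells_s, method: str = "mle", bin_width_s: float | None = None,
                    drop_first_bin: bool = True, truncate_below_s: float | None = None,
                    state: int = -1, min_dwells: int = 10) -> DwellFit:
    """Fit a mono-exponential decay to a sample of dwell durations.

    ``mle``: tau is the sample mean with SE tau/sqrt(n) (the exponential
    maximum-likelihood estimate).  ``histogram``: least-squares fit of
    A*exp(-t/tau) to binned counts, with the first bin dropped by default
    as a guard against missed short events at the camera resolution.

    ``truncate_below_s`` applies the same missed-event guard to the MLE:
    idealized camera traces cannot resolve dwells shorter than about two
    frames, so the sample is left-truncated at that reliability limit and
    tau is the maximum-likelihood estimate of the truncated exponential,
    ``mean(d | d >= c) - c`` (memorylessness makes this exact when the
    retained dwells are completely observed).
    """
    d = np.asarray(dwells_s, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    if d.size < min_dwells:
        raise ValueError(f"need >= {min_dwells} uncensored dwells, got {d.size}")
    if method == "mle":
        c = 0.0 if truncate_below_s is None else float(truncate_below_s)
        if c > 0:
            d = d[d >= c - 1e-12]
            if d.size < min_dwells:
                raise ValueError(
                    f"only {d.size} dwells remain above the {c} s truncation")
        tau = float(d.mean() - c)
        se = tau / np.sqrt(d.size)
    elif method == "histogram":
        if bin_width_s is None:
            bin_width_s = float(np.median(d)) / 2 if d.size else 1.0
        edges = np.arange(0.0, d.max() + 2 * bin_width_s, bin_width_s)
        counts, _ = np.histogram(d, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        if drop_first_bin:
            counts, centers = counts[1:], centers[1:]
        keep = counts > 0
        if keep.sum() < 3:
            raise ValueError("too few populated histogram bins for a fit")
        p0 = (counts[keep].max(), max(float(d.mean()), bin_width_s))
        popt, pcov = curve_fit(lambda t, a, tau: a * np.exp(-t / tau),
                               centers[keep], counts[keep], p0=p0, maxfev=10000)
        tau = float(popt[1])
        se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    else:
        raise ValueError("method must be 'mle' or 'histogram'")
    return DwellFit(state=state, tau_s=tau, se_s=se, method=method, n_dwells=d.size)


def fit_dwells(dwell_table: pd.DataFrame, method: str = "mle",
               include_censored: bool = False, **kw) -> dict[int, DwellFit]:
    """Per-state exponential fits from an extract_dwells table."""
    df = dwell_table if include_censored else dwell_table[~dwell_table["censored"]]
    return {int(s): fit_exponential(g["duration_s"], method=method, state=int(s), **kw)
            for s, g in df.groupby("state")}


@dataclass
class TransitionStats:
    """Counts and relative frequencies of decoded state-to-state steps."""

    counts: np.ndarray                 # n_ij, zero diagonal
    time_in_state_s: np.ndarray

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


def transition_frequencies(paths, n_states: int | None = None) -> TransitionStats:
    """Tally i -> j steps and per-state residence time across decoded paths."""
    if n_states is None:
        n_states = 1 + max((int(p.states.max()) for p in paths if len(p)), default=0)
    counts = np.zeros((n_states, n_states), dtype=int)
    time_in = np.zeros(n_states)
    for p in paths:
        s = p.states
        if s.size == 0:
            continue
        frm, to = s[:-1], s[1:]
        step = frm != to
        np.add.at(counts, (frm[step], to[step]), 1)
        dt = p.frame_period_s if np.isfinite(p.frame_period_s) else 0.0
        np.add.at(time_in, s, dt)
    return TransitionStats(counts=counts, time_in_state_s=time_in)


@dataclass
class RateMatrix:
    """Transition rates k_ij (1/s) for the allowed topology edges."""

    topology: str
    rates: dict = field(default_factory=dict)   # (i, j) -> k in 1/s

    def rounded(self, ndigits: int = 1) -> dict:
        return {ij: round(k, ndigits) for ij, k in self.rates.items()}

    def __getitem__(self, ij):
        return self.rates[ij]


def derive_rates(dwell_fits: dict[int, DwellFit], transition_stats: TransitionStats,
                 topology: str, forbidden_tol: float = 0.05) -> RateMatrix:
    """Transition rates from dwell times and branching fractions.

    For each state i, k_ij = branching_fraction(i -> j) / tau_i with the
    branching fractions taken from the transition counts over the allowed
    edges; single-exit states reduce to k = 1/tau.  Transitions forbidden
    by the topology with more than ``forbidden_tol`` of all counts raise a
    warning (at adequate frame rates they are resolution artifacts).
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    allowed = TOPOLOGIES[topology]
    counts = transition_stats.counts
    total = counts.sum()
    if total > 0:
        forbidden = sum(counts[i, j] for i in range(counts.shape[0])
                        for j in range(counts.shape[1])
                        if i != j and (i, j) not in allowed)
        if forbidden / total > forbidden_tol:
            warnings.warn(
                f"{forbidden}/{total} transitions are forbidden by the "
                f"{topology} topology (above tolerance {forbidden_tol})")
    rates = {}
    for i, fit in dwell_fits.items():
        exits = [(a, b) for a, b in allowed if a == i]
        if not exits:
            continue
        if len(exits) == 1:
            fracs = {exits[0]: 1.0}
        else:
            n_exit = np.array([counts[a, b] for a, b in exits], dtype=float)
            if n_exit.sum() == 0:
                fracs = {e: 1.0 / len(exits) for e in exits}
            else:
                fracs = {e: n / n_exit.sum() for e, n in zip(exits, n_exit)}
        for e, frac in fracs.items():
            rates[e] = frac / fit.tau_s
    return RateMatrix(topology=topology, rates=rates)


def temperature_factor(tau_low_T_s: float, tau_high_T_s: float):
    """Fold-change of a dwell time between temperatures.

    Returns ``(ratio, nearest_integer)`` as the field reports it
    (e.g. 19.2 s / 1.14 s -> 16.8, quoted as "~17").
    """
    if tau_low_T_s <= 0 or tau_high_T_s <= 0:
        raise ValueError("dwell times must be positive")
    ratio = tau_low_T_s / tau_high_T_s
    return ratio, int(round(ratio))


@dataclass
class SurvivalFit:
    """Mono-exponential complex-survival lifetime."""

    lifetime_s: float
    se_s: float
    amplitude: float = 1.0

    @property
    def lifetime_min(self) -> float:
        return self.lifetime_s / 60.0

    @property
    def se_min(self) -> float:
        return self.se_s / 60.0


def fit_survival(series: SurvivalSeries, free_amplitude: bool = False) -> SurvivalFit:
    """Least-squares fit of f(t) = exp(-t/lifetime) to a survival series."""
    t = series.times_s
    f = series.surviving_fraction
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    slope = np.polyfit(t, f, 1)[0]
    if slope >= 0:
        raise ValueError("survival series does not decay; nothing to fit")
    tau0 = max(t.max() / max(-np.log(max(f[-1], 1e-6)), 1e-6), t[1] - t[0])
    if free_amplitude:
        popt, pcov = curve_fit(lambda t, a, tau: a * np.exp(-t / tau), t, f,
                               p0=(1.0, tau0), maxfev=10000)
        amp, tau = popt
        se = float(np.sqrt(pcov[1, 1]))
    else:
        popt, pcov = curve_fit(lambda t, tau: np.exp(-t / tau), t, f,
                               p0=(tau0,), maxfev=10000)
        amp, tau = 1.0, popt[0]
        se = float(np.sqrt(pcov[0, 0]))
    return SurvivalFit(lifetime_s=float(tau), se_s=se, amplitude=float(amp))


@dataclass
class KdFit:
    """Langmuir-isotherm dissociation constant."""

    kd_nM: float
    se_nM: float

    def model(self, c):
        c = np.asarray(c, dtype=float)
        return c / (c + self.kd_nM)


def fit_kd(titration: TitrationCurve, weighted: bool = True) -> KdFit:
    """Weighted least-squares fit of the bent fraction f = c/(c + Kd).

    Weights are the binomial standard errors when the per-point molecule
    count is known, otherwise the fit is unweighted.  The free protein
    concentration is taken equal to the total (protein in large excess
    over the picomolar DNA).
    """
    c = titration.concentrations_nM
    f = titration.fraction_bent
    if c.size < 4:
        raise ValueError("need at least 4 concentrations")
    if np.all(f <= 0) or np.all(f >= 1):
        raise ValueError("titration is saturated or empty; Kd unidentifiable")
    sigma = None
    if weighted and titration.n_per_point:
        p = np.clip(f, 1.0 / titration.n_per_point, 1 - 1.0 / titration.n_per_point)
        sigma = np.sqrt(p * (1 - p) / titration.n_per_point)
    # midpoint-crossing initial guess
    kd0 = float(np.interp(0.5, np.clip(f, 0, 1), c)) if f.max() > 0.5 else float(c.max())
    kd0 = max(kd0, 1e-6)
    popt, pcov = curve_fit(lambda c, kd: c / (c + kd), c, f, p0=(kd0,),
                           sigma=sigma, absolute_sigma=sigma is not None,
                           bounds=(1e-12, np.inf), maxfev=10000)
    return KdFit(kd_nM=float(popt[0]), se_nM=float(np.sqrt(pcov[0, 0])))
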