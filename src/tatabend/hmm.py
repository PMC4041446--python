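"""TIRF trajectory analysis: correction, bleach truncation, HMM idealization.

The idealizer is a K-state hidden Markov model with Gaussian emissions on
the one-dimensional FRET time series E(t), fitted by expectation-
maximization (Baum-Welch) over all traces pooled, then decoded per trace
with the Viterbi algorithm.  K is fixed by the user: two states for the
archaeal TBPs, three for the eukaryotic TBP/TF(II)B complex.  Frames with
undefined E are treated as missing emissions and bridged by the transition
model, never as zeros.  Decoded paths are run-length encoded into dwells;
the first and last dwell of every trace are flagged as censored because
their true start or end was not observed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bursts import CorrectionFactors
from .containers import Trace


class DegenerateDataError(ValueError):
    """Raised when the pooled E values carry no variance to separate states."""


def correct_trace(donor_raw, acceptor_raw, background=(0.0, 0.0),
                  corrections: CorrectionFactors | None = None,
                  direct_exc_ref: float = 0.0,
                  frame_period_s: float = 0.02,
                  trace_id: str = "trace0") -> Trace:
    """Background-subtract and crosstalk-correct a raw intensity pair.

    ``background`` is a (donor, acceptor) pair of scalars or per-frame
    series.  The acceptor channel loses the donor leakage and the
    configured direct-excitation term:
    I_A <- I_A - bg_A - l*I_D - d*direct_exc_ref.
    """
    i_d = np.asarray(donor_raw, dtype=float)
    i_a = np.asarray(acceptor_raw, dtype=float)
    if i_d.shape != i_a.shape:
        raise ValueError("donor and acceptor series differ in length")
    bg_d, bg_a = background
    i_d = i_d - np.asarray(bg_d, dtype=float)
    i_a = i_a - np.asarray(bg_a, dtype=float)
    if corrections is not None:
        i_a = i_a - corrections.leakage * i_d - corrections.direct_exc * direct_exc_ref
    return Trace(trace_id=trace_id, frame_period_s=frame_period_s,
                 donor=i_d, acceptor=i_a)


def _rolling_median(x: np.ndarray, w: int) -> np.ndarray:
    if x.size < w:
        return np.full(x.size, np.median(x) if x.size else np.nan)
    return pd.Series(x).rolling(w, min_periods=1, center=False).median().to_numpy()


def detect_bleaching(trace: Trace, window: int = 5, drop_frac: float = 0.5,
                     rise_frac: float = 1.5) -> tuple[int, int]:
    """Find the single-step photobleach and truncate the analysable range.

    Two signatures end a trace: a drop of the total intensity I_D + I_A
    below ``drop_frac`` of its preceding running median (donor bleach, or
    acceptor bleach after donor loss), or an anticorrelated acceptor loss
    (acceptor falls below ``drop_frac`` of its local median while the donor
    rises above ``rise_frac`` of its own).  Traces without either signature
    keep their full range.  Sets and returns ``trace.valid_range``.
    """
    total = trace.donor + trace.acceptor
    n = total.size
    if n < 2 * window:
        return trace.valid_range

    def first_step(series, other=None):
        pre = _rolling_median(series, window)
        for i in range(window, n - 1):
            # the frame itself must drop and the drop must be sustained
            thresh = drop_frac * max(pre[i - 1], 1e-12)
            if series[i] >= thresh or np.median(series[i:i + window]) >= thresh:
                continue
            if other is None:
                return i
            pre_o, post_o = np.median(other[max(0, i - window):i]), \
                np.median(other[i:i + window])
            if post_o > rise_frac * max(pre_o, 1e-12):
                return i
        return None

    candidates = [c for c in (first_step(total),
                              first_step(trace.acceptor, other=trace.donor))
                  if c is not None]
    end = min(candidates) if candidates else n
    trace.valid_range = (0, end)
    return trace.valid_range


@dataclass
class HMMModel:
    """Gaussian-emission HMM on E(t); states sorted by mean ascending."""

    n_states: int
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray      # per-frame transition probabilities
    startprob: np.ndarray
    log_likelihood: float = np.nan
    history: list = field(default_factory=list)   # per-iteration log-likelihood
    converged: bool = False
    seed: int | None = None


@dataclass
class StatePath:
    """Decoded per-frame state labels for one trace."""

    trace_id: str
    states: np.ndarray
    frame_period_s: float

    def __len__(self):
        return self.states.size

    def runs(self):
        """Run-length encoding: list of (state, n_frames)."""
        s = self.states
        if s.size == 0:
            return []
        edges = np.flatnonzero(np.diff(s)) + 1
        bounds = np.concatenate([[0], edges, [s.size]])
        return [(int(s[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


def _as_e_arrays(traces):
    out = []
    for tr in traces:
        if isinstance(tr, Trace):
            out.append((tr.trace_id, np.asarray(tr.valid_efficiency(), dtype=float)))
        else:
            out.append((f"trace{len(out):04d}", np.asarray(tr, dtype=float)))
    return out


def _pack(e_arrays):
    lengths = np.array([e.size for _, e in e_arrays])
    T = int(lengths.max())
    N = len(e_arrays)
    x = np.full((N, T), np.nan)
    for n, (_, e) in enumerate(e_arrays):
        x[n, : e.size] = e
    inside = np.arange(T)[None, :] < lengths[:, None]
    observed = inside & np.isfinite(x)
    return x, lengths, inside, observed


def _emission_probs(x, observed, means, sds):
    # B[n, t, k]; missing or padded frames contribute probability 1
    z = (x[..., None] - means) / sds
    b = np.exp(-0.5 * z ** 2) / (math.sqrt(2 * math.pi) * sds)
    b = np.where(observed[..., None], b, 1.0)
    return np.maximum(b, 1e-300)


def _forward_backward(b, lengths, inside, A, pi):
    """Scaled forward-backward, vectorized over traces.

    Returns loglik, gamma0 (N,K), xi_sum (K,K) and the smoothed
    responsibilities gamma (N,T,K) (zeroed outside each sequence).
    """
    N, T, K = b.shape
    alpha = np.empty((N, T, K))
    c = np.empty((N, T))
    a = pi[None, :] * b[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * b[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    loglik = float(np.sum(np.log(c)[inside]))

    gamma = np.empty((N, T, K))
    beta = np.ones((N, K))
    gamma[:, T - 1] = alpha[:, T - 1]
    xi_sum = np.zeros((K, K))
    trans_ok = inside[:, 1:]  # transition t -> t+1 counted iff t+1 in sequence
    for t in range(T - 2, -1, -1):
        bb = b[:, t + 1] * beta                      # (N, K)
        xi = alpha[:, t, :, None] * A[None] * bb[:, None, :] / c[:, t + 1, None, None]
        xi_sum += xi[trans_ok[:, t]].sum(axis=0)
        beta = (bb @ A.T) / c[:, t + 1, None]
        gamma[:, t] = alpha[:, t] * beta
    gamma = np.where(inside[..., None], gamma, 0.0)
    return loglik, gamma, xi_sum


def fit_hmm(traces, K: int, init_strategy: str = "quantile",
            n_restarts: int = 10, max_iter: int = 100, tol: float = 1e-6,
            seed: int = 0, sd_floor: float = 1e-3) -> HMMModel:
    """Maximum-likelihood Gaussian-emission HMM over pooled traces.

    The EM log-likelihood is asserted non-decreasing at every iteration.
    Initialization places state means at evenly spaced quantiles of the
    pooled E values; the remaining restarts draw random means between the
    1st and 99th percentile and the best final likelihood is kept.  State
    labels are sorted by mean ascending before returning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    e_arrays = _as_e_arrays(traces)
    if not e_arrays or max(e.size for _, e in e_arrays) < 1:
        raise ValueError("need at least one trace with valid frames")
    x, lengths, inside, observed = _pack(e_arrays)
    pooled = x[observed]
    if pooled.size < 10:
        raise ValueError("need >= 10 valid frames in total")
    if K > 1 and np.std(pooled) == 0:
        raise DegenerateDataError(
            "pooled E values are constant; cannot separate more than one state")
    if init_strategy not in ("quantile", "random"):
        raise ValueError("init_strategy must be 'quantile' or 'random'")

    if K == 1:
        mu = np.array([pooled.mean()])
        sd = np.array([max(pooled.std(), sd_floor)])
        return HMMModel(1, mu, sd, np.ones((1, 1)), np.ones(1),
                        log_likelihood=float(
                            np.sum(np.log(_emission_probs(x, observed, mu, sd)[observed, 0]))),
                        converged=True, seed=seed)

    rng = np.random.default_rng(seed)
    p1, p99 = np.percentile(pooled, [1, 99])
    sd0 = max(np.std(pooled) / K, sd_floor)
    best = None
    for restart in range(max(1, n_restarts)):
        if restart == 0 and init_strategy == "quantile":
            mu = np.percentile(pooled, np.linspace(0, 100, K + 2)[1:-1])
        else:
            mu = np.sort(rng.uniform(p1, p99, K))
        mu = mu.astype(float).copy()
        sd = np.full(K, sd0)
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9)
        pi = np.full(K, 1.0 / K)

        prev = -np.inf
        history, converged = [], False
        for _ in range(max_iter):
            b = _emission_probs(x, observed, mu, sd)
            loglik, gamma, xi_sum = _forward_backward(b, lengths, inside, A, pi)
            assert loglik >= prev - 1e-6 * max(1.0, abs(prev)), \
                "EM log-likelihood decreased"
            history.append(loglik)
            if np.isfinite(prev) and abs(loglik - prev) < tol * max(1.0, abs(prev)):
                converged = True
                break
            prev = loglik
            # M-step
            g_obs = gamma * observed[..., None]
            denom = g_obs.sum(axis=(0, 1))
            denom = np.maximum(denom, 1e-12)
            mu = (g_obs * np.nan_to_num(x)[..., None]).sum(axis=(0, 1)) / denom
            var = (g_obs * (np.nan_to_num(x)[..., None] - mu) ** 2).sum(axis=(0, 1)) / denom
            sd = np.maximum(np.sqrt(var), sd_floor)
            A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-12)
            A = np.maximum(A, 1e-12)
            A /= A.sum(axis=1, keepdims=True)
            pi = gamma[:, 0].mean(axis=0)
            pi = np.maximum(pi, 1e-12)
            pi /= pi.sum()
        if best is None or loglik > best.log_likelihood:
            order = np.argsort(mu)
            best = HMMModel(K, mu[order], sd[order], A[np.ix_(order, order)],
                            pi[order], log_likelihood=loglik, history=history,
                            converged=converged, seed=seed)
    return best


def viterbi_path(model: HMMModel, trace) -> StatePath:
    """Most probable state sequence for one trace (deterministic).

    Frames with undefined E contribute no emission term and are bridged by
    the transition model.  Ties are broken toward the lower-index (lower
    mean) state.
    """
    if isinstance(trace, Trace):
        e = trace.valid_efficiency()
        trace_id, dt = trace.trace_id, trace.frame_period_s
    else:
        e = np.asarray(trace, dtype=float)
        trace_id, dt = "trace", np.nan
    T, K = e.size, model.n_states
    if T == 0:
        return StatePath(trace_id, np.empty(0, dtype=int), dt)
    obs = np.isfinite(e)
    z = (np.nan_to_num(e)[:, None] - model.means) / model.sds
    logb = -0.5 * z ** 2 - np.log(model.sds) - 0.5 * math.log(2 * math.pi)
    logb = np.where(obs[:, None], logb, 0.0)
    logA = np.log(np.maximum(model.transmat, 1e-300))
    delta = np.log(np.maximum(model.startprob, 1e-300)) + logb[0]
    psi = np.zeros((T, K), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA           # (from, to)
        psi[t] = np.argmax(cand, axis=0)        # first max -> lower index wins
        delta = cand[psi[t], np.arange(K)] + logb[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1][states[t + 1]]
    return StatePath(trace_id, states, dt)


def decode(model: HMMModel, traces) -> list[StatePath]:
    """Viterbi-decode a batch of traces."""
    paths = []
    for i, tr in enumerate(traces):
        p = viterbi_path(model, tr)
        if not isinstance(tr, Trace):
            p.trace_id = f"trace{i:04d}"
        paths.append(p)
    return paths


def extract_dwells(paths, frame_period_s: float | None = None) -> pd.DataFrame:
    """Run-length dwells pooled across traces, with censoring flags.

    The first and last dwell of every trace are censored (their true entry
    or exit was not observed) and are excluded from exponential fitting by
    default downstream.  Durations are n_frames x frame_period.
    """
    rows = []
    for path in paths:
        dt = frame_period_s if frame_period_s is not None else path.frame_period_s
        runs = path.runs()
        for i, (state, n) in enumerate(runs):
            rows.append({
                "trace_id": path.trace_id,
                "state": state,
                "n_frames": n,
                "duration_s": n * dt,
                "censored": i == 0 or i == len(runs) - 1,
            })
    return pd.DataFrame(rows, columns=["trace_id", "state", "n_frames",
                                       "duration_s", "censored"])
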