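"""Confocal ALEX burst analysis: the diffusing-molecule pipeline.

Burst search on the pooled photon stream with the sliding-window (T, M, N)
criterion, class-wise background subtraction and optional leakage /
direct-excitation correction, proximity ratio E and stoichiometry S per
burst, kernel-density (2CDE-style) burst filtering, and Gaussian population
fitting of E histograms.  E and S are the standard uncorrected ALEX
quantities

    E = F_AD / (F_AD + F_DD)
    S = (F_AD + F_DD) / (F_AD + F_DD + F_AA)

computed from summed, background-corrected counts per burst.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .containers import AA, AD, DA, DD, PhotonStream


@dataclass
class BurstSearchParams:
    """Sliding-window burst criterion: >= M photons within a window of
    length T around a photon, for runs of >= N consecutive such photons.

    Defaults are the Cy3b/ATTO647n settings (T = 500 us, M = 30, N = 120);
    the ATTO532/ATTO647n variant uses (500, 10, 50).
    """

    T_us: int = 500
    M: int = 30
    N: int = 120
    window: str = "centered"  # or "start": window anchored at the photon

    def __post_init__(self):
        if self.T_us <= 0 or self.M <= 0 or self.N <= 0:
            raise ValueError("T, M and N must be positive")
        if self.M > self.N:
            raise ValueError("M must not exceed N")
        if self.window not in ("centered", "start"):
            raise ValueError("window must be 'centered' or 'start'")


@dataclass
class CorrectionFactors:
    """Leakage, direct excitation and per-class background rates."""

    leakage: float = 0.0
    direct_exc: float = 0.0
    background_rates: dict = field(default_factory=dict)  # photons/s per class

    def __post_init__(self):
        if not (0.0 <= self.leakage < 1.0 and 0.0 <= self.direct_exc < 1.0):
            raise ValueError("leakage and direct excitation must lie in [0, 1)")
        if any(v < 0 for v in self.background_rates.values()):
            raise ValueError("background rates must be non-negative")


@dataclass
class Burst:
    """A contiguous photon cluster with corrected counts and derived scores."""

    start_index: int
    stop_index: int          # inclusive
    start_us: int
    stop_us: int
    raw_counts: dict
    F_DD: float = np.nan
    F_AD: float = np.nan
    F_AA: float = np.nan
    E: float = np.nan
    S: float = np.nan
    alex_2cde: float = np.nan
    fret_2cde: float = np.nan
    flags: set = field(default_factory=set)

    @property
    def n_photons(self) -> int:
        return self.stop_index - self.start_index + 1

    @property
    def duration_s(self) -> float:
        return (self.stop_us - self.start_us) / 1e6


def classify_photons(stream: PhotonStream, alternation_period_us: int | None = None,
                     gates: tuple | None = None) -> PhotonStream:
    """Assign each photon its excitation slot from the alternation clock.

    The default gates put donor excitation in the first half-period and
    acceptor excitation in the second half, matching the 50/50 alternation
    duty cycle.  Photon counts are conserved; the combination with the
    detection channel yields the DD/AD/AA/DA class labels.
    """
    period = alternation_period_us or stream.alternation_period_us
    if gates is None:
        gates = (0, period // 2)
    lo, hi = gates
    phase = stream.timestamps_us % period
    slot = np.where((phase >= lo) & (phase < hi), 0, 1).astype(np.int8)
    stream.excitation_slot = slot
    return stream


def qualifying_photons(stream: PhotonStream, params: BurstSearchParams) -> np.ndarray:
    """Boolean mask: photon i has >= M photons within its length-T window."""
    ts = stream.timestamps_us
    if params.window == "centered":
        lo, hi = ts - params.T_us // 2, ts + params.T_us // 2
    else:
        lo, hi = ts, ts + params.T_us
    left = np.searchsorted(ts, lo, side="left")
    right = np.searchsorted(ts, hi, side="right")
    return (right - left) >= params.M


def search_bursts(stream: PhotonStream, params: BurstSearchParams) -> list[Burst]:
    """Sliding-window burst search on the pooled photon stream.

    A burst is a maximal run of at least N consecutive qualifying photons;
    bursts are disjoint and ordered.  All detection classes are pooled for
    the search, as in the experiment.
    """
    if len(stream) == 0:
        return []
    ok = qualifying_photons(stream, params)
    ts = stream.timestamps_us
    labels = stream.class_labels
    bursts = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
    for run_start, run_end in zip(edges[::2], edges[1::2]):
        run_len = run_end - run_start
        if run_len < params.N:
            continue
        sl = slice(run_start, run_end)
        raw = {name: int(np.sum(labels[sl] == code))
               for code, name in ((DD, "DD"), (AD, "AD"), (AA, "AA"), (DA, "DA"))}
        bursts.append(Burst(start_index=int(run_start), stop_index=int(run_end - 1),
                            start_us=int(ts[run_start]), stop_us=int(ts[run_end - 1]),
                            raw_counts=raw))
    return bursts


def correct_counts(burst: Burst, corrections: CorrectionFactors,
                   apply_crosstalk: bool = False) -> tuple[float, float, float]:
    """Background-subtract (and optionally crosstalk-correct) burst counts.

    Each class count is reduced by background_rate x burst duration and
    floored at zero.  With ``apply_crosstalk``, the apparent acceptor signal
    under donor excitation loses the donor leakage and direct-excitation
    contributions: F_AD <- F_AD - l*F_DD - d*F_AA, floored at zero.
    """
    dur = burst.duration_s
    bg = corrections.background_rates
    f = {}
    for cls in ("DD", "AD", "AA"):
        f[cls] = max(0.0, burst.raw_counts.get(cls, 0) - bg.get(cls, 0.0) * dur)
    if apply_crosstalk:
        f["AD"] = max(0.0, f["AD"] - corrections.leakage * f["DD"]
                      - corrections.direct_exc * f["AA"])
    burst.F_DD, burst.F_AD, burst.F_AA = f["DD"], f["AD"], f["AA"]
    burst.flags.add("corrected")
    return f["DD"], f["AD"], f["AA"]


def compute_es(F_DD: float, F_AD: float, F_AA: float) -> tuple[float, float]:
    """Proximity ratio and stoichiometry from corrected counts.

    Returns NaN for a ratio whose denominator is zero.
    """
    if min(F_DD, F_AD, F_AA) < 0:
        raise ValueError("corrected counts must be non-negative")
    dex = F_AD + F_DD
    total = dex + F_AA
    e = F_AD / dex if dex > 0 else np.nan
    s = dex / total if total > 0 else np.nan
    return e, s


def _kde_at(eval_times: np.ndarray, photon_times: np.ndarray, tau_us: float) -> np.ndarray:
    """Exponential-kernel photon density Sum_j exp(-|t - t_j|/tau)."""
    if photon_times.size == 0:
        return np.zeros(eval_times.size)
    d = np.abs(eval_times[:, None] - photon_times[None, :]) / tau_us
    return np.exp(-d).sum(axis=1)


def two_cde_scores(burst: Burst, stream: PhotonStream,
                   kde_time_constant_us: float = 100.0) -> tuple[float, float]:
    """Kernel-density burst-uniformity scores (ALEX-2CDE, FRET-2CDE).

    Both statistics compare exponential-kernel photon densities of two
    streams at each photon's arrival time, with the photon's own stream
    density taken self-excluded (nbKDE).  FRET-2CDE is
    ``110 - 100*[(E)_D + (1-E)_A]`` over the donor-excitation DD and AD
    photons, which sits near 10 for a burst with static FRET and moves out
    of that neighbourhood when E changes within the burst (acceptor
    blinking/bleaching).  ALEX-2CDE is ``|100 - 50*(BR_DexAex + BR_AexDex)|``
    with BR the opposite-stream/own-stream density ratio normalised by the
    opposite stream size: near zero for a dual-labelled molecule of
    balanced, constant brightness, and large for donor-only or
    acceptor-only bursts and for excitation-stream intensity dynamics.
    Scores are deterministic given the stream and the time constant.
    """
    tau = float(kde_time_constant_us)
    sl = slice(burst.start_index, burst.stop_index + 1)
    ts = stream.timestamps_us[sl].astype(float)
    labels = stream.class_labels[sl]
    slot = stream.excitation_slot[sl]

    t_dd = ts[labels == DD]
    t_ad = ts[labels == AD]
    t_dex = ts[slot == 0]
    t_aex = ts[slot == 1]

    # FRET-2CDE over donor-excitation photons
    if t_dd.size < 2 or t_ad.size < 2:
        fret_2cde = np.nan
        burst.flags.add("fret_2cde_undefined")
    else:
        kde_a_at_d = _kde_at(t_dd, t_ad, tau)
        nb_d = _kde_at(t_dd, t_dd, tau) - 1.0
        e_d = np.mean(kde_a_at_d / np.maximum(kde_a_at_d + nb_d, 1e-12))
        kde_d_at_a = _kde_at(t_ad, t_dd, tau)
        nb_a = _kde_at(t_ad, t_ad, tau) - 1.0
        one_minus_e_a = np.mean(kde_d_at_a / np.maximum(kde_d_at_a + nb_a, 1e-12))
        fret_2cde = 110.0 - 100.0 * (e_d + one_minus_e_a)

    # ALEX-2CDE over excitation streams
    if t_dex.size < 2 or t_aex.size < 2:
        alex_2cde = np.inf
        burst.flags.add("alex_2cde_undefined")
    else:
        br_da = np.mean(_kde_at(t_dex, t_aex, tau)
                        / np.maximum(_kde_at(t_dex, t_dex, tau) - 1.0, 1e-12))
        br_da *= t_dex.size / t_aex.size
        br_ad = np.mean(_kde_at(t_aex, t_dex, tau)
                        / np.maximum(_kde_at(t_aex, t_aex, tau) - 1.0, 1e-12))
        br_ad *= t_aex.size / t_dex.size
        alex_2cde = abs(100.0 - 50.0 * (br_da + br_ad))

    burst.alex_2cde = alex_2cde
    burst.fret_2cde = fret_2cde
    return alex_2cde, fret_2cde


@dataclass
class FilterThresholds:
    """Burst-selection thresholds; ``None`` disables a criterion."""

    alex_2cde_max: float | None = 12.0
    fret_2cde_min: float | None = None
    fret_2cde_max: float | None = None
    s_min: float | None = None
    s_max: float | None = None
    drop_undefined: bool = True


def filter_bursts(bursts: list[Burst], thresholds: FilterThresholds):
    """Apply the enabled thresholds; returns (kept, removed_per_criterion)."""
    kept, removed = [], {"alex_2cde": 0, "fret_2cde": 0, "s_range": 0, "undefined": 0}
    th = thresholds
    for b in bursts:
        if th.alex_2cde_max is not None:
            if math.isnan(b.alex_2cde):
                if th.drop_undefined:
                    removed["undefined"] += 1
                    continue
            elif b.alex_2cde > th.alex_2cde_max:
                removed["alex_2cde"] += 1
                b.flags.add("filtered")
                continue
        if th.fret_2cde_min is not None or th.fret_2cde_max is not None:
            if math.isnan(b.fret_2cde):
                if th.drop_undefined:
                    removed["undefined"] += 1
                    continue
            elif ((th.fret_2cde_min is not None and b.fret_2cde < th.fret_2cde_min)
                    or (th.fret_2cde_max is not None and b.fret_2cde > th.fret_2cde_max)):
                removed["fret_2cde"] += 1
                b.flags.add("filtered")
                continue
        if th.s_min is not None or th.s_max is not None:
            if math.isnan(b.S):
                if th.drop_undefined:
                    removed["undefined"] += 1
                    continue
            elif ((th.s_min is not None and b.S < th.s_min)
                    or (th.s_max is not None and b.S > th.s_max)):
                removed["s_range"] += 1
                b.flags.add("filtered")
                continue
        kept.append(b)
    return kept, removed


@dataclass
class PopulationFit:
    """Sum-of-Gaussians description of a burst E histogram."""

    components: list          # (mean, sd, weight), sorted by mean
    residual: float
    bin_width: float
    converged: bool = True

    @property
    def bent_fraction(self) -> float:
        """Weight of the highest-mean (most bent) component."""
        return self.components[-1][2]


def _gauss_sum(x, *p):
    y = np.zeros_like(x)
    for k in range(len(p) // 3):
        a, mu, sd = p[3 * k: 3 * k + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_populations(e_values, n_components: int, bin_width: float = 0.025,
                    hist_range: tuple = (-0.1, 1.1)) -> PopulationFit:
    """Least-squares fit of ``n_components`` Gaussians to the binned E histogram.

    Component weights are the normalised Gaussian areas; the bent fraction
    is the weight of the highest-mean component.
    """
    e = np.asarray(e_values, dtype=float)
    e = e[np.isfinite(e)]
    if e.size < 50:
        raise ValueError(f"need >= 50 E values to fit populations, got {e.size}")
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    edges = np.arange(hist_range[0], hist_range[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(e, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    qs = np.linspace(0, 100, n_components + 2)[1:-1]
    mu0 = np.percentile(e, qs)
    sd0 = max(np.std(e) / n_components, 0.02)
    a0 = counts.max() / n_components
    p0, lo, hi = [], [], []
    for mu in np.atleast_1d(mu0):
        p0 += [a0, float(mu), sd0]
        lo += [0.0, hist_range[0], 0.005]
        hi += [np.inf, hist_range[1], 0.5]
    converged = True
    try:
        popt, _ = curve_fit(_gauss_sum, centers, counts, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
    except RuntimeError:
        popt, converged = np.array(p0), False
    comps = sorted(
        ((popt[3 * k + 1], popt[3 * k + 2], popt[3 * k] * popt[3 * k + 2])
         for k in range(n_components)),
        key=lambda c: c[0])
    area = sum(c[2] for c in comps)
    comps = [(mu, sd, w / area if area > 0 else np.nan) for mu, sd, w in comps]
    residual = float(np.sum((counts - _gauss_sum(centers, *popt)) ** 2))
    return PopulationFit(components=comps, residual=residual,
                         bin_width=bin_width, converged=converged)


def analyze_stream(stream: PhotonStream, params: BurstSearchParams,
                   corrections: CorrectionFactors | None = None,
                   thresholds: FilterThresholds | None = None,
                   apply_crosstalk: bool = False,
                   kde_time_constant_us: float = 100.0) -> list[Burst]:
    """Full burst pipeline: classify, search, correct, score, filter.

    Background defaults to the stream's stored per-class rates when the
    corrections carry none.
    """
    if stream.excitation_slot is None:
        classify_photons(stream)
    corrections = corrections or CorrectionFactors()
    if not corrections.background_rates and stream.background_rates:
        corrections = CorrectionFactors(
            leakage=corrections.leakage, direct_exc=corrections.direct_exc,
            background_rates=dict(stream.background_rates))
    bursts = search_bursts(stream, params)
    for b in bursts:
        correct_counts(b, corrections, apply_crosstalk=apply_crosstalk)
        b.E, b.S = compute_es(b.F_DD, b.F_AD, b.F_AA)
        two_cde_scores(b, stream, kde_time_constant_us)
    if thresholds is not None:
        bursts, _ = filter_bursts(bursts, thresholds)
    return bursts
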