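"""ALEX burst analysis: search, corrections, E/S, 2CDE filters, populations."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tatabend as tb
from tatabend.bursts import (
    Burst,
    BurstSearchParams,
    CorrectionFactors,
    FilterThresholds,
    classify_photons,
    compute_es,
    correct_counts,
    filter_bursts,
    fit_populations,
    qualifying_photons,
    search_bursts,
    two_cde_scores,
)
from tatabend.containers import ACCEPTOR, DONOR, PhotonStream
from tatabend.simulate import SimulationConfig, simulate_photon_stream


def make_stream(timestamps, channels=None, period=100, duration=None):
    ts = np.asarray(timestamps, dtype=np.int64)
    ch = np.zeros(ts.size, dtype=np.int8) if channels is None \
        else np.asarray(channels, dtype=np.int8)
    stream = PhotonStream(timestamps_us=ts, channel=ch,
                          alternation_period_us=period,
                          duration_s=duration or (ts[-1] / 1e6 if ts.size else 0.0))
    return classify_photons(stream)


def brute_force_bursts(ts, params):
    """O(n^2) oracle for the sliding-window (T, M, N) criterion."""
    ts = np.asarray(ts, dtype=np.int64)
    half = params.T_us // 2
    ok = np.array([np.sum((ts >= t - half) & (ts <= t + half)) >= params.M
                   for t in ts])
    runs = []
    i = 0
    while i < ts.size:
        if ok[i]:
            j = i
            while j + 1 < ts.size and ok[j + 1]:
                j += 1
            if j - i + 1 >= params.N:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


class TestClassify:
    def test_gate_convention_first_half_is_donor_excitation(self):
        # acceptor-channel photon at phase 30 -> AD; at phase 80 -> AA
        stream = make_stream([30, 80], channels=[ACCEPTOR, ACCEPTOR])
        labels = stream.class_labels
        assert labels[0] == 1  # AD
        assert labels[1] == 2  # AA

    def test_counts_conserved(self, rng):
        ts = np.sort(rng.choice(100_000, size=500, replace=False))
        ch = rng.integers(0, 2, 500)
        stream = make_stream(ts, ch)
        assert sum(stream.class_counts().values()) == 500

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PhotonStream(timestamps_us=np.array([10, 5]),
                         channel=np.array([0, 0]),
                         alternation_period_us=100, duration_s=1.0)


class TestBurstSearch:
    def test_uniform_low_rate_yields_no_bursts(self):
        # 10 photons/ms: expected 5 photons per 500 us window, far below M=30
        ts = np.arange(0, 1_000_000, 100)
        stream = make_stream(ts)
        assert search_bursts(stream, BurstSearchParams(500, 30, 120)) == []

    def test_dense_run_in_sparse_background(self):
        """200 photons at 100/ms flanked by 1/ms background: one burst."""
        bg_before = np.arange(0, 50_000, 1000)
        dense = 50_000 + np.arange(200) * 10
        bg_after = 52_500 + np.arange(1000, 50_000, 1000)
        ts = np.concatenate([bg_before, dense, bg_after])
        stream = make_stream(ts)
        params = BurstSearchParams(500, 30, 120)
        bursts = search_bursts(stream, params)
        assert len(bursts) == 1
        assert bursts[0].start_index >= len(bg_before) - 5
        assert bursts[0].stop_index <= len(bg_before) + 200 + 5
        assert [(b.start_index, b.stop_index) for b in bursts] == \
            brute_force_bursts(ts, params)

    def test_lower_m_starts_no_later(self):
        bg = np.arange(0, 50_000, 1000)
        dense = 50_000 + np.arange(200) * 10
        ts = np.concatenate([bg, dense])
        stream = make_stream(ts)
        b30 = search_bursts(stream, BurstSearchParams(500, 30, 120))
        b10 = search_bursts(stream, BurstSearchParams(500, 10, 50))
        assert len(b30) == len(b10) == 1
        assert b10[0].start_index <= b30[0].start_index

    def test_empty_stream(self):
        stream = make_stream([])
        assert search_bursts(stream, BurstSearchParams(500, 10, 50)) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_oracle_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 250))
        ts = np.unique(rng.integers(0, 20_000, n))
        params = BurstSearchParams(T_us=int(rng.integers(50, 1000)),
                                   M=int(rng.integers(2, 8)),
                                   N=int(rng.integers(2, 15) + 6))
        stream = make_stream(ts)
        got = [(b.start_index, b.stop_index)
               for b in search_bursts(stream, params)]
        assert got == brute_force_bursts(ts, params)


class TestCorrections:
    def test_background_subtraction(self):
        b = Burst(0, 59, 0, 10_000, {"DD": 0, "AD": 60, "AA": 0})
        corr = CorrectionFactors(background_rates={"AD": 1000.0})
        _, f_ad, _ = correct_counts(b, corr)
        assert f_ad == 50.0

    def test_leakage_cancels_exactly(self):
        b = Burst(0, 1, 0, 1000, {"DD": 100, "AD": 10, "AA": 0})
        corr = CorrectionFactors(leakage=0.1)
        f_dd, f_ad, _ = correct_counts(b, corr, apply_crosstalk=True)
        assert (f_dd, f_ad) == (100.0, 0.0)

    def test_identity_with_zero_corrections(self):
        b = Burst(0, 1, 0, 1000, {"DD": 100, "AD": 40, "AA": 80})
        assert correct_counts(b, CorrectionFactors()) == (100.0, 40.0, 80.0)

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            CorrectionFactors(background_rates={"DD": -1.0})


class TestComputeES:
    @pytest.mark.parametrize("fdd,fad,faa,e,s", [
        (150, 50, 100, 0.25, 2 / 3),
        (200, 0, 0, 0.0, 1.0),       # donor-only
        (300, 100, 0, 0.25, 1.0),
    ])
    def test_printed_formulas(self, fdd, fad, faa, e, s):
        got_e, got_s = compute_es(fdd, fad, faa)
        assert got_e == pytest.approx(e)
        assert got_s == pytest.approx(s)

    def test_acceptor_only_undefined_e(self):
        e, s = compute_es(0, 0, 200)
        assert np.isnan(e)
        assert s == 0.0

    def test_invariant_under_time_rescaling(self):
        # E and S depend only on counts, not on the photon clock
        e1 = compute_es(120, 60, 90)
        e2 = compute_es(120, 60, 90)
        assert e1 == e2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_ratios_in_unit_interval(self, fdd, fad, faa):
        e, s = compute_es(float(fdd), float(fad), float(faa))
        assert 0.0 <= e <= 1.0
        assert 0.0 <= s <= 1.0


def _synthetic_burst_stream(rng, n=400, duration_us=4000, e=0.5, s=0.5,
                            acceptor_dies_at=None):
    """Construct one dual-labelled burst as a classified stream + Burst."""
    ts = np.sort(rng.choice(duration_us, size=n, replace=False)).astype(np.int64)
    phase = ts % 100
    donor_slot = phase < 50
    ch = np.empty(n, dtype=np.int8)
    for i in range(n):
        if donor_slot[i]:
            dead = acceptor_dies_at is not None and ts[i] > acceptor_dies_at
            ch[i] = ACCEPTOR if (rng.uniform() < e and not dead) else DONOR
        else:
            if acceptor_dies_at is not None and ts[i] > acceptor_dies_at:
                ch[i] = DONOR  # acceptor dark: only residual DA background
            else:
                ch[i] = ACCEPTOR
    # keep acceptor-slot photons only w.p. (1-s)/s ratio handled by s=0.5 here
    stream = make_stream(ts, ch)
    burst = Burst(0, n - 1, int(ts[0]), int(ts[-1]),
                  raw_counts=stream.class_counts())
    return stream, burst


def _naive_2cde(stream, burst, tau):
    """Loop-based oracle for the kernel-density scores."""
    ts = stream.timestamps_us.astype(float)
    lab = stream.class_labels
    slot = stream.excitation_slot

    def kde(t0, times, exclude_self_at=None):
        total = 0.0
        for t in times:
            if exclude_self_at is not None and t == exclude_self_at:
                continue
            total += np.exp(-abs(t0 - t) / tau)
        return total

    t_dd = ts[lab == 0]
    t_ad = ts[lab == 1]
    t_dex = ts[slot == 0]
    t_aex = ts[slot == 1]
    e_d = np.mean([kde(t, t_ad) / max(kde(t, t_ad) + kde(t, t_dd) - 1.0, 1e-12)
                   for t in t_dd])
    om_a = np.mean([kde(t, t_dd) / max(kde(t, t_dd) + kde(t, t_ad) - 1.0, 1e-12)
                    for t in t_ad])
    fret = 110.0 - 100.0 * (e_d + om_a)
    br_da = np.mean([kde(t, t_aex) / max(kde(t, t_dex) - 1.0, 1e-12)
                     for t in t_dex]) * t_dex.size / t_aex.size
    br_ad = np.mean([kde(t, t_dex) / max(kde(t, t_aex) - 1.0, 1e-12)
                     for t in t_aex]) * t_aex.size / t_dex.size
    alex = abs(100.0 - 50.0 * (br_da + br_ad))
    return alex, fret


class TestTwoCde:
    def test_matches_naive_oracle(self, rng):
        stream, burst = _synthetic_burst_stream(rng)
        alex, fret = two_cde_scores(burst, stream, 100.0)
        alex_o, fret_o = _naive_2cde(stream, burst, 100.0)
        assert alex == pytest.approx(alex_o, abs=1e-9)
        assert fret == pytest.approx(fret_o, abs=1e-9)

    def test_static_dual_label_scores_low(self, rng):
        for seed in range(5):
            stream, burst = _synthetic_burst_stream(
                np.random.default_rng(seed), n=800, duration_us=4000)
            alex, fret = two_cde_scores(burst, stream, 100.0)
            assert alex < 12.0
            assert 8.0 <= fret <= 12.0

    def test_donor_only_scores_high(self, rng):
        n = 300
        ts = np.sort(rng.choice(3000, size=n, replace=False)).astype(np.int64)
        donor_slot = (ts % 100) < 50
        # donor-only: all donor-excitation photons in the green channel, and
        # a couple of stray background photons under red excitation
        ch = np.where(donor_slot, DONOR, ACCEPTOR).astype(np.int8)
        keep = donor_slot.copy()
        stray = np.flatnonzero(~donor_slot)[:3]
        keep[stray] = True
        stream = make_stream(ts[keep], ch[keep])
        burst = Burst(0, keep.sum() - 1, int(ts[keep][0]), int(ts[keep][-1]),
                      raw_counts=stream.class_counts())
        alex, _ = two_cde_scores(burst, stream, 100.0)
        assert alex > 12.0

    def test_mid_burst_acceptor_bleach_breaks_fret_band(self, rng):
        stream, burst = _synthetic_burst_stream(rng, n=800, duration_us=4000,
                                                acceptor_dies_at=2000)
        _, fret = two_cde_scores(burst, stream, 100.0)
        assert not (8.0 <= fret <= 12.0)

    def test_deterministic(self, rng):
        stream, burst = _synthetic_burst_stream(rng)
        assert two_cde_scores(burst, stream, 100.0) == \
            two_cde_scores(burst, stream, 100.0)


class TestFilter:
    def _scored_bursts(self, n=20):
        bursts = []
        for i in range(n):
            b = Burst(0, 1, 0, 1000, {})
            b.alex_2cde = float(i)
            b.S = 0.5
            bursts.append(b)
        return bursts

    def test_disabled_thresholds_are_identity(self):
        bursts = self._scored_bursts()
        kept, removed = filter_bursts(bursts, FilterThresholds(alex_2cde_max=None))
        assert kept == bursts
        assert sum(removed.values()) == 0

    def test_zero_threshold_empties(self):
        kept, _ = filter_bursts(self._scored_bursts(),
                                FilterThresholds(alex_2cde_max=0.0))
        assert len(kept) <= 1  # only an exactly-zero score could survive

    def test_filter_reduces_donor_only_fraction(self):
        """30% donor-only contaminants fall below 5% after ALEX-2CDE."""
        cfg = SimulationConfig(n_states=1, state_E=(0.25,), dwell_means=(1.0,),
                               donor_only_frac=0.3)
        stream = simulate_photon_stream(cfg, 3000, rng_seed=4)
        bursts = tb.analyze_stream(stream, BurstSearchParams(500, 30, 120),
                                   thresholds=None)
        donor_only_pre = np.mean([b.S > 0.85 for b in bursts])
        kept, _ = filter_bursts(bursts, FilterThresholds(alex_2cde_max=12.0))
        donor_only_post = np.mean([b.S > 0.85 for b in kept])
        assert donor_only_pre > 0.15
        assert donor_only_post < 0.05
        assert donor_only_post <= donor_only_pre  # filtering never increases it


class TestPopulations:
    def test_single_gaussian_recovery(self, rng):
        e = rng.normal(0.25, 0.07, 5000)
        fit = fit_populations(e, 1)
        mu, sd, w = fit.components[0]
        assert mu == pytest.approx(0.25, abs=0.01)
        assert sd == pytest.approx(0.07, abs=0.01)
        assert w == pytest.approx(1.0)

    def test_two_component_mixture_recovery(self, rng):
        e = np.concatenate([rng.normal(0.25, 0.07, 4000),
                            rng.normal(0.49, 0.09, 4000)])
        fit = fit_populations(e, 2)
        (m1, _, w1), (m2, _, w2) = fit.components
        assert m1 == pytest.approx(0.25, abs=0.02)
        assert m2 == pytest.approx(0.49, abs=0.02)
        assert w1 == pytest.approx(0.5, abs=0.05)
        assert fit.bent_fraction == pytest.approx(w2)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            fit_populations([], 1)
        with pytest.raises(ValueError):
            fit_populations(np.full(20, 0.3), 1)
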