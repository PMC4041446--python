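"""Confocal ALEX burst analysis of diffusing promoter DNA.

Simulates a mixed population of unbent (E = 0.25) and TBP-bent (E = 0.49)
promoter DNA diffusing through a confocal volume, then runs the burst
pipeline: sliding-window burst search, background correction, E/S
computation, kernel-density filtering and a two-Gaussian population fit.
The fitted high-E weight is the fraction of bent DNA.
"""
import numpy as np

import tatabend as tb

# two-state bending equilibrium chosen to give roughly half-bent DNA
config = tb.SimulationConfig(
    n_states=2, state_E=(0.25, 0.49), dwell_means=(1.0, 1.0),
    donor_only_frac=0.1)
stream = tb.simulate_photon_stream(config, n_bursts=8000, rng_seed=1)
print(f"simulated {len(stream)} photons "
      f"({stream.duration_s:.0f} s, classes {stream.class_counts()})")

bursts = tb.analyze_stream(
    stream,
    tb.BurstSearchParams(T_us=500, M=30, N=120),
    thresholds=tb.FilterThresholds(alex_2cde_max=12.0))
e_values = np.array([b.E for b in bursts])
e_values = e_values[np.isfinite(e_values)]
print(f"{len(bursts)} bursts pass the (T=500 us, M=30, N=120) search "
      "and the ALEX-2CDE <= 12 filter")

fit = tb.fit_populations(e_values, n_components=2)
for mean, sd, weight in fit.components:
    print(f"  population: E = {mean:.2f} +/- {sd:.2f}, weight {weight:.2f}")
print(f"fraction bent = {fit.bent_fraction:.2f}")
print("-> the two E populations sit at the unbent/bent proximity ratios and")
print("   their weights estimate the bending equilibrium (here ~0.5).")
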