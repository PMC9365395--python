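"""Open-channel block of the homomer by QX-222 across concentrations.

Simulates recordings at 0-100 uM blocker from the four-state scheme (the
spontaneous scheme plus one open-blocked state), shows the two hallmarks of
open-channel block — shortening openings and multiplying brief closings —
and fits the blocking rate constants globally with the core rates
constrained to their blocker-free values.
"""

import numpy as np

import patchkin as pk

DEAD_TIME = 18.83e-6
BLOCKER = "QX-222"

scheme = pk.scheme_preset("S2", blocker=BLOCKER, variant="free")
datasets = []
for ci, conc in enumerate((0.0, 10.0, 30.0, 60.0, 100.0)):
    for r in range(3):
        cfg = pk.SimulationConfig(scheme=scheme, seed=7 + 100 * ci + r,
                                  n_events=4000,
                                  concentrations={BLOCKER: conc})
        ev = pk.impose_dead_time(pk.simulate_recording(cfg), DEAD_TIME)
        datasets.append((pk.BurstSet([ev], np.inf), conc))

series = pk.BlockSeries(blocker=BLOCKER, scheme=scheme, datasets=datasets,
                        dead_time=DEAD_TIME)

print("concentration dependence (apparent, after dead-time conditioning):")
print(pk.block_signatures(series).to_string(index=False))
print("\nMean open time falls with blocker because each blockage truncates")
print("an opening; the closing rate rises in step.\n")

core = {s: v for s, v in scheme.rates().items()
        if s not in ("k_plusB", "k_minusB")}
fits = pk.fit_block_series(series, core_rates=core, seed=3, n_starts=1)
for name, res in fits.items():
    kon, koff = res.rate("k_plusB"), res.rate("k_minusB")
    kb = res.derived.K_B["blocker"]
    print(f"{name:12s} k_+B = {kon:6.1f} uM^-1 s^-1   "
          f"k_-B = {koff:7.0f} s^-1   K_B = {kb:6.2f} uM")
print("\nGenerating values: k_+B = 95 uM^-1 s^-1, k_-B = 1400 s^-1,")
print("K_B = 14.74 uM.  Constrained and free fits should agree closely —")
print("the rates of block are insensitive to the core-scheme constraint.")
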