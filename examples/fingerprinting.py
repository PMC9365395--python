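"""Count subunits by electrical fingerprinting.

Channels assembled from a binomial mix of high-conductance (HC, ~16 pA) and
low-conductance (LC, ~1.5 pA) subunit variants produce burst amplitudes
that segregate into n + 1 evenly spaced classes for an n-subunit channel.
Fitting Gaussian amplitude classes and anchoring the extremes to the pure
populations yields the subunit count.
"""

import numpy as np

import patchkin as pk

cfg = pk.PentamerAssemblyConfig(seed=5, n_bursts=500, p_hc=0.5,
                                amp_lc=1.5, amp_hc=16.0, class_sd=0.3)
amps, true_counts = pk.simulate_fingerprint_bursts(cfg)

model = pk.fit_amplitude_classes(amps, seed=0)
print(f"{model.n_classes} amplitude classes from {amps.size} bursts:")
for mu, w in zip(model.means, model.weights):
    print(f"  {mu:6.2f} pA   weight {w:.3f}")

out = pk.infer_subunit_count(model, endpoint_amplitudes=(1.5, 16.0))
slope, intercept, resid = pk.class_mean_regression(model)
print(f"\ninferred subunits: {out['subunits']} "
      f"(classes - 1, endpoints matched within "
      f"{100 * max(out['endpoint_error_low'], out['endpoint_error_high']):.1f}%)")
print(f"class means vs HC count: slope {slope:.2f} pA/subunit, "
      f"intercept {intercept:.2f} pA, residual SD {resid:.3f} pA")
print("\nSix classes with near-equal ~2.9 pA steps mean five positions each")
print("contribute equally to conductance: the channel is a pentamer.")
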