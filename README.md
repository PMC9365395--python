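# patchkin

Single-channel kinetic analysis of patch-clamp recordings: aggregated
continuous-time Markov gating schemes, missed-event-corrected maximum
likelihood estimation of rate constants, burst analysis, open-channel
block, and electrical-fingerprinting stoichiometry inference.

The package was built around the analysis of reconstructed ancestral
muscle-type acetylcholine-receptor β-subunits, which assemble into
homopentameric channels that open *spontaneously* — without agonist — in
bursts of closely spaced openings. Their activity is described by a linear
priming scheme

```
        k+1'        beta1
   C  <------>  C' <------>  O'
        k-1'        alpha1
```

where `C` is the resting closed state, `C'` a primed (flipped) closed
intermediate, and `O'` the open state. Adding a blocker (acetylcholine at
high concentration, or QX-222) appends an open-blocked, non-conducting
state `O'B` entered from `O'` at rate `k+B·[B]` and left at `k-B`. A
multi-priming variant chains three primed closed states, each with its own
open state. The same machinery handles the wild-type receptor's
binding–gating–block scheme. Everything downstream works for any
user-defined scheme with `open`/`shut` state classes.

## What it computes

* **Exact dwell-time structure.** From a scheme's generator (Q) matrix:
  equilibrium occupancies, open/shut dwell densities and their exponential
  components (eigenvalues of the within-class sub-generators), mean dwell
  times, and derived equilibrium constants `K' = k+'/k-'`,
  `Θ = β/α`, `K_n = k-n/k+n`, `K_B = k-B/k+B`.
* **Synthetic data.** Exact stochastic simulation of dwell sequences,
  rendering as Gaussian-filtered noisy current traces, and binomial
  pentamer-assembly burst-amplitude populations — with hidden ground truth
  retained for testing.
* **Preprocessing.** 50 % threshold idealization, filter-risetime
  correction of brief events, dead-time imposition (default 18.83 µs),
  critical shut duration `τ_crit` from the intersection of adjacent
  exponential components, burst definition (≥ 3 events), and a two-pass
  burst `P_open` filter.
* **Rate estimation (the core).** The dwell-sequence likelihood with
  MIL-style first-order missed-event correction: within-class
  sub-generators are corrected as
  `Q'_aa = Q_aa + Q_ab (I − e^{Q_bb t_d}) (−Q_bb)^{-1} Q_ba`
  (undetected opposite-class sojourns shorter than the dead time are
  folded into the running dwell) and cross-class factors become
  `Q_ab e^{Q_bb t_d}`. Global multi-recording, multi-concentration fits
  share rate symbols, honour fixed parameters exactly, and report standard
  errors from the inverse observed information.
* **Block analysis.** Concentration series fitted constrained (core rates
  held at blocker-free values) and free, reporting `k+B`, `k-B`, `K_B`.
* **Fingerprinting.** Event-based amplitude histograms, equal-variance
  Gaussian amplitude classes selected by BIC, subunit count = classes − 1
  anchored to pure high-/low-conductance endpoints, and the linearity of
  class means versus subunit count.

## Worked example

`examples/spontaneous_kinetics.py` simulates three recordings of 10,000
events from the spontaneous scheme at its published agonist-free rates,
imposes the 18.83 µs dead time, and refits the four rate constants:

```
rate                 fitted       SE  generating
k_plus1_prime          3961       96        3900
k_minus1_prime         7573      330        7600
beta_1                10173      262       10000
alpha_1                 312        3         310

priming equilibrium  K' = 0.52  (truth 0.51)
gating equilibrium Theta = 32.64  (truth 32.26)
```

Each fitted rate lands within roughly one standard error of the value
used to generate the data, showing that the missed-event-corrected
likelihood removes the bias that dead-time censoring would otherwise
introduce (about 17 % of shut dwells here are shorter than the dead time).
The derived constants say the channel primes reluctantly (`K' ≈ 0.5`) but,
once primed, opens strongly (`Θ ≈ 32`) — the kinetic signature of
efficient spontaneous activation.

The other examples cover the blocker concentration series
(`block_series.py`), subunit counting (`fingerprinting.py`), dwell-time
distributions and component-count selection (`dwell_distributions.py`),
and the trace-to-bursts pipeline (`trace_idealization.py`).

Event lists are exchanged as a simple TSV dialect (`#key<TAB>value` header
comments for recording metadata, then `index / class / duration_s /
amplitude_pA` columns); see `patchkin.io`.

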