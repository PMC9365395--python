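# Methods

## Model

Channel gating is an aggregated continuous-time Markov chain. States carry
one of two observable conductance classes, `open` or `shut`; open-blocked
states are non-conducting and therefore belong to the shut class. The
generator (Q) matrix holds transition rates in s⁻¹, with second-order
(association) rates given in µM⁻¹·s⁻¹ and multiplied by the relevant
ligand concentration in µM when the matrix is built. All internal time
arithmetic is in seconds; reports use ms/µs as convenient.

For a class *a* with sub-generator `Q_aa`, the ideal dwell density is
`f(t) = φ e^{Q_aa t} (−Q_aa) 1`, with `φ` the equilibrium class-entry
vector (stationary flux from the complementary class, normalised). Its
exponential components come from the eigenvalues of `Q_aa`; a defective
sub-generator falls back to matrix-exponential evaluation without a
component decomposition. Equilibrium occupancy solves `π Q = 0, Σπ = 1`
by least squares on the augmented system.

Built-in presets cover the schemes used in the source analyses: the
three-state spontaneous priming scheme, its four-state open-block
extension (acetylcholine or QX-222, free or core-constrained rate sets),
the wild-type receptor's sequential binding/gating/block scheme, the same
with a QX-222-blocked state at fixed agonist concentration, and the
seven-state multi-priming scheme. The multi-priming topology is a linear
chain of shut states with one open state attached to each primed shut
state and no open–open transitions; the wild-type scheme places a single
blocked state on the diliganded open state per blocker (no block of the
monoliganded open state — a single forward/backward block-rate pair exists
per blocker).

## Missed-event correction and likelihood

Recordings cannot resolve events shorter than a dead time `t_d`
(18.83 µs by default). The simulator reproduces this by deleting sub-`t_d`
events and folding their durations into the merge of their (same-class)
neighbours, iterated left to right until stable; a trailing unresolvable
event is folded into the preceding dwell and unresolvable leading events
are dropped. The operation is idempotent and conserves total duration
apart from dropped leading events.

The likelihood uses the matching MIL-style first-order correction:

* within-class propagator `e^{Q'_aa (t − t_d)}` with
  `Q'_aa = Q_aa + Q_ab (I − e^{Q_bb t_d}) (−Q_bb)^{-1} Q_ba`
  (brief, undetected excursions into the opposite class are absorbed);
* cross-class factor `Q_ab e^{Q_bb t_d}` (the entered sojourn must survive
  the dead time to be detected).

With these, `−Q'_aa 1 = Q_ab e^{Q_bb t_d} 1`, so each apparent-dwell
density integrates to one on `t ≥ t_d`, and at `t_d = 0` every kernel
reduces exactly to the ideal likelihood (verified against a dense
matrix-exponential oracle at 10⁻⁸ relative). The correction is first
order: it ignores the small inflation of apparent durations by the missed
sojourn times and the exact treatment of dwells shorter than `2 t_d`. It
is accurate while `t_d` is small relative to mean dwells; a warning is
issued when `t_d` exceeds ten times the shortest mean state sojourn. The
exact asymptotic treatment is a noted extension point. In the regimes
exercised here (dead time 18.83 µs against 50–500 µs shut components),
parameter-recovery tests show sub-percent bias for the spontaneous scheme;
for very fast block (mean blocked dwell below the dead time) the
individual block rates carry a ~10 % first-order bias that largely cancels
in the ratio `K_B`.

Per burst, the likelihood is `φ · Π_i [propagator(t_i) · cross] · end`,
summed in log over bursts and datasets; each dataset's generator is built
at its own ligand concentrations from the shared symbol set. Burst entry
uses the equilibrium class-entry vector (the recordings emulate
steady-state patches) with a uniform-entry alternative available; the end
factor sums over all exits to the opposite class. Rate fits are run on
whole conditioned recordings (a single "burst" with `τ_crit = ∞`) rather
than on `τ_crit`-truncated bursts: excluding long shut dwells without
conditioning the likelihood on them would censor the slow shut component
and bias the resting-state rates. Burst definition is still used for burst
statistics (`P_open`, openings per burst) and for amplitude measurements.
Per-burst log-likelihoods are summed across recordings (equivalent to, and
used in place of, concatenation).

The scan runs in the eigenbasis of the corrected sub-generators with
per-step rescaling; complex eigenpairs are handled in complex arithmetic
and only the final (real) likelihood is taken. A numba-compiled scan is
used when numba imports, with an identical pure-numpy fallback.
Optimisation is quasi-Newton (L-BFGS-B) on log rates with box bounds
[10⁻², 10⁷] s⁻¹, seeded multi-start. Standard errors come from the
central-difference Hessian of the log-likelihood in log-rate space,
inverted and mapped to natural units by the delta method; a singular
information matrix yields absent SEs with a warning (as for block rates
fitted with no blocker present).

## Preprocessing

Idealization detects transitions at 50 % of the open amplitude with linear
interpolation between samples; inverted polarity is handled by
normalisation. Brief-event durations are corrected for Gaussian-filter
attenuation by inverting the apparent-vs-true width map of half-amplitude
detection (tabulated once from the filtered-pulse step response; pulses
shorter than ≈1.35 filter sigmas never reach threshold and set the
correction's domain). Events longer than about three risetimes pass
through unchanged. The Gaussian filter stands in for the recording
hardware's Bessel filter; only the step-response risetime
(≈ 0.34 / f_c for the −3 dB cutoff, the numerically exact Gaussian value)
matters downstream.

`τ_crit` solves `a₁/τ₁ e^{−t/τ₁} = a₂/τ₂ e^{−t/τ₂}` between the slowest
intra-burst and fastest inter-burst shut components (default split:
penultimate vs slowest component; the fingerprinting pipeline instead
imposes a uniform 2 ms `τ_crit`). Bursts are runs of events between shut
dwells longer than `τ_crit`, trimmed to start and end on openings; bursts
with fewer than three events are dropped. The `P_open` filter removes
outliers at median ± 5 scaled MADs, then fits a Gaussian to the survivors
and keeps bursts within 2 SD; both pass sizes are recorded in metadata.
Because burst `P_open` is bounded at 1 and left-skewed, the 2-SD pass
retains somewhat less than the Gaussian 95 % on homogeneous data (~90 %).

Dwell-histogram fits are maximum likelihood on raw durations left-
truncated at the dead time (not least squares on binned counts), with
softmax weights and log time constants, multi-start from log-duration
quantiles. The component count is the smallest k for which adding a
component fails `2·ΔlogL > 10`; the k+1 fit is seeded from the k solution
so the log-likelihood is non-decreasing in k. Log-binned square-root-
ordinate histograms are display only (default 10 bins per decade,
cosmetic).

## Synthetic data

The generator simulates exactly (Gillespie) from the scheme at its stated
rates, starting from equilibrium occupancy, and merges same-class sojourns
into alternating events; hidden truth (state path, subunit counts) is kept
for oracle tests. Default study conditions mirror the source analyses:
three recordings per condition, 10⁴ events each for spontaneous fits,
blocker series over 0/10/30/60/100 µM with three recordings per
concentration, dead time 18.83 µs. Fingerprinting defaults: pentamers,
all-LC amplitude 1.5 pA and all-HC 16 pA (the reported pure-population
amplitudes), within-class SD 0.3 pA, balanced assembly probability 0.5,
500 bursts — values the recordings report only qualitatively (amplitude
"~1–2 pA" and "~16 pA") are fixed at these round numbers. Trace mode adds
Gaussian filtering and white noise; noise SD and channel count per patch
are free parameters (the sources do not report them; default one channel,
no baseline drift, no overlapping openings). What passing tests show is
therefore fidelity to the scheme-generated, stationary, single-channel
world; real records add baseline drift, multiple channels and non-Markov
artifacts that this generator deliberately omits.

For the acceptance script, problem sizes are chosen for quick desk-scale
runs: 3 × 5000 events (~1500 bursts) for the burst open probability and
3 × 10⁴ events for the rate-recovery fit.

## Amplitude classes

Event-based amplitude histograms are normalised per burst count so patches
pool by concatenation. Classes are equal-variance (tied) Gaussian
mixtures, k = 1…8, selected by BIC; each k is fitted from both a k-means
initialisation and an evenly spaced grid over the amplitude range (the
physically expected configuration), keeping the better likelihood — plain
k-means alone can miss rare extreme classes. Subunit-count inference
requires the extreme class means to match the pure-LC/pure-HC endpoint
amplitudes within 20 % relative; otherwise it is refused, since the class
count alone is ambiguous when extreme classes are unpopulated.

## Known limitations

First-order (not exact) missed-event correction; no conditioning of the
burst likelihood on the `τ_crit` definition (CHS-style vectors are not
implemented); no hidden-Markov fitting of raw traces; no multi-channel or
subconductance handling; no model-topology search or selection verdict
between equally fitting three-state schemes; voltage dependence of block
and trapped-block models are out of scope.
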