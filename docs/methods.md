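# Methods

This note documents the models, conventions and numerical choices behind
`statekin`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic validation does and does not
show.

## Gating model

Channel gating is a continuous-time Markov chain over four unbound states
— resting (R), open (O), fast-inactivated (FI), slow-inactivated (SI) —
and three bound, non-conducting mirror states (B_R, B_FI, B_SI). The
gating transitions are

    R <-> O -> FI <-> SI,    FI -> R,    R -> SI.

Each rate is a capped exponential in voltage,
`rate(V) = min(base · exp((V − v_half)/efold_mV), cap)` with a default cap
of 2·10⁴ s⁻¹ so the generator stays finite over the command range
[−140, +20] mV. The defaults live in `statekin/data/default_model.json`.

Two topology choices deserve comment:

- **Single FI and SI states.** Real VGSCs populate several fast- and
  slow-inactivated states; we deliberately use one of each, which keeps
  the repriming decomposition and the affinity solve exactly aligned with
  the model's state space.
- **A direct R → SI route.** In a pure chain R ↔ O → FI ↔ SI the
  steady-state ratio SI/FI equals the ratio of two monotone functions of
  voltage and is therefore monotone in V. That has two consequences: a
  slow-inactivated fraction cannot persist at strongly hyperpolarized
  holding potentials where FI has vanished, and the three-holding-potential
  linear system for the per-state association constants becomes numerically
  singular (its FI and SI columns are nearly proportional; condition
  number ≈ 10³). Closed-state slow inactivation is a documented feature of
  multi-state VGSC models, and adding a small voltage-shaped R → SI rate
  (≈ 0.006 s⁻¹ above −100 mV, vanishing below ≈ −110 mV so that repriming
  at −120 mV still recovers completely) restores both properties and
  brings the system's condition number to ≈ 50.

**Binding.** Each unbound state S binds the inhibitor at `k_S · x(t)`
(1/s per unit of the lumped concentration x = [X]·C; absolute
concentration and the proportionality constant are not separately
identifiable, so only their product is exposed). The open state binds at
`k_O = k_R` by default (open-state affinity is never probed by the
protocols modelled here) and, since there are only three bound mirror
states, O binds into B_R. Bound channels carry no current, do not
interconvert between gating conformations, and unbind at a single
voltage-independent rate `k_off` back to their gating partner. The default
`k_off = 1 s⁻¹` matches the ≈ 1 s recovery of current at −120 mV after
full inhibition. Whether a bound channel conducts partially is unknown; we
assume fully non-conducting.

**Availability** is the occupancy of the unbound resting-side pool, R plus
O: the open state re-equilibrates with R within a millisecond and binds at
k_R, so it belongs with the available pool for every readout used here.
The peak-current proxy is availability at test-pulse onset times a fixed
maximal amplitude (activation kinetics are not rendered into current
waveforms); currents are treated as magnitudes.

**Propagation** is by exact matrix exponentials of the generator over
steps of at most `dt`, with the inhibitor concentration frozen at each
step midpoint (second-order accurate in the schedule); when the
concentration is constant over an interval a single exponential covers it,
which is exact. The stationary distribution is the null vector of the
transposed generator; a chain with more than one closed communicating
class (e.g. `k_off = 0` with inhibitor present) is rejected with the
classes named. Occupancies are conserved to 10⁻⁹ along every trajectory.

## Calibration of the default model

Only printed control values were used as calibration targets, and all
constants live in the JSON config, not in code:

| target | calibrated model | printed control value |
|---|---|---|
| availability midpoint, 100 ms conditioning | −58.7 mV | −58.3 mV |
| availability midpoint, 5 s conditioning + 100 ms recovery | −59.3 mV | −59.2 mV |
| available fraction after 5 s at +10 mV + 100 ms at −120 mV | 0.50 | 0.45–0.56 |
| fast repriming τ at −120 mV | ≈ 1 ms | 0.9–2.1 ms |
| slow recovery τ at −120 mV | ≈ 0.65 s | 0.2–0.9 s |

Known limitation: the model's apparent valences come out at ≈ 2.1–2.2 e,
shallower than the measured 4.2 e (fast) and 2.3 e (slow). A steeper
availability foot makes the fast-inactivated fraction collapse within
10 mV of the midpoint, which drives the three-potential affinity system
toward singularity; with a single FI state one cannot have both the
printed steepness and a solvable system, and we prioritised the midpoints
(the quantities the affinity analysis actually uses) over the slope.

## Inhibitor schedule and the squared-exponential onset

The inhibitor concentration follows a configurable schedule: zero
(control), step (a directly applied blocker), or a linear ramp to a
plateau (an indirectly generated inhibitor accumulating downstream of a
receptor). Under a ramp `x(t) = ρt` the survival of unbound channels obeys
`−ln U(t) = k_eff · ρ t²/2` with `k_eff = Σ F_S k_S`, i.e. exactly the
squared-exponential form; under a step it is a single exponential. This
reproduces the diagnostic distinction between indirect and direct
inhibition, and `compare_forms` (small-sample AICc over single, squared
and constant models) recovers the generating form in ≥ 95 % of noisy
trials.

Diary plots deliver test pulses every 2 s (0.5 Hz); the 10–20 ms test
depolarizations themselves are not propagated, because repriming at the
holding potentials completes within a few ms and 0.5 Hz stimulation leaves
no measurable accumulation. Peaks are normalized to the pre-onset baseline
mean.

## Repriming decomposition

A double-pulse protocol (10 ms S1 to −20 mV, a variable recovery period at
−120 mV, then S2) yields I₂/I₁con versus recovery time, normalized to the
pre-drug current elicited from the holding potential. The curve is fitted
with a double exponential (total asymptote T); components are classified
by absolute timescale — anything slower than 50 ms is attributed to the
slow-inactivated pool — because pure fast/slow ordering mislabels curves
that contain only a slow phase (hyperpolarized holding potentials with no
FI). The decomposition is then

    R component  = 1                      F_R  = 1/T
    FI component = max(0, A_fast − 1)     fast asymptote A_fast = T − (slow amplitude)
    SI component = T − max(A_fast, 1)     fractions = components / T

and F_R + F_FI + F_SI = 1 by construction. T < 1 is rejected as a
normalization fault. On ideal two-exponential curves the decomposition is
exact; on simulated protocols the residual biases are ≈ 0.003 (absolute,
per fraction), dominated by the ≈ 0.3 % of channels that remain
fast-inactivated at −120 mV and by slow inactivation accrued during S1.

Fitting robustness: time constants are bounded above by 10× the
observation window (by the window itself for repriming curves, so the
asymptote never rests on slower-than-observable components), and the
double-exponential initialization splits the amplitudes at the end of the
fast phase so that a small slow tail riding on a large fast component is
not lost. A double fit whose time constants collapse (within 5 %) or whose
secondary amplitude is negligible is refitted as a single exponential and
flagged.

## The affinity solve

One linear equation per holding potential, coefficients [F_R, F_FI, F_SI]
and right-hand side the inhibition rate, solved exactly for three
equations and by ordinary least squares for more. Only the ratios
k_FI/k_R and k_SI/k_R are identifiable; they are invariant (to machine
precision) under common rescaling of the rates and under row permutation.
Negative solved rates are reported with a warning, never clipped; a
non-negativity-constrained variant (scipy NNLS) is available behind a
flag, off by default. An independent Cramer's-rule oracle agrees with the
solver to 10⁻¹⁰ relative on random full-rank systems. Solving the system
assembled from the bundled printed state-fraction table (rates 0.0096,
0.0040, 0.0020 s⁻¹) gives ratios 10.54 and 2.15; the residual discrepancy
from the reported 10.1 and 2.3 traces to the rounding of the printed
fractions and rates.

**Rate convention.** When the rate comes from a squared-exponential diary
fit under a ramp, the fitted 1/τ is proportional to √k_eff, not k_eff
(since 1/τ² = k_eff·ρ/2). The synthetic end-to-end loop therefore enters
1/τ² into the system — the common factor ρ/2 cancels in the ratios — so
that the generator's true ratios are recoverable. When printed per-
potential rates are supplied directly (as in the bundled table), they are
used as given.

## The end-to-end validation loop and its regime

`recover_ratios_end_to_end` simulates, per holding potential (−60, −80,
−100 mV): the drug-free repriming protocol (48 log-spaced recovery times,
0.2 ms–8 s), decomposed into state fractions; and an inhibition diary
(1600 s at 0.5 Hz) under a ramp schedule, fitted with the squared
exponential. The diary runs in the regime in which the analysis is valid:

- ramp rate 2.5·10⁻⁶ conc/s, so the binding hazard stays far below the
  gating relaxation rates and the unbound pool remains at its gating
  steady state (the quasi-equilibrium assumption behind the
  state-fraction model);
- unbinding 10⁻⁵ s⁻¹ for the diary, i.e. negligible on the onset
  timescale — the same slow-off-rate assumption under which the
  mass-action rate equation is derived. (The model default of 1 s⁻¹,
  appropriate for recovery at −120 mV, would otherwise prevent any
  inhibition from developing over a several-hundred-second onset.)

With measurement noise, six replicates per holding potential are
simulated (typical cell counts for such recordings); replicate repriming
curves are averaged pointwise before fitting, as averaged multi-cell
curves are in practice, and the median inhibition rate is used. With true
ratios (10, 2): noise-free recovery is (9.6, 2.0), within 5 %; at
sigma = 0.02 Gaussian noise per point the recovered ratios are within
≈ 10 % (FI) and ≈ 25 % (SI) for typical seeds — the SI ratio is the most
noise-sensitive quantity because its information enters through fraction
differences of a few percent. With state-independent binding (1, 1, 1)
the measured inhibition rate is voltage independent to < 1 % and the
recovered ratios are exactly 1, as they must be (rows of state fractions
sum to one).

What passing these checks shows — and does not show: the pipeline is
self-consistent (it recovers what the generator put in, through the full
protocol/fit/decompose/solve chain, at realistic noise), but the
generator shares the single-FI/SI-state simplification with the analysis.
Real recordings, with multiple inactivated states, rundown, series-
resistance error and non-stationary drug delivery, will violate the
model in ways the synthetic data do not probe.

## Spike-feature extraction

Threshold is the membrane potential at which dV/dt (central two-point
difference at the native 20 kHz sampling, no smoothing) first reaches
20 mV/ms; amplitude is peak minus threshold; half-width is the interval
between the flanks at the level halfway between peak and *holding*
potential — the holding reference is unusual but implemented verbatim,
with linear interpolation between samples and a missing-value flag when a
flank never crosses the level. Detected windows closer than 2 ms merge
(refractory handling). Input resistance is the steady-state deflection
divided by the injected current (70 pA standard). The stylized spike-train
generator snaps the threshold kink and the apex onto the sample grid so
that round-trip feature recovery is exact to within one sample; its
triangular spikes are caricatures for testing the extractor, not
biophysical waveforms.

## Expression fractions

Per-subunit-type isoform fractions are computed on the linear scale,
`100 · 2^L / Σ_type 2^L` from log2 expression levels; rounding happens
only at presentation. The bundled expression and state-fraction tables are
verified against a sha256 manifest at load time.

## Determinism and problem sizes

Every stochastic operation takes an explicit integer seed (numpy
`default_rng` / `SeedSequence`; no global state), and the pipeline report
is byte-identical across reruns with the same configuration, keyed by a
hash of the computation-relevant fields. Default problem sizes — 17-point
voltage grids, 48-point recovery curves, 800-pulse diaries, 6 replicates,
8-seed recovery studies — were chosen so the entire test suite runs in
well under a minute on one CPU while keeping every estimate comfortably
inside its validation tolerance.
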