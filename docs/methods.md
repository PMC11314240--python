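# Methods

This note records the models, estimators, parameter choices and numerical
decisions behind `npfcs`, and what the synthetic-data generators do and do
not emulate.

## Correlation model and conventions

The observable is the normalized fluctuation cross-correlation of the two
detector channels, G(τ) = ⟨δI_A(t) δI_B(t+τ)⟩ / (⟨I_A⟩⟨I_B⟩), with no +1
baseline, so a single diffusing species in a 3D-Gaussian detection volume
gives G(0) = 1/N exactly. The monomer/aggregate model ties the aggregate
brightness to the comprised particle volume (Qₐ/Q₁ = (dₐ/d₁)³), making the
aggregate term enter with weight Xₐ(dₐ/d₁)⁶ — the reason FCS amplitude is
dominated by even small number fractions of large aggregates, and the
reason the aggregate *volume* fraction φₐ = Xₐdₐ³/(Xₐdₐ³+(1−Xₐ)d₁³) is
the sensitive onset statistic. No formula for φₐ accompanies the fitted
quantities in standard treatments; this number-weighted cube-diameter form
is the only parameter-free definition available from the fit parameters
themselves, and it is computed per replicate from that replicate's fitted
values. Photophysics (triplet blinking), anomalous diffusion and
polydispersity beyond two populations are deliberately out of scope.

Diffusion times use the finite-size expression τ_D = (ω₀²+(d/2)²)/(4D),
which is meaningful only for d ≤ 2ω₀ ≈ 700 nm at the default optics;
fitted diameters beyond that are reported but carry `size_validity=False`.
ω₀ = 350 nm is treated as the *lateral radius*, the role the symbol plays
in the decay law, and the aspect ratio S ≈ 11 as the axial/lateral extent.
Physical constants are CODATA exact values; the default solvent is water
at 21 °C (η = 0.978 mPa·s, T = 294.15 K). At the study concentration of
500 pM the standard effective volume V_eff = π^{3/2}Sω₀³ ≈ 2.63 µm³ holds
≈ 0.79 particles; descriptions putting "about 2 particles" in the
detection volume at this concentration imply a ~2.5× larger volume
definition, and both numbers are documented here rather than reconciled.

## Correlator

All estimators subtract channel means and normalize by their product.
`direct_cross_correlate` is the O(n·k) brute-force reference on a linear
lag grid. `multiple_tau_cross_correlate` evaluates lags 1..m (default
m = 16 points per octave) at native resolution, then repeatedly halves the
time resolution by pairwise summation and evaluates lags m/2+1..m, up to
half the trace duration; at stage-0 lags it reproduces the direct oracle
to machine precision, and coarser stages differ only by the documented
binning (pre-averaging) bias. Normalization is invariant under rescaling
either channel.

Finite observation windows bias any mean-subtracted correlation estimate
down by ≈ (2/T)∫G dτ, because fluctuations slower than the window are
absorbed into the window's own mean. With S = 11 the axial tail integrates
far out (∫g dτ ≈ 7 τ_D) and a 10 s window incurs a visible bias, so
`segment_and_average` normalizes every window against the mean count rates
of the *whole acquisition* (monitor override in the multiple-τ estimator).
Per-lag standard errors are the across-window standard deviation divided
by √(number of windows). An all-dark (zero-mean) channel raises a
validation error instead of propagating NaNs.

## Synthetic data

`simulate_trace` random-walks point emitters (per-axis step σ = √(2DΔt))
through a periodic box, evaluates the Gaussian detection profile, draws
per-bin Poisson counts and splits them 50/50 binomially onto two channels
— emulating the two-photodiode beam-splitter detection that removes
afterpulsing. Default bin width 10 µs (≥ 50 bins per diffusion time);
positions advance in float32 (box-wrapped coordinates keep absolute
rounding ~10⁻¹³ m, far below a step). The box default is 20ω₀ × 20ω₀ ×
3Sω₀: periodic boundaries quantize lateral concentration-fluctuation
modes at k = 2πn/L, so modes slower than L²/(4π²D) do not exist in the
box; at 10ω₀ that cutoff falls near 10 τ_D and demonstrably shortens
fitted diffusion times by ~15%, while at 20ω₀ it sits beyond the lag
range that carries fitting weight. Two deliberate simplifications: the
emitters are points (the (d/2)² finite-size term in τ_D is *not* emulated,
a ~2% effect at d = 100 nm), and detector dead time, afterpulsing and
background structure are absent.

`simulate_curve` is the fast stand-in for fitting studies: it evaluates
the two-population model on a log-spaced lag grid (default 160 points,
10 µs–10 s, ≈ 27 per decade like a multiple-τ grid) and adds independent
Gaussian noise with σ(τ) = noise_scale·(G(τ)+1/N)/√(index+1), a pragmatic
shape (large at short lags, amplitude-coupled) that is *not* the
instrument's true noise law; the stderr column carries the exact σ. All
recovery tolerances quoted in the tests are therefore statements about
this stand-in noise, not about instrument noise.

`generate_scenario` emulates a concentration series: the aggregate number
fraction follows a logistic onset Xₐ(c) = Xₐ,max/(1+exp(−(c−c₀)/w)) in
total biopolymer concentration, the solution viscosity follows the
stand-in polynomial η = η_w(1 + 0.9c + 0.2c²) in the alginate share of c
(anchored to the manufacturer's 30–90 mPa·s specification for a 1%
low-viscosity alginate solution, at the low end), and every concentration
× replicate yields one noisy curve plus a ground-truth table. Defaults:
500 pM nanoparticles, d₁ = 110 nm, dₐ = 400 nm, onset 3.5 g/L with width
0.08 g/L (well below the 1 g/L grid spacing, i.e. a sharp onset),
Xₐ,max = 0.005, six replicates (triplicates of two experiments). Xₐ,max
is chosen so both populations remain resolvable above the onset (aggregate
amplitude share ~90%, φₐ plateau ≈ 0.19): at much larger Xₐ,max the
aggregates own essentially all of the amplitude, the monomer component
becomes undetectable and the model selection — correctly — collapses to
one population, which no longer reflects a series in which both diameters
are measurable throughout. The generator mimics only the observable
signatures (Xₐ, dₐ, η trends), not the underlying adsorption, bridging or
depletion chemistry.

## Fitting

Both model fits are weighted least squares (weights 1/stderr when a valid
stderr column is present, else unit weights), using variable projection:
for fixed diameters the model is linear in the non-negative component
amplitudes, which are solved in closed form inside the residual, leaving a
1-D (one population) or 2-D (two populations) bounded nonlinear search.
This removes the severely ill-conditioned ridge that a naive 4-parameter
(N, Xₐ, d₁, dₐ) search exhibits when one component dominates the
amplitude. Diameter ordering is enforced by parameterization
(dₐ = d₁·eˢ, s ≥ 0), not a post-hoc swap; the two-population search runs
from 8 starts over log-spaced diameter ratios, each with two d₁ scalings
(the half-decay lag tracks the monomer when monomers dominate the
amplitude but the aggregate when aggregates do). Convergence tolerances
are 10⁻¹⁴ (the dominated component can sit five orders of magnitude below
the signal on noiseless curves and still must be recovered); N and Xₐ are
recovered from the projected amplitudes afterwards. Reduced χ² uses
ν = n−2 and ν = n−4 respectively.

Two physically motivated constraints regularize the two-population fit.
First, the fitted ratio dₐ/d₁ has a lower bound (default 2.6): two sizes
closer than roughly that factor cannot be resolved by FCS even at a 10%
fraction and good per-particle signal, so closer splits are statistically
meaningless; the one-population model remains nested through a vanishing
aggregate amplitude, so χ²(2 pop) ≤ χ²(1 pop) always. Second, the series
pipeline bounds fitted diameters below at 50 nm (configurable): the
samples' only emitters are ~100 nm labelled particles, and without the
bound a spurious sub-physical fast component can absorb short-lag noise
and relabel the real particles as "aggregate", inflating φₐ to ~0.5 on
aggregate-free data.

Model selection follows an Occam rule: the one-population fit is kept
when its reduced χ² is equivalent or better,
χ²_red(1 pop) ≤ (1+ε)·χ²_red(2 pop), with a small absolute floor so exact
(noiseless) fits on both sides count as equivalent. The margin ε defaults
to 2%: on 200 aggregate-free synthetic curves per seed set this keeps
spurious two-population selections at ~4–6%, whereas a 1% margin admits
11–14% once both fits are fully converged — the aggregate size is
unidentified under the null, so the effective test statistic is a
supremum over sizes and its tail is heavier than a naive χ² mixture
suggests.

`calibrate` fits (ω₀, S, N) to a reference curve with the bead diameter
fixed (study beads: 110 nm); a fit pinned at the S = 1 bound flags a curve
without long-lag information. `viscosity_correct` re-derives diameters
from the fitted diffusion times at the true solution viscosity by
re-inverting the full finite-size expression (a cubic with one positive
root, solved in closed form) rather than scaling linearly, since τ_D
depends on d both through D and the (d/2)² term.

In the series pipeline the solution viscosity η(c) enters the fit itself
(through the Stokes–Einstein relation), and the corrector is then an
identity that records the viscosity used. Correcting only *after* a
water-viscosity fit would fix the diameters but not Xₐ: the amplitude
weights are set by the apparent diameter ratio, which wrong-viscosity
fitting distorts, and at η ≈ 5η_w the resulting φₐ is inflated ~18×. The
standalone corrector remains available (and exact for diameters) for fits
performed at an assumed viscosity.

## Pipeline

Replicates are fitted separately and parameters averaged (mean ± SEM
across replicates; SEM only for ≥ 2 replicates), preserving the meaning
of the error bars, rather than fitting averaged curves. Aggregate-diameter
statistics average only replicates where the two-population model was
selected. The aggregation onset is reported as the grid interval
bracketing the first crossing of mean φₐ above a threshold (default 0.05,
set above the fitted-φₐ noise floor of ≤ 0.002 measured on aggregate-free
scenarios with the default pipeline bounds); non-monotonic series use the
first crossing and carry a flag. A failed calibration aborts the series; a
concentration point whose replicates all fail is flagged and skipped. All
randomness derives from a single config seed (calibration and scenario
streams are spawned from it), so identical configs produce byte-identical
result tables. Results are written as TSV tables plus a YAML run report
(config echo, calibration geometry, onset, software version) with full
numeric round-trip on re-reading.

## Problem sizes and limitations

The test suite and the acceptance script use: 1000 random draws for the
model-equivalence identity; 10,000-bin traces for correlator/oracle
agreement; 50 random draws for zero-noise recovery; a 60 s, 10 µs-bin,
170-particle Brownian simulation for photon-level recovery (d within 10%,
N within 15%); 200 noisy curves for the selection false-positive rate;
and a 6-point × 6-replicate series for end-to-end onset recovery. The
photon-level check is seed-fixed because a single 60 s acquisition
carries ±6–8% statistical scatter on the fitted diameter: the slowest
detectable fluctuation modes live near S²τ_D ≈ 0.85 s, so one minute of
data holds only ~70 independent samples of them (this is why real
acquisitions run 150–900 s, longer for larger aggregates). Known
limitations: the photon-level d estimate additionally carries the ~2%
point-emitter bias; the stand-in noise and viscosity models are
phenomenological; pH enters only as a label (the generator does not model
pH-dependent interactions); and χ² values are comparable only within this
package's weighting scheme, not across instruments.
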