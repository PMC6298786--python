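# Methods

This note documents the models and procedures implemented in vspkit, the
parameters that matter, the synthetic data the tests rely on, and the
numerical and design choices that were genuinely open.

## Membrane-binding and orientation classification

**Depth reference.** All depths are measured along z (the membrane normal)
relative to the *phosphorus layer*: the plane of lipid phosphorus atoms of
the monolayer proximal to the protein, estimated per frame as the arithmetic
mean of their z-coordinates (a median option exists for lattices with
outliers).  +z points from the protein side toward that monolayer, so the
protein sits at negative relative depth.  Coordinates are ingested in nm
(the native unit of GRO/XTC); depths are reported in Å, the unit in which
the cutoffs are defined.

**Binding.** A domain is bound when its *top atom* — the selection atom with
the highest z — sits at or above a cutoff relative to the phosphorus layer.
The cutoffs are resolution- and composition-specific because the bulky
phosphoinositide headgroups keep protein atoms further from the
phosphorylcholine phosphates: atomistic POPC 0 Å, atomistic POPC+PIP₃ −4 Å,
coarse-grained POPC −2 Å, coarse-grained POPC+PIP₃ −12 Å.  Boundary equality
counts as bound.  These four values are configuration data
(`ClassifierConfig.binding_cutoffs_A`), not code.

**Productive orientation.** Two vectors span the membrane-facing face of the
CCR: v1 from the Arg-281 Cα to the midpoint of the Lys-516/Arg-520 Cα pair
(C2 β6–7 loop), v2 from the same origin to the midpoint of the
Lys-555/Lys-558 Cα pair (β8–9 loop).  The pose is productive when v1 × v2
makes an angle within [0°, 30°] of +z, both ends inclusive (the band is
configurable).  The cross-product order and the z-sign convention each flip
the angle to 180° − θ; `cross_order="v1xv2"` with +z toward the proximal
monolayer is the package default, exposed as a switch because neither
convention is canonical.  Frames with collinear anchor vectors have no
defined orientation; they are flagged, counted as non-productive, and
reported with a warning.  The His-332 Cβ / Lys-367 Cα depth difference
(≲0.3 Å in the productive pose) is computed as a diagnostic only.

**Summaries.** Time fractions are frame counts over total frames for
uniformly spaced trajectories and trapezoidally time-weighted otherwise.
The productive column counts frames that are productive *and* have both
domains bound, so it can never exceed either binding fraction.  No
equilibration prefix is trimmed by default — callers can slice the
trajectory first.  Coarse-grained effective time is raw time × 4, the
standard Martini speed-up convention.

## Enzyme activity from episodic recordings

The test-pulse amplitude of episode i (1-based) is the mean current over the
final 2 ms of the test-pulse window (robust to single-sample noise; the
window is configurable down to one sample).  Amplitudes are normalized to
episode 1 and plotted against accumulated depolarization time
t_i = (i−1) × depolarization duration; episode 1 precedes any
depolarization, so the series starts at (0, 1) by construction and the
fitted rate is invariant to rescaling all raw amplitudes.

The default decay model is I(t) = (1−C)·e^(−kt) + C with the plateau C free
in [0, 1), because normalized reporter currents visibly approach non-zero
floors (incomplete substrate depletion, channel background); a pure
exponential (C ≡ 0) is an option recorded in the result metadata.  Fits use
bounded Levenberg–Marquardt (trust-region reflective) with a log-linear
initial slope estimate and tight tolerances (1e-14), so noiseless data are
recovered to ~1e-7 relative.

**Cap rule.** If the *second* episode's normalized amplitude is below 1% of
the first, the decay is complete within one depolarization and fitting is
meaningless; the result is assigned τ = 0.065 s and k = 15.4 s⁻¹ (the
conventional cap for this protocol, reported exactly as printed — note
1/0.065 rounds to 15.4) with `capped=True`.  The rule looks only at episode
2, never at later episodes.

**Off-sensing charge.** The P/N estimate of leak and symmetric capacitative
current — N × the mean of the 1/N-scaled subsweeps — is subtracted from the
main sweep; the residual is baseline-corrected by its mean over the 5 ms
before the repolarization step and integrated (trapezoid; μA × ms = nC).
The default integration window runs from step onset until the transient
decays below 1% of its peak, which by construction leaves ~1% of an
exponential transient uncollected; a fixed window recovers essentially all
of it.  Constant offsets cancel in the baseline step and linear leak cancels
in the P/N step, so the estimate is invariant to both.

Cross-construct statistics use the classical equal-variance two-tailed
two-sample t-test (Welch as an option), Pearson and Spearman coefficients
for property associations, and replicate-wise normalization to the
reference construct's mean for in vitro assays.  No multiple-comparison
correction is applied; p-values are reported raw.

## Fluorometry

F–V points are extracted per test voltage by one of three strategies: mean
of the last 1 ms of the pulse (default for slow, saturating probes),
endpoint sample, or the sample at the peak time of a designated
reference-voltage trace (for probes whose signal is transient; the
reference trace is the dataset's own, e.g. the 200 mV sweep).  Optional
normalization divides all points by the value at the reference voltage even
when the curve has not saturated there; the reference is recorded in the
dataset metadata.

The Boltzmann model is the rising convention F(V) = A / (1 + exp((V½ −
V)/s)) with slope s constrained positive and signal direction carried by
the sign of A.  (The falling convention negates s; |s|, V½, A and the
midpoint identity F(V½) = A/2 are unchanged, so fitted parameters are
directly comparable between conventions.)  Two-component fits report the
amplitude ratios Aᵢ/(A₁+A₂)×100 and order components by V½.  Fitting is
bounded least squares with up to 16 multi-start jitters of a heuristic
initialization (V½ seeded from fractional-amplitude crossings of the
monotone envelope of the data, amplitudes from the inter-transition plateau
level), a fixed RNG seed for reproducibility, and early termination once
restarts stop improving the optimum.  Covariances come from the
Gauss–Newton approximation at the solution.

Model selection between one and two components uses small-sample corrected
AIC by default (with one extra free parameter counted for the noise
variance) and the extra-sum-of-squares F-test at α = 0.05 as an option;
both criteria's values are returned so the choice is auditable.  A caveat
documented here because it is easy to miss: when the smaller component
carries ~25% of the amplitude and the noise SD is ~3% of the total, the
best single-component fit differs from the two-component truth by only
~1.5% RMS on a 10 mV voltage grid, so *no* selection rule can be both
sensitive and specific — the extra-sum-of-squares noncentrality is ≈8,
giving ~60–65% power at α = 0.05, and the conditional V½ estimates of the
weakly identified component are biased by several mV.  Reliable two-
component resolution at such amplitude ratios needs either lower noise,
replicate averaging, or a several-fold denser voltage grid.

Kinetics: t½ is the first crossing of baseline + ½(extremum − baseline),
linearly interpolated between samples; exponential kinetics are fitted as
F(t) = Σ Aᵢ(1 − e^(−t/τᵢ)) after pulse onset with multi-start bounded least
squares, components ordered fast-to-slow, and the slow fraction defined as
|A_slow|/Σ|Aᵢ| × 100.

## Synthetic data

The generators produce exactly the geometry or signal structure the
analysis consumes, nothing more, so every downstream noiseless output is
predictable in closed form from the recorded `GroundTruth`:

* **Trajectories.** Two flat phosphorus lattices (6×6, 0.8 nm spacing,
  4 nm apart) form the bilayer; PD and C2 are rigid 10-atom blobs whose top
  atoms are placed 3 Å above (bound) or below (unbound) the system cutoff
  according to a per-frame schedule; the seven anchors sit on a rigid
  internal frame tilted to 15° (productive) or 90° (non-productive) and
  rotated randomly about z, which leaves the classification angle
  invariant.  Optional Gaussian jitter is validated against the worst-case
  classification margins (≥3σ) and rejected otherwise.  Schedules are
  either deterministic blocks hitting requested fractions exactly or
  two-state telegraph chains with closed-form stationary occupancy.  What
  this deliberately does *not* emulate: lipid disorder, membrane
  undulation, protein flexibility, or intermediate poses — passing tests
  show the classifiers are correct, not that the cutoffs are biologically
  optimal.
* **Kir recordings.** 20 episodes (ramp 50 ms, test pulse 50 ms, 300 or
  50 ms depolarization; 10 kHz sampling) with test-pulse amplitudes
  following the plateau-exponential decay; amplitude noise is one Gaussian
  draw per episode on the normalized scale (episode 1 exact, since it
  defines the normalization).  Default amplitude −10 μA, the scale of
  robust oocyte Kir currents.
* **Sensing sweeps.** An exponential transient of known total charge
  (default 25 nC over τ = 5 ms, typical of strongly expressing oocytes)
  over ohmic leak and a constant offset, stepped from +150 mV to −60 mV;
  P/N subsweeps carry the 1/N-scaled leak only.
* **F–V and fluorescence sweeps.** Boltzmann-sum curves on a −100…+200 mV,
  10 mV grid (on the dense end of practice) with additive Gaussian noise;
  sweeps rise from baseline as sums of exponentials scaled so the pulse-end
  value equals the generating F(V) exactly at zero noise.
* **In vitro plates.** Replicates drawn as truth × (1 + N(0, cv)) around a
  10 nmol reference phosphate release, 9 replicates by default.

Identical (parameters, seed) reproduce byte-identical datasets; every
generator's seed and parameters are serialized in its `GroundTruth`.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
these sizes, chosen to make sampling error small relative to the margins
being tested: 1000 random frames for classifier/oracle agreement, 200-frame
schedules (×4 systems) for occupancy exactness, 100 recordings for
decay-rate recovery, 100 datasets per ground truth for model selection, and
single datasets for the exact noiseless recoveries.

## Known limitations

* The trajectory generator's rigid geometry cannot probe classifier
  behaviour on genuinely ambiguous poses (top atom hovering at the cutoff);
  real trajectories will flicker near thresholds where the synthetic ones
  cannot.
* The decay model assumes a single well; biphasic substrate depletion (two
  activity states) would be mis-summarized by one rate constant.
* Model selection at Table-2-like amplitude ratios is power-limited at 3%
  noise (see the fluorometry caveat above); two-component parameters should
  be interpreted with their covariances, not as point values.
* ABF ingestion is not implemented; recordings enter via the documented CSV
  layout.
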