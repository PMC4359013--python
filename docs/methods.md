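# Methods

## The model

Under fast exchange between water pools (cross-relaxation much faster than
relaxation), the observed longitudinal relaxation rate is a pool-fraction-
weighted sum of pool rates, `R1 = Σ fᵢ R1ᵢ`. With the free-water pool
dominant and the macromolecular and iron pools entering through their
fraction × relaxivity products, substituting imaging surrogates — the
MT-saturation map for macromolecular content, R2\* for iron — yields the
voxelwise linear model

    R1(r) = β0 + β1·MT(r) + β2·R2*(r) + ε(r),

with one global coefficient triple per subject. β is the least-squares
solution of R1 = **M**β over pooled brain voxels, **M** having columns
(1, MT, R2\*). β0 estimates the free-water relaxation rate (T1 = 1/β0);
β1·MT is the bound-fraction × relaxivity product at macromolecular sites
(the `macromolecular_relaxivity` helper re-expresses it per unit bound
fraction, which must be supplied externally, e.g. from calorimetry); β2
absorbs the iron contribution and is the smallest and least stable term.

Key assumptions: fast exchange; MT saturation and R2\* are valid linear
surrogates for macromolecular and iron content; the coefficients are
spatially global (the residual map ε localizes everything the global model
misses — iron-rich deep gray matter, artifacts).

## Signal model and simulator

Spoiled gradient-echo (FLASH) steady state with mono-exponential echo decay:

    S(TE) = PD · sin α · (1 − E1)/(1 − cos α · E1) · exp(−TE·R2*),  E1 = exp(−TR·R1).

The MT prepulse removes a fraction δ = MTsat/100 of longitudinal
magnetization once per TR. With event order excite → saturate → relax, the
steady state before excitation is `Mz = (1 − E1)/(1 − (1−δ)·cos α·E1)`;
this closed form equals the per-TR Bloch recursion iterated to convergence
(verified in the tests by brute force) and reduces exactly to the plain
FLASH signal at δ = 0. The saturation-event placement within the TR is a
convention; the chosen order is exposed through `mt_flash_signal` so any
alternative recursion can be compared against it.

Default protocol (all values configurable): PDw 23.7 ms TR / 6° with 8
echoes at TE = 2.2 : 2.5 : 19.7 ms; T1w 18.7 ms / 20° and MTw 23.7 ms / 6°
with the first six echoes of the same grid (an 8-echo train would not fit
inside the 18.7 ms T1w TR). The mean of the first six echo times is
8.45 ms, recorded as the effective TE of the averaged volumes. The MT pulse
(4 ms, 220° nominal, 2 kHz off-resonance) is carried as metadata only; the
simulator parameterizes its effect directly by the per-TR saturation δ.
Perfect spoiling is assumed. Noise is additive zero-mean Gaussian per echo
volume — magnitude data from a multi-channel coil at high SNR is
near-Gaussian, but genuinely Rician/non-central-χ behavior at low SNR is
not modeled.

## Map estimation chain

1. **R2\***: per-voxel ordinary least squares of ln S against TE over the
   PDw echoes; slope = −R2\*. Voxels with any non-positive echo are NaN
   (excluded, not clipped, to avoid log-fit bias). A signal-squared-weighted
   variant is available behind a flag; the default is unweighted.
2. **Echo averaging**: arithmetic mean of the first six echoes per
   weighting. The residual R2\* attenuation is identical across weightings
   sharing an echo grid and therefore cancels in the ratio-based estimators
   below; it does attenuate the amplitude A (an apparent, TE-weighted PD).
   A TE = 0 log-extrapolation mode (`echo_treatment="te_zero"`) is provided
   for validation runs in which A must recover true PD.
3. **R1 and A**: rational small-flip-angle inversion of the Ernst equation
   from the PDw/T1w pair, with local flips α = b1_rel × nominal. On
   noiseless data at the default protocol this approximation is accurate to
   ≈ 1–2.5% in R1 (max 2.5% over the default phantom); that bias, not the
   least-squares fit, dominates the end-to-end coefficient error.
4. **MT saturation**: δ = (A·α/S_MT − 1)·R1·TR − α²/2, in percent units.
   Two transmit-field conventions are implemented. The conventional
   semi-quantitative definition evaluates the formula at the *nominal* flip
   and then applies the empirical correction
   δ_corr = δ·(1 − c)/(1 − c·b1_rel) with c = 0.4 (the literature
   calibration, which compensates the B1 dependence of the saturation pulse
   power in real acquisitions). Because this simulator deliberately models
   δ as a tissue property rather than modeling pulse power, the matched
   estimator for simulated data instead evaluates the formula at the
   B1-corrected local flip (`mt_b1_mode="flip"`, the pipeline default),
   which removes the B1 dependence at the source; the empirical path
   (`mt_b1_mode="empirical"`) is retained for nominal-flip workflows on
   real data. With the default pipeline the end-to-end MT error is ≤ 2.7%.
5. **MTR**: 100·(S_ref − S_MT)/S_ref with the averaged PDw volume as the
   MT-off reference (same nominal flip/TR as MTw in the default protocol;
   the reference choice is a documented convention).

## Masking and fitting

Voxels enter the fit when gray *or* white matter probability exceeds 0.5
and CSF probability is below 0.5 (both thresholds configurable; a display
convention of 0.3 on GM/WM — paired with 0.7 on CSF so the rule relaxes
monotonically — yields a superset of the 0.5 mask). Rows are ordered by
C-order flat voxel index; masked voxels with invalid regressors or invalid
R1 are dropped with logged counts. The solver is QR-type
(`scipy.linalg.lstsq`, `gelsy`); normal equations are reserved for the test
oracle. Designs with condition number above 1e8 raise an error naming the
most collinear column pair rather than returning a silent pseudo-inverse
answer. Normalized residuals are reported as 100·(measured −
synthesized)/measured — the denominator convention is a package choice —
so positive bias means the model synthesizes lower R1 than measured.
Pearson correlation is computed between **M**β and measured R1 over the
fitted voxels; exactly constant inputs are flagged degenerate (Pearson
undefined) rather than returning a spurious ±1.

## The phantom (what the generator emulates, and what it does not)

Four tissue classes on concentric ellipsoidal compartments (deep gray
matter core, white matter, cortical gray matter, CSF outermost — geometry
is irrelevant to a voxel-pooled fit, so no atlas is used). Default class
means are literature-plausible 3T values, chosen once and documented here
(no canonical table exists for them):

| class | R1 (s⁻¹) | PD (a.u.) | MT (p.u.) | R2\* (s⁻¹) |
| --- | --- | --- | --- | --- |
| white matter | 1.11 | 690 | 2.00 | 21 |
| cortical GM | 0.70 | 830 | 1.00 | 14 |
| deep GM (iron-rich) | 0.88 | 810 | 1.30 | 40 |
| CSF | 0.26 | 1000 | 0.02 | 1 |

The R1 means are additionally consistent (to rounding) with the three-term
model at the reference coefficients β = (0.2677, 0.3971, 0.0025), so
synthetic cohorts produce coefficients on the reported scale. Within-class
variation is an independent truncated-at-zero Gaussian per parameter
(default fractional SD 5%). `linked_brain_spec` instead *generates* R1
voxelwise from the model, making the generating coefficients exact ground
truth for recovery studies. Tissue probabilities are smoothed one-hot
labels renormalized to sum to one (tolerance 1e-9 everywhere); the relative
B1⁺ field is a smooth low-order polynomial ramp spanning 0.9–1.1 by
default, typical of 3T head transmit.

Not emulated: anatomical geometry, partial-volume mixing of tissue
parameters within a voxel (probabilities are smoothed but each voxel's
parameters are pure-class), susceptibility field maps, R2\* fiber-
orientation dependence, imperfect spoiling, motion, and Rician noise.
Passing tests therefore demonstrate correctness of the estimators and the
fitting machinery under the stated signal model — not robustness to those
real-data effects.

## Cohorts and model variants

A synthetic cohort perturbs every class-parameter mean multiplicatively
(Gaussian, default fractional SD 3%) per subject, shares one anatomical
template (so a cohort with zero perturbation and zero noise yields
identical coefficients by construction), and draws independent acquisition
noise (default SD 0.5 a.u., ≈ 1% of the mean PDw signal). Default cohort
size is 20 — population spread is summarized by mean, sample SD (n−1) and
CoV = 100·SD/mean, which makes the summaries exactly recomputable from the
per-subject table. Variant comparison fits the full model, intercept+MT
(iron ablation) and MTR-surrogate designs on identical masks and reports
per-variant Pearson, residual summaries and the residual-difference map
|ε_no-iron| − |ε_full|, which highlights the iron-rich class whenever the
generating β2 > 0. The MTR-vs-B1 structure comparison is made at a
realistic noise level: on exactly noiseless data the full model's
residuals consist solely of the smooth approximation bias of the
estimators, which itself tracks B1 and would dominate the comparison.

## Numerical choices and degenerate inputs

- Units: TR/TE in ms at every API boundary, rates in s⁻¹, flips in degrees
  externally and radians internally; all conversions in `units.py`.
- Invalid voxels are NaN throughout and dropped (with logged counts) at the
  design-matrix and fit stages; denominators are flagged at 1e-9 relative
  to the magnitude of their terms.
- The B1 correction factor is computed before multiplying so b1_rel = 1 is
  an exact fixed point; seeded generators (`numpy` `default_rng` /
  `SeedSequence.spawn`) make every simulation bit-reproducible, and all
  derived seeds stay below 2³¹.
- Problem sizes used by the test suite and the reproduction script — 32³
  phantoms, 20-subject cohorts on 20–24³ grids, 10⁵-voxel recovery
  replicates — were chosen as comfortable desk-scale sizes at which the
  Monte-Carlo error of every checked quantity is far below its tolerance.

## Known limitations

- The rational dual-angle approximation biases R1 (and hence β0) by a few
  percent at the default flips; an exact Ernst inversion is deliberately
  not substituted, since the approximation is part of the method being
  modeled.
- The empirical MT/B1 correction constant c = 0.4 is a literature value for
  real pulse sequences; it is not recalibrated for the simulator (see the
  `mt_b1_mode` discussion above).
- β2 is reported dimensionless; its instability under noise and
  between-subject perturbation is a property of the model, reproduced but
  not mitigated here.
- The exact arithmetic behind a literature white-matter relaxivity value
  cannot be reproduced without the external calorimetric bound fraction, so
  `macromolecular_relaxivity` is parameterized rather than fixed.
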