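# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic-data generator does and does not emulate.

## The measurement and its preprocessing

Spectra are absorbance readings on a fixed wavelength grid; the default
synthetic grid has 125 evenly spaced channels over 908–1,670 nm
(step ≈ 6.145 nm), matching a portable instrument with roughly 7 nm
resolution. Analysis is restricted to the first overtone of water,
1,300–1,600 nm, where the O–H stretch overtones of the different water
molecular conformations absorb.

**SNV.** Each spectrum is standardised to zero mean and unit standard
deviation across channels (sample, *n*−1 denominator — used consistently for
every standard deviation in the package). SNV removes per-spectrum additive
offsets and multiplicative scatter exactly (`snv(a·x + b) = snv(x)`, a > 0);
a linear baseline tilt is removed only to first order. A spectrum whose
spread is at floating-point round-off level (`sd ≤ 1e−12·max(1, |mean|)`) is
rejected as degenerate rather than amplified into noise.

**Difference spectra.** `avg(S_target) − avg(S_reference)` per channel,
computed on SNV-treated spectra of one condition. The reference day is
configurable between day 0 (pre-storage) and day 1 (first day in storage);
the default is day 1, so differences reflect changes *during* storage rather
than the step into the fridge. Day-0 references are useful for quantifying
that step itself.

**Per-wavelength standardisation (aquagram normalisation).** Channels are
z-scored across *all* spectra of the dataset — both storage conditions and
all days pooled — so that the aquagram profiles of the two conditions share
one scale and are directly comparable. The plausible alternative reading
(per-spectrum vector normalisation) was not adopted; the z-score form is the
classical aquagram convention.

## Weight statistics

Weight loss rate is `(W_f − W_s)/W_f × 100` with `W_f` the fresh (day 0)
weight; it is scale-invariant per fruit. Daily weight change is
`weight(day) − weight(day−1)` in grams. The condition comparison is a
pooled-variance two-sample t-test (df = n₁ + n₂ − 2): fruits in the two
fridges are different individuals, so fruit-wise pairing across conditions
is not defined; a paired variant (`paired_ttest`) is provided for day-wise
pairing of group means. Apparent weight gain (balance noise) yields a
negative loss rate plus a warning, not an error.

## SIMCA

One PCA submodel per class (storage day), each centred on its own class
mean. The retained rank k_c is the smallest number of components explaining
≥ 95% of class variance, capped at min(5, n_c − 2) and at least 1 — the rank
rule is a package choice since per-class ranks are rarely reported and
vendor defaults are not public.

Residual variances carry the classical SIMCA degree-of-freedom corrections:
fitting a k-component model to its own n samples leaves (n − k − 1)(p − k)
residual degrees of freedom, while a foreign sample keeps (p − k). Without
this correction the in-sample optimism of the class PCA inflates every
cross/self variance ratio (two identical classes would score a spuriously
positive distance). Per-channel variances are scaled so their channel mean
equals the pooled value.

With s²_ij the (pooled or per-channel) residual variance of class-i samples
under the class-j model:

- interclass distance `d_ij = sqrt((s²_ij + s²_ji)/(s²_ii + s²_jj)) − 1`,
  ≈ 0 for indistinguishable classes. The −1 offset is a convention choice;
  vendor implementations differ, so literature thresholds ("distance > 1 is
  meaningful") are treated as qualitative.
- discriminating power
  `DP(λ) = sqrt( Σ_{i<j} (s²_ij(λ) + s²_ji(λ)) / Σ_i s²_ii(λ) )`, summed over
  unordered class pairs so two identical classes give a flat profile ≈ 1.
  Channels with zero within-class residual variance are floored at machine
  epsilon with a warning.

Classification assigns the class with the smallest standardised residual
distance (RMS residual over the class's own residual SD); this argmin rule,
with no reject class, is what classification accuracy counts. Separately, a
`no_match` flag marks samples whose residual variance ratio exceeds the
F-based critical limit at α = 0.05 (df₁ = p − k, df₂ = (n − k − 1)(p − k)).
SIMCA consumes raw (non-SNV) spectra: scatter and baseline variation are
real class information here and the class PCA absorbs them.

Two properties of the method worth knowing: (i) within-class variance that
lies *along* a between-class difference direction is absorbed into the class
models and removed from both numerator and denominator of DP, so
discriminating power localises mean differences best when the within-class
nuisance is unstructured (offsets, tilts, white noise); the localisation
tests use exactly that regime. (ii) On the full default design, adjacent
storage days overlap substantially, and day-classification accuracy
(~50–60% over 15 classes) is correspondingly moderate even though distant
days separate cleanly — consistent with a ~1.6-day regression error on the
same data.

## PLSR

PLS1 on mean-centred raw spectra against centred days-of-storage, computed
by NIPALS (closed-form per component for a single response; no iteration,
fully deterministic). The regression vector for a components is
`b = W (PᵀW)⁻¹ q`. Metrics: SEC = sqrt(RSS/n), R²c = 1 − RSS/TSS,
SECV = sqrt(PRESS/n), R²cv = 1 − PRESS/TSS.

Cross-validation leaves out contiguous blocks of six spectra in acquisition
order ("stepwise exclusion of six"); with the synthetic row order a block is
exactly the six spectra of one fruit-day, so validation is leave-fruit-day-
out. A trailing short block is kept. A venetian-blind (interleaved) variant
is available behind `method="venetian"`. The rank is chosen by minimum SECV,
capped at 15 latent variables.

The visual "jaggedness" screen against overfitting is automated as a
roughness statistic — the sum of squared second differences of the
regression vector over its squared norm; a model more than 10× rougher than
its own 2-LV baseline is flagged (`jagged_flag`), never rejected.

Day-0 spectra: both analysis windows are explicit day lists; the presets use
days 1–4 (and 1–8) for the short windows and 0–14 for the full run, so
day-0 inclusion is a configuration fact, not a hidden default.

## WAMACS and band importance

The package ships (a) the WAMACS region catalog — ranges C1–C12 in the
first overtone plus four tentative single-wavelength coordinates Ci–Cl at
1,503, 1,528, 1,534 and 1,559 nm — and (b) a 28-band inventory of
storage-relevant bands with occurrence counts, plus a functional annotation
lookup for the 20 axis bands. Some inventory bands sit a few nm outside the
nominal range of the region they are conventionally assigned to (e.g.
1,391 nm vs C5's 1,396–1,403 nm); the inventory therefore carries its own
label column, while `assign_wamacs` for new bands uses strict range
containment plus a 3 nm tolerance to the tentative coordinates. Adjacent
regions sharing an endpoint (C10/C11 at 1,482 nm) are tolerated; a band on
the shared endpoint goes to the lower region.

Peak picking uses local extrema of |v| with prominence ≥ 5% of the maximum
(conservative; recovers all generator-injected bands in tests). Importance
is the number of *distinct* analyses citing a band. Aquagram axes derived
from a tally keep every band cited at least twice plus any tentative
coordinate, deduplicated to one representative per WAMACS region (highest
importance wins, lower wavelength breaks ties) — a package rule, since the
underlying axis-selection procedure is only loosely specified in the
aquagram literature.

Because 1,521 and 1,528 nm carry identical functional descriptions, two
axis presets exist: the full 20-band list and a 19-band list dropping
1,521 nm; the 20-band preset is the default.

## Aquagrams

Pipeline: SNV → pooled per-wavelength z-score → average per
(condition, day) → subtract the condition's reference-day average →
evaluate at the axis channels (each nominal band snapped to its nearest
channel; two axes snapping to one channel is an error). The reference-day
profile is identically zero by construction, profiles are invariant to
per-spectrum offset and gain, and swapping reference and target days negates
a profile.

Profile comparison reports cosine similarity and RMS difference. The
best-matching-day search defaults to minimum RMS: aquagram magnitude grows
with time in storage, so the scale-free cosine discriminates neighbouring
days worse than RMS. The lag estimator averages `target_day − best_match`
over target days 5–9, trading a little bias resolution for much lower
variance than a single-day argmax.

## Synthetic data generator

Each spectrum is
`gain · [background + Σ_b amp_b(condition, day, fruit) · N(λ; centre_b, width_b)] + offset + slope·(λ − λ̄) + noise`,

with a broad first-overtone background (Gaussian at 1,450 nm, σ = 75 nm,
amplitude 1.1, plus a smaller 1,190 nm shoulder) and one Gaussian per
inventory band (σ = 9 nm, base amplitude 0.12 — widths chosen so bands
overlap realistically on the 6.145 nm grid and peak picking is non-trivially
exercised). Band amplitudes follow piecewise-linear day trajectories per
condition encoding the observed storage dynamics: a rise to day 4 then fall
at 1,373 nm (vapour-like water, larger peak under the electric field),
monotone free-water decline at 1,404/1,410 nm (steeper in the control
fridge at 1,404, steeper under the field at 1,410), a control-only rise of
the bulk-water bands 1,428–1,497 nm after day 4, a step increase at
1,503 nm upon entering storage in both conditions, and a control-only late
decline of the strongly-bound-water bands 1,521–1,559 nm.

Nuisance terms: per-spectrum offset (sd 0.02), tilt (sd 3·10⁻⁵ per nm), gain
(sd 0.03) and white channel noise (sd 0.003) — the family SNV is designed to
remove; a per-fruit multiplicative factor on the trajectory amplitudes
(sd 0.15) and a per-(fruit, day, band) amplitude jitter (sd 0.012) shared by
the six spectra of a fruit-day — the biological variation that actually
limits day prediction. The jitter scale was calibrated once, by simulation
at the full design, so that cross-validated day prediction lands near the
~2-day error scale reported for this kind of data (it comes out ≈ 1.6–2.1
days per condition), and then frozen.

Weights follow `W(f, d) = W(f, 0) · (1 − rate·d + ε_d)` with per-fruit fresh
weights around 20 g (sd 12%), daily loss-fraction noise sd 0.0097, and rates
calibrated to day-7 mean losses of ≈ 7.3% (CF) and ≈ 5.9% (SCF) — the
reported anchor values for the two cooling systems.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning: stream 0 for spectra, stream 1 for weights, each split per
condition, so each product is reproducible in isolation. Identical seeds
give bit-identical outputs.

Two derived configurations support comparison experiments:
`identical_conditions_config()` (SCF trajectories replaced by CF's — a null
configuration) and `delayed_config(lag)` (SCF follows CF's trajectories
delayed by `lag` days, clamped at day 0 — the construction behind the
ripening-delay analysis).

**What the generator does not emulate:** physical radiative transfer or
scattering, instrument nonlinearity, temperature-dependent band shifts,
fruit-surface curvature effects, day-level session effects shared across
fruits, and microbial spoilage events. Passing tests therefore demonstrate
that the analysis chain recovers the statistical structure it assumes —
trends, group differences, localised band changes under realistic nuisance —
not that it would survive every artefact of a real instrument campaign.

## Problem sizes and determinism

Simulation-backed tests use reduced designs (typically 4–8 fruits, one
position, 1–2 replicates) where group-level behaviour is being probed, and
the full 2,160-spectra-per-condition design where the claim concerns the
study scale (design counts, day-prediction error, the difference-spectrum
minimum, the lag estimate). Monte-Carlo suites run 20–100 replicates with
fixed seeds; every statistical assertion is made on a seeded, deterministic
sample. The pipeline report is serialised with sorted keys and rounded
floats so identical seeds yield byte-identical JSON.

## Known limitations

- The SIMCA conventions (rank rule, distance offset, F-limit) match common
  practice but not any specific vendor implementation bit-for-bit; absolute
  distance values should be compared only within this package.
- Interclass distances and discriminating power assume classes of broadly
  similar size; strongly unbalanced designs will weight the pooled residuals
  accordingly.
- The aquagram lag estimator assumes the two conditions traverse a similar
  trajectory at different speeds; it has no meaning for qualitatively
  different dynamics.
- The t statistic comparing day-7 weight loss depends on the loss-noise
  scale; with the calibrated means and noise the synthetic t is larger than
  literature values printed alongside similar means, whose pairing scheme is
  typically under-documented.
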