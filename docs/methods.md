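# Methods

## The recommendation model

The package implements the SPAD-anchored sensor algorithm for
in-season nitrogen recommendation in wheat. Its ingredients:

**Sufficiency indices.** Every reading — SPAD chlorophyll meter or
canopy sensor NDVI — is normalized against a well-fertilized reference
strip: SI = target / reference. SI = 1 means N-sufficient; values
below 1 signal deficiency; values above 1 (target greener than the
reference) are legitimate and are passed through, with a configurable
soft cap (default 2.0) that flags, never clamps. The default reference
rule takes the per-stage mean of the plots at the highest applied N
rate in the trial (150 kg N/ha in the standard design), on the grounds
that those plots are the closest thing to a non-limiting strip the
trial contains. Any frame that already carries `si_spad` / `si_sensor`
columns (normalized upstream against a dedicated strip) bypasses the
rule.

**Quadratic SPAD response.** Across an N-rate trial the SPAD
sufficiency index follows a concave quadratic in applied N,

    SI_SPAD = a0 + a1·N + a2·N²,   a2 < 0.

`a0` is the zero-N sufficiency, and the vertex N* = −a1/(2a2) is the
rate that maximizes SI (`nrate_max`), with maximum SI_max =
a0 − a1²/(4a2). Inverting the ascending branch gives the rate that
produces a measured SI, and the recommendation is the deficit to the
vertex:

    N_app(SI_SPAD) = N* − N(SI_SPAD) = √((SI_max − SI_SPAD) / |a2|).

**Linear bridge.** Sensor and SPAD sufficiency indices are related
linearly, SI_SPAD = b0 + b1·SI_sensor with b1 > 0. Substituting the
bridge into the deficit formula collapses the chain into the
two-constant field algorithm

    N_app = R·√(SI_R − SI_sensor),
    R = √(−b1/a2),
    SI_R = (4·a2·a0 − a1² − 4·a2·b0) / (4·a2·b1),

where SI_R is the sensor SI at which the recommendation reaches zero.
The square root is essential: R carries units of kg N/ha per unit
√SI, and the published booting constant 51.89 equals
√(1.616/0.0006) to four significant figures, which confirms the
radical form. The equivalence of the two routes (quadratic inversion
composed with the bridge vs. the parametric closed form) is verified
numerically over thousands of random concave calibrations; it holds to
relative 1e−9 with an absolute floor of ~R·√ε from cancellation at the
vertex.

**Branch and clamping choices.** The quadratic has two roots per SI
value; the ascending-branch root (≤ the vertex) is the physically
meaningful one — the descending branch would make the recommendation
negative. Field SI values routinely leave the calibration envelope, so
out-of-range inputs clamp rather than raise: SI above SI_max returns
the vertex rate with a warning, rates clamp to [0, N*], and the
parametric form returns 0 at or above SI_R. `clamp=False` exposes the
raw algebra for verification. Recommendations are reported to 0.1 kg
N/ha; internal math is full precision.

**SN lookup mode.** The alternative recommendation path maps raw
sensor values (SN, the instrument's unitless crop-status score)
directly to rates through per-stage anchor tables. The published
anchors are bands: tillering 7–11 → 75 and 33.1–37 → 45 kg N/ha;
booting 17–24 → 40 and 76.1–84 → 25 kg N/ha. Inside a band the rate is
exact; between bands the package interpolates linearly between the
flanking (band midpoint, rate) pairs, because no finer binning was
published; outside the table the nearest anchor's rate is returned
with an extrapolation warning. Interpolated and extrapolated values
are flagged in pipeline output.

## Published fixtures and their internal inconsistencies

The published stage calibrations are stored verbatim:

| stage | a0 | a1 | a2 | b0 | b1 | R | SI_R |
|---|---|---|---|---|---|---|---|
| tillering | −0.047 | 0.2649 | −0.00013 | −0.0056 | 1.0461 | 87.17 | 1.35 |
| booting | 0.542 | 0.003 | −0.0006 | −0.608 | 1.616 | 51.89 | 1.33 |

These sets are not mutually consistent, and the package does not
pretend they are:

- the tillering quadratic evaluates to SI_SPAD ≈ 36 at 150 kg N/ha —
  a sufficiency index on an implausible scale (likely a misprint);
- the vertex rate −a1/(2a2) gives 1019 (tillering) and 2.5 (booting)
  kg N/ha, neither the 150 the response curves suggest;
- R derived from the tillering coefficients is 89.7, not 87.17
  (consistent with a2 having been rounded from ≈ −0.000138);
- the published SI_R values (1.35, 1.33) cannot be recovered from the
  coefficient sets; the derived booting value is 0.714.

Consequently `published_coefficients` (raw coefficient sets) and
`published_algorithm` (the deployable R, SI_R constants) are separate
fixtures with separate provenance, and only relations that actually
hold — such as R(booting) = √(−b1/a2) — are asserted anywhere.

## Calibration fitting

Both models are fitted by ordinary least squares (no weighting, no
robust loss, no block effects) on per-plot SI values. A quadratic fit
needs ≥ 3 observations at ≥ 3 distinct rates; the bridge needs ≥ 2
distinct abscissae; rank deficiency raises. Non-concave quadratics
(a2 ≥ 0) and non-positive bridge slopes warn at fit time — exploratory
fits stay inspectable — but raise (`DerivationError`) when passed to
algorithm derivation. R² is reported per fit; a constant response is
defined to have R² = 0 (no variance to explain). Fits are verified in
the test suite against an independently coded normal-equations solver
to 1e−9.

## The synthetic trial generator

`trial_synth` emulates the trial the calibration assumes: 6 N levels
(0–150 kg N/ha) × 3 replicate blocks × 3 growth stages = 54
observations, urea split 50 % basal / 25 % / 25 % at the first two
irrigations. It generates on the SI scale and maps outward, because
the algorithm chain never consumes raw spectra; simulating full
600–1100 nm scans would add surface without testable benefit.

Default generating model, per stage:

- SI_SPAD(N) concave with the vertex pinned at 150 kg N/ha and
  SI_max = 1, with the zero-N SI rising with crop age (0.55 at
  tillering, 0.64 at booting, 0.73 at ear emergence) — older canopies
  show less contrast;
- the published bridges for tillering and booting, identity for ear
  emergence;
- SPAD = 50 · SI_SPAD (the reference SPAD of 50 is an arbitrary
  plausible constant and cancels in every SI computation);
- NDVI = reference NDVI (0.70 / 0.78 / 0.80 by stage) × sensor SI;
- SN and biomass affine in NDVI, on scales matching the instrument's
  reported per-stage ranges (SN ≈ 7–37 at tillering, ≈ 20–84 at
  booting);
- lab leaf N (%) = 1.2 + 2.0·SI, lab chlorophyll (mg/g) =
  0.8 + 1.8·SI, both from the *true* SI plus assay noise;
- yield (t/ha) = 2.2 + 3.5·(1 − (1 − N/150)²) + block effect, drawn
  once per plot (a plot has one harvest), plus noise.

Because every channel is affine in the common signal (N − 150)² when
noiseless, all per-stage attribute–target correlations are exactly ±1
at zero noise, and the OLS fits recover the generating coefficients to
machine precision — the generator and the fitters are exact inverses.

Noise is Gaussian per attribute with stage-specific standard
deviations that grow from tillering (sensor SI σ 0.010) through
booting (0.030) to ear emergence (0.055), alongside growing assay
noise. This encodes the observed field pattern that tillering is the
most predictive sensing stage; under the defaults the
sensor-value/yield correlation at tillering exceeds the ear-emergence
one in ≥ 90 % of seeds (empirically ~0.97 vs ~0.86 on 18-plot stages,
matching the qualitative field ordering 0.94 vs 0.85). SPAD SI noise
is 0.02 everywhere.

Instrument and assay outputs (SN, biomass, lab values, yield) are
floored at zero, as the real devices report. The calibration-carrying
channels (SPAD, NDVI) are never clipped: the `paper_*` presets apply
the published coefficient sets verbatim to all stages, which drives
those channels outside physical range (negative SPAD at high N under
the booting set); the generator warns and keeps the values, so
noiseless recovery of the printed coefficients stays exact. Validation
of physical range is instead enforced at CSV read time.

Randomness is counter-based: each draw seeds a fresh generator from
the tuple (seed, replicate, N level, stage, attribute), so output is
reproducible, independent of loop order, and stable under adding new
attributes.

What the generator does *not* emulate — and hence what passing tests
do not show about real data: spatial field structure and within-plot
variance, weather and phenology dynamics, sensor view-angle and
irradiance effects, non-Gaussian and heteroscedastic instrument error,
and any genuine nonlinearity between sensor attributes and lab
chemistry. The correlation-ordering test validates the machinery and
the qualitative stage ranking, not the published correlation
magnitudes, which derive from field data this package cannot access.

## Analysis machinery

Pearson r uses the standard product-moment estimator with two-sided
p-values from the t transform on n − 2 degrees of freedom (via
scipy), verified against a covariance-ratio oracle to 1e−12; constant
inputs raise rather than returning NaN. The correlation table has one
cell per attribute × target × stage plus pooled "overall" rows; the
pooled rows concatenate raw observations across stages rather than
averaging per-stage r values (the natural reading of an overall
column; documented as an assumption). Cells with under 3 usable rows
are flagged, not fatal. No multiple-testing correction is applied —
the tables report raw p-values. Trend fits are OLS polynomials
(default quadratic) against N rate with R² verified against
1 − SSE/SST.

## Pipeline and formats

Observation CSVs carry one row per plot × stage with columns
`plot_id, replicate, stage, n_rate, spad, sn, biomass, ndvi, lab_n,
lab_chl, yield_t_ha`; unknown columns are preserved but ignored.
Stages are canonical lowercase tokens (`tillering`, `booting`,
`ear_emergence`); days-after-sowing and sensor growth-stage codes
(`55DAS`, `28`, …) are accepted as aliases. Reads are fail-fast with
row numbers in diagnostics; NDVI must lie in [−1, 1]. All rates are kg
N/ha and all indices dimensionless — no unit-conversion layer.

Calibration artifacts serialize to JSON (sorted keys) and round-trip
byte-identically; on load the stored (R, SI_R) are recomputed from the
stored coefficients and must agree to 1e−9, so a hand-edited artifact
cannot silently decouple its constants from its fit. Provenance
records the input file hash, timestamp and reference values. Every
number in a recommendation CSV is reproducible by calling the module
operations with the artifact's coefficients.

The `nsensor` CLI is a thin layer over these functions
(`geometry`, `simulate`, `calibrate`, `derive`, `recommend`,
`correlate`, `run-pipeline`); warnings (extrapolation, non-concavity)
propagate to output flags and never silently alter values.

## Numerical and scale choices

Monte-Carlo checks run at sizes chosen to keep the full suite fast
while leaving comfortable statistical margin: 500 seeded replicates
for the a2 bias check (mean bias well under the 10 % bound at SI noise
0.02), 200 seeds for the correlation-ordering check, ≥ 1000 random
coefficient sets for path equivalence. Identity checks on the
quadratic inversion use relative 1e−9 with an absolute floor of 1e−4
kg N/ha to absorb √ε-scale cancellation at the parabola vertex.

## Known limitations

- The reference-strip rule (mean of highest-N plots) is a pragmatic
  stand-in for a dedicated non-limiting strip; if the highest trial
  rate is itself deficient, SI values are inflated and SI_R shifts.
- The published tillering calibration cannot be used quantitatively
  (scale misprint, see above); only the booting chain closes
  numerically end to end.
- SN lookup between published bands is linear interpolation on band
  midpoints — a modelling choice, not published behaviour.
- No economic-optimum adjustment, soil-test integration, yield-goal
  capping, spatial smoothing or prescription-map export.
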