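# Methods

## Conservative mixing framework

The aquifer is modelled as a two-end-member mixing system: meteoric
freshwater (MFW) and saline groundwater (SGW), indexed by a conservative
tracer.  The tracer is chloride; salinity is an exact linear rescaling
(chloride in mg l⁻¹ × 0.0018066), so the mixing fraction

    f = (T_SGW − T_MIX)/(T_SGW − T_MFW)

is identical whichever of the two is used, and the package accepts either
(chloride is authoritative when both are present, with a 5 % cross-check
warning).  Conservative concentration is the linear blend
C_MIX = f·C_MFW + (1−f)·C_SGW; the conservative isotope value is the
concentration-weighted blend δ_MIX = (f·C_MFW·δ_MFW + (1−f)·C_SGW·δ_SGW)/C_MIX.
Samples whose tracer falls outside the end-member bracket get f outside
[0, 1]; the value is flagged, never clamped, and extrapolated evaluation
of a mixing line must be requested explicitly.

Per sampling event, two mixing lines are built for each constituent: the
lowest fresh with the lowest saline end-member concentration, and the
highest with the highest.  The mixing field (envelope) is the pointwise
minimum/maximum over all event lines on a tracer grid — 200 points,
linear in tracer, since mixing is linear in tracer and log axes on the
published diagrams are presentation only.  Interpolation between grid
points is linear.  A brackish measurement below the field indicates
consumption, above it production; a measurement within k·σ of a bound
(σ = replicate analytical error, k = 1 by default) is called
conservative, because plotted symbols carry that uncertainty.  An
additional ~1e−9 relative slack absorbs grid round-off so a point exactly
on a line is conservative.

Net removal in the brackish layer is

    % consumed = (C_MIX − C_MBW)/C_MFW × 100

with C_MIX at the brackish tracer value.  The denominator is the fresh
end-member inventory, so the statistic reads "fraction of the delivered
constituent consumed".  Negative values (net production) are returned and
flagged, not clipped.  Two averaging modes exist: *pooled* (water-mass
means across all events — the default reporting mode) and *per-event*
(statistic per event, then averaged).  With one event they coincide; with
event-resolved end members they differ, and both are reported.

DIC in the brackish layer typically sits *above* the mixing field; the
package reports the excess (mean brackish DIC minus the envelope's upper
bound) but deliberately attributes no source to it — respired CO₂ and
carbonate dissolution are not separable with these data alone.  Sulfate is
run through the same machinery as a conservative control.  Note the
percent-consumed statistic is ill-conditioned for constituents whose
fresh-water inventory is tiny relative to the saline one (sulfate):
measurement noise in the brackish mean divides by a small C_MFW, so for
such constituents the sample-level envelope classification, not the pooled
percentage, is the meaningful output.

## Trophic two-source mixing

A consumer's bulk δ¹³C is a linear blend of a methane end member
(δ¹³C = −66.3 ± 0.7 ‰, fresh-water microbial methane) and a soil-OM end
member (δ¹³C = −28.0 ± 0.1 ‰, fresh-water DOC standing in for soil
organic matter).  No trophic-enrichment offset is applied and the (small)
fractionation by the intermediary methanotrophs is deliberately ignored.
Raw fractions outside [0, 100] % arise for specimens isotopically heavier
than the OM source; the default clamps to [0, 100] and retains the raw
value, and the population summary (min/max/mean, insects excluded by a
taxon filter) averages clamped values — consistent with reporting a
dietary range that starts at 0.  Both choices are switchable.

The δD source extrapolation fits consumer δD against δ¹³C and evaluates
the line at the methane δ¹³C end member.  Default fit is ordinary least
squares; a reduced-major-axis option exists because both axes carry error
(for data generated by exact two-source mixing the two coincide).  The
interval is a bootstrap percentile band over specimen resamples
(B = 1000, seeded).  Strictly, hydrogen-pool mixing is linear in the
hydrogen fraction, not the carbon fraction; treating the (δ¹³C, δD) cloud
as one line is the same linearisation the synthetic generator uses, and
it is exact when both isotope systems mix with the same fraction.

## Halocline detection

A halocline is a maximal run of inter-record intervals whose salinity
gradient magnitude is at least a threshold (default 1 psu m⁻¹, well below
the ≥4 psu m⁻¹ implied by the observed 20–60 cm steps and well above
open-water background), merged across gaps shorter than 0.3 m.  The two
intervals with the largest total salinity step are labelled H1 and H2 in
top-down depth order; extras are returned unlabelled.  Detection recovers
a generated step's depth to within half the profile resolution whenever
the step gradient is at least twice the threshold.

## Water-mass classification

The observed salinity ranges (0.3–0.7, 2.0–2.5, 34.8–37.6 psu) are
bracketed by default cutoffs MFW ≤ 1 psu < MBW ≤ 10 psu, SGW > 30 psu,
with 10–30 psu left UNASSIGNED (the mixing interface; nothing in the
stratified column actually lives there).  POOL and SEA labels can only
come from metadata — a cenote pool at ~1 psu is indistinguishable from
MFW by salinity alone.  Cutoffs are configurable.

## Synthetic scenarios

The generator's defaults *are* the study conditions: water-mass tracer
values 0.26/1.81/32.87 psu; end members at the fresh/saline water-mass
means (CH₄ 6466/110 nM, DOC 661/41 µM, DIC 4.4/2.4 mM, SO₄ 0.3/26.4 mM,
with their δ¹³C values); 8/29/13 samples per water mass; per-variable
Gaussian noise with standard deviation = published standard error × √n
(i.e. the water-mass standard deviation), independent across variables
since no covariances are reported.  Brackish-layer removal multiplies the
conservative expectation by (1 − r); the default r pins expected brackish
CH₄ and DOC at their observed means (157 nM, 131 µM), giving expected
removal percentages of 92.9 % and 75.7 %.  `removal_for_target_percent`
inverts the chain for calibrated scenarios.  Residual methane δ¹³C
follows the closed-system Rayleigh approximation δ ≈ δ_mix + ε·ln(1−r)
with ε = −15 ‰ by default, inside the range typical of aerobic
methanotrophy; ε is configurable because no system-specific value is
constrained.  Generated mixing fractions are clamped to [0, 1]: a sample
drawn (by tracer noise) beyond an end member takes that end member's
composition rather than an unphysical extrapolation.  Concentrations are
truncated at zero after noise; at default noise this is a rare-tail event
for fresh-water DOC only.  POC is drawn around per-water-mass means as an
observational variable — it is not part of the mixing model and exists to
feed the DOC:POC partition.  Sonde casts are piecewise-linear salinity
ramps (default steps at 7 and 20 m, 0.4 m thick, layers 0.5/2.2/35 psu,
0.05 m resolution) with the two observed dissolved-oxygen regimes
(invariant vs gradient brackish layer).  Consumers take true methane
fractions (given, or uniform on [0, 0.55]), blend both isotope systems
linearly by that fraction from sources (−66.3, −390) and (−28.0, −96) ‰,
and add analytical noise (0.04 ‰ δ¹³C, 1.9 ‰ δD).

Every generated table carries a sidecar with the full scenario and the
expected value of each downstream estimate, so recovery tests score
against generator truth only.  What the generator does *not* emulate:
event-to-event variability of end members (one event per table),
covariance between solutes, DOC–methane coupling, rainfall-driven regime
shifts, and the heavier-tailed error structure of real field data.
Passing recovery tests therefore demonstrates the correctness and
statistical calibration of the inference chain under the stated noise
model, not robustness to real-world structure violations.

## Numerical choices and edge cases

- Mixing-line evaluation beyond the end-member bracket can cross zero
  concentration, where δ is undefined; those grid points are NaN and the
  δ envelope uses NaN-aware min/max.
- Degenerate end members (equal tracers), zero fresh-water inventory in
  the consumption statistic, identical isotope sources, < 3 specimens or
  zero δ¹³C variance in the regression, and empty inputs all raise a
  validation error rather than returning NaN.
- Reports carry full-precision values plus display-rounded percentages
  (0 decimals); JSON is written with sorted keys so identical inputs give
  byte-identical reports.
- Classification boundaries: salinity exactly at a water-mass cutoff
  belongs to the fresher mass; a measurement exactly on an envelope line
  is conservative.

Problem sizes throughout (sample counts, 100-seed recovery ensembles,
12–29 specimen regressions, 1000 bootstrap resamples) match the scale of
the emulated field campaign; the full suite runs in a few seconds on one
CPU.

## Known limitations

- The per-event averaging mode is implemented but the package bundles no
  event-resolved end-member data, so pooled mode is the default reporting
  path.
- The two-source dietary model has no trophic fractionation, no
  concentration-dependence and no third source; it is a first-order
  attribution, not a Bayesian mixing model.
- The δD extrapolation inherits the shared-fraction linearisation; with
  differing C:H stoichiometry between sources the true mixing curve bends
  and the OLS estimate would be biased accordingly.
- No reactive-transport modelling: the consumption statistic is a net
  mass-balance deficit, silent about rates and locations.
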