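# karstmix

Conservative-mixing and stable-isotope inference for density-stratified
karst subterranean estuaries.

Coastal carbonate (karst) aquifers host a stratified "subterranean
estuary": a meteoric freshwater lens (MFW, ~0.3 psu) over a meteoric
brackish layer (MBW, ~2 psu) over intruding saline groundwater (SGW,
~33 psu), separated by haloclines only tens of centimetres thick.  Methane
and dissolved organic carbon (DOC) produced from soil organic matter enter
with the fresh water; methanotrophic and heterotrophic bacteria consume
them in the brackish layer; filter-feeding cave shrimp eat the bacteria.
`karstmix` implements the quantitative chain that turns water-column
chemistry and consumer isotope values into estimates of that carbon flow.
It is written for groundwater geochemists and ecosystem ecologists working
with anchialine (coastal subterranean) systems, but the machinery is the
generic end-member mixing toolkit of estuarine chemistry.

## The model

A non-reactive solute mixes linearly in the conservative tracer (chloride,
expressed as salinity via the fixed factor 0.0018066 psu per mg l⁻¹ Cl⁻):

```
f_MFW = (S_SGW − S_MIX) / (S_SGW − S_MFW)
C_MIX = f_MFW·C_MFW + (1 − f_MFW)·C_SGW
δ_MIX = [f_MFW·C_MFW·δ_MFW + (1 − f_MFW)·C_SGW·δ_SGW] / C_MIX
```

An ensemble of mixing lines over repeat sampling events spans a mixing
field; measurements below it indicate consumption, above it production.
The net removal of a constituent within the brackish layer is

```
% consumed = (C_MIX − C_MBW) / C_MFW × 100
```

with C_MIX evaluated at the brackish salinity.  On the food-web side, a
consumer's bulk δ¹³C is treated as a two-source blend of methane-derived
and soil-OM-derived carbon:

```
% methane carbon = (δ_consumer − δ_OM) / (δ_methane − δ_OM) × 100
```

and, where δD is also measured, regressing consumer δD on δ¹³C and
evaluating the fit at the methane δ¹³C end member extrapolates the δD
signature of the methane source itself.

The package also ships halocline detection for sonde profiles, water-mass
classification from salinity, a validating CSV reader, and a synthetic
scenario generator that produces water-column, sonde and consumer tables
with ground-truth sidecars for every downstream estimate.

## Worked example

Using the published water-mass means (salinity 0.26/1.81/32.87 psu; CH₄
6466/157/110 nM; DOC 661/131/41 µM for MFW/MBW/SGW):

```python
from karstmix import (mixing_fraction, conservative_concentration,
                      percent_consumed, methane_fraction)

f = mixing_fraction(1.81, 0.26, 32.87).value          # 0.9525
c_mix = conservative_concentration(f, 6466, 110)      # 6163.9 nM
res = percent_consumed(c_mix, 157, 6466)
print(res.percent_consumed)                           # 92.90  → 93 %

print(methane_fraction(-49.1).percent)                # 55.09  → 55 %
```

92.9 % means: of the methane the fresh end member delivers, only ~7 % of
the conservative expectation survives into the brackish layer — the rest
is consumed, presumably by aerobic methanotrophy.  The 55 % is the
methane-carbon share of the most ¹³C-depleted shrimp's diet under the
two-source model.

The same chain from the command line, on synthetic data with known truth:

```
$ karstmix simulate --seed 7 --out-dir sim
$ karstmix mix --samples sim/samples.csv --out-dir mixout
CH4: 93.3% consumed (pooled; reduction 6316)
DOC: 74.9% consumed (pooled; reduction 458)
DIC: -8.7% consumed (pooled; reduction -0)
SO4: 29.1% consumed (pooled; reduction 0)
$ karstmix trophic --consumers sim/shrimp.csv --out-dir troout --seed 7
methane-carbon contribution: 0–55%, mean 29% (n=29)
δD source estimate: -390‰ [-392, -387] (ols)
```

(The negative DIC "consumption" is net production — brackish DIC sits
above the mixing field, consistent with carbonate dissolution; the SO₄
percentage is noise amplified by the tiny fresh-water sulfate inventory,
and its sample-level classification is conservative.)

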