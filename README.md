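# chemmap

Positional 2′-F / 2′-OMe activity mapping and PK/PD statistics for
GalNAc–siRNA design screens.

## The problem

Therapeutic siRNA duplexes (21-nt sense / 23-nt antisense, GalNAc-conjugated
for hepatocyte delivery) are fully modified at every ribose 2′ position with
either 2′-*O*-methyl (2′-OMe) or 2′-deoxy-2′-fluoro (2′-F), plus terminal
phosphorothioate (PS) linkages. 2′-OMe stabilizes better against nucleases
but its bulk can abolish RNAi activity at sensitive positions; the design
goal is to minimize 2′-F content while preserving intrinsic silencing. With
2²¹ × 2²³ possible chemistry patterns, brute-force screening is impossible,
so the workhorse is a **positional regression** over a large heterogeneous
screen: for duplex *i* with measured fraction of target mRNA remaining
*y_i*,

    ln y_i = μ + Σ_p γ_p · 1[chem_{ip} = 2′-F] + site_s(i) + ε_i

with 2′-OMe as the reference chemistry, fixed effects for the target site
(which absorb target and cell-line species) and one coefficient γ_p per
strand position. γ_p < 0 means 2′-F improves silencing at position *p*;
positions with p < 0.05 are flagged. Candidate designs are then scored
additively and a constrained search proposes minimal-2′-F patterns, and an
in vivo statistics suite (semilog EC50/EC80 fits of knockdown against
Ago2-loaded antisense strand, extra-sum-of-squares F-test, baseline-100
AUC, recovery-slope comparison, two-way ANOVA with Dunnett/Sidak
post-tests) evaluates whether in vitro gains translate in vivo.

The package is aimed at oligonucleotide chemists and computational
biologists running modification SAR campaigns. Because published screens of
this kind are not released with machine-readable chemistry patterns, a
first-class synthetic-data module generates screens and time courses with
planted ground truth, so every estimator ships with parameter-recovery and
type-I-error calibration tests.

## Worked example

```python
import chemmap as cm

# a synthetic screen: 5 targets x 3 sites x 126 duplexes, 10 & 0.1 nM, n=4
screen = cm.gen_screen(cm.ScreenSimConfig(seed=0))
model = cm.PositionalActivityModel(min_designs=10, dose_nM=0.1).fit(screen)
pm = model.positional_map_
crit = pm[((pm.strand == "antisense") & pm.position.isin([2, 6, 14]))
          | ((pm.strand == "sense") & (pm.position == 11))]
print(crit[["strand", "position", "delta_ln", "se", "significant"]])
```

```
       strand  position  delta_ln        se  significant
10      sense        11 -0.405429  0.007006         True
22  antisense         2 -0.399085  0.006992         True
26  antisense         6 -0.344966  0.007019         True
34  antisense        14 -0.457588  0.006980         True
```

The four planted "critical" positions (AS2, AS6, AS14, S11) come back with
strongly negative model-adjusted ln-differences — 2′-F at those positions
improves silencing by ≈ 0.35–0.46 natural-log units — and are flagged
significant. Feeding the map into the design search proposes patterns that
keep 2′-F only where it pays:

```python
coeffs = cm.coefficients_from_map(pm)
parent = cm.reference_designs()["parent"].chemistry_pattern()
cons = cm.DesignConstraints(fixed_F={("AS", 2), ("AS", 6), ("AS", 14), ("S", 11)})
props = cm.propose_variants(coeffs, cons, parent, max_predicted_loss=0.1, top_k=3)
print(props[0].n_F_total, round(props[0].predicted_delta_ln, 3))
```

On the in vivo side, `fit_semilog_ec` inverts the fitted line
knockdown% = a + b·log10(loading): for the exact line
y = 20 + 30·log10(x) it returns EC50 = 10 and EC80 = 100 ng/g, and on a
noise-free synthetic time course it recovers the planted parent-like
potency (EC50 0.066, EC80 0.24 ng/g) exactly.

## Command line

`chemmap validate`, `chemmap simulate screen|pkpd`, `chemmap
fit-positional`, `chemmap analyze-dv`, `chemmap propose` and `chemmap pkpd
ec|auc|slopes|anova` wrap the library for TSV-in / TSV- or JSON-out use.

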