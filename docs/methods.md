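# Methods

## Data model

Each child contributes a demographic record and two 24-hour recall days of
intake already disaggregated into MyPyramid-style food-group equivalents
(cups / ounces), energy (kcal), nutrient quantities, and percent-of-energy
terms. Usual intake is the field-wise arithmetic mean of the available days;
children with fewer than two days are excluded by default (a loader flag
keeps them for sensitivity runs). Scores are computed on the two-day average
only — never per day — and no usual-intake distribution correction (NCI /
Iowa State) is applied: the comparison scores the same sample twice under two
rule sets, so between-person distribution modelling would add nothing.

Demographic recoding: age groups 2–5 / 6–11 / 12–18 (completed years;
non-integer ages are floored with a warning); income groups from the
poverty-income ratio (PIR, truncated at 5.0) at the food-assistance cut
points low ≤ 1.85, high ≥ 3.5, medium otherwise — the printed cut points
leave (1.85, 1.86) and [3.4, 3.5) undefined for continuous PIR, and this
reading preserves both printed endpoints while partitioning the line; ethnic
groups Hispanic/other (Mexican American, other Hispanic, and all remaining
non-white/non-black categories), non-Hispanic white, non-Hispanic black.

## HEI-2005 scoring

Twelve components, 100 points, on a per-1000-kcal density basis
(`density = amount × 1000 / energy`; percent-of-energy quantities pass
through). Standards ship in `src/childdqi/data/hei2005_standards.csv`:

| component | max | standard (full points) | zero at |
|---|---|---|---|
| total fruit | 5 | ≥ 0.8 c | 0 |
| whole fruit | 5 | ≥ 0.4 c | 0 |
| total vegetables | 5 | ≥ 1.1 c | 0 |
| dark-green/orange veg & legumes | 5 | ≥ 0.4 c | 0 |
| total grains | 5 | ≥ 3.0 oz | 0 |
| whole grains | 5 | ≥ 1.5 oz | 0 |
| milk | 10 | ≥ 1.3 c | 0 |
| meat & beans | 10 | ≥ 2.5 oz | 0 |
| oils | 10 | ≥ 12 g | 0 |
| saturated fat | 10 | ≤ 7 % energy | ≥ 15 % |
| sodium | 10 | ≤ 0.7 g | ≥ 2.0 g |
| SoFAAS | 20 | ≤ 20 % energy | ≥ 50 % |

Moderation components use a **single linear segment** between the two printed
anchors. The official HEI-2005 technical report instead uses an intermediate
breakpoint (e.g. 8 points at 10 % saturated fat); the config option
`hei_proration` reserves `technical_piecewise` for that curve but only
`paper_linear` is implemented — the single-segment reading follows the
published description of proration "in a linear fashion" between two anchors.
Consequences worth knowing: adequacy scores are zero **iff** intake is zero,
and all density scores are invariant to scaling amounts and energy jointly
(both are property-tested).

Legume allocation between the vegetable and meat groups is out of scope:
inputs arrive pre-allocated.

## RC-DQI scoring

Thirteen components, 90 points, against age-indexed targets shipped as two
table variants (`rcdqi_targets_b.csv`, `rcdqi_targets_c.csv`) that differ in
the grain/fruit/vegetable food-group patterns, the EER row, and two iron
bands. Which variant the original index's published application used is not
determinable from the printed tables, so both are implemented and the variant
is a required, logged configuration choice (default `table_b`, the
first-printed variant). Targets are indexed by age only; a sex parameter is
reserved but unused because the printed tables resolve by age alone.

Component rules (maxima in parentheses):

* **Food groups** (total grains 5, whole grains 5, fruit 10, vegetable 10,
  dairy 10): `max × min(1, intake/target)` — full points at the target,
  proportional deduction below, zero only at zero intake.
* **Ranges** (fat 2.5 at 30–40 % of energy for ages 2–3 and 25–35 % for 4–18;
  linoleic 2.5 at 5–10 %; linolenic 2.5 at 0.6–1.2 %): full points inside the
  interval, linear decay `max × value/lo` below, ratio decay `max × hi/value`
  above. The linoleic row's stray "≤" before "5–10 %" is read as a
  typographical artifact; the interval [5, 10] is scored.
* **Caps** (added sugar 10 at ≤ 10 % energy; DHA+EPA 2.5 at ≤ 10 % of
  α-linolenic acid; excess juice 10 at the AAP limit of 6 fl oz for ages 2–6
  and 12 fl oz for 7–18): full points at or below the cap, ratio decay
  `max × cap/value` above. Ratio decay (rather than a finite zero point) keeps
  every continuous component zero-free except at the extreme, matching the
  index's "continuous score" designation.
* **Iron** (10): categorical — 0 points at or below the EAR-equivalent
  threshold, 10 at or above the RDA-equivalent, 5 between. The four printed
  threshold columns are mapped to the age bands 2–3 / 4–8 / 9–13 / 14–18,
  the same bands the food-group rows use. Values falling in the small gaps
  between printed band edges (e.g. 6.95 mg in the 6.9–7.0 gap of the
  youngest band) resolve by the ≤ EAR / < RDA / ≥ RDA rule.
* **TV/energy** (10): the mean of a screen-time score and an energy score.
  Screen time: ≤ 2 h/day earns 10; above that the score decays as
  `10 × 2/hours` (the published rule states only the 2-hour threshold; ratio
  decay is this package's reading, continuous at 2 h and never negative).
  Missing screen time is imputed by age band: 2–6 y → 2 h, 7–14 y → 4 h,
  15–18 y → 3.5 h. Energy: 10 points inside 0.9–1.1 × the age's EER. The
  published deduction formula for intakes outside the window is
  discontinuous at the window edges if read literally (at 0.9 × EER it
  yields 0 where the window yields 10); the default `proportional` formula
  instead decays anchored at the window edges — `10 × energy/(0.9·EER)`
  below, `10 × (1.1·EER)/energy` above — which is continuous, zero only at
  zero intake, and consistent with the index's proportional-deduction
  philosophy. The literal reading is preserved behind
  `eer_formula: literal` so the two can be compared.

A consequence of the cap rules worth stating explicitly: a child consuming
nothing scores zero on every shortfall component but earns **full** points on
added sugar, juice, and DHA/EPA (absence cannot violate a cap), so an
all-zero diet does not score an all-zero total.

## The comparison

The five comparable components are rescaled to 0–5 (HEI milk / 2; RC-DQI
dairy, fruit, vegetable / 2; grains unchanged in both) and summed to a 0–25
subscore. HEI "fruit" is total fruit (juice-inclusive) and "vegetables" is
total vegetables — the top-level groups; RC-DQI fruit includes juice, whose
excess is handled by its separate cap component.

Correlations are unweighted Pearson r (the published comparison's
correlation table is labelled "r-square" yet contains negative entries, so
signed r is the only consistent reading), with two-sided t-test significance
flags at 0.05 and 0.01 and no multiple-testing correction. A component
constant within a stratum yields missing r, never 0. Survey weights are
accepted and ignored with a warning — the comparison is of scoring schemes,
not population estimation.

Distribution classes count children at the exact minimum (0), strictly
between, and at the exact maximum (5, or 25 for the subscore), with a 1e-9
boundary tolerance; the three proportions sum to 1 in every stratum.

## Synthetic survey generator

The generator emulates the *structure* of a two-day national recall survey of
children, not any population's true distributions. Per child: a latent diet
quality `z ~ N(0,1)`; per component, a child-level mean
`mean × exp(λz + σ_b ε − σ_b²/2)` with a structural non-consumer probability
`p_zero` (both recall days zero); per day, mean-one gamma noise with CV 0.35.
Food groups are drawn as densities per 1000 kcal and multiplied by the day's
energy; hierarchical parts (whole fruit, dark-green/orange vegetables, whole
grains) are per-child beta shares of their parent, guaranteeing part ≤ whole;
consumers' shares are floored at 0.1 % because a real recall never records a
physically meaningless 10⁻¹² oz. Energy is lognormal (σ = 0.12) around the
age-indexed EER; negative loadings on SoFAAS/added sugar/saturated fat make
high-`z` children better on moderation components too.

Default levels are typical US-child intakes: fruit ≈ 0.55 c/1000 kcal,
vegetables ≈ 0.65 c, grains ≈ 3.4 oz, whole-grain share ≈ 12 % (22 %
structural non-consumers), dairy ≈ 1.05 c, juice ≈ 3.5 fl oz (30 %
non-consumers), added sugar ≈ 16 % of energy, SoFAAS ≈ 35 %. The
study-shaped preset draws N = 5,936 with age-group proportions
1,405 : 1,586 : 2,945 and λ = 0.17 on the five comparable groups, which
places within-index score correlations in the weakly-positive 0.05–0.3 band
characteristic of real recall data (humans do not eat predictably; high
fruit intake barely predicts high dairy intake).

What passing tests on synthetic data do and do not show: they verify the
scoring arithmetic, the structural contracts (zero score ⇔ zero intake; the
RC-DQI's empty minimum class when everyone consumes something; recovery of
configured zero-consumer rates as HEI minimum-class proportions), and the
qualitative dichotomization contrast between the schemes. They do not
reproduce published population values (correlation magnitudes, the exact
12 %/88 %/0 % HEI subscore split) — those depend on the real survey's joint
intake distributions, which the generator does not calibrate to. One known
structural simplification: the generator's fruit-juice component feeds only
the RC-DQI juice cap and is not embedded inside total fruit.

## Numerical choices and degenerate inputs

Scores are kept at full float precision; rounding happens only at report
time. Zero energy is an error (densities undefined); empty record lists,
mixed child ids, negative amounts, parts exceeding wholes, and out-of-range
ages/PIR raise before scoring. Correlations need ≥ 3 children per stratum;
distribution classes need ≥ 1. The generator derives all randomness from one
seed and is bitwise reproducible per (config, seed).

## Problem sizes

The analysis drivers run the full study-shaped cohort (N = 5,936; ≈ 10 s end
to end). The test suite uses cohorts of 400–5,936 where a distributional
claim needs power and single-child fixtures elsewhere.

## Known limitations

* Only the single-segment ("paper-linear") HEI proration is implemented; the
  technical report's piecewise curve is reserved but absent, so HEI scores
  for mid-range moderation intakes differ slightly from official tooling.
* RC-DQI targets resolve by age only; if the original index applied
  sex-specific energy patterns, table variant choice is the only lever.
* The generator's components are conditionally independent given (z, energy);
  real diets have richer substitution structure (e.g. juice vs whole fruit
  trade-offs).
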