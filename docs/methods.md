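# Methods

## The screening model

The package analyses a genotype × treatment pot trial at the vegetative
stage: each line is grown under a well-watered control (WW) and a
water-stressed treatment (WS) with replicate pots, and 17 shoot and
root traits are measured per pot — tiller number (TN), plant height
(PH, cm), chlorophyll content (CC, µmol m⁻²), leaf osmotic potential
(LOP, MPa, always ≤ 0), leaf green area (LGA, cm²), relative growth
rate (RGR, d⁻¹), shoot and root dry weight (SDW, RDW, g), root:shoot
ratio (RSR), root length (RL, cm), crown root number (CRN), crown roots
per tiller (CRPT), maximum nodal root length (MRL, cm), root average
diameter (RAD, mm), root tips (RTi), root forks (RF) and percent
lateral roots (%LR).  Replicate means per (line, treatment, trait) are
the unit of all downstream computation.

The Total Drought Response Index is the plain, unweighted sum of the 17
WS/WW mean ratios.  Modelling assumptions worth stating:

* **Ratios of means, not means of ratios.** Treatment means are taken
  first; the index is computed once per line.  Per-replicate ratio
  averaging is not offered for the index (it is for CRPT, below).
* **LOP enters as the raw ratio of two negative means.** Osmotic
  adjustment (more negative potential under stress) therefore yields a
  ratio > 1 and raises the index — favourable, consistent with its
  physiological reading.  No absolute-value transform is applied.
* **No capping of extreme ratios.** A trait that quadruples under
  stress contributes 4 to the sum; the index is deliberately additive,
  so increasing any single ratio by δ moves the TDRI by exactly δ.

### Tolerance bands

Published band definitions are gapped (13.5–15, 15.1–17, >17.1).  The
classifier uses cut points at the gap midpoints — low ≤ 15.05 <
moderate ≤ 17.05 < tolerant — which makes the function total (any
finite TDRI classifies, including values below 13.5 such as a
drought-sensitive recurrent parent) and reproduces every published
assignment of the 18-genotype reference panel.  Both cut points are
parameters.  Ranking is by descending TDRI with lexicographic
tie-breaking, so the ordering is deterministic.

### Trait grouping report

The per-line high/medium/low trait grouping has no published
construction rule.  The implemented rule — place each line's stress
ratio against the empirical tertiles (1/3 and 2/3 quantiles) of that
trait's ratio distribution across all lines, strictly above the upper
tertile = high, strictly below the lower = low, otherwise medium — is a
documented **reconstruction** and is labelled as such in all outputs.
A degenerate all-equal distribution maps every line to medium.  Cost
traits (percent reduction in shoot dry weight) are sign-flipped before
banding so "high" always reads as favourable.  Exact reproduction of
any published grouping table is not claimed.

## Leaf-area estimation

LGA = card_area × green_pixels / blue_pixels, with a 100 cm² blue card
as the default reference.  Pixels are classed in HSV space: green hue
∈ [70°, 165°], blue hue ∈ [190°, 260°], both requiring saturation
≥ 0.25 and value ≥ 0.15 (white or grey background fails the saturation
gate).  The hue ranges are parameters; the defaults separate foliage
from a blue card under diffuse light.  No morphological cleanup runs by
default — the counts are bit-predictable — with optional small-blob
removal by minimum component size.  The estimator assumes card and
canopy are at comparable optical scale; no perspective correction is
applied.  RGR between two imaging dates is
(ln LGA₂ − ln LGA₁)/(d₂ − d₁); negative values (shrinking canopy) are
legal.

## Derived traits

* WU (kg) = pot weight at last irrigation − pot weight at harvest;
  pots are sealed, so the loss is transpiration.  A pot that gained
  weight is an error, not a clamp.
* WUE (g L⁻¹) = SDW / WU, with 1 kg water ≡ 1 L.
* %R_SDW = 100 × (SDW_ww − SDW_ws)/SDW_ww, computed on treatment means
  (the control is a single value); negative when stress exceeds
  control.
* RSR = RDW/SDW; CRPT = CRN/TN per plant.  CRPT defaults to the
  per-plant ratio then averaged (mean of ratios), because published
  treatment-level CRPT values are not exactly the ratio of the CRN and
  TN means; the ratio-of-means alternative is exposed as an option.
* WU, WUE and %R_SDW exist only under stress (or as a WS-vs-WW
  contrast) and are excluded from the 17-trait index.

## Trial statistics

Descriptive statistics use the sample standard deviation (n−1):
SE = sd/√n, CV = 100·sd/|mean|, banded low < 15% ≤ medium ≤ 30% < high.
The genotype effect per (trait, treatment) is a one-way fixed-effects
ANOVA across lines; Fisher's least significant difference is
LSD = t(1−α/2, df_E)·√(2·MSE/r) with r the harmonic-mean replicate
count (exact for balanced designs, the standard generalisation
otherwise).  The compact letter display exploits that a fixed
difference threshold on sorted means induces an interval relation: the
maximal runs of within-LSD means are exactly the maximal cliques, so
one letter per maximal run gives the property that two means share a
letter **iff** they differ by at most the LSD (verified by brute force
in the tests).  Degenerate inputs: zero residual variance with equal
means → F undefined (NaN), one shared letter; with unequal means →
F = ∞, p = 0, LSD = 0, fully separated letters.

Correlations are Pearson r over per-line means of one treatment
(stress by default), with two-sided p-values from the exact transform
t = r√((n−2)/(1−r²)) on n−2 degrees of freedom.  Zero-variance traits
get NaN rather than an arbitrary sign.  Significance stars use fixed
thresholds (0.05/0.01/0.001) with no multiplicity correction by
default, matching common reporting practice in trial papers; a Holm
step-down option exists on the long-form correlation table.

## Synthetic data

The generator emulates the reference trial design: 6 low + 3 moderate
+ 6 tolerant lines, 2 replicate pots per treatment, well-watered
baselines set to published trial-wide WW means (TN 6.19, PH 44.6 cm,
LGA 269.4 cm², LOP −1.31 MPa, SDW 1.39 g, …) and a class ratio profile
fixing the expected WS/WW ratio per trait.  The default profiles encode
the qualitative physiology of a drought screen — shoot traits depressed
(to ~0.5 of control for susceptible lines), root length/tips/forks and
lateral-root share increased in tolerant lines, osmotic potential
roughly doubled in magnitude — and sum to 14.0 (low), 16.0 (moderate)
and 18.1 (tolerant), comfortably inside their bands and close to the
published panel's spread (12.5–18.7).  Profiles are configuration, not
code, and a profile whose sum violates its band is rejected.

Noise is multiplicative Gaussian with CV 0.08 by default (a
conservative between-pot CV for controlled greenhouse conditions,
below most published trait CVs), clipped at ±3σ so positive traits stay
positive and LOP stays negative.  Count traits (TN, CRN, RTi, RF) are
rounded to integers ≥ 1 in the noisy regime; the noiseless mode
(noise_cv = 0) skips rounding so each line's computed TDRI equals its
profile's ratio sum to machine precision — the generator's
exact-identifiability mode.  All randomness flows through numpy's
PCG64 `default_rng`, so identical seeds reproduce identical tables on
any platform.

With the default 8% CV and 2 replicates the band-recovery rate of the
full pipeline is ≈99–100% over 100 seeds (the class sums sit ≈1 index
unit, roughly 3σ of the TDRI noise, from the nearest cut point); the
tests assert the ≥90% floor.  What the generator does **not** emulate:
tank/block spatial effects, genotype-specific trait correlations,
replicate-count imbalance, measurement floors/ceilings, or marker
genetics.  Passing tests therefore demonstrate correctness of the
computation and robustness to independent multiplicative noise, not
performance on structured field variation.

The image generator paints exact pixel counts (a blue block of
round(card_area·px_per_cm²) pixels, green row-fragments totalling
round(leaf_area·px_per_cm²)) on white, never overlapping, and returns
the painted counts as the segmentation oracle.  Problem sizes
throughout the suite (15-line trials, 100 seeds, 20 images at 4 px/cm
on a 500×800 canvas) were chosen as the smallest designs that exercise
every code path with stable statistics.

## Known limitations

* The published per-line trait means behind the reference panel are
  unavailable, so the panel's TDRI values are consumed as classification
  and ranking inputs rather than recomputed from raw traits.
* The trait-grouping tertile rule is a reconstruction (above).
* The LGA estimator inherits the pixel-ratio method's geometric
  assumption; oblique photographs will bias it.
* The LSD letter display is exact for the fixed-threshold relation it
  implements; it is not a substitute for multiplicity-adjusted pairwise
  tests when many lines are compared.
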