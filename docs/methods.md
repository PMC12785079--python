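# Methods

## Scope and model

`mcspatial` quantifies the spatial organization of the mast-cell (MC)
population in endometrial tissue from cell-detection tables (per-cell
centroids in µm, nuclear semi-axes, phenotype labels). Five analyses are
provided:

1. **Nearest-partner interaction bands.** For every MC the minimum Euclidean
   centroid distance to each partner phenotype (CD8⁺ T cells, CD14⁺
   monocytes, CD68⁺CD163⁻ M1 macrophages, CD163⁺ M2 macrophages) is
   classified as juxtacrine (< 10 µm), paracrine (10–20 µm) or
   non-interacting (> 20 µm). "Colocalization" is the combined
   juxtacrine + paracrine share of the MC population. 10 µm itself falls in
   the paracrine band (the contact band is strictly below 10), and 20 µm is
   the last paracrine value, so the three bands are exhaustive. An optional
   `nuclear_sum` mode replaces the fixed 10 µm contact cap per pair with
   min(a₁ + a₂, 10 µm), where a₁, a₂ are the two nuclear major semi-axes —
   the morphological definition of contact.
2. **Relative abundance.** A phenotype's detection count as a percentage of
   all segmented cells in the sample.
3. **Hexagonal density maps.** The region is tiled with equal-area hexagons
   (default 8660 µm², side s = √(2A/(3√3)) ≈ 57.735 µm, pointy-top, axial
   indexing). Detections are assigned by fractional axial coordinates and
   cube rounding, so every cell lands in exactly one hexagon and counts are
   conserved. Hexagons at or above a count quantile (default 0.90, over
   non-empty hexagons) are flagged as accumulation loci; adjacent flagged
   hexagons merge into connected loci; two phenotypes' locus layers combine
   into per-hexagon classes (A-only / B-only / both / neither).
4. **Severity grading.** A conjunctive four-criterion rule set (fibrosis,
   arteriolar lumen area, arteriolar diameter, CD138⁺ plasma-cell count)
   assigns mild/moderate/severe chronic endometritis; discordant criteria
   yield `indeterminate` with the votes reported rather than an invented
   tie-break. Ranges are inclusive of their printed endpoints and values are
   compared at the printed resolution (area: integers; diameter: 0.1 µm), so
   the range gaps created by printing (e.g. 99 → 100 µm²) are empty after
   rounding; only lumen area ≥ 450 µm² and diameter ≥ 20 µm fall outside
   every range and vote "none".
5. **Group statistics.** Per-sample metrics (one value per patient — the
   statistically defensible unit) are summarized as mean ± SEM and compared
   group-vs-control with Student's t-test when both groups pass Shapiro-Wilk
   at α = 0.05, otherwise the two-sided Mann-Whitney U test (exact null for
   n ≤ 8 without ties, tie-corrected normal approximation otherwise).
   Bonferroni correction uses the family of group-vs-control comparisons for
   one metric (m = 3 under the default design); stars mark adjusted
   p < 0.05 / 0.01 / 0.001. The normality gate is configurable, including
   forcing either test.

No edge correction is applied to nearest-neighbor distances (a small
negative bias for MCs near the region border), and boundary hexagons keep
their full nominal area in locus-area arithmetic; both simplifications are
deliberate and documented rather than corrected.

## Synthetic cohort generator

Because no per-cell data ship with the study design this package targets,
the generator produces cohorts whose group-level parameters are encoded in a
plain-text preset file, and the analyses must *recover* them from the
generated point patterns. Per sample:

* **"Other" cells** — homogeneous Poisson process at the residual fraction
  of the total density.
* **MCs** — Thomas (Neyman-Scott) cluster process: Poisson parents on a
  window extended by 4 cluster radii, Poisson(µ) offspring per parent with
  isotropic Gaussian dispersion, restricted to the region. The parent
  intensity is scaled so the expected MC count equals mc_fraction × expected
  total. This reproduces the locus-like accumulation of MCs in inflamed
  tissue and makes per-hexagon MC counts overdispersed (index of dispersion
  1 + µ for the totals).
* **Partner phenotypes** — uniform background plus distance coupling. The
  preset coupling values (p_juxta, p_para) are the band fractions the
  nearest-partner analysis should measure. Uniform background already puts a
  partner within radius R of an MC with probability q(R) = 1 − exp(−λπR²),
  so coupling is realized by thinning: each MC without a chance partner
  within 20 µm independently receives one placed partner in the juxtacrine
  annulus [1, 10) µm with probability (p_juxta − q₁₀)/(1 − q₂₀) or the
  paracrine annulus [10, 20] µm with probability (p_para − (q₂₀ − q₁₀))/(1 −
  q₂₀). Each MC is then colocalized with probability exactly p_juxta +
  p_para, per band, independently of sample size. (An earlier design that
  scaled the coupling by the *realized* per-sample chance fraction is
  exactly right in expectation only for large samples — the clipping at zero
  biases small samples upward — hence the analytic thinning.) Placed
  partners are rejection-sampled (up to 40 draws) to lie inside the region
  and more than 20 µm from every other MC, so one MC's partner cannot
  silently colocalize a neighbor; in pathological crowding the last draw is
  accepted. If the paracrine chance alone exceeds the paracrine target, the
  surplus is promoted to placed juxtacrine partners (which override a ≥10 µm
  chance distance); full coupling (1, 0) therefore yields 100 % contact
  exactly. The background intensity is the phenotype's budget minus the
  expected coupled count (fixed-point iteration); configs whose coupled
  count exceeds the partner budget, or whose chance colocalization already
  exceeds the target, are rejected as infeasible.
* **Nuclear geometry** — major semi-axes from a normal (mean 4 µm, sd 1 µm)
  truncated to positive values by resampling, so that typical pair sums stay
  near the 10 µm contact cap; minor semi-axes a uniform 0.55–0.95 multiple
  of the major. The minimum coupled-partner offset is 1 µm (coincident
  centroids are non-physical).
* **Morphometry** — per-grade records drawn uniformly within the grading
  ranges (at printed resolution), so generator and classifier round-trip by
  construction.

All randomness flows from a single seed (cohorts derive per-sample seeds
from the master seed via `numpy.random.SeedSequence`), and detection tables
are bitwise reproducible.

### Preset calibration

The four severity presets (control, mild, moderate, severe) encode the
group-level endpoints: MC fractions 0.014 / 0.067 / 0.113 / 0.206 % of total
cells, and per-partner colocalization targets (CD8 4.6/11.6/18.5/28.0 %,
CD14 5.6/18.7/26.8/28.8 %, M1 5.6/13.5/17.4/24.6 %, M2 3.4/9.6/9.1/21.5 %).
Each combined target is split juxtacrine:paracrine = 1:2, matching the
roughly two-to-one paracrine excess seen in band-resolved interaction data.

Parameters the endpoints do not determine were fixed once at values
realistic for endometrial stroma and are calibration choices, not claims
about any particular dataset: total density 3000 cells/mm²; default region
3200 × 3200 µm (≈ 10.2 mm²); cluster mean offspring 1 (control — MCs occur
singly in healthy endometrium) rising to 3/4/5 with severity; cluster radius
sd 60 µm; coupled partner fractions 0.5/1/1.5/2 % of total cells per
phenotype with severity; an uncoupled CD3 population at 3 %.

## What the simulation does and does not show

The generator reproduces the *statistical* structure the analyses assume —
clustered MC loci, severity-graded abundance, distance-coupled partners on a
uniform immune background — but not tissue anatomy: no glands, vessels,
stromal/epithelial compartments, segmentation errors, phenotype
misclassification, or autofluorescence artifacts. Passing recovery tests
therefore demonstrates that the pipeline is an unbiased, correctly scaled
estimator of the quantities the generator encodes; it does not validate the
biological parameter values themselves, which must come from real detection
exports (the `qupath_export` dialect exists for exactly that).

## Numerical choices and problem sizes

* Nearest-neighbor queries use a k-d tree; tests hold it to exact equality
  with an O(n²) scan.
* Hexagon geometry is exact closed-form; interior polygon areas agree with
  the nominal area to 1 × 10⁻⁶ relative.
* Recovery tests and the acceptance script size each run so sampling error
  is small relative to the target: ≥ 50,000 cells per sample for severe-
  group abundance, ≥ 100,000 (in practice ~1.2 M) for the control group
  (its MC fraction of 0.014 % needs large areas for stable MC counts), and
  regions giving ≥ 500 — typically 2000–4500 — MCs per colocalization run.
  Tolerances are 3 standard errors of the relevant estimator (SEM across
  samples for abundance; binomial SE for band fractions); these follow from
  the sampling model, with no empirical slack added.
* Ties in nearest distance keep the first target in scan order (the distance
  is unaffected); +∞ distances (no target cells) are non-interacting; a
  zero-source query is an error distinct from an empty target.

## Known limitations

* Abundance percentages treat every detection equally; no per-compartment
  normalization.
* The locus quantile (0.90) is a reasonable operationalization of "areas of
  local accumulation", not a validated clinical threshold; it is exposed as
  a parameter.
* Border effects (uncorrected nearest-neighbor censoring, partial boundary
  hexagons) bias spatial statistics slightly for regions much smaller than
  ~1 mm²; at the default region sizes the effect is well below sampling
  noise.
* The severity classifier grades any record, including controls, and will
  usually return `indeterminate` for healthy morphometry — normal tissue is
  outside the rule set's domain by construction.
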