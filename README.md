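# mcspatial

Spatial phenotyping of the mast-cell (MC) population in endometrial tissue.

Chronic endometritis (CE) reshapes the endometrial immune landscape: mast
cells accumulate in discrete loci and move closer to other immune cells as
inflammation and fibrosis progress. Given per-cell detection tables from
multiplex-stained whole-slide images (centroid x/y in µm, nuclear semi-axes,
phenotype label), `mcspatial` quantifies that reorganization for
histopathologists and image-analysis groups working on endometrial
inflammation:

* **Interaction bands** — for every MC, the minimum Euclidean centroid
  distance d to each partner phenotype (CD8⁺ T cells, CD14⁺ monocytes,
  CD68⁺CD163⁻ M1 and CD163⁺ M2 macrophages), classified as
  juxtacrine (d < 10 µm), paracrine (10 µm ≤ d ≤ 20 µm) or non-interacting
  (d > 20 µm); *colocalization* = juxtacrine + paracrine share of the MC
  population. An optional mode defines contact per pair as
  d < min(a₁ + a₂, 10 µm) from the nuclear major semi-axes.
* **Relative abundance** — phenotype count as % of all segmented cells.
* **Hexagonal density maps** — equal-area hexagons (8660 µm² each, side
  √(2A/(3√3)) ≈ 57.7 µm) with per-phenotype counts, accumulation-locus
  flagging at a count quantile, and two-phenotype colocalization classes.
* **Severity grading** — the four-criterion CE rule set (fibrosis,
  arteriolar lumen area, arteriolar diameter, CD138⁺ plasma cells):
  mild = no fibrosis, 150–449 µm², 10.0–19.9 µm, ≤ 1 CD138⁺;
  moderate = fibrosis, 100–149 µm², 8.0–9.9 µm, 2–3;
  severe = fibrosis, ≤ 99 µm², ≤ 7.9 µm, ≥ 4 — conjunctive, with
  `indeterminate` plus per-criterion votes on conflict.
* **Group statistics** — per-sample metrics as mean ± SEM;
  Shapiro-Wilk-gated Student's t / Mann-Whitney U group-vs-control tests,
  Bonferroni-corrected, starred at p < 0.05/0.01/0.001.
* **Synthetic cohorts** — a clustered point-process generator (Thomas
  process MC loci, distance-coupled partners, severity presets for a
  control=10 / mild=18 / moderate=16 / severe=19 cohort) providing ground
  truth for every analysis; see `docs/methods.md`.

## Worked example

```python
from mcspatial import simulate_sample, interaction_profile, relative_abundance
from mcspatial.presets import preset_config

cfg = preset_config("severe", region_width=6000.0, region_height=6000.0)
sample = simulate_sample(cfg, seed=42, sample_id="SCE_01", group="severe")
print(f"cells: {sample.n_cells}, area: {sample.area/1e6:.1f} mm^2")

ab = relative_abundance(sample, "MC")
print(f"MC abundance: {ab.n_pheno}/{ab.n_total} = {ab.pct:.3f}%")

prof = interaction_profile(sample, "MC", "CD8")
print(f"MC-CD8: juxtacrine {prof.pct_juxtacrine:.1f}%  "
      f"paracrine {prof.pct_paracrine:.1f}%  colocalized {prof.pct_colocalized:.1f}%")
```

prints

```
cells: 108064, area: 36.0 mm^2
MC abundance: 248/108064 = 0.229%
MC-CD8: juxtacrine 12.1%  paracrine 14.1%  colocalized 26.2%
```

One simulated severe-CE sample of 36 mm² holds ~108k segmented cells of
which 248 (0.229 %) are MCs — a single draw scattering around the severe
preset's 0.206 % — and 26.2 % of those MCs have their nearest CD8⁺ cell
within 20 µm (preset target 28.0 %), split roughly 1:1 between contact and
paracrine range at this sample size.

## Command line

```bash
mcspatial simulate --seed 1 --out out/            # default 63-sample cohort
mcspatial analyze --detections cells.tsv --dialect qupath_export --out out/
mcspatial grade --morphometry morpho.csv --out out/
```

`simulate` writes the cohort (`detections.tsv`, `morphometry.csv`) and all
analysis tables (`profiles.csv`, `abundance.csv`, `hexmap.csv`,
`grades.csv`, `comparisons.csv`, `manifest.json`); runs are byte-identical
for a fixed seed. `analyze` runs the same analyses on an existing detection
table (native TSV or a QuPath-style CSV export).

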