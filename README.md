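# modaspects

Region-count stroke scoring for neonates and children: the modified
pediatric ASPECTS (0–30), infarct volumetry normalized to supratentorial
brain volume (SBV), synthetic phantom cohorts, and the validation
statistics that relate the two.

## The problem

Infarct volume as a percent of SBV predicts hemorrhagic transformation and
poor outcome in pediatric arterial ischemic stroke, but measuring it takes
hours of manual segmentation per subject. The modified pediatric ASPECTS is
a bedside alternative: each hemisphere is split into 15 regions — M1–M6 and
the insula (cortical MCA), A1–A2 (ACA), P1–P2 (PCA), and caudate,
lentiform, internal capsule, thalamus (subcortical) — and one point is
added per region showing restricted diffusion, even if only a small portion
is involved:

    score = Σ_regions 1[region involved],  0 ≤ score ≤ 30 (15 per hemisphere)

This package computes that score automatically from a 3D label atlas and a
binary infarct mask, measures infarct volume / SBV / the ≥5% "large"
classification by voxel counting, and implements the statistics used to
validate the score against volumetry: Spearman ρ (criterion validity),
one-way ANOVA ICC(1) with F-bound CIs (interrater reliability),
sensitivity/specificity of the score ≥ 5 rule with exact Clopper–Pearson
CIs, ROC AUC by pairwise concordance, and rank-based group comparisons.
Because the original MRI data are not public, a synthetic-cohort module
generates phantom atlases and territorial / watershed / multifocal-punctate
lesions with the published territory mix and volume-fraction distributions,
plus noisy raters — so the whole study design runs end to end from one
seed. See `docs/methods.md` for the model details.

## Worked example

```python
from modaspects import score_from_regions

result = score_from_regions("L_C,L_L,L_IC,L_I,L_M1,L_M2,L_M3,L_M4,L_M5,L_M6")
print(result.total, result.per_hemisphere)
```

prints `10 {'left': 10, 'right': 0}` — a child with the full left deep gray
plus all six MCA cortical parcels involved scores 10. The companion example
(left internal capsule, insula, M3, M5, M6, P1, P2, thalamus) scores 8.

The same computation from images:

```bash
modaspects atlas --shape 40,40,26 --voxel 3 --sbv 300 --seed 2 -o atlas.nii.gz
modaspects simulate --atlas atlas.nii.gz --group childhood -n 12 --seed 5 --masks -o cohort/
modaspects score --mask cohort/chil_0003.nii.gz --atlas atlas.nii.gz
modaspects volumes --mask cohort/chil_0003.nii.gz --atlas atlas.nii.gz
```

the last command printing, for one simulated subject,

```json
{"infarct_ml": 20.115, "sbv_ml": 303.264, "fraction": 0.066328, "size_class": "large"}
```

i.e. a 20 ml infarct occupying 6.6% of SBV — above the 5% threshold, so
prognostically "large".

## The analysis

Numbered drivers under `analysis/` rebuild the study from nothing and write
tables under `results/`:

1. `01_build_atlases.py` — neonatal (350 ml) and childhood (1050 ml) phantoms;
2. `02_simulate_cohorts.py` — 31 perinatal + 40 childhood subjects with
   three noisy raters each (CSV per cohort);
3. `03_run_validation.py` — the full validation report (ρ with/without
   punctate subjects, ICC, classification at score ≥ 5 vs volume ≥ 5%,
   rank-sum between groups) as JSON and Markdown;
4. `04_reproduce_printed_counts.py` — the published classification
   arithmetic recomputed from its confusion counts (childhood 96/114 =
   84.2%, sensitivity 80.0% with 95% CI 65.4–90.4%, specificity 87.0% with
   CI 76.7–93.9%; perinatal 75/90 = 83.3%, sensitivity 85.0%, specificity
   80.0%).

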