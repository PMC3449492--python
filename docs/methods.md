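# Methods

## The score and what it is for

The modified pediatric ASPECTS is a semiquantitative estimate of acute
arterial ischemic stroke burden on diffusion-weighted MRI in neonates and
children. Each hemisphere is divided into 15 regions — six cortical MCA
ribbon parcels (M1–M3 at the ganglionic level, M4–M6 above it) plus the
insula, two cortical ACA parcels (A1 proximal, A2 distal), two cortical PCA
parcels (P1 inferior, P2 superior), and four subcortical structures
(caudate, lentiform nucleus, internal capsule, thalamus). One point is
*added* per involved region (the adult convention subtracts from a normal
total of 10 and covers only the MCA territory), so the score runs 0–30 with
at most 15 per hemisphere. A region counts as involved even when only a
small portion is affected, including watershed bands and punctate foci
(`min_voxels=1`; the threshold is configurable for noise suppression, and a
non-default value is flagged in the score's output metadata).

The reference standard against which the score is validated is infarct
volume expressed as a fraction of supratentorial brain volume (SBV,
ventricular CSF excluded), which normalizes for head growth across ages.
Infarcts occupying ≥ 5% of SBV ("large") carry elevated risk of hemorrhagic
transformation and poor outcome; the boundary is inclusive at exactly 5%.

## Phantom atlases instead of anatomy

The scoring logic is anatomy-agnostic given a label volume, so validation
runs on parameterized phantoms rather than real templates: an ellipsoidal
brain with an infratentorial slab removed, mirrored medial ventricles,
four deep-gray nuclei per side, an insular shell at mid-depth, and an outer
cortical ribbon parcellated by axial angle (ACA sector anterior, MCA
lateral, PCA posterior) and by a lower/upper tier split. The global brain
scale is bisected until the supratentorial non-ventricular volume lands
within 2% of a requested SBV target, and the right hemisphere is an exact
mirror of the left. Voxel indices are 0-based; axis 0 is lateral with lower
indices on the left, and the left hemisphere is `x < hemisphere_plane`.
Relative parcel sizes respect the clinical caveat that motivates the
equal-weight limitation: each M parcel carries far more volume than the
internal capsule, insula or caudate. Sulcal/extra-axial CSF is not modeled
separately (only ventricular volume is excluded from SBV), and the parcels
are an ordered, plausible parcellation, not a reproduction of any
template's exact boundaries. The study uses one phantom per age group —
same grid, different voxel scale (2.2 mm vs 3.2 mm) and SBV target (350 ml
neonatal, 1050 ml childhood) — because the volume *fraction* is
scale-free but the absolute head size is not.

Label volumes are NIfTI files with a JSON sidecar mapping label integers to
region tokens. Atlases merged from separate per-structure masks can carry
composite label-table entries; `validate_atlas` reports these (a label that
is both ventricle and a scoring region is an exclusivity violation) along
with empty regions, duplicate-label bijectivity failures, and voxels on the
wrong side of the hemisphere plane.

## Lesion mechanisms

* **Territorial** — randomized Dijkstra growth from a seed voxel inside the
  target territory (MCA = M1–M6, insula, caudate, lentiform, internal
  capsule; ACA = A1–A2; PCA = P1–P2 and thalamus, i.e. lenticulostriate
  supply with the MCA, thalamic supply with the posterior circulation).
  Steps within the territory cost 1, steps through other supratentorial
  tissue cost 60, so lesions fill their territory before leaking along
  white-matter bridges. The mask is the first `round(severity × territory
  volume)` voxels of the deterministic pop sequence, which makes growth
  monotone in severity for a fixed seed. Bilateral lesions are two
  independent growths, one per side.
* **Watershed** — growth restricted to borderzone bands: cortical parcels of
  adjacent territories within a 3-voxel dilation of each other (ACA–MCA and
  MCA–PCA), plus a 2-voxel white-matter rim around the deep MCA nuclei.
  Only band voxels enter the mask.
* **Multifocal punctate** — `punctate_count` scattered blobs of 1–3 voxels
  across at least three distinct regions. These subjects have tiny volumes
  but many involved regions, which is exactly the pattern that inflates a
  region-count score relative to volume.

Masks never intersect ventricles, infratentorial tissue or background.

## Cohort generation

Mechanism, territory combination and laterality frequencies are the
published stroke-distribution table rows (perinatal: 64.5% isolated MCA,
16.1% MCA+PCA, 32.3% bilateral, one punctate subject, and so on; childhood
analogously, including 5% watershed-only and 5% punctate). Rows annotated
as watershed in the source table become watershed-mechanism subjects with
that row's probability.

Severity is not sampled directly. Each subject draws a target volume
fraction from a log-normal distribution fitted once to the published
median and IQR of infarct volume as a percent of SBV — perinatal
μ = ln 0.069, σ = 1.46; childhood μ = ln 0.02, σ = 2.37 (σ from the
log-IQR width over twice the 75th-percentile normal deviate) — and converts
it to a severity via the territory's voxel count, clipped to (0, 1]. The
realized volume fraction and true involved-region set are then *measured*
from the generated mask by the volumetrics and scoring modules, so
truncation by territory size is reflected honestly in the cohort tables.

Raters are modeled as independent Bernoulli readers: each truly involved
region is detected with probability 0.9 and each uninvolved region is
falsely marked with probability 0.02; a rater's score is the count of
marked regions. These defaults place three-rater agreement in the "almost
perfect" ICC band reported for the human raters. All randomness flows from
one `SeedSequence`; each subject record stores its lesion sub-seed, so any
mask can be regenerated from its CSV row.

What the generator does *not* emulate: image intensities (only binary
masks), hemorrhagic transformation, rater biases that correlate across
raters or depend on lesion conspicuity, registration/resampling between
sequences (one shared grid is required), and clinical covariates. Passing
tests therefore show that the scoring/volumetrics/statistics machinery is
correct and that the score–volume relationship has the expected shape under
the published lesion mix — not that the phantom reproduces human anatomy.

## Statistics

* **Spearman ρ** — average ranks for ties, Pearson correlation of ranks;
  two-sided p by the t approximation for n > 10 and exact enumeration of
  all n! pairings for n ≤ 10. Strength bands follow the upper-closed
  published notation: (0, 0.3] weak, (0.3, 0.7] moderate, (0.7, 1] strong.
* **ICC(1)** — one-way ANOVA form (MSB − MSW)/(MSB + (k−1)·MSW), treating
  raters as interchangeable random ratings, which is the form consistent
  with the reported CI widths. 95% CI from F-distribution bounds on
  MSB/MSW; p from the ANOVA F test. A matrix with zero within-subject
  variance returns ICC 1 with a degenerate flag. Landis–Koch bands at
  0.41/0.61/0.81.
* **Sensitivity/specificity** — simple proportions over *ratings* (subjects
  × raters, matching the published 114/90 denominators; within-subject
  correlation of repeated ratings is deliberately ignored, as in the
  source arithmetic) with exact Clopper–Pearson beta-quantile CIs.
* **ROC AUC** — pairwise concordance with ties counted ½ (the normalized
  Mann–Whitney statistic); CI by the Hanley–McNeil variance by default,
  DeLong placement-value variance behind a flag.
* **Threshold sweep** — every integer threshold 0–30 under the rule
  "predict large iff score ≥ t", reporting the sensitivity-maximizing
  threshold with ties broken toward higher specificity, then higher t.
* **Group comparisons** — Kruskal–Wallis across rater columns and the
  two-sided Wilcoxon rank-sum between cohort volume fractions, both with
  tie correction; all-identical inputs return p = 1 flagged rather than
  erroring.

Classification statistics exclude the multifocal-punctate subjects (a
pre-specified choice in the study design this emulates); the correlation is
reported both ways, and the punctate-excluded subset must reconcile:
n_all = n_excluded + n_punctate.

## Problem sizes and numerical choices

Default study runs use 31 perinatal and 40 childhood subjects on 56×56×36
grids; the test suite validates distributional claims on 500-subject
cohorts and 20-replicate Monte-Carlo comparisons on 100-subject cohorts,
sizes at which the sample medians sit comfortably inside the published
IQRs while a full study completes in seconds. Degenerate inputs are
explicit errors (constant vectors for correlation, single-class labels for
ROC, SBV = 0 atlases) rather than NaNs. Exact-permutation Spearman p-values
are only attempted for n ≤ 10, where enumeration is cheap.

## Known limitations

The phantom's deep nuclei are small and box-like; watershed bands are
geometric dilations, not perfusion models; severity-to-volume conversion
truncates at full-territory involvement, slightly compressing the upper
tail of the perinatal volume distribution; and the published headline
correlations/ICCs on the original MRI cohort cannot be recomputed here —
only their printed classification arithmetic and interval estimates can be,
and are.
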