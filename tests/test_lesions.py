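"""Synthetic lesion mechanisms, cohort distributions and rater noise."""

import numpy as np
import pytest

from modaspects import (
    LesionSpec,
    RaterModel,
    simulate_cohort,
    simulate_lesion,
    simulate_raters,
)
from modaspects.atlas import BACKGROUND, INFRATENTORIAL, VENTRICLE
from modaspects.scoring import score_from_mask
from modaspects.stats import icc_oneway, spearman_rho
from modaspects.volumetrics import measure


class TestLesionSpec:
    def test_territorial_needs_territory(self):
        with pytest.raises(ValueError, match="territory"):
            LesionSpec("territorial")

    def test_punctate_needs_count(self):
        with pytest.raises(ValueError, match="punctate_count"):
            LesionSpec("punctate", punctate_count=1)

    def test_severity_range(self):
        with pytest.raises(ValueError, match="severity"):
            LesionSpec("territorial", (("MCA", "left"),), severity=0.0)


class TestSimulateLesion:
    @pytest.mark.parametrize(
        "spec",
        [
            LesionSpec("territorial", (("MCA", "left"),), severity=0.4, seed=1),
            LesionSpec("watershed", (("MCA", "right"),), severity=0.5, seed=2),
            LesionSpec("punctate", punctate_count=10, severity=0.01, seed=3),
        ],
        ids=["territorial", "watershed", "punctate"],
    )
    def test_mask_confined_to_supratentorial_brain(self, atlas, spec):
        mask = simulate_lesion(atlas, spec)
        for forbidden in (VENTRICLE, INFRATENTORIAL, BACKGROUND):
            assert not (mask.data & (atlas.labels == forbidden)).any()

    def test_deterministic_given_seed(self, atlas):
        spec = LesionSpec("territorial", (("MCA", "left"),), severity=0.3, seed=9)
        m1 = simulate_lesion(atlas, spec)
        m2 = simulate_lesion(atlas, spec)
        assert np.array_equal(m1.data, m2.data)

    def test_severity_monotone_nesting(self, atlas):
        masks = [
            simulate_lesion(
                atlas,
                LesionSpec("territorial", (("MCA", "left"),), severity=s, seed=4),
            )
            for s in (0.1, 0.35, 0.8)
        ]
        assert (masks[0].data <= masks[1].data).all()
        assert (masks[1].data <= masks[2].data).all()

    def test_complete_mca_infarct_involves_all_mca_parcels(self, atlas):
        spec = LesionSpec("territorial", (("MCA", "left"),), severity=1.0, seed=5)
        result = score_from_mask(simulate_lesion(atlas, spec), atlas)
        assert result.total >= 7
        assert result.per_hemisphere["right"] == 0

    def test_punctate_small_volume_many_regions(self, atlas):
        spec = LesionSpec("punctate", punctate_count=12, severity=0.01, seed=6)
        mask = simulate_lesion(atlas, spec)
        assert measure(mask, atlas).fraction < 0.05
        assert score_from_mask(mask, atlas).total >= 3

    def test_bilateral_spec_hits_both_hemispheres(self, atlas):
        spec = LesionSpec(
            "territorial", (("MCA", "left"), ("MCA", "right")), severity=0.5, seed=7
        )
        result = score_from_mask(simulate_lesion(atlas, spec), atlas)
        assert result.per_hemisphere["left"] > 0
        assert result.per_hemisphere["right"] > 0


class TestSimulateCohort:
    def test_single_subject_fully_populated(self, atlas):
        (rec,) = simulate_cohort(atlas, "childhood", 1, seed=0)
        assert rec.subject_id
        assert rec.group == "childhood"
        assert 0.0 <= rec.volume_fraction <= 1.0
        assert rec.size_class in ("large", "small")
        assert rec.true_regions
        assert rec.rater_scores == ()

    def test_invalid_args(self, atlas):
        with pytest.raises(ValueError):
            simulate_cohort(atlas, "childhood", 0, seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(atlas, "adult", 5, seed=0)

    def test_reproducible_by_seed(self, atlas):
        a = simulate_cohort(atlas, "perinatal", 8, seed=3)
        b = simulate_cohort(atlas, "perinatal", 8, seed=3)
        assert [r.volume_fraction for r in a] == [r.volume_fraction for r in b]
        assert [r.true_regions for r in a] == [r.true_regions for r in b]

    def test_childhood_punctate_proportion(self, childhood_cohort_500):
        frac = np.mean(
            [r.lesion_spec.mechanism == "punctate" for r in childhood_cohort_500]
        )
        assert 0.02 <= frac <= 0.08  # table frequency 5% +- MC error

    def test_score_volume_coupling_without_punctate(self, childhood_cohort_500):
        # criterion validity of the score itself: on territorial/watershed
        # lesions the region count tracks volume strongly
        recs = [
            r for r in childhood_cohort_500
            if r.lesion_spec.mechanism in ("territorial", "watershed")
        ][:150]
        rho, p = spearman_rho(
            [r.true_score for r in recs], [r.volume_fraction for r in recs]
        )
        assert rho >= 0.7
        assert p < 0.001

    def test_punctate_inflates_score_relative_to_volume(self, childhood_cohort_500):
        ratio = {
            m: np.mean(
                [
                    r.true_score / max(r.volume_fraction, 1e-9)
                    for r in childhood_cohort_500
                    if r.lesion_spec.mechanism == m
                ]
            )
            for m in ("punctate", "territorial")
        }
        assert ratio["punctate"] > ratio["territorial"]


class TestSimulateRaters:
    def test_noise_free_raters_reproduce_true_score(self, atlas):
        records = simulate_cohort(atlas, "childhood", 10, seed=5)
        rated = simulate_raters(records, RaterModel(1.0, 0.0, seed=0), k=3)
        for rec in rated:
            assert rec.rater_scores == (rec.true_score,) * 3

    def test_noise_free_raters_have_perfect_icc(self, atlas):
        records = simulate_cohort(atlas, "childhood", 10, seed=5)
        rated = simulate_raters(records, RaterModel(1.0, 0.0, seed=0), k=3)
        ratings = np.array([r.rater_scores for r in rated])
        assert icc_oneway(ratings).icc == pytest.approx(1.0)

    def test_realistic_raters_near_perfect_icc(self, childhood_cohort_500):
        records = childhood_cohort_500[:200]
        rated = simulate_raters(records, RaterModel(0.9, 0.02, seed=1), k=3)
        ratings = np.array([r.rater_scores for r in rated])
        icc = icc_oneway(ratings).icc
        assert 0.8 < icc < 1.0

    def test_requires_two_raters(self, atlas):
        records = simulate_cohort(atlas, "childhood", 3, seed=5)
        with pytest.raises(ValueError):
            simulate_raters(records, RaterModel(), k=1)

    def test_reproducible_by_seed(self, atlas):
        records = simulate_cohort(atlas, "childhood", 5, seed=5)
        a = simulate_raters(records, RaterModel(seed=11), k=3)
        b = simulate_raters(records, RaterModel(seed=11), k=3)
        assert [r.rater_scores for r in a] == [r.rater_scores for r in b]
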