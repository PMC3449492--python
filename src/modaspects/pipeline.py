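"""End-to-end study orchestration: atlas -> cohorts -> raters -> statistics.

``run_study`` regenerates the full validation analysis (criterion validity
with and without the multifocal-punctate subjects, interrater reliability,
threshold classification, group comparison) on synthetic cohorts;
``reproduce_printed_counts`` recomputes the published classification
arithmetic from its confusion counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .atlas import build_phantom_atlas
from .lesions import RaterModel, SubjectRecord, cohort_to_frame, simulate_cohort, simulate_raters
from .stats import (
    ConfusionCounts,
    ValidationReport,
    confusion_from_scores,
    confusion_stats,
    icc_oneway,
    kruskal_across_raters,
    ranksum_groups,
    roc_auc,
    spearman_rho,
    threshold_sweep,
)

log = logging.getLogger("modaspects")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of a synthetic study run (fully determined by ``seed``)."""

    perinatal_n: int = 31
    childhood_n: int = 40
    seed: int = 42
    atlas_shape: tuple[int, int, int] = (56, 56, 36)
    #: neonatal vs childhood head size: same grid, different voxel scale
    perinatal_voxel_mm: float = 2.2
    childhood_voxel_mm: float = 3.2
    perinatal_sbv_ml: float = 350.0
    childhood_sbv_ml: float = 1050.0
    k_raters: int = 3
    detect_prob: float = 0.9
    false_pos_prob: float = 0.02
    score_threshold: int = 5
    volume_threshold: float = 0.05
    exclude_punctate_from_classification: bool = True

    def __post_init__(self) -> None:
        if self.perinatal_n < 3 or self.childhood_n < 3:
            raise ValueError("need n >= 3 per group for the correlation stages")
        if self.score_threshold <= 0 or self.volume_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _pooled_ratings(records: Sequence[SubjectRecord]):
    """Per-rating vectors: each subject contributes k (score, volume) pairs."""
    scores, volumes, labels = [], [], []
    for r in records:
        for s in r.rater_scores:
            scores.append(s)
            volumes.append(r.volume_fraction)
            labels.append(1 if r.size_class == "large" else 0)
    return np.array(scores), np.array(volumes), np.array(labels)


def analyze_cohort(
    records: Sequence[SubjectRecord],
    group: str,
    score_threshold: int = 5,
    volume_threshold: float = 0.05,
    exclude_punctate: bool = True,
) -> ValidationReport:
    """Compute one cohort's ValidationReport from rated subject records.

    The unit of analysis is the individual rating (subjects x raters), as in
    the published counts; classification statistics are computed on the
    non-punctate subjects.
    """
    if any(not r.rater_scores for r in records):
        raise ValueError("records must carry rater scores (run simulate_raters)")
    punctate = [r for r in records if r.lesion_spec.mechanism == "punctate"]
    non_punct = [r for r in records if r.lesion_spec.mechanism != "punctate"]

    s_all, v_all, _ = _pooled_ratings(records)
    rho_all = spearman_rho(s_all, v_all)
    if punctate and len(non_punct) >= 3:
        s_np, v_np, _ = _pooled_ratings(non_punct)
        rho_excl = spearman_rho(s_np, v_np)
    else:
        rho_excl = rho_all

    ratings = np.array([r.rater_scores for r in records])
    icc = icc_oneway(ratings)
    kr = kruskal_across_raters(ratings)

    cls_records = non_punct if exclude_punctate else list(records)
    s_c, v_c, y_c = _pooled_ratings(cls_records)
    labels = (v_c >= volume_threshold).astype(int)
    confusion = confusion_from_scores(s_c, labels, score_threshold)
    sens, spec = confusion_stats(confusion)
    auc = roc_auc(s_c, labels)
    _, best_t = threshold_sweep(s_c, labels)

    return ValidationReport(
        group=group,
        n_subjects=len(records),
        n_punctate=len(punctate),
        rho_all=rho_all,
        rho_excl_punctate=rho_excl,
        icc=icc,
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_threshold=best_t,
        kruskal=kr,
        median_volume_fraction=float(np.median([r.volume_fraction for r in records])),
        score_threshold=score_threshold,
        volume_threshold=volume_threshold,
    )


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole synthetic study; deterministic given ``config.seed``.

    Returns a dict with per-group ValidationReports, the between-group
    volume-fraction rank-sum comparison, and the cohort tables.  When
    ``outdir`` is given, all intermediate tables and reports are persisted
    (cohort CSVs, report JSON, Markdown summary).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]

    stage = "atlas"
    try:
        atlases = {
            "perinatal": build_phantom_atlas(
                config.atlas_shape, (config.perinatal_voxel_mm,) * 3,
                config.perinatal_sbv_ml, seed=seeds[0],
            ),
            "childhood": build_phantom_atlas(
                config.atlas_shape, (config.childhood_voxel_mm,) * 3,
                config.childhood_sbv_ml, seed=seeds[0],
            ),
        }
        stage = "cohort"
        cohorts = {
            "perinatal": simulate_cohort(
                atlases["perinatal"], "perinatal", config.perinatal_n, seeds[1]
            ),
            "childhood": simulate_cohort(
                atlases["childhood"], "childhood", config.childhood_n, seeds[2]
            ),
        }
        stage = "raters"
        rater_model = {
            g: RaterModel(config.detect_prob, config.false_pos_prob, seed=seeds[3 + i])
            for i, g in enumerate(("perinatal", "childhood"))
        }
        cohorts = {
            g: simulate_raters(recs, rater_model[g], k=config.k_raters)
            for g, recs in cohorts.items()
        }
        stage = "statistics"
        reports = {
            g: analyze_cohort(
                recs, g, config.score_threshold, config.volume_threshold,
                config.exclude_punctate_from_classification,
            )
            for g, recs in cohorts.items()
        }
        ranksum = ranksum_groups(
            [r.volume_fraction for r in cohorts["perinatal"]],
            [r.volume_fraction for r in cohorts["childhood"]],
        )
    except Exception as exc:  # pragma: no cover - defensive reporting
        raise RuntimeError(f"study failed at stage {stage!r}: {exc}") from exc

    result = {
        "config": asdict(config),
        "reports": {g: rep.to_dict() for g, rep in reports.items()},
        "group_comparison": {
            "volume_fraction_ranksum_z": round(ranksum[0], 4),
            "volume_fraction_ranksum_p": ranksum[1],
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g, recs in cohorts.items():
            cohort_to_frame(recs).to_csv(outdir / f"cohort_{g}.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(result, indent=1, sort_keys=True))
        md = ["## Synthetic study report", ""]
        for g in ("perinatal", "childhood"):
            md += [reports[g].to_markdown(), ""]
        md += [
            "### Group comparison",
            f"- perinatal vs childhood volume fraction: rank-sum z = "
            f"{ranksum[0]:.2f}, p = {ranksum[1]:.4f}",
        ]
        (outdir / "report.md").write_text("\n".join(md))
        log.info("study outputs written to %s", outdir)

    result["_cohorts"] = cohorts  # in-memory only; not serialized
    result["_reports"] = reports
    return result


# -- published-count fixtures ------------------------------------------------

#: confusion counts implied by the published classification paragraphs:
#: childhood: 15 large and 23 small subjects x 3 ratings, 9 FN + 9 FP;
#: perinatal: 20 large and 10 small subjects x 3 ratings, 9 FN + 6 FP.
PRINTED_CONFUSION = {
    "childhood": ConfusionCounts(tp=36, fp=9, tn=60, fn=9),
    "perinatal": ConfusionCounts(tp=51, fp=6, tn=24, fn=9),
}


def reproduce_printed_counts() -> dict:
    """Recompute the published classification arithmetic from its counts.

    Returns, per cohort: ratings correct and accuracy, sensitivity and
    specificity with exact 95% CIs.  These values are recomputed, not stored,
    so any drift in the statistics implementation surfaces here.
    """
    out = {}
    for group, counts in PRINTED_CONFUSION.items():
        sens, spec = confusion_stats(counts)
        out[group] = {
            "n_ratings": counts.n,
            "n_correct": counts.n_correct,
            "accuracy_pct": round(100 * counts.accuracy, 1),
            "sensitivity_pct": round(100 * sens.value, 1),
            "sensitivity_ci_pct": [round(100 * sens.ci_low, 1), round(100 * sens.ci_high, 1)],
            "specificity_pct": round(100 * spec.value, 1),
            "specificity_ci_pct": [round(100 * spec.ci_low, 1), round(100 * spec.ci_high, 1)],
        }
    return out
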