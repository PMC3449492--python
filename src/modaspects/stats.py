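"""Validity, reliability and classification statistics.

Implements the study-level statistics used to validate a semiquantitative
score against volumetry: Spearman rank correlation (criterion validity),
the one-way ANOVA intraclass correlation ICC(1) with F-based confidence
bounds (interrater reliability, Landis-Koch agreement bands), exact
Clopper-Pearson binomial intervals for sensitivity/specificity of the
score>=threshold rule, the ROC area by pairwise concordance with a
Hanley-McNeil interval (DeLong optional), a full integer-threshold sweep,
and the rank-based group comparisons (Kruskal-Wallis across raters,
Wilcoxon rank-sum between cohorts).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

# Landis-Koch agreement bands for ICC
_ICC_BANDS = ((0.81, "almost perfect"), (0.61, "substantial"), (0.41, "moderate"))
# published correlation-strength cuts: (0,0.3] weak, (0.3,0.7] moderate, (0.7,1] strong


def correlation_band(rho: float) -> str:
    """Strength label for a positive correlation per the 0.3 / 0.7 cuts."""
    a = abs(rho)
    if a > 0.7:
        return "strong"
    if a > 0.3:
        return "moderate"
    if a > 0.0:
        return "weak"
    return "none"


def icc_band(icc: float) -> str:
    for cut, name in _ICC_BANDS:
        if icc >= cut:
            return name
    return "below-moderate"


# -- Spearman ---------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks; rho is the Pearson correlation of the rank
    vectors.  The p-value uses the t approximation for n > 10 and exact
    enumeration of all rank pairings for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n > 10:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    else:
        p = _exact_spearman_p(rx, ry, rho)
    return rho, float(min(p, 1.0))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! pairings of the rank vectors."""
    n = rx.size
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    obs = abs(rho_obs) * denom - 1e-9
    count = 0
    total = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 40000))
        if not chunk:
            break
        P = rx[np.array(chunk)]
        dots = np.abs(P @ ry)
        count += int((dots >= obs).sum())
        total += len(chunk)
    return count / total


# -- ICC --------------------------------------------------------------------

@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    k_raters: int
    band: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "icc": round(self.icc, 4),
            "ci": [round(self.ci_low, 4), round(self.ci_high, 4)],
            "p_value": self.p_value,
            "n_subjects": self.n_subjects,
            "k_raters": self.k_raters,
            "band": self.band,
            "degenerate": self.degenerate,
        }


def icc_oneway(ratings: np.ndarray, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(1) from a subjects x raters matrix via one-way ANOVA.

    ICC(1) = (MSB - MSW) / (MSB + (k-1) MSW), where MSB/MSW are the between-
    and within-subject mean squares treating subjects as the grouping factor
    (raters as random, interchangeable ratings).  The confidence interval
    comes from F-distribution bounds on the variance ratio; the p-value is
    the one-way ANOVA F test against ICC = 0.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 by k>=2 matrix")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must have no missing cells")
    n, k = m.shape
    grand = m.mean()
    subj_means = m.mean(axis=1)
    ssb = k * float(((subj_means - grand) ** 2).sum())
    ssw = float(((m - subj_means[:, None]) ** 2).sum())
    df_b, df_w = n - 1, n * (k - 1)
    msb, msw = ssb / df_b, ssw / df_w

    if msw == 0.0 and msb == 0.0:
        # all ratings identical everywhere: agreement is perfect but the
        # variance decomposition is empty
        return ReliabilityResult(1.0, 1.0, 1.0, float("nan"), n, k,
                                 icc_band(1.0), degenerate=True)
    if msw == 0.0:
        return ReliabilityResult(1.0, 1.0, 1.0, 0.0, n, k, icc_band(1.0),
                                 degenerate=True)

    F = msb / msw
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_low = F / sps.f.ppf(1 - alpha / 2, df_b, df_w)
    f_high = F * sps.f.ppf(1 - alpha / 2, df_w, df_b)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    p = float(sps.f.sf(F, df_b, df_w))
    return ReliabilityResult(
        float(icc), float(max(-1.0, ci_low)), float(min(1.0, ci_high)), p,
        n, k, icc_band(float(icc)),
    )


# -- classification ---------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Counts for the score>=threshold vs large-infarct classification."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class ProportionEstimate:
    value: float
    ci_low: float
    ci_high: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return {
            "value": round(self.value, 4),
            "ci": [round(self.ci_low, 4), round(self.ci_high, 4)],
            "k": self.k,
            "n": self.n,
        }


def confusion_stats(
    counts: ConfusionCounts, alpha: float = 0.05
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """Sensitivity and specificity with exact binomial confidence intervals."""
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one subject in each reference class")
    sens = ProportionEstimate(
        counts.tp / n_pos, *clopper_pearson(counts.tp, n_pos, alpha), counts.tp, n_pos
    )
    spec = ProportionEstimate(
        counts.tn / n_neg, *clopper_pearson(counts.tn, n_neg, alpha), counts.tn, n_neg
    )
    return sens, spec


def confusion_from_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    score_threshold: float = 5,
) -> ConfusionCounts:
    """Tabulate the predict-large-iff-score>=threshold rule against labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= score_threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    alpha: float = 0.05,
    method: str = "hanley-mcneil",
) -> tuple[float, float, float]:
    """ROC area by pairwise concordance (ties count 1/2) with a CI.

    Equivalent to the normalized Mann-Whitney U statistic.  The default
    confidence interval uses the Hanley-McNeil variance; ``method="delong"``
    uses the DeLong placement-value variance instead.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    conc = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    auc = float(conc) / (n1 * n0)

    if method == "delong":
        v10 = ((diff > 0) + 0.5 * (diff == 0)).mean(axis=1)  # per-positive placements
        v01 = ((diff > 0) + 0.5 * (diff == 0)).mean(axis=0)  # per-negative placements
        var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0 if min(n1, n0) > 1 else 0.0
    else:
        q1 = auc / (2 - auc)
        q2 = 2 * auc * auc / (1 + auc)
        var = (
            auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
        ) / (n1 * n0)
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def threshold_sweep(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[dict], int]:
    """Sensitivity/specificity at every integer threshold 0..30.

    The rule is predict-large iff score >= threshold.  Returns the sweep
    table and the sensitivity-maximizing threshold, ties broken toward
    higher specificity and then toward the higher threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    table = []
    for t in range(0, 31):
        pred = s >= t
        sens = int((pred & (y == 1)).sum()) / n1
        spec = int((~pred & (y == 0)).sum()) / n0
        table.append({"threshold": t, "sensitivity": sens, "specificity": spec})
    best = max(table, key=lambda r: (r["sensitivity"], r["specificity"], r["threshold"]))
    return table, int(best["threshold"])


# -- group comparisons ------------------------------------------------------

def kruskal_across_raters(ratings: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis test that the k raters' score distributions coincide."""
    m = np.asarray(ratings, dtype=float)
    cols = [m[:, j] for j in range(m.shape[1])]
    if np.ptp(m) == 0:
        return 0.0, 1.0  # degenerate: all pooled values identical
    h, p = sps.kruskal(*cols)
    return float(h), float(p)


def ranksum_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (normal approximation with tie correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    z, p = sps.ranksums(a, b)
    return float(z), float(p)


# -- aggregate report -------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    """Validity / reliability / classification results for one cohort."""

    group: str
    n_subjects: int
    n_punctate: int
    rho_all: tuple[float, float]
    rho_excl_punctate: tuple[float, float]
    icc: ReliabilityResult
    confusion: ConfusionCounts
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    auc: tuple[float, float, float]
    best_threshold: int
    kruskal: tuple[float, float]
    median_volume_fraction: float
    score_threshold: int = 5
    volume_threshold: float = 0.05

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_subjects": self.n_subjects,
            "n_punctate": self.n_punctate,
            "median_volume_fraction": round(self.median_volume_fraction, 4),
            "validity": {
                "rho_all": round(self.rho_all[0], 4),
                "rho_all_p": self.rho_all[1],
                "rho_all_band": correlation_band(self.rho_all[0]),
                "rho_excl_punctate": round(self.rho_excl_punctate[0], 4),
                "rho_excl_punctate_p": self.rho_excl_punctate[1],
                "rho_excl_band": correlation_band(self.rho_excl_punctate[0]),
            },
            "reliability": {
                **self.icc.to_dict(),
                "kruskal_h": round(self.kruskal[0], 4),
                "kruskal_p": round(self.kruskal[1], 4),
            },
            "classification": {
                "score_threshold": self.score_threshold,
                "volume_threshold": self.volume_threshold,
                "counts": {
                    "tp": self.confusion.tp, "fp": self.confusion.fp,
                    "tn": self.confusion.tn, "fn": self.confusion.fn,
                },
                "n_ratings": self.confusion.n,
                "n_correct": self.confusion.n_correct,
                "accuracy_pct": round(100 * self.confusion.accuracy, 1),
                "sensitivity": self.sensitivity.to_dict(),
                "specificity": self.specificity.to_dict(),
                "auc": [round(v, 4) for v in self.auc],
                "best_threshold": self.best_threshold,
            },
        }

    def to_markdown(self) -> str:
        d = self.to_dict()
        v, r, c = d["validity"], d["reliability"], d["classification"]
        lines = [
            f"### {self.group} cohort (n = {self.n_subjects}, "
            f"{self.n_punctate} multifocal punctate)",
            "",
            "#### Validity",
            f"- Spearman rho (all subjects): {v['rho_all']:.2f} "
            f"(p = {v['rho_all_p']:.2g}, {v['rho_all_band']})",
            f"- Spearman rho (excluding punctate): {v['rho_excl_punctate']:.2f} "
            f"(p = {v['rho_excl_punctate_p']:.2g}, {v['rho_excl_band']})",
            "",
            "#### Reliability",
            f"- ICC(1): {r['icc']:.2f} (95% CI {r['ci'][0]:.2f}-{r['ci'][1]:.2f}, "
            f"{r['band']})",
            f"- Kruskal-Wallis across raters: H = {r['kruskal_h']:.2f}, "
            f"p = {r['kruskal_p']:.2f}",
            "",
            "#### Classification (score >= "
            f"{c['score_threshold']} vs volume >= {100*c['volume_threshold']:.0f}% SBV, "
            "punctate excluded)",
            f"- {c['n_correct']}/{c['n_ratings']} ratings correct "
            f"({c['accuracy_pct']:.1f}%)",
            f"- Sensitivity {100*c['sensitivity']['value']:.1f}% "
            f"(95% CI {100*c['sensitivity']['ci'][0]:.1f}-{100*c['sensitivity']['ci'][1]:.1f}%)",
            f"- Specificity {100*c['specificity']['value']:.1f}% "
            f"(95% CI {100*c['specificity']['ci'][0]:.1f}-{100*c['specificity']['ci'][1]:.1f}%)",
            f"- AUC {c['auc'][0]:.2f} (95% CI {c['auc'][1]:.2f}-{c['auc'][2]:.2f}); "
            f"sensitivity-maximizing threshold {c['best_threshold']}",
        ]
        return "\n".join(lines)
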