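"""Score-based species discrimination: ANOVA, post-hoc tests, CI thresholds.

Component scores from the rotated PCA are compared across species with a
one-way ANOVA and Bonferroni-adjusted pairwise t tests. For each species pair
a component separates, a decision threshold is placed at the midpoint of the
gap between the two groups' 95% confidence intervals for the mean; a new
plant is then labelled by which side of the threshold its score falls on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientGroups,
    MissingComponent,
    OverlappingIntervals,
    ZeroWithinVariance,
)

#: The reference study's pairing plan: which species pair each component
#: separates and which species lies on the high-score side.
DEFAULT_PLAN = [
    ("PC1", "wheat", "ryegrass"),  # ryegrass high
    ("PC2", "wheat", "brome"),  # brome high
    ("PC3", "ryegrass", "wheat"),  # ryegrass low
]


@dataclass
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    F: float
    p: float


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float  # a minus b
    se: float
    p_bonferroni: float


@dataclass
class GroupDescriptives:
    species: str
    n: int
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class Threshold:
    component: str
    species_low: str
    species_high: str
    value: float


def anova_from_sums(
    ss_between: float, df_between: int, ss_within: float, df_within: int
) -> AnovaResult:
    """Complete an ANOVA table from its sums of squares and df alone."""
    if ss_within <= 0:
        raise ZeroWithinVariance("within-group sum of squares must be positive")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    F = ms_b / ms_w
    return AnovaResult(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        df_total=df_between + df_within,
        ms_between=ms_b,
        ms_within=ms_w,
        F=F,
        p=float(stats.f.sf(F, df_between, df_within)),
    )


def _groups(scores: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    groups = {str(g): scores[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2:
        raise InsufficientGroups("need at least two groups")
    small = [g for g, v in groups.items() if v.size < 2]
    if small:
        raise InsufficientGroups(f"groups with fewer than 2 observations: {small}")
    return groups


def one_way_anova(scores: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """Standard one-way decomposition with the upper-tail F probability."""
    groups = _groups(scores, labels)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_b = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ss_w == 0:
        raise ZeroWithinVariance("all within-group variation is zero")
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    return anova_from_sums(float(ss_b), df_b, float(ss_w), df_w)


def pooled_se(ms_within: float, n_a: int, n_b: int) -> float:
    """Pooled standard error of a group-mean difference."""
    return float(np.sqrt(ms_within * (1.0 / n_a + 1.0 / n_b)))


def bonferroni_pairwise(
    scores: np.ndarray,
    labels: np.ndarray,
    ms_within: float | None = None,
    df_within: int | None = None,
) -> list[PairwiseComparison]:
    """All pairwise group comparisons with Bonferroni-adjusted p-values.

    The pooled within-group mean square from the ANOVA is used for every
    standard error (recomputed here if not supplied); each two-sided t
    probability is multiplied by the number of comparisons and capped at 1.
    """
    groups = _groups(scores, labels)
    if ms_within is None or df_within is None:
        a = one_way_anova(scores, labels)
        ms_within, df_within = a.ms_within, a.df_within
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    out = []
    for a_name, b_name in combinations(names, 2):
        va, vb = groups[a_name], groups[b_name]
        diff = float(va.mean() - vb.mean())
        se = pooled_se(ms_within, va.size, vb.size)
        t = diff / se
        p = min(1.0, m * 2.0 * float(stats.t.sf(abs(t), df_within)))
        out.append(PairwiseComparison(a_name, b_name, diff, se, p))
    return out


def group_descriptives(
    scores: np.ndarray, labels: np.ndarray, confidence: float = 0.95
) -> list[GroupDescriptives]:
    """Per-group n, mean, sd, se and the Student-t confidence interval."""
    groups = _groups(scores, labels)
    out = []
    for name, v in groups.items():
        n = int(v.size)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        se = sd / np.sqrt(n)
        tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
        out.append(
            GroupDescriptives(
                species=name,
                n=n,
                mean=mean,
                sd=sd,
                se=float(se),
                ci_low=mean - tcrit * se,
                ci_high=mean + tcrit * se,
            )
        )
    return out


def describe_scores(
    scores: pd.DataFrame, labels: np.ndarray, confidence: float = 0.95
) -> pd.DataFrame:
    """Descriptives of every score column, stacked into one tidy table."""
    rows = []
    for comp in scores.columns:
        for d in group_descriptives(scores[comp].to_numpy(), labels, confidence):
            rows.append({"component": comp, **asdict(d)})
    return pd.DataFrame(rows)


def derive_thresholds(
    descriptives: pd.DataFrame,
    plan: list[tuple[str, str, str]] | None = None,
) -> list[Threshold]:
    """Place a decision threshold in the CI gap of each planned species pair.

    ``plan`` lists (component, species_a, species_b) triples; the species with
    the higher mean on that component is taken as the high side, and the
    threshold is the midpoint between the low species' CI upper bound and the
    high species' CI lower bound. Overlapping CIs raise
    :class:`OverlappingIntervals` rather than guessing a boundary.
    """
    plan = plan if plan is not None else DEFAULT_PLAN
    out = []
    for comp, sp_a, sp_b in plan:
        sub = descriptives[descriptives["component"] == comp].set_index("species")
        for sp in (sp_a, sp_b):
            if sp not in sub.index:
                raise MissingComponent(f"no descriptives for {sp} on {comp}")
        low, high = (sp_a, sp_b) if sub.loc[sp_a, "mean"] <= sub.loc[sp_b, "mean"] else (sp_b, sp_a)
        upper_low = float(sub.loc[low, "ci_high"])
        lower_high = float(sub.loc[high, "ci_low"])
        if upper_low >= lower_high:
            raise OverlappingIntervals(
                f"{comp}: CIs of {low} and {high} overlap "
                f"([..., {upper_low:.3f}] vs [{lower_high:.3f}, ...])"
            )
        out.append(Threshold(comp, low, high, (upper_low + lower_high) / 2.0))
    return out


def suggest_plan(
    descriptives: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """Pick, for each species pair, the component with the widest CI gap.

    A refit model's components are not guaranteed to line up with any fixed
    plan (rotation order and sign are data-dependent), so the pipeline selects
    the best-separating retained component per pair from the training-set
    descriptives. Raises :class:`OverlappingIntervals` if no component
    separates a pair.
    """
    plan = []
    for sp_a, sp_b in pairs:
        best, best_gap = None, 0.0
        for comp in descriptives["component"].unique():
            sub = descriptives[descriptives["component"] == comp].set_index("species")
            if sp_a not in sub.index or sp_b not in sub.index:
                continue
            low, high = (sp_a, sp_b) if sub.loc[sp_a, "mean"] <= sub.loc[sp_b, "mean"] else (sp_b, sp_a)
            gap = float(sub.loc[high, "ci_low"] - sub.loc[low, "ci_high"])
            if gap > best_gap:
                best, best_gap = (comp, sp_a, sp_b), gap
        if best is None:
            raise OverlappingIntervals(f"no component separates {sp_a} and {sp_b}")
        plan.append(best)
    return plan


def classify_pairwise(
    scores: pd.DataFrame,
    labels: np.ndarray,
    thresholds: list[Threshold],
) -> dict:
    """Label each plant of a threshold's species pair by its score side.

    A score strictly above the threshold predicts the high-side species; a
    score at or below it (including exact ties) predicts the low side.
    Returns a report with per-threshold accuracy and per-image predictions.
    """
    labels = np.asarray(labels)
    report = {"comparisons": [], "predictions": []}
    for thr in thresholds:
        if thr.component not in scores.columns:
            raise MissingComponent(f"scores lack component {thr.component}")
        sel = np.isin(labels, [thr.species_low, thr.species_high])
        vals = scores.loc[sel, thr.component].to_numpy()
        truth = labels[sel]
        pred = np.where(vals > thr.value, thr.species_high, thr.species_low)
        n_correct = int((pred == truth).sum())
        n_total = int(sel.sum())
        report["comparisons"].append(
            {
                "component": thr.component,
                "pair": [thr.species_low, thr.species_high],
                "threshold": thr.value,
                "n_correct": n_correct,
                "n_total": n_total,
                "accuracy_pct": 100.0 * n_correct / n_total if n_total else float("nan"),
            }
        )
        idx = scores.index[sel]
        for i, t, p_, v in zip(idx, truth, pred, vals):
            report["predictions"].append(
                {
                    "index": int(i) if np.issubdtype(type(i), np.integer) else i,
                    "component": thr.component,
                    "true": str(t),
                    "predicted": str(p_),
                    "score": float(v),
                }
            )
    return report


def evaluate_holdout(
    table: pd.DataFrame, split_fraction: float = 0.2, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split without replacement; test size = round(f·n)."""
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie strictly between 0 and 1")
    n = len(table)
    n_test = int(round(split_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.iloc[train_idx].copy(), table.iloc[test_idx].copy()


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
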