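"""Nonparametric male/female comparisons.

Sex contrasts are tested with two-sided Wilcoxon rank-sum (Mann-Whitney)
tests — exact enumeration when both groups have ≤ 10 tie-free observations,
tie-corrected normal approximation otherwise — and, for cumulative-error
curves, a Kruskal-Wallis test over the last hour (60 per-minute values per
animal) of cumulative error.  Raw p-values are reported per contrast with
no multiplicity correction; the report carries the number of contrasts so
users can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .baseline import ErrorCurve

__all__ = [
    "ComparisonResult",
    "rank_sum_test",
    "kruskal_last_hour",
    "sex_comparison_report",
    "ALPHA",
]

#: Conventional significance threshold used for effect-direction reporting.
ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    statistic_name: str  # "rank_sum_W" | "kruskal_chi2"
    statistic_value: float
    p_value: float
    group_sizes: tuple[int, ...]
    effect_direction: str  # "male_greater" | "female_greater" | "none"

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _direction(males, females) -> str:
    dm, df = float(np.median(males)), float(np.median(females))
    if dm > df:
        return "male_greater"
    if df > dm:
        return "female_greater"
    return "none"


def rank_sum_test(males, females) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test of males vs. females.

    The reported statistic is W, the rank sum of the male group.  Exact
    enumeration is used when both groups have ≤ 10 observations and the
    pooled sample is tie-free.
    """
    males = np.asarray(males, dtype=float)
    females = np.asarray(females, dtype=float)
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([males, females])
    if np.ptp(pooled) == 0:  # every observation tied: no evidence either way
        u, p = len(males) * len(females) / 2.0, 1.0
    else:
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = (
            "exact" if (len(males) <= 10 and len(females) <= 10 and tie_free)
            else "asymptotic"
        )
        res = sps.mannwhitneyu(
            males, females, alternative="two-sided", method=method,
            use_continuity=False,
        )
        u, p = float(res.statistic), float(res.pvalue)
    w = u + len(males) * (len(males) + 1) / 2.0
    return ComparisonResult(
        statistic_name="rank_sum_W",
        statistic_value=w,
        p_value=float(min(p, 1.0)),
        group_sizes=(len(males), len(females)),
        effect_direction=_direction(males, females),
    )


def kruskal_last_hour(
    curves_by_group: dict[str, list[ErrorCurve]],
    n_minutes: int = 60,
    per_animal_mean: bool = False,
) -> ComparisonResult:
    """Kruskal-Wallis on the last hour of cumulative error scores.

    The final ``n_minutes`` cumulative values of every animal are pooled
    into that animal's group (or averaged per animal first when
    ``per_animal_mean``), and a tie-corrected Kruskal-Wallis H (χ²) test is
    run across groups.
    """
    if len(curves_by_group) < 2:
        raise ValueError("need at least 2 groups")
    groups: dict[str, np.ndarray] = {}
    for name, curves in curves_by_group.items():
        chunks = []
        for c in curves:
            if len(c.cumulative) < n_minutes:
                raise ValueError(
                    f"curve {c.animal_id} shorter than {n_minutes} minutes"
                )
            tail = c.cumulative[-n_minutes:]
            chunks.append(np.array([tail.mean()]) if per_animal_mean else tail)
        groups[name] = np.concatenate(chunks)
    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:
        chi2, p = 0.0, 1.0  # all values tied: no evidence of group differences
    else:
        chi2, p = sps.kruskal(*samples)
    direction = "none"
    if set(groups) == {"male", "female"}:
        direction = _direction(groups["male"], groups["female"])
    return ComparisonResult(
        statistic_name="kruskal_chi2",
        statistic_value=float(chi2),
        p_value=float(p),
        group_sizes=tuple(len(g) for g in samples),
        effect_direction=direction,
    )


def sex_comparison_report(
    contrasts: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Aggregate per-animal contrast values into one rank-sum report table.

    ``contrasts`` maps a contrast name to ``(male_values, female_values)``
    arrays of per-animal summary values.  One row per contrast with the
    statistic, p-value and median-based direction; ``n_contrasts`` is
    attached so downstream users can correct for multiplicity.
    """
    if not contrasts:
        raise ValueError("no contrasts supplied")
    rows = []
    for name, (males, females) in contrasts.items():
        if males is None or females is None:
            raise ValueError(f"contrast {name!r} is missing a group")
        r = rank_sum_test(males, females)
        rows.append(
            {
                "contrast": name,
                "statistic_name": r.statistic_name,
                "statistic": r.statistic_value,
                "p_value": r.p_value,
                "n_male": r.group_sizes[0],
                "n_female": r.group_sizes[1],
                "direction": r.effect_direction,
                "significant": r.significant,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_contrasts"] = len(rows)
    return df
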