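"""Group statistics: one-way ANOVA with Bonferroni-corrected pairwise
baseline contrasts, and the Mann-Whitney U (Wilcoxon rank-sum) test.

Period contrasts (baseline vs. ictal / early / late postictal) use ANOVA
across the four periods followed by baseline-versus-each pairwise t tests
with the p values multiplied by the family size of 3 and capped at 1.
Independent two-group contrasts (hit vs. miss, spared vs. impaired,
phase vs. Pre-Aud) use the Mann-Whitney U test; the exact null
distribution is enumerated for small tie-free samples, otherwise the
normal approximation with tie and continuity corrections is used.
Significance level alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .session import ValidationError

__all__ = ["GroupComparison", "MWResult", "anova_with_bonferroni", "mann_whitney_u", "ALPHA"]

ALPHA = 0.05
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    grouping: str
    groups: tuple[str, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sem: tuple[float, ...]
    test: str
    statistic: float
    p_raw: float
    p_corrected: float

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA

    def as_row(self) -> dict:
        return {
            "metric": self.metric,
            "grouping": self.grouping,
            "groups": "|".join(self.groups),
            "n": "|".join(map(str, self.n)),
            "mean": "|".join(f"{m:.6g}" for m in self.mean),
            "sem": "|".join(f"{s:.6g}" for s in self.sem),
            "test": self.test,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class MWResult:
    u: float
    p: float
    n_a: int
    n_b: int
    method: str


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def anova_with_bonferroni(
    values_by_period: dict[str, np.ndarray],
    baseline_key: str = "baseline",
    metric: str = "",
) -> list[GroupComparison]:
    """One-way ANOVA across periods + Bonferroni pairwise baseline contrasts.

    Returns the omnibus comparison followed by one ``baseline vs period``
    comparison per non-baseline period, each raw t-test p multiplied by the
    family size (number of pairwise comparisons) and capped at 1.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_period.items()}
    if baseline_key not in groups:
        raise ValidationError(f"missing baseline group {baseline_key!r}")
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    names = list(groups)
    f, p = sstats.f_oneway(*groups.values())
    out = [
        GroupComparison(
            metric=metric,
            grouping="periods",
            groups=tuple(names),
            n=tuple(v.size for v in groups.values()),
            mean=tuple(float(v.mean()) for v in groups.values()),
            sem=tuple(_sem(v) for v in groups.values()),
            test="one-way ANOVA",
            statistic=float(f),
            p_raw=float(p),
            p_corrected=float(p),
        )
    ]
    others = [k for k in names if k != baseline_key]
    m = len(others)
    for k in others:
        t, p_raw = sstats.ttest_ind(groups[baseline_key], groups[k])
        out.append(
            GroupComparison(
                metric=metric,
                grouping=f"{baseline_key}-vs-{k}",
                groups=(baseline_key, k),
                n=(groups[baseline_key].size, groups[k].size),
                mean=(float(groups[baseline_key].mean()), float(groups[k].mean())),
                sem=(_sem(groups[baseline_key]), _sem(groups[k])),
                test=f"t (Bonferroni x{m})",
                statistic=float(t),
                p_raw=float(p_raw),
                p_corrected=float(min(1.0, p_raw * m)),
            )
        )
    return out


def mann_whitney_u(a: np.ndarray, b: np.ndarray, two_sided: bool = True) -> MWResult:
    """Mann-Whitney U with exact small-sample p and tie-corrected approximation.

    Exact enumeration of the rank-sum null when ``min(n_a, n_b) <= 8`` and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    alternative = "two-sided" if two_sided else "greater"
    res = sstats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return MWResult(
        u=float(res.statistic), p=float(res.pvalue), n_a=int(a.size), n_b=int(b.size),
        method=method,
    )


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in comparisons])
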