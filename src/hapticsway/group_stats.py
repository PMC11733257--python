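"""Condition-level inference: one-way repeated-measures ANOVA and
Tukey-corrected pairwise comparisons.

Implements the classical within-subject decomposition directly (it is a
few lines of sum-of-squares arithmetic) and evaluates Tukey adjusted
p-values with scipy's studentized-range distribution.  Uncorrected degrees
of freedom are reported by default; a Greenhouse-Geisser corrected p is
attached as a labelled extra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = ["ConditionTable", "AnovaResult", "rm_anova", "tukey_pairwise"]


@dataclass
class ConditionTable:
    """Complete subject x condition matrix of per-subject condition means."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D subject x condition array")
        n, k = self.values.shape
        if k != len(self.labels):
            raise ConfigurationError("labels must match the number of conditions")
        if n < 2 or k < 2:
            raise ConfigurationError("need at least 2 subjects and 2 conditions")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("table must be complete (no missing cells)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ms_error: float
    gg_epsilon: float = 1.0
    p_gg: float = np.nan
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def rm_anova(tab: ConditionTable) -> AnovaResult:
    """Classical one-way within-subject F = MS_condition / MS_error.

    Subject means are removed (the subject main effect is partitioned out),
    so F is invariant to adding any per-subject constant.
    """
    y = tab.values
    n, k = y.shape
    grand = y.mean()
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = y - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else np.inf)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eps = _gg_epsilon(y)
    p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), df1=df1, df2=df2, p=p, ms_error=float(ms_err),
        gg_epsilon=float(eps), p_gg=p_gg,
    )


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the condition covariance."""
    k = y.shape[1]
    S = np.cov(y, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def tukey_pairwise(tab: ConditionTable, anova: AnovaResult | None = None) -> dict:
    """Tukey HSD adjusted p per condition pair.

    q = |mean_i - mean_j| / sqrt(MS_error / n) referred to the studentized
    range distribution with k groups and the ANOVA error df.  Uses the
    within-subject MS_error, consistent with the repeated-measures design.
    """
    if anova is None:
        anova = rm_anova(tab)
    y = tab.values
    n, k = y.shape
    se = np.sqrt(anova.ms_error / n)
    means = y.mean(axis=0)
    out: dict[tuple[str, str], float] = {}
    for i, j in combinations(range(k), 2):
        if se == 0:
            p = 1.0 if means[i] == means[j] else 0.0
        else:
            q = abs(means[i] - means[j]) / se
            p = float(stats.studentized_range.sf(q, k, anova.df2))
        out[(tab.labels[i], tab.labels[j])] = p
    anova.pairwise = out
    return out
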