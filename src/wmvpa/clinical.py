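"""Cohort-comparison statistics and weighting-covariate association checks.

Wraps the standard nonparametric tests used to compare favorable (FO) and
non-favorable (Non-FO) outcome groups — Fisher's exact test on the
febrile-seizure history, Mann-Whitney U on continuous characteristics,
four-group Kruskal-Wallis — plus Spearman correlation between a
per-subject classifier weighting and clinical covariates, and the
support-vector vs non-support-vector group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "febrile_contingency",
    "mann_whitney_u",
    "kruskal_wallis",
    "weighting_covariate_correlation",
    "sv_vs_nonsv_comparison",
]


@dataclass
class ContingencyTable2x2:
    """Counts with rows = febrile yes/no and columns = FO / Non-FO."""

    a: int  # febrile, FO
    b: int  # febrile, Non-FO
    c: int  # not febrile, FO
    d: int  # not febrile, Non-FO

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if (self.a + self.b == 0 and self.c + self.d == 0) \
                or (self.a + self.c == 0 and self.b + self.d == 0):
            raise ValueError("table margins must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher's exact p by the minimum-likelihood rule.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) \
        else np.asarray(table, dtype=int)
    if arr.min() < 0:
        raise ValueError("cell counts must be non-negative")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def febrile_contingency(clinical: pd.DataFrame) -> ContingencyTable2x2:
    """Build the febrile-seizures x outcome table from a clinical table."""
    fo = clinical["label"] == 1
    feb = clinical["febrile"] == 1
    return ContingencyTable2x2(
        a=int((feb & fo).sum()), b=int((feb & ~fo).sum()),
        c=int((~feb & fo).sum()), d=int((~feb & ~fo).sum()),
    )


def mann_whitney_u(group_a, group_b, method: str = "auto") -> tuple[float, float, str]:
    """Mann-Whitney U with an exact or normal-approximation p.

    Returns ``(U_a, p, backend)``. The exact null distribution is used
    when there are no ties and min(n_a, n_b) <= 12; otherwise a normal
    approximation with tie correction and a centered continuity
    correction (|U - mean| reduced by 1/2, floored at 0, so identical
    samples give p = 1 exactly).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    has_ties = len(np.unique(combined)) < len(combined)
    if method == "auto":
        method = "exact" if (not has_ties and min(na, nb) <= 12) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise ValueError("exact backend is undefined with ties")
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue)
        return u_a, p, "exact"
    mean = na * nb / 2.0
    n = na + nb
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var == 0:  # every observation identical
        return u_a, 1.0, "asymptotic"
    z = max(abs(u_a - mean) - 0.5, 0.0) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return u_a, p, "asymptotic"


def kruskal_wallis(groups: dict | list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = groups - 1)."""
    samples = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in samples):
        raise ValueError("every group must be non-empty")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in samples])
    if len(np.unique(flat)) == 1:
        return 0.0, 1.0  # all observations tied: no rank variation
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def weighting_covariate_correlation(weighting, covariate) -> tuple[float, float]:
    """Spearman rank correlation between per-subject weighting and a covariate."""
    w = np.asarray(weighting, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if w.shape != c.shape or w.size < 3:
        raise ValueError("need equal-length vectors of at least 3 subjects")
    if np.all(w == w[0]) or np.all(c == c[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(w, c)
    return float(rho), float(p)


def sv_vs_nonsv_comparison(
    alpha: np.ndarray,
    clinical: pd.DataFrame,
    characteristics=("age_at_onset", "followup_months", "seizure_freq_per_month"),
) -> pd.DataFrame:
    """Compare support-vector and non-support-vector patients within outcomes.

    Subjects are partitioned by whether their dual coefficient in the
    final model is positive, crossed with the FO / Non-FO label; each
    clinical characteristic is compared across the resulting four groups
    with a Kruskal-Wallis test. A degenerate partition (e.g. every
    subject a support vector) is reported with ``degenerate=True`` and no
    p-value.
    """
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) != len(clinical):
        raise ValueError("alpha and clinical table must cover the same subjects")
    is_sv = alpha > 0
    fo = clinical["label"].to_numpy() == 1
    partition = {
        "SV_FO": is_sv & fo, "SV_NonFO": is_sv & ~fo,
        "NonSV_FO": ~is_sv & fo, "NonSV_NonFO": ~is_sv & ~fo,
    }
    occupied = {k: m for k, m in partition.items() if m.any()}
    degenerate = len(occupied) < 2
    rows = []
    for char in characteristics:
        vals = clinical[char].to_numpy(dtype=float)
        sizes = {k: int(m.sum()) for k, m in partition.items()}
        if degenerate:
            rows.append({"characteristic": char, "H": np.nan, "p": np.nan,
                         "degenerate": True, **sizes})
            continue
        h, p = kruskal_wallis([vals[m] for m in occupied.values()])
        rows.append({"characteristic": char, "H": h, "p": p,
                     "degenerate": False, **sizes})
    return pd.DataFrame(rows)
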