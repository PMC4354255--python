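"""Partial prey consumption: proportions and Kruskal-Wallis tests.

Amphipods often kill prey and eat only part of each carcass, which distorts
curves built on "prey killed".  Partial consumption was recorded only when
two or more prey in a pot were killed and partly eaten, so the analysis unit
is the per-pot proportion of kills that were partial, restricted to pots
with at least two kills.  Proportion data of this kind are bounded, heavily
tied and heteroscedastic, so group effects (density, predator species,
parasitism, fish presence) are tested nonparametrically with tie-corrected
Kruskal-Wallis statistics; density is treated as a seven-level factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KWResult",
    "kruskal_wallis",
    "partial_consumption_analysis",
    "PartialConsumptionResult",
]

#: total sample size at or below which the K-W p-value is computed by full
#: enumeration of group assignments instead of the chi-square approximation
EXACT_ENUMERATION_N = 10


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis H with df = groups - 1."""

    h: float
    df: int
    p: float
    group_sizes: tuple
    method: str  # "chi2", "exact", or "degenerate"


def _h_statistic(values: np.ndarray, labels: np.ndarray, groups) -> float:
    n = len(values)
    ranks = stats.rankdata(values)
    rank_sum_term = 0.0
    for g in groups:
        r = ranks[labels == g]
        rank_sum_term += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * rank_sum_term - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_correction == 0.0:  # every observation identical
        return 0.0
    return h / tie_correction


def _exact_p(values, labels, groups, h_obs):
    """Permutation p-value by full enumeration of group assignments.

    The multiset of values is fixed; every partition of the observations into
    groups of the observed sizes is equally likely under the null, so the
    p-value is the fraction of partitions with H >= observed.
    """
    n = len(values)
    sizes = [int(np.sum(labels == g)) for g in groups]
    count = 0
    total = 0
    indices = list(range(n))

    def assignments(remaining, size_idx):
        if size_idx == len(sizes) - 1:
            yield [tuple(remaining)]
            return
        for combo in itertools.combinations(remaining, sizes[size_idx]):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, size_idx + 1):
                yield [combo] + tail

    for parts in assignments(indices, 0):
        perm_labels = np.empty(n, dtype=object)
        for g, part in zip(groups, parts):
            for i in part:
                perm_labels[i] = g
        total += 1
        if _h_statistic(values, perm_labels, groups) >= h_obs - 1e-12:
            count += 1
    return count / total


def kruskal_wallis(values, group_labels) -> KWResult:
    """Kruskal-Wallis rank test of k independent groups.

    ``H`` uses the standard tie correction ``1 - sum(t^3 - t) / (N^3 - N)``.
    The p-value comes from the chi-square(k-1) approximation, replaced by
    full permutation enumeration when the total sample size is <= 10.  If
    every observation is identical the degenerate convention ``H = 0, p = 1``
    applies.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels, dtype=object)
    if len(values) != len(labels):
        raise ValueError("values and group labels differ in length")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups)}")
    sizes = tuple(int(np.sum(labels == g)) for g in groups)
    if min(sizes) == 0:
        raise ValueError("every group must be nonempty")

    if np.ptp(values) == 0:
        return KWResult(0.0, len(groups) - 1, 1.0, sizes, "degenerate")

    h = _h_statistic(values, labels, groups)
    df = len(groups) - 1
    if len(values) <= EXACT_ENUMERATION_N:
        p = _exact_p(values, labels, groups, h)
        return KWResult(float(h), df, float(p), sizes, "exact")
    p = float(stats.chi2.sf(h, df))
    return KWResult(float(h), df, p, sizes, "chi2")


@dataclass
class PartialConsumptionResult:
    """Proportion tables and per-factor Kruskal-Wallis tests."""

    proportions: pd.DataFrame
    tests: pd.DataFrame
    observations: pd.DataFrame = field(repr=False, default=None)
    skipped: bool = False


_FACTORS = {
    "density": "density",
    "predator_species": "predator_species",
    "parasitised": "parasitised",
    "fish_present": "fish_present",
}


def _proportion_rows(records, scope, factor, column):
    rows = []
    for level, grp in records.groupby(column):
        killed = int(grp["killed"].sum())
        partial = int(grp["partially_eaten"].sum())
        rows.append(
            {
                "scope": scope,
                "factor": factor,
                "group": level,
                "n_pots": len(grp),
                "killed": killed,
                "partially_eaten": partial,
                "proportion": partial / killed if killed > 0 else np.nan,
            }
        )
    return rows


def partial_consumption_analysis(records: pd.DataFrame) -> PartialConsumptionResult:
    """Partial-consumption summary per prey species and pooled over prey.

    Group proportions aggregate counts (``sum partial / sum killed``; groups
    with no kills are reported missing).  Each Kruskal-Wallis test uses the
    per-pot proportion among kills as the observation, restricted to pots
    with >= 2 kills (pots below that threshold cannot express partial
    consumption under the recording rule, pooling over amphipod species as
    in the density summaries).  If no pot anywhere has >= 2 kills the tests
    are skipped with an explicit flag.
    """
    records = records.reset_index(drop=True)
    eligible = records[records["killed"] >= 2].copy()
    eligible["prop_partial"] = eligible["partially_eaten"] / eligible["killed"]

    prop_rows = []
    test_rows = []
    scopes = [("pooled", records, eligible)]
    for prey, grp in records.groupby("prey_species"):
        scopes.append((prey, grp, eligible[eligible["prey_species"] == prey]))

    for scope, scope_records, scope_obs in scopes:
        for factor, column in _FACTORS.items():
            prop_rows.extend(_proportion_rows(scope_records, scope, factor, column))
            if len(scope_obs) == 0 or scope_obs[column].nunique() < 2:
                test_rows.append(
                    {
                        "scope": scope,
                        "factor": factor,
                        "n_obs": len(scope_obs),
                        "H": np.nan,
                        "df": np.nan,
                        "p": np.nan,
                        "skipped": True,
                    }
                )
                continue
            kw = kruskal_wallis(
                scope_obs["prop_partial"].to_numpy(), scope_obs[column].to_numpy()
            )
            test_rows.append(
                {
                    "scope": scope,
                    "factor": factor,
                    "n_obs": len(scope_obs),
                    "H": kw.h,
                    "df": kw.df,
                    "p": kw.p,
                    "skipped": False,
                }
            )

    skipped = len(eligible) == 0
    return PartialConsumptionResult(
        proportions=pd.DataFrame(prop_rows),
        tests=pd.DataFrame(test_rows),
        observations=eligible,
        skipped=skipped,
    )
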