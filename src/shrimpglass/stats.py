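"""Group statistics for small reflectance samples.

Two procedures: the unpaired two-sample Wilcoxon rank-sum test, computed
exactly by complete enumeration of group assignments whenever the pooled
sample is small (which it always is here: five species, 2-3 individuals
each), and a linear model of reflectance on cleaner status assessed by
an ANOVA comparison of the full model against the intercept-only model.

The exact test enumerates all C(n+m, n) ways of assigning the pooled
observations to the first group, using midranks so ties are handled by
a complete permutation null rather than an asymptotic correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "StatusModelResult",
    "wilcoxon_exact",
    "fit_status_model",
    "run_cleaner_contrasts",
    "FOCAL_SPECIES",
]

#: species of the five-species comparison and their grouping labels
FOCAL_SPECIES = {
    "Ancylomenes pedersoni": {"status": "obligate", "ultrastructure": True, "white": True},
    "Lysmata amboinensis": {"status": "obligate", "ultrastructure": True, "white": True},
    "Lysmata debelius": {"status": "obligate", "ultrastructure": True, "white": True},
    "Periclimenes yucatanicus": {"status": "facultative", "ultrastructure": False, "white": True},
    "Lysmata boggessi": {"status": "non-cleaner", "ultrastructure": False, "white": False},
}


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-sample rank-sum comparison."""

    labels: tuple[str, str]
    n: int
    m: int
    statistic: float        # rank sum W of the first group (midranks)
    p_value: float
    method: str             # "exact" | "normal-approximation"

    @property
    def u_statistic(self) -> float:
        return self.statistic - self.n * (self.n + 1) / 2.0


def wilcoxon_exact(x, y, labels: tuple[str, str] = ("x", "y"), exact_limit: int = 20) -> GroupComparison:
    """Unpaired two-sample Wilcoxon rank-sum test, exact for small samples.

    The two-sided p-value is twice the smaller tail probability of the
    rank sum W under the permutation null (point mass included), capped
    at 1.  Beyond ``exact_limit`` pooled observations a normal
    approximation with tie-corrected variance and continuity correction
    is used; the ``method`` field records which route was taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks under ties
    w_obs = float(np.sum(ranks[:n]))

    if n + m <= exact_limit:
        total = comb(n + m, n)
        le = 0
        ge = 0
        for idx in combinations(range(n + m), n):
            w = ranks[list(idx)].sum()
            if w <= w_obs + 1e-9:
                le += 1
            if w >= w_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return GroupComparison(labels, n, m, w_obs, p, "exact")

    mu = n * (n + m + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n + m) * (n + m - 1.0))
    var = n * m / 12.0 * (n + m + 1.0 - tie_term)
    if var <= 0:
        return GroupComparison(labels, n, m, w_obs, 1.0, "normal-approximation")
    z = (w_obs - mu - np.sign(w_obs - mu) * 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return GroupComparison(labels, n, m, w_obs, p, "normal-approximation")


@dataclass(frozen=True)
class StatusModelResult:
    """Linear model of reflectance on a categorical factor, with the
    ANOVA comparison of full vs intercept-only model."""

    levels: tuple[str, ...]
    group_means: dict
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    rss_full: float
    rss_null: float


def fit_status_model(
    dataset: pd.DataFrame,
    group_col: str = "status",
    value_col: str = "reflectance",
) -> StatusModelResult:
    """Least-squares fit of value ~ factor and full-vs-null F comparison.

    Identical to the closed-form one-way ANOVA: the full model fits one
    mean per level, the null model the grand mean, and
    F = ((RSS0 - RSS1)/(k-1)) / (RSS1/(N-k)).
    """
    groups = dataset.groupby(group_col, sort=False)[value_col]
    levels = tuple(groups.groups.keys())
    if len(levels) < 2:
        raise ValueError("need at least two factor levels")
    y = dataset[value_col].to_numpy(dtype=float)
    n_total = len(y)
    k = len(levels)
    if n_total - k < 1:
        raise ValueError("no residual degrees of freedom")
    means = groups.mean()
    fitted = dataset[group_col].map(means).to_numpy(dtype=float)
    rss_full = float(np.sum((y - fitted) ** 2))
    rss_null = float(np.sum((y - y.mean()) ** 2))
    df1, df2 = k - 1, n_total - k
    if rss_full == 0.0:
        f = np.inf if rss_null > rss_full else 0.0
        p = 0.0 if rss_null > rss_full else 1.0
    else:
        f = (rss_null - rss_full) / df1 / (rss_full / df2)
        p = float(sps.f.sf(f, df1, df2))
    return StatusModelResult(levels, dict(means), float(f), (df1, df2), p, rss_full, rss_null)


def _individual_means(dataset: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("status", "ultrastructure") if c in dataset.columns]
    agg = {"reflectance": "mean", **{c: "first" for c in cols}}
    return dataset.groupby(["species", "individual"], sort=False).agg(agg).reset_index()


def run_cleaner_contrasts(dataset: pd.DataFrame) -> dict:
    """The four published contrasts on per-individual reflectance means.

    1. obligate vs non-obligate cleaners, rank-sum test;
    2. linear model with three-level cleaner status, ANOVA comparison;
    3. among white-antennae species, ultrastructure present vs absent
       (the three obligate species vs P. yucatanicus), rank-sum test;
    4. linear model of ultrastructure presence among white species.
    """
    missing = sorted(set(FOCAL_SPECIES) - set(dataset["species"].unique()))
    if missing:
        raise ValueError(f"dataset is missing species: {missing}")
    indiv = _individual_means(dataset)
    if "status" not in indiv.columns:
        indiv["status"] = indiv["species"].map(lambda s: FOCAL_SPECIES[s]["status"])
    indiv["ultrastructure"] = indiv["species"].map(lambda s: FOCAL_SPECIES[s]["ultrastructure"])
    indiv["white"] = indiv["species"].map(lambda s: FOCAL_SPECIES[s]["white"])

    obligate = indiv.loc[indiv["status"] == "obligate", "reflectance"]
    non_obligate = indiv.loc[indiv["status"] != "obligate", "reflectance"]
    white = indiv[indiv["white"]]
    ultra = white.loc[white["ultrastructure"], "reflectance"]
    no_ultra = white.loc[~white["ultrastructure"], "reflectance"]

    return {
        "status_wilcoxon": wilcoxon_exact(
            obligate, non_obligate, labels=("obligate", "non-obligate")
        ),
        "status_model": fit_status_model(indiv, group_col="status"),
        "ultrastructure_wilcoxon": wilcoxon_exact(
            ultra, no_ultra, labels=("ultrastructure", "no-ultrastructure")
        ),
        "ultrastructure_model": fit_status_model(white, group_col="ultrastructure"),
    }
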