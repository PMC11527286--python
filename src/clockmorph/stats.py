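"""Normality-gated group-comparison workflow and contingency statistics.

The routing mirrors common practice in the fly circadian field: every group
is first screened with the D'Agostino–Pearson omnibus normality test
(alpha = 0.05); if all groups pass, parametric tests are used (unpaired
t-test for two groups, one-way ANOVA with Tukey HSD for three or more),
otherwise nonparametric ones (Mann–Whitney U, Kruskal–Wallis with Dunn's
multiple-comparison post hoc).  Percent-rhythmicity contrasts use Fisher's
exact test on 2×2 tables, and subcellular-localisation time courses use a
two-way ANOVA (Type II sums of squares).

Dunn's post hoc is implemented here (rank-sum z statistics with tie
correction) with Bonferroni family adjustment by default, Holm optionally.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "PosthocPair",
    "TestReport",
    "normality_gate",
    "compare_groups",
    "fisher_exact_2x2",
    "two_way_anova",
    "dunn_posthoc",
    "significance_stars",
]

_MIN_NORMALITY_N = 8  # omnibus test minimum sample size


@dataclass(frozen=True)
class GroupData:
    """A labelled sample of per-brain or per-fly observations."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError(f"group {self.label!r} needs >= 2 values")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"group {self.label!r} contains non-finite values")


class PosthocPair(NamedTuple):
    pair: tuple[str, str]
    p_raw: float
    p_adjusted: float


@dataclass
class TestReport:
    """Outcome of one routed comparison."""

    family: str  # two_group | multi_group | contingency | two_way
    chosen_test: str
    statistic: float
    p_value: float
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)
    gate: str | None = None  # parametric | nonparametric
    posthoc: list[PosthocPair] = field(default_factory=list)
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    alpha: float = 0.05


def significance_stars(p: float) -> str:
    """Tier labels: * < 0.05, ** < 0.01, *** < 0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_groups(groups: Sequence[GroupData] | Mapping[str, Sequence[float]]
               ) -> list[GroupData]:
    if isinstance(groups, Mapping):
        return [GroupData(k, tuple(v)) for k, v in groups.items()]
    return list(groups)


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def _normality_outcomes(groups: Sequence[GroupData]
                        ) -> dict[str, tuple[float, float]]:
    out = {}
    for g in groups:
        if len(g.values) < _MIN_NORMALITY_N:
            raise ValueError(
                f"group {g.label!r} has n={len(g.values)} < "
                f"{_MIN_NORMALITY_N}; the omnibus normality test is "
                "undefined — pass gate_override='nonparametric'"
            )
        stat, p = sps.normaltest(g.values)
        out[g.label] = (float(stat), float(p))
    return out


def normality_gate(
    groups: Sequence[GroupData] | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> str:
    """'parametric' iff every group passes the D'Agostino–Pearson test."""
    outcomes = _normality_outcomes(_as_groups(groups))
    if all(p > alpha for _, p in outcomes.values()):
        return "parametric"
    return "nonparametric"


# ---------------------------------------------------------------------------
# Dunn's post hoc
# ---------------------------------------------------------------------------

def dunn_posthoc(
    groups: Sequence[GroupData], adjust: str = "bonferroni"
) -> list[PosthocPair]:
    """Dunn's rank-based pairwise z tests with tie correction.

    Two-sided p values with Bonferroni (default) or Holm family adjustment
    over all k(k-1)/2 pairs.
    """
    groups = list(groups)
    values = np.concatenate([g.values for g in groups])
    labels = np.concatenate([
        np.full(len(g.values), i) for i, g in enumerate(groups)
    ])
    n = len(values)
    ranks = sps.rankdata(values)
    # tie correction term
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term

    mean_ranks = [ranks[labels == i].mean() for i in range(len(groups))]
    sizes = [len(g.values) for g in groups]
    raw = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        raw.append(((groups[i].label, groups[j].label), p))

    m = len(raw)
    if adjust == "bonferroni":
        adjusted = [min(1.0, p * m) for _, p in raw]
    elif adjust == "holm":
        order = np.argsort([p for _, p in raw])
        adjusted = [0.0] * m
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[k][1]))
            adjusted[k] = running
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        PosthocPair(pair, p, p_adj)
        for (pair, p), p_adj in zip(raw, adjusted)
    ]


# ---------------------------------------------------------------------------
# routed group comparison
# ---------------------------------------------------------------------------

def compare_groups(
    groups: Sequence[GroupData] | Mapping[str, Sequence[float]],
    gate_override: str | None = None,
    alpha: float = 0.05,
    posthoc_adjust: str = "bonferroni",
) -> TestReport:
    """Route two or more groups through the normality-gated workflow."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if all(np.std(g.values) == 0 for g in groups):
        raise ValueError("all groups are degenerate (zero variance)")

    normality: dict[str, tuple[float, float]] = {}
    if gate_override is None:
        normality = _normality_outcomes(groups)
        gate = (
            "parametric"
            if all(p > alpha for _, p in normality.values())
            else "nonparametric"
        )
    else:
        if gate_override not in ("parametric", "nonparametric"):
            raise ValueError(f"bad gate_override {gate_override!r}")
        gate = gate_override

    arrays = [np.asarray(g.values) for g in groups]
    posthoc: list[PosthocPair] = []
    if len(groups) == 2:
        family = "two_group"
        if gate == "parametric":
            stat, p = sps.ttest_ind(*arrays)
            chosen = "t-test"
        else:
            stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
            chosen = "Mann-Whitney"
    else:
        family = "multi_group"
        if gate == "parametric":
            stat, p = sps.f_oneway(*arrays)
            chosen = "one-way ANOVA"
            res = sps.tukey_hsd(*arrays)
            for i, j in itertools.combinations(range(len(groups)), 2):
                p_pair = float(res.pvalue[i, j])
                posthoc.append(
                    PosthocPair((groups[i].label, groups[j].label),
                                p_pair, p_pair)
                )
        else:
            stat, p = sps.kruskal(*arrays)
            chosen = "Kruskal-Wallis"
            posthoc = dunn_posthoc(groups, adjust=posthoc_adjust)

    return TestReport(
        family=family,
        chosen_test=chosen,
        statistic=float(stat),
        p_value=float(p),
        normality=normality,
        gate=gate,
        posthoc=posthoc,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# contingency and two-way designs
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Returns (conditional-MLE odds ratio, two-sided p).  The p value sums
    hypergeometric probabilities of tables at most as probable as the
    observed one, margins fixed.
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if np.any(table < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every margin must be positive")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    odds = sps.contingency.odds_ratio(table, kind="conditional").statistic
    return float(odds), float(p)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
) -> TestReport:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Requires >= 2 levels per factor and >= 2 replicates in every cell;
    offending cells are named in the error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "A": list(factor_a),
        "B": list(factor_b),
    })
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("both factors need >= 2 levels")
    cell_sizes = df.groupby(["A", "B"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["A"].unique()), sorted(df["B"].unique())], names=["A", "B"]
    )
    cell_sizes = cell_sizes.reindex(full, fill_value=0)
    bad = [f"({a}, {b})" for (a, b), size in cell_sizes.items() if size < 2]
    if bad:
        raise ValueError(
            "cells with fewer than 2 replicates: " + ", ".join(bad)
        )

    model = smf.ols("value ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {
        "A": (float(table.loc["C(A)", "F"]), float(table.loc["C(A)", "PR(>F)"])),
        "B": (float(table.loc["C(B)", "F"]), float(table.loc["C(B)", "PR(>F)"])),
        "A:B": (
            float(table.loc["C(A):C(B)", "F"]),
            float(table.loc["C(A):C(B)", "PR(>F)"]),
        ),
    }
    return TestReport(
        family="two_way",
        chosen_test="two-way ANOVA (Type II)",
        statistic=effects["A:B"][0],
        p_value=effects["A:B"][1],
        effects=effects,
    )
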