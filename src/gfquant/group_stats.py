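"""Group-comparison statistics: normality, one-way ANOVA, Tukey-Kramer HSD.

The experimental design compares genotype groups animal by animal (N is the
number of animals).  Normality of each group is assessed with Shapiro-Wilk
and reported, not used to auto-switch tests; normally distributed measures
are compared with one-way ANOVA followed by post-hoc Tukey tests
(Tukey-Kramer, so unequal group sizes are allowed).  Significance stars
follow the usual convention: * p <= 0.05, ** p <= 0.01, *** p <= 0.001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["StatsReport", "test_normality", "anova_tukey", "stars"]


def test_normality(values) -> float:
    """Shapiro-Wilk p-value for one group of per-animal values.

    Requires n >= 3.  A zero-variance (constant) sample has no defined
    statistic; it is reported as NaN with a warning rather than an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError(f"normality test requires n >= 3, got n = {values.size}")
    if np.ptp(values) == 0:
        logger.warning("constant sample: Shapiro-Wilk undefined, reporting NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(values).pvalue)


def stars(p: float) -> str:
    """Significance code: ns, *, **, *** at 0.05 / 0.01 / 0.001 (inclusive)."""
    p = float(p)
    if np.isnan(p):
        return "ns"
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class StatsReport:
    """ANOVA + Tukey report for one measure across groups."""

    measure: str
    groups: list[str]
    n: dict[str, int]
    means: dict[str, float]
    sems: dict[str, float]
    normality_p: dict[str, float]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, stars
    anova_stars: str = ""

    def __post_init__(self) -> None:
        if not self.anova_stars:
            self.anova_stars = stars(self.anova_p) if np.isfinite(self.anova_p) else "ns"

    def pair_p(self, g1: str, g2: str) -> float:
        t = self.tukey
        row = t[((t.group1 == g1) & (t.group2 == g2)) | ((t.group1 == g2) & (t.group2 == g1))]
        if row.empty:
            raise KeyError(f"no Tukey comparison between {g1!r} and {g2!r}")
        return float(row.iloc[0].p_adj)

    def mean_diff(self, g1: str, g2: str) -> float:
        """Mean of g2 minus mean of g1."""
        return self.means[g2] - self.means[g1]

    def any_star(self) -> bool:
        return bool((self.tukey.p_adj <= 0.05).any())

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "groups": self.groups,
            "n": self.n,
            "means": self.means,
            "sems": self.sems,
            "normality_p": self.normality_p,
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "anova_stars": self.anova_stars,
            "tukey": self.tukey.to_dict(orient="records"),
        }


def _tukey_kramer(arrays: dict) -> pd.DataFrame:
    """All-pairs Tukey-Kramer HSD table.

    Uses the studentized-range statistic with the Kramer adjustment for
    unequal group sizes: ``q_ij = |m_i - m_j| / sqrt(MSE/2 (1/n_i + 1/n_j))``
    with p-values from the studentized range distribution on
    ``(k, N - k)``.  Degenerate zero-variance designs report p = 1 for equal
    means and p = 0 otherwise.
    """
    names = list(arrays)
    k = len(names)
    n_total = sum(a.size for a in arrays.values())
    df_w = n_total - k
    means = {g: a.mean() for g, a in arrays.items()}
    sse = sum(((a - means[g]) ** 2).sum() for g, a in arrays.items())
    mse = sse / df_w if df_w > 0 else 0.0

    pairs = [(names[i], names[j]) for i in range(k) for j in range(i + 1, k)]
    diffs = np.array([means[g2] - means[g1] for g1, g2 in pairs])
    if mse > 0:
        se = np.array(
            [
                np.sqrt(mse / 2.0 * (1.0 / arrays[g1].size + 1.0 / arrays[g2].size))
                for g1, g2 in pairs
            ]
        )
        q = np.abs(diffs) / se
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_adj = sps.studentized_range.sf(q, k, df_w)
        p_adj = np.clip(np.nan_to_num(p_adj, nan=1.0), 0.0, 1.0)
    else:
        p_adj = np.where(np.abs(diffs) > 0, 0.0, 1.0)

    rows = [
        {
            "group1": str(g1),
            "group2": str(g2),
            "meandiff": float(d),
            "p_adj": float(p),
            "stars": stars(float(p)),
        }
        for (g1, g2), d, p in zip(pairs, diffs, p_adj)
    ]
    return pd.DataFrame(rows, columns=["group1", "group2", "meandiff", "p_adj", "stars"])


def anova_tukey(
    table: pd.DataFrame,
    measure: str | None = None,
    value_col: str = "value",
    group_col: str = "group",
) -> StatsReport:
    """One-way ANOVA across groups followed by Tukey-Kramer pairwise tests.

    ``table`` is the long-format group table (one row per animal); if
    ``measure`` is given, rows are filtered on a ``measure`` column first.
    Requires at least two groups with n >= 2 each.
    """
    df = table
    if measure is not None and "measure" in df.columns:
        df = df[df["measure"] == measure]
    df = df[[group_col, value_col]].dropna()
    if df.empty:
        raise ValueError(f"no data for measure {measure!r}")
    group_names = list(pd.unique(df[group_col]))
    if len(group_names) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = {g: df.loc[df[group_col] == g, value_col].to_numpy(dtype=float) for g in group_names}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has n = {a.size} < 2")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_val = sps.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):  # all values identical in every group
        f_stat, p_val = 0.0, 1.0

    means = {g: float(a.mean()) for g, a in arrays.items()}
    sems = {g: float(a.std(ddof=1) / np.sqrt(a.size)) for g, a in arrays.items()}
    ns = {g: int(a.size) for g, a in arrays.items()}
    normality = {}
    for g, a in arrays.items():
        try:
            normality[g] = test_normality(a) if a.size >= 3 else float("nan")
        except ValueError:
            normality[g] = float("nan")

    tukey = _tukey_kramer(arrays)
    return StatsReport(
        measure=measure or value_col,
        groups=[str(g) for g in group_names],
        n=ns,
        means=means,
        sems=sems,
        normality_p=normality,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
    )
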