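"""Habitat-level inference on NRI/NTI values.

Per habitat, a one-tailed one-sample t-test asks whether the mean index
exceeds zero (phylogenetic clustering); a two-way factorial ANOVA with
sequential (Type I) sums of squares partitions variation into substrate,
physiognomy and their interaction; Tukey–Kramer contrasts compare factor
levels using the studentized range distribution.  Shapiro–Wilk and
median-centred Levene checks are reported as advisories — they never block
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "HabitatTestRow",
    "AnovaRow",
    "significance_flag",
    "check_assumptions",
    "one_tailed_t",
    "two_way_anova",
    "tukey_contrast",
]


def significance_flag(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, else NS."""
    if np.isnan(p):
        return "NS"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class HabitatTestRow:
    habitat: str
    metric: str
    count: int
    mean: float
    sd: float
    se: float
    df: int
    t_stat: float
    p_value: float
    flag: str


@dataclass(frozen=True)
class AnovaRow:
    response: str
    term: str  # substrate | physiognomy | interaction | error
    df: int
    sum_sq: float
    mean_square: float
    f_value: float | None
    p_value: float | None


def check_assumptions(groups: dict[str, np.ndarray | list]) -> pd.DataFrame:
    """Shapiro–Wilk per group and median-centred Levene across groups.

    Advisory only.  Groups of constant values get an undefined normality
    entry.  Returns one row per group plus a "levene" row.
    """
    rows = []
    clean = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 3 or np.ptp(v) == 0:
            rows.append({"test": "shapiro", "group": name, "stat": np.nan,
                         "p": np.nan, "note": "undefined (constant or n<3)"})
        else:
            w, p = stats.shapiro(v)
            rows.append({"test": "shapiro", "group": name, "stat": w, "p": p, "note": ""})
        clean[name] = v
    if len(clean) >= 2 and all(len(v) >= 2 for v in clean.values()):
        w, p = stats.levene(*clean.values(), center="median")
        rows.append({"test": "levene", "group": "all", "stat": w, "p": p, "note": ""})
    return pd.DataFrame(rows)


def one_tailed_t(
    values, habitat: str = "", metric: str = "", alternative: str = "greater"
) -> HabitatTestRow:
    """One-sample t-test of mean > 0 (default) on a habitat's index values.

    t = mean/(sd/sqrt(n)); p is the upper tail of Student's t with n−1 df.
    A two-sided test is available via alternative="two-sided".
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    mean = float(v.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    if alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "two-sided":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return HabitatTestRow(habitat, metric, n, mean, sd, float(se), df, float(t),
                          p, significance_flag(p))


def two_way_anova(response, substrate, physiognomy, response_name: str = "index") -> list[AnovaRow]:
    """Two-way factorial ANOVA, sequential (Type I) SS.

    Terms enter in the fixed order substrate → physiognomy → interaction;
    with unbalanced cells the order matters, so it is pinned.  All four cells
    must be non-empty.
    """
    df = pd.DataFrame(
        {"y": np.asarray(response, dtype=float),
         "substrate": list(substrate), "physiognomy": list(physiognomy)}
    )
    cells = df.groupby(["substrate", "physiognomy"]).size()
    n_sub = df["substrate"].nunique()
    n_phy = df["physiognomy"].nunique()
    if n_sub < 2 or n_phy < 2 or len(cells) < n_sub * n_phy or (cells == 0).any():
        raise ValueError(f"empty design cell(s); counts:\n{cells}")
    model = smf.ols("y ~ C(substrate) * C(physiognomy)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    name_map = {
        "C(substrate)": "substrate",
        "C(physiognomy)": "physiognomy",
        "C(substrate):C(physiognomy)": "interaction",
        "Residual": "error",
    }
    rows = []
    for raw, r in tab.iterrows():
        term = name_map[raw]
        d = int(r["df"])
        ss = float(r["sum_sq"])
        ms = ss / d
        f = None if term == "error" else float(r["F"])
        p = None if term == "error" else float(r["PR(>F)"])
        rows.append(AnovaRow(response_name, term, d, ss, ms, f, p))
    return rows


def anova_frame(rows: list[AnovaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "response": [r.response for r in rows],
            "term": [r.term for r in rows],
            "df": [r.df for r in rows],
            "mean_square": [r.mean_square for r in rows],
            "f_value": [r.f_value for r in rows],
            "p_value": [r.p_value for r in rows],
            "flag": [significance_flag(r.p_value) if r.p_value is not None else ""
                     for r in rows],
        }
    )


def tukey_contrast(response, factor, mse: float, df_error: int) -> pd.DataFrame:
    """Tukey–Kramer pairwise contrasts of factor-level means.

    Uses the ANOVA's mean-square error and error df; for each level pair the
    studentized range statistic is q = |m_i − m_j| / sqrt((MSE/2)(1/n_i + 1/n_j))
    with adjusted p from the studentized range distribution over k levels.
    With two equal-n levels this reduces to the pooled two-sided t-test
    (q = √2·|t|).
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    df = pd.DataFrame({"y": np.asarray(response, dtype=float), "g": list(factor)})
    levels = sorted(df["g"].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 factor levels")
    means = df.groupby("g")["y"].mean()
    ns = df.groupby("g")["y"].size()
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[b] - means[a])
            se = np.sqrt((mse / 2.0) * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_error))
            rows.append({"level_a": a, "level_b": b, "diff": diff,
                         "se": float(se), "q": float(q), "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)
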