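"""Size-structure and sex-ratio inference.

Two-sample Kolmogorov–Smirnov tests compare length-frequency distributions
between data sources or areas; Welch's heteroscedastic one-way F test with
Games–Howell post hoc compares mean fork length across depth strata or years
without assuming equal variances; chi-square goodness-of-fit tests compare
observed male/female counts against the 1:1 expectation, overall and per
stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "KSResult",
    "WelchResult",
    "SexRatioResult",
    "ks_two_sample",
    "welch_anova",
    "games_howell",
    "sex_ratio_test",
    "sex_ratio_by_stratum",
]


@dataclass(frozen=True)
class KSResult:
    d: float
    pvalue: float


@dataclass(frozen=True)
class WelchResult:
    f: float
    df1: float
    df2: float
    pvalue: float


@dataclass(frozen=True)
class SexRatioResult:
    ratio: float  # males per female, "x : 1"
    chi2: float
    pvalue: float
    n: int
    low_n: bool = False


def ks_two_sample(x, y, mode: str = "asymp") -> KSResult:
    """Two-sample K-S test, D = sup|ECDF_x − ECDF_y|.

    ``mode`` is 'asymp' (Kolmogorov distribution, the large-n default) or
    'exact'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method=mode)
    return KSResult(float(res.statistic), float(res.pvalue))


def _validate_groups(groups: dict) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        if np.var(v, ddof=1) <= 0:
            raise ValueError(f"group {name!r} has zero variance")
        out[name] = v
    return out


def _long_frame(groups: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups.keys()),
                               [len(v) for v in groups.values()]),
        }
    )


def welch_anova(groups: dict) -> WelchResult:
    """Welch's variance-weighted one-way F test (Satterthwaite-type df2)."""
    groups = _validate_groups(groups)
    res = pg.welch_anova(data=_long_frame(groups), dv="value", between="group")
    return WelchResult(
        f=float(res["F"].iloc[0]),
        df1=float(res["ddof1"].iloc[0]),
        df2=float(res["ddof2"].iloc[0]),
        pvalue=float(res["p_unc"].iloc[0]),
    )


def games_howell(groups: dict, ci_level: float = 0.95) -> pd.DataFrame:
    """Games–Howell pairwise comparisons (studentized range with Welch df).

    Returns a tidy table with one row per pair: mean difference, standard
    error, Welch df, t, studentized-range adjusted p, and confidence interval.
    """
    groups = _validate_groups(groups)
    res = pg.pairwise_gameshowell(
        data=_long_frame(groups), dv="value", between="group"
    )
    k = len(groups)
    q = stats.studentized_range.ppf(ci_level, k, res["df"])
    half = q / math.sqrt(2.0) * res["se"]
    out = pd.DataFrame(
        {
            "group_a": res["A"],
            "group_b": res["B"],
            "mean_diff": res["diff"],
            "se": res["se"],
            "df": res["df"],
            "t": res["T"],
            "pvalue": res["pval"],
            "ci_low": res["diff"] - half,
            "ci_high": res["diff"] + half,
        }
    )
    return out


def sex_ratio_test(males: int, females: int) -> SexRatioResult:
    """Chi-square goodness of fit of (males, females) against 1:1 (df = 1).

    The ratio is reported as males per female; an all-male stratum gives an
    infinite ratio but the test is still computed.
    """
    if males < 0 or females < 0:
        raise ValueError("counts must be >= 0")
    n = males + females
    if n == 0:
        raise ValueError("males + females must be > 0")
    ratio = males / females if females > 0 else math.inf
    chi2, p = stats.chisquare([males, females])
    return SexRatioResult(ratio=float(ratio), chi2=float(chi2),
                          pvalue=float(p), n=int(n), low_n=n < 10)


def sex_ratio_by_stratum(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum 1:1 tests from a frame with columns
    ``stratum, males, females``; strata with n < 10 are flagged, not dropped."""
    rows = []
    for _, r in counts.iterrows():
        res = sex_ratio_test(int(r["males"]), int(r["females"]))
        rows.append(
            (r["stratum"], res.ratio, res.chi2, res.pvalue, res.n, res.low_n)
        )
    return pd.DataFrame(
        rows, columns=["stratum", "ratio", "chi2", "pvalue", "n", "low_n"]
    )
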