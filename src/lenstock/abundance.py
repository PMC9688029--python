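"""Fishery-dependent abundance indices: hurdle–lognormal standardization,
min–max normalization, and ANCOVA comparison of index trends.

Catch rates from commercial trips confound abundance with fleet behaviour
(vessel size, gear, season, targeting). Standardization fits a two-part GLM —
binomial on the probability a trip catches the species at all, Gaussian on
log(catch/effort) of the positive trips — on categorical factors including
year, and extracts the annual index as the least-squares mean of the year
effect (every other factor balanced at equal level weights), back-transformed
and combined across the two parts as exp(LSM_pos) · logit⁻¹(LSM_bin).

Indices from different data streams are put on a common [0, 1] scale by
min–max normalization and their linear year-trends compared by ANCOVA: a
significant year×index interaction means the slopes differ; if slopes are
parallel a Tukey test on the index intercepts says which series sit higher.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AbundanceIndex",
    "TrendComparison",
    "standardize_cpue_hurdle",
    "minmax_normalize",
    "compare_trends_ancova",
]

_SS_TOL = 1e-10  # relative sum-of-squares threshold for degenerate fits


@dataclass
class AbundanceIndex:
    """Annual standardized index with SEs and a min–max normalized copy."""

    name: str
    table: pd.DataFrame  # columns: year, index, se, normalized
    undefined_years: list = field(default_factory=list)

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.table["index"].to_numpy()


def minmax_normalize(series) -> np.ndarray:
    """(x − min)/(max − min); a constant series maps to 0.5 with a warning."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if np.any(~np.isfinite(x)):
        raise ValueError("series must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series under min-max normalization; mapping to 0.5")
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def _factor_design(df, factors, levels_map):
    """Treatment-coded design; returns (matrix, coef index per (factor, level))."""
    n = len(df)
    cols = [np.ones(n)]
    pos = {}
    for f in factors:
        levels = levels_map[f]
        for lev in levels[1:]:
            pos[(f, lev)] = len(cols)
            cols.append((df[f].to_numpy() == lev).astype(float))
    return np.column_stack(cols), pos


def _lsm_vectors(factors, levels_map, pos, n_params):
    """One averaging row per year: the year's own dummy plus every other
    factor's coefficients at equal level weights."""
    year_levels = levels_map["year"]
    rows = {}
    for y in year_levels:
        l = np.zeros(n_params)
        l[0] = 1.0
        if (("year", y)) in pos:
            l[pos[("year", y)]] = 1.0
        for f in factors:
            if f == "year":
                continue
            levels = levels_map[f]
            for lev in levels[1:]:
                l[pos[(f, lev)]] = 1.0 / len(levels)
        rows[y] = l
    return rows


def standardize_cpue_hurdle(
    trips: pd.DataFrame,
    factors=("year", "quarter", "vessel", "gear"),
    catch_col: str = "catch",
    effort_col: str = "effort",
    name: str = "CPUE",
    target_col: str | None = None,
    positive_part_only: bool = False,
) -> AbundanceIndex:
    """Two-part standardization of trip catch rates to an annual index.

    ``factors`` must include 'year' and are treated as categoricals; a
    continuous ``target_col`` (species share of the catch, in [0, 1]) is
    binned to quartile categories and added as a factor. SEs come from the
    delta method on the combined back-transformed least-squares means.
    ``positive_part_only=True`` reports exp(LSM) of the Gaussian part alone.
    """
    factors = list(factors)
    if "year" not in factors:
        raise ValueError("factors must include 'year'")
    df = trips.copy()
    if target_col is not None:
        tq = pd.qcut(df[target_col], 4, duplicates="drop")
        if tq.nunique() >= 2:
            df["target_bin"] = tq.astype(str)
            factors = factors + ["target_bin"]
    if df["year"].nunique() < 2:
        warnings.warn("single year of data; index has one value")
    if np.any(df[effort_col] <= 0):
        raise ValueError("effort must be > 0")
    if np.any(df[catch_col] < 0):
        raise ValueError("catch must be >= 0")

    levels_map = {}
    for f in factors:
        levels = sorted(df[f].unique().tolist())
        if len(levels) < 2 and f != "year":
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        levels_map[f] = levels

    positive = df[catch_col].to_numpy() > 0
    pos_df = df[positive]
    years = levels_map["year"]
    undefined = [y for y in years if not np.any(pos_df["year"] == y)]

    # Gaussian part on log catch rate of positive trips
    lv_pos = {f: sorted(pos_df[f].unique().tolist()) for f in factors}
    Xp, pos_idx = _factor_design(pos_df, factors, lv_pos)
    yp = np.log(pos_df[catch_col].to_numpy() / pos_df[effort_col].to_numpy())
    ols = sm.OLS(yp, Xp).fit()
    lsm_pos = _lsm_vectors(factors, lv_pos, pos_idx, Xp.shape[1])
    cov_pos = np.asarray(ols.cov_params())

    # Binomial part on all trips, unless every trip is positive
    all_positive = bool(positive.all())
    if not all_positive and not positive_part_only:
        Xb, bin_idx = _factor_design(df, factors, levels_map)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(positive.astype(float), Xb,
                         family=sm.families.Binomial()).fit()
        lsm_bin = _lsm_vectors(factors, levels_map, bin_idx, Xb.shape[1])
        cov_bin = np.asarray(glm.cov_params())
    else:
        glm = None

    rows = []
    for y in years:
        if y in undefined:
            rows.append((y, np.nan, np.nan))
            continue
        l = lsm_pos[y]
        eta_p = float(l @ ols.params)
        var_p = float(l @ cov_pos @ l)
        mu = math.exp(eta_p)
        var_log = var_p
        if glm is not None:
            lb = lsm_bin[y]
            eta_b = float(lb @ glm.params)
            var_b = float(lb @ cov_bin @ lb)
            p = 1.0 / (1.0 + math.exp(-eta_b))
            mu *= p
            # delta method on log scale: d log(invlogit)/d eta = 1 - p
            var_log = var_p + ((1.0 - p) ** 2) * var_b
        rows.append((y, mu, mu * math.sqrt(max(var_log, 0.0))))

    table = pd.DataFrame(rows, columns=["year", "index", "se"])
    defined = table["index"].notna()
    norm = np.full(len(table), np.nan)
    if defined.any():
        norm[defined.to_numpy()] = minmax_normalize(
            table.loc[defined, "index"].to_numpy()
        )
    table["normalized"] = norm
    if undefined:
        warnings.warn(f"years with no positive trips (index undefined): {undefined}")
    return AbundanceIndex(name=name, table=table, undefined_years=undefined)


@dataclass
class TrendComparison:
    per_index: pd.DataFrame  # index, slope, intercept
    ancova: pd.DataFrame  # term, ss, df, F, pvalue
    interaction_f: float
    interaction_p: float
    parallel: bool
    tukey: pd.DataFrame | None  # pairwise intercept contrasts (if parallel)


def _stack(indices) -> pd.DataFrame:
    frames = []
    for idx in indices:
        t = idx.table.dropna(subset=["index"])
        if len(t) < 3:
            raise ValueError(f"index {idx.name!r} has fewer than 3 years")
        frames.append(
            pd.DataFrame(
                {"year": t["year"], "value": t["normalized"], "index": idx.name}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    # reject indices whose year supports cannot identify a common slope
    spans = df.groupby("index")["year"].agg(["min", "max"])
    if (spans["min"] == spans["max"]).any():
        raise ValueError("an index has a single-year support")
    return df


def compare_trends_ancova(indices, alpha: float = 0.05) -> TrendComparison:
    """ANCOVA on the stacked normalized series: value ~ year * index.

    The interaction F compares the full (separate slopes) model against the
    pooled-slope model. When the interaction is not significant at ``alpha``
    the additive model is refit and Tukey contrasts (studentized range on the
    index-coefficient differences) say which intercepts differ.
    """
    indices = list(indices)
    if len(indices) < 2:
        raise ValueError("need at least 2 indices")
    df = _stack(indices)
    names = sorted(df["index"].unique())
    g = len(names)

    per = []
    for nm in names:
        sub = df[df["index"] == nm]
        reg = stats.linregress(sub["year"], sub["value"])
        per.append((nm, reg.slope, reg.intercept))
    per_index = pd.DataFrame(per, columns=["index", "slope", "intercept"])

    year = df["year"].to_numpy(dtype=float)
    val = df["value"].to_numpy(dtype=float)
    dummies = np.column_stack([(df["index"] == nm).to_numpy(float) for nm in names[1:]])
    X_add = np.column_stack([np.ones(len(df)), year, dummies])
    X_full = np.column_stack([X_add, dummies * year[:, None]])
    fit_add = sm.OLS(val, X_add).fit()
    fit_full = sm.OLS(val, X_full).fit()

    tss = float(np.sum((val - val.mean()) ** 2))
    ss_int = max(fit_add.ssr - fit_full.ssr, 0.0)
    df_int = g - 1
    df_res = len(df) - X_full.shape[1]
    ss_res = fit_full.ssr
    degenerate = tss > 0 and ss_res < _SS_TOL * tss
    if degenerate:
        if ss_int < _SS_TOL * tss:
            f_int, p_int = 0.0, 1.0
        else:
            f_int, p_int = math.inf, 0.0
    else:
        f_int = (ss_int / df_int) / (ss_res / df_res)
        p_int = float(stats.f.sf(f_int, df_int, df_res))

    # year and index main-effect rows (sequential SS on the additive model)
    fit_year = sm.OLS(val, np.column_stack([np.ones(len(df)), year])).fit()
    ss_year = max(tss - fit_year.ssr, 0.0)
    ss_index = max(fit_year.ssr - fit_add.ssr, 0.0)

    def frow(ssq, dfree):
        if degenerate:
            return (math.inf, 0.0) if ssq > _SS_TOL * tss else (0.0, 1.0)
        f = (ssq / dfree) / (ss_res / df_res)
        return f, float(stats.f.sf(f, dfree, df_res))

    f_y, p_y = frow(ss_year, 1)
    f_i, p_i = frow(ss_index, g - 1)
    ancova = pd.DataFrame(
        [
            ("year", ss_year, 1, f_y, p_y),
            ("index", ss_index, g - 1, f_i, p_i),
            ("year:index", ss_int, df_int, f_int, p_int),
            ("residuals", ss_res, df_res, np.nan, np.nan),
        ],
        columns=["term", "ss", "df", "F", "pvalue"],
    )

    parallel = p_int >= alpha
    tukey = None
    if parallel:
        cov = np.asarray(fit_add.cov_params())
        params = np.asarray(fit_add.params)
        df_add = len(df) - X_add.shape[1]
        rows = []
        for a, b in itertools.combinations(range(g), 2):
            c = np.zeros(X_add.shape[1])
            if a > 0:
                c[1 + a] = -1.0  # offset of index a relative to reference
            if b > 0:
                c[1 + b] += 1.0
            est = float(c @ params)
            se = float(math.sqrt(max(c @ cov @ c, 0.0)))
            if degenerate or se == 0.0:
                t = math.inf if abs(est) > 1e-12 else 0.0
                p = 0.0 if abs(est) > 1e-12 else 1.0
            else:
                t = est / se
                p = float(
                    stats.studentized_range.sf(abs(t) * math.sqrt(2.0), g, df_add)
                )
            rows.append((names[a], names[b], est, se, t, p))
        tukey = pd.DataFrame(
            rows, columns=["index_a", "index_b", "estimate", "se", "t", "pvalue"]
        )
    return TrendComparison(per_index, ancova, float(f_int), float(p_int), parallel, tukey)
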