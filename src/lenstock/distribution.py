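"""Two-part (hurdle) additive spatial distribution model for zero-inflated
survey catch rates.

Station catch rates of a longline survey are mostly zero, so presence and
abundance are modelled separately: a binomial GAM with logit link on
presence/absence of all stations, and a Gaussian GAM on the natural log of the
positive catch rates. Both parts share the linear predictor

    s(longitude, latitude) + s(depth) + substrate

where s(longitude, latitude) is a low-rank thin-plate radial smooth,
s(depth) a penalized B-spline (basis dimension 4 by default), and substrate a
seven-level factor with coarse sediment (C.Sed) as reference. Penalized fits
use statsmodels' GAM machinery; the smoothing parameters default to a fixed
mild penalty, with optional data-driven selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .synthetic import SUBSTRATE_LEVELS

__all__ = ["HurdleSDMFit", "fit_hurdle_sdm", "predict_hurdle"]

REFERENCE_SUBSTRATE = "C.Sed"


class ThinPlateSmoother:
    """Low-rank bivariate thin-plate radial smoother.

    Basis: the two (standardized) coordinates plus r²·log(r) radial functions
    centred on a quantile grid of knots; the penalty is the radial-energy
    matrix (projected to positive semi-definite), leaving the linear part
    unpenalized. Plugs into statsmodels GLMGam as one smooth component.
    """

    def __init__(self, xy, n_knots: int = 16, variable_names=("longitude", "latitude")):
        xy = np.asarray(xy, dtype=float)
        self.nobs = xy.shape[0]
        self.mean = xy.mean(axis=0)
        scale = xy.std(axis=0)
        self.scale = np.where(scale > 0, scale, 1.0)
        z = (xy - self.mean) / self.scale
        side = max(2, int(round(np.sqrt(n_knots))))
        qs = np.linspace(0.05, 0.95, side)
        kx = np.quantile(z[:, 0], qs)
        ky = np.quantile(z[:, 1], qs)
        self.knots = np.array([(a, b) for a in kx for b in ky])
        self.dim_basis = self.knots.shape[0] + 2
        self.basis = self._design(z)
        energy = self._radial(self.knots, self.knots)
        pen = np.zeros((self.dim_basis, self.dim_basis))
        pen[2:, 2:] = (energy + energy.T) / 2.0
        w, v = np.linalg.eigh(pen)
        self.cov_der2 = (v * np.clip(w, 0.0, None)) @ v.T
        self.col_names = [f"s(lon,lat).{i}" for i in range(self.dim_basis)]
        self.variable_names = list(variable_names)

    @staticmethod
    def _radial(a, b):
        d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = d * d * np.log(d)
        out[d == 0] = 0.0
        return out

    def _design(self, z):
        return np.column_stack([z[:, 0], z[:, 1], self._radial(z, self.knots)])

    def transform(self, xy_new):
        xy_new = np.asarray(xy_new, dtype=float)
        z = (xy_new - self.mean) / self.scale
        return self._design(z)


class CompositeSmoother:
    """Additive container of smooth components, each consuming one or more
    columns of the smooth-covariate matrix (GLMGam smoother interface)."""

    def __init__(self, parts, ncols):
        self.smoothers = list(parts)
        self.ncols = list(ncols)
        self.nobs = parts[0].nobs
        self.basis = np.hstack([p.basis for p in parts])
        self.dim_basis = self.basis.shape[1]
        self.penalty_matrices = [p.cov_der2 for p in parts]
        self.col_names = sum((list(p.col_names) for p in parts), [])
        self.k_variables = len(parts)
        self.mask = []
        c = 0
        for p in parts:
            m = np.zeros(self.dim_basis, dtype=bool)
            m[c : c + p.dim_basis] = True
            self.mask.append(m)
            c += p.dim_basis

    def transform(self, x_new):
        x_new = np.asarray(x_new, dtype=float)
        out, c = [], 0
        for p, k in zip(self.smoothers, self.ncols):
            block = x_new[:, c : c + k]
            if k == 1:
                col = block[:, 0]
                knots = getattr(p, "knots", None)
                if knots is not None:
                    # B-spline bases are undefined outside the training knots
                    col = np.clip(col, np.min(knots), np.max(knots))
                out.append(p.transform(col))
            else:
                out.append(p.transform(block))
            c += k
        return np.hstack(out)


@dataclass
class PartFit:
    """One hurdle part: fitted penalized GLM plus its summaries."""

    result: object
    deviance_explained: float
    adj_r2: float | None
    coef_table: pd.DataFrame
    smooth_table: pd.DataFrame
    separation_warning: bool = False


@dataclass
class HurdleSDMFit:
    binomial: PartFit
    gaussian: PartFit
    substrate_levels: list
    reference_level: str
    depth_basis_dim: int
    smoother_bin: CompositeSmoother = field(repr=False, default=None)
    smoother_pos: CompositeSmoother = field(repr=False, default=None)
    train_ranges: dict = field(default_factory=dict)
    alpha: tuple = (1.0, 1.0)
    penalty_criterion: str = "fixed"

    def depth_profile(self, part: str = "gaussian", grid=None) -> pd.DataFrame:
        """Partial effect of depth on the link scale over a depth grid."""
        pf = self.gaussian if part == "gaussian" else self.binomial
        sm_obj = self.smoother_pos if part == "gaussian" else self.smoother_bin
        dsm = sm_obj.smoothers[1]
        lo = float(np.min(dsm.knots))
        hi = float(np.max(dsm.knots))
        if grid is None:
            grid = np.linspace(lo, hi, 200)
        grid = np.clip(np.asarray(grid, dtype=float), lo, hi)
        basis = dsm.transform(grid)
        k_exog = pf.result.model.exog.shape[1] - sm_obj.dim_basis
        start = k_exog + sm_obj.smoothers[0].dim_basis
        coefs = pf.result.params[start : start + dsm.dim_basis]
        return pd.DataFrame({"depth": grid, "effect": basis @ coefs})


def _design_parametric(substrate, levels, reference):
    """Intercept + treatment-coded substrate dummies."""
    cols = [np.ones(len(substrate))]
    names = ["Intercept"]
    for lev in levels:
        if lev == reference:
            continue
        cols.append((np.asarray(substrate) == lev).astype(float))
        names.append(f"substrate[{lev}]")
    return np.column_stack(cols), names


def _fit_part(y, exog, exog_names, smoother, family, alpha):
    gam = GLMGam(y, exog=exog, smoother=smoother, alpha=list(alpha), family=family)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = gam.fit()
        except Exception as err:  # perfect separation and kin: report, don't crash
            if "separation" in str(err).lower():
                separation = True
                res = gam.fit(maxiter=25)
            else:
                raise
    mu_null = np.full_like(np.asarray(y, dtype=float), np.mean(y))
    null_dev = family.deviance(np.asarray(y, dtype=float), mu_null)
    dev_expl = 1.0 - res.deviance / null_dev if null_dev > 0 else 0.0

    k_par = exog.shape[1]
    coef = pd.DataFrame(
        {
            "term": exog_names,
            "estimate": res.params[:k_par],
            "se": res.bse[:k_par],
            "z": res.tvalues[:k_par],
            "pvalue": res.pvalues[:k_par],
        }
    )
    rows = []
    edf = res.edf
    c = k_par
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, s in enumerate(smoother.smoothers):
            term_edf = float(np.sum(edf[c : c + s.dim_basis]))
            c += s.dim_basis
            try:
                wt = res.test_significance(i)
                stat = float(np.squeeze(wt.statistic))
                pval = float(np.squeeze(wt.pvalue))
            except Exception:
                stat, pval = np.nan, np.nan
            name = "s(longitude,latitude)" if isinstance(s, ThinPlateSmoother) else "s(depth)"
            rows.append((name, term_edf, stat, pval))
    smooth_table = pd.DataFrame(rows, columns=["term", "edf", "chi2", "pvalue"])

    adj_r2 = None
    if isinstance(family, sm.families.Gaussian):
        y_arr = np.asarray(y, dtype=float)
        rss = float(np.sum((y_arr - res.fittedvalues) ** 2))
        tss = float(np.sum((y_arr - y_arr.mean()) ** 2))
        edf_total = float(np.sum(res.edf))
        n = y_arr.size
        denom = max(n - edf_total, 1.0)
        adj_r2 = 1.0 - (rss / denom) / (tss / (n - 1))
    return PartFit(res, float(dev_expl), adj_r2, coef, smooth_table, separation)


def fit_hurdle_sdm(
    records: pd.DataFrame,
    basis_dim_depth: int = 4,
    n_knots_space: int = 16,
    alpha: tuple = (1.0, 1.0),
    select_penalty: bool = False,
) -> HurdleSDMFit:
    """Fit the binomial-presence and Gaussian log-abundance parts.

    ``records`` needs columns longitude, latitude, depth, substrate, rpn.
    Zero-catch stations inform only the binomial part; the Gaussian part sees
    log(rpn) of the positive stations. ``select_penalty=True`` replaces the
    fixed smoothing parameters by GCV-selected ones (slower).
    """
    req = {"longitude", "latitude", "depth", "substrate", "rpn"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    bad = set(records["substrate"]) - set(SUBSTRATE_LEVELS)
    if bad:
        raise ValueError(f"unknown substrate categories {sorted(bad)}")
    if np.any(records["rpn"] < 0):
        raise ValueError("rpn must be >= 0")

    pres = (records["rpn"] > 0).to_numpy().astype(float)
    if pres.sum() < 2 or (1 - pres).sum() < 2:
        raise ValueError("need at least 2 presence and 2 absence records")
    pos = records[records["rpn"] > 0]
    if len(pos) < 10:
        raise ValueError("need at least 10 positive records for the Gaussian part")

    levels = [l for l in SUBSTRATE_LEVELS if l in set(records["substrate"])]
    if len(levels) < 2:
        warnings.warn("substrate has a single level; factor dropped")
        levels = []
    reference = REFERENCE_SUBSTRATE if REFERENCE_SUBSTRATE in levels else (
        levels[0] if levels else None
    )

    def build(df):
        xy = df[["longitude", "latitude"]].to_numpy(dtype=float)
        depth = df["depth"].to_numpy(dtype=float)
        tps = ThinPlateSmoother(xy, n_knots=n_knots_space)
        if basis_dim_depth < 4:
            raise ValueError("basis_dim_depth must be >= 4 for a cubic spline")
        bs = BSplines(
            depth, df=[basis_dim_depth], degree=[3], include_intercept=False
        )
        comp = CompositeSmoother([tps, bs.smoothers[0]], [2, 1])
        if levels:
            exog, names = _design_parametric(df["substrate"], levels, reference)
        else:
            exog, names = np.ones((len(df), 1)), ["Intercept"]
        return comp, exog, names

    comp_bin, exog_bin, names_bin = build(records)
    comp_pos, exog_pos, names_pos = build(pos)
    log_rpn = np.log(pos["rpn"].to_numpy(dtype=float))

    crit = "fixed"
    a_bin = a_pos = tuple(alpha)
    if select_penalty:
        crit = "gcv"
        grid = [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
        gb = GLMGam(pres, exog=exog_bin, smoother=comp_bin,
                    alpha=list(alpha), family=sm.families.Binomial())
        a_bin = tuple(gb.select_penweight(alphas=[grid, grid])[0])
        gp = GLMGam(log_rpn, exog=exog_pos, smoother=comp_pos,
                    alpha=list(alpha), family=sm.families.Gaussian())
        a_pos = tuple(gp.select_penweight(alphas=[grid, grid])[0])

    part_bin = _fit_part(
        pres, exog_bin, names_bin, comp_bin, sm.families.Binomial(), a_bin
    )
    part_pos = _fit_part(
        log_rpn, exog_pos, names_pos, comp_pos, sm.families.Gaussian(), a_pos
    )

    ranges = {
        "depth": (float(records["depth"].min()), float(records["depth"].max())),
        "longitude": (float(records["longitude"].min()), float(records["longitude"].max())),
        "latitude": (float(records["latitude"].min()), float(records["latitude"].max())),
    }
    return HurdleSDMFit(
        binomial=part_bin,
        gaussian=part_pos,
        substrate_levels=levels,
        reference_level=reference,
        depth_basis_dim=basis_dim_depth,
        smoother_bin=comp_bin,
        smoother_pos=comp_pos,
        train_ranges=ranges,
        alpha=(a_bin, a_pos),
        penalty_criterion=crit,
    )


def predict_hurdle(
    fit: HurdleSDMFit, records: pd.DataFrame, combined: bool = False
) -> pd.DataFrame:
    """Per-record presence probability and conditional abundance.

    Conditional abundance is exp of the Gaussian-part prediction (no bias
    correction). ``combined=True`` adds p(presence) × E[abundance | positive].
    New covariates outside the training ranges are flagged (``extrapolated``)
    and clipped to the training hull for basis evaluation; an unseen substrate
    level is an error.
    """
    if fit.substrate_levels:
        bad = set(records["substrate"]) - set(fit.substrate_levels)
        if bad:
            raise ValueError(f"substrate level(s) not seen in training: {sorted(bad)}")

    extrap = np.zeros(len(records), dtype=bool)
    clipped = records.copy()
    for var in ("depth", "longitude", "latitude"):
        lo, hi = fit.train_ranges[var]
        v = records[var].to_numpy(dtype=float)
        extrap |= (v < lo) | (v > hi)
        clipped[var] = np.clip(v, lo, hi)

    def lin_pred(part, smoother, df):
        if fit.substrate_levels:
            exog, _ = _design_parametric(
                df["substrate"], fit.substrate_levels, fit.reference_level
            )
        else:
            exog = np.ones((len(df), 1))
        xs = df[["longitude", "latitude", "depth"]].to_numpy(dtype=float)
        full = np.hstack([exog, smoother.transform(xs)])
        return full @ part.result.params

    eta_bin = lin_pred(fit.binomial, fit.smoother_bin, clipped)
    p_pres = 1.0 / (1.0 + np.exp(-eta_bin))
    eta_pos = lin_pred(fit.gaussian, fit.smoother_pos, clipped)
    out = pd.DataFrame(
        {
            "p_presence": p_pres,
            "cond_abundance": np.exp(eta_pos),
            "extrapolated": extrap,
        },
        index=records.index,
    )
    if combined:
        out["expected_abundance"] = out["p_presence"] * out["cond_abundance"]
    return out
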