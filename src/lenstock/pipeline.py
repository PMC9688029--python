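"""Pipeline orchestration: growth → mortality → sdm → structure → abundance.

Each requested stage runs independently where possible; a failed stage aborts
only the stages that depend on its output, and every stage reports a
machine-readable status. The whole run is a pure function of (config, inputs).
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import abundance as ab
from . import distribution as dist
from . import growth as gr
from . import io as lio
from . import mortality as mort
from . import structure as st
from .io import RunConfig

log = logging.getLogger("lenstock")

__all__ = ["run_pipeline"]


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> dict:
    """Run the requested stages; returns (and optionally writes) a report.

    The report maps stage name → {status, ...results}; statuses are 'ok',
    'failed' (with the error message) or 'skipped' (with the missing
    dependency named).
    """
    report = {"seed": config.seed, "stages": {}}
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    lfq = None
    if config.lfq_path:
        lfq = lio.read_lfq(config.lfq_path)

    growth_fit = None
    if "growth" in config.stages:
        if lfq is None:
            report["stages"]["growth"] = {
                "status": "failed",
                "error": "growth requested but no lfq_path configured",
            }
        else:
            try:
                growth_fit = gr.fit_growth_ga(
                    lfq,
                    ga_settings=gr.GASettings(
                        pop_size=config.ga_pop_size,
                        generations=config.ga_generations,
                    ),
                    n_bootstrap=config.n_bootstrap,
                    seed=config.seed,
                    ma=config.ma,
                )
                report["stages"]["growth"] = {
                    "status": "ok",
                    "linf": growth_fit.point.linf,
                    "k": growth_fit.point.k,
                    "t_anchor": growth_fit.point.t_anchor,
                    "rn": growth_fit.rn_score,
                    "phi_prime": growth_fit.phi_prime,
                    "ci_linf": growth_fit.ci_linf,
                    "ci_k": growth_fit.ci_k,
                    "ci_phi": growth_fit.ci_phi,
                }
                if out_dir and growth_fit.bootstrap_samples is not None:
                    growth_fit.bootstrap_samples.to_csv(
                        os.path.join(out_dir, "growth_bootstrap.csv"), index=False
                    )
            except Exception as err:
                report["stages"]["growth"] = {"status": "failed", "error": str(err)}

    if "mortality" in config.stages:
        if config.linf is not None and config.k is not None:
            p = gr.VBGFParams(config.linf, config.k)
        elif growth_fit is not None:
            p = growth_fit.point
        else:
            p = None
        if p is None:
            report["stages"]["mortality"] = {
                "status": "skipped",
                "error": "mortality needs growth output or explicit (linf, k)",
            }
        elif lfq is None:
            report["stages"]["mortality"] = {
                "status": "failed",
                "error": "mortality requested but no lfq_path configured",
            }
        else:
            try:
                est = mort.mortality_estimates(
                    lfq, p, tmax=config.tmax, temperature=config.temperature
                )
                cc = mort.length_converted_catch_curve(lfq, p)
                report["stages"]["mortality"] = {
                    "status": "ok",
                    "z": est.z,
                    "z_se": est.z_se,
                    "m": est.m,
                    "f": est.f,
                    "e": est.e,
                    "f_implausible": est.f_implausible,
                }
                if out_dir:
                    cc.to_frame().to_csv(
                        os.path.join(out_dir, "catch_curve.csv"), index=False
                    )
            except Exception as err:
                report["stages"]["mortality"] = {"status": "failed", "error": str(err)}

    survey = None
    if config.survey_path:
        survey = lio.read_survey(config.survey_path)

    if "sdm" in config.stages:
        if survey is None:
            report["stages"]["sdm"] = {
                "status": "failed",
                "error": "sdm requested but no survey_path configured",
            }
        else:
            try:
                fit = dist.fit_hurdle_sdm(survey, basis_dim_depth=config.depth_basis_dim)
                report["stages"]["sdm"] = {
                    "status": "ok",
                    "deviance_explained_binomial": fit.binomial.deviance_explained,
                    "deviance_explained_gaussian": fit.gaussian.deviance_explained,
                    "adj_r2_gaussian": fit.gaussian.adj_r2,
                    "reference_substrate": fit.reference_level,
                }
                if out_dir:
                    fit.binomial.coef_table.to_csv(
                        os.path.join(out_dir, "sdm_binomial_coefs.csv"), index=False
                    )
                    fit.gaussian.coef_table.to_csv(
                        os.path.join(out_dir, "sdm_gaussian_coefs.csv"), index=False
                    )
            except Exception as err:
                report["stages"]["sdm"] = {"status": "failed", "error": str(err)}

    if "structure" in config.stages:
        if not config.fish_path:
            report["stages"]["structure"] = {
                "status": "skipped",
                "error": "structure needs fish_path (per-fish length/sex records)",
            }
        else:
            try:
                fish = pd.read_csv(config.fish_path)
                out = {"status": "ok"}
                if "sex" in fish.columns:
                    sr = st.sex_ratio_test(
                        int((fish["sex"] == "M").sum()),
                        int((fish["sex"] == "F").sum()),
                    )
                    out["sex_ratio"] = sr.ratio
                    out["sex_ratio_chi2"] = sr.chi2
                    out["sex_ratio_p"] = sr.pvalue
                if "area" in fish.columns and fish["area"].nunique() == 2:
                    a, b = sorted(fish["area"].unique())
                    ks = st.ks_two_sample(
                        fish.loc[fish["area"] == a, "length"],
                        fish.loc[fish["area"] == b, "length"],
                    )
                    out["ks_area_d"] = ks.d
                    out["ks_area_p"] = ks.pvalue
                if "depth_stratum" in fish.columns:
                    groups = {
                        g: sub["length"].to_numpy()
                        for g, sub in fish.groupby("depth_stratum")
                        if len(sub) >= 10 and np.var(sub["length"], ddof=1) > 0
                    }
                    if len(groups) >= 2:
                        w = st.welch_anova(groups)
                        out["welch_depth_f"] = w.f
                        out["welch_depth_p"] = w.pvalue
                report["stages"]["structure"] = out
            except Exception as err:
                report["stages"]["structure"] = {"status": "failed", "error": str(err)}

    if "abundance" in config.stages:
        if not config.trips_path:
            report["stages"]["abundance"] = {
                "status": "failed",
                "error": "abundance requested but no trips_path configured",
            }
        else:
            try:
                trips = lio.read_trips(config.trips_path)
                factors = [
                    f for f in ("year", "quarter", "vessel", "gear")
                    if f in trips.columns and trips[f].nunique() >= 2
                ]
                if "year" not in factors:
                    factors = ["year"] + factors
                idx = ab.standardize_cpue_hurdle(trips, factors=factors)
                report["stages"]["abundance"] = {
                    "status": "ok",
                    "years": [int(y) for y in idx.years],
                    "index": list(idx.values),
                    "normalized": list(idx.table["normalized"]),
                }
                if out_dir:
                    idx.table.to_csv(
                        os.path.join(out_dir, "abundance_index.csv"), index=False
                    )
            except Exception as err:
                report["stages"]["abundance"] = {"status": "failed", "error": str(err)}

    if out_dir:
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
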