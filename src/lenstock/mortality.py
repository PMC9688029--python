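"""Mortality estimation: length-converted catch curve (Z), an empirical
natural-mortality battery (M), and the derived fishing mortality F = Z − M and
exploitation rate E = F/(F + M).

The catch curve converts pooled length-bin counts to relative ages through the
inverse von Bertalanffy function, corrects for the time Δt a cohort spends in
each bin, and regresses ln(N/Δt) on age over the descending limb; Z is the
negative slope. The natural-mortality battery evaluates fourteen published
empirical estimators from (L∞, k, tmax, T) and averages them; tmax defaults to
the longevity rule 3/k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import VBGFParams, inverse_vbgf_age_at_length
from .lfq import LengthFrequencyTable

__all__ = [
    "CatchCurveData",
    "NaturalMortalityTable",
    "MortalityEstimates",
    "length_converted_catch_curve",
    "natural_mortality_battery",
    "fishing_mortality",
    "exploitation_rate",
    "M_METHODS",
]


@dataclass
class CatchCurveData:
    midpoints: np.ndarray
    t: np.ndarray
    dt: np.ndarray
    ln_n_dt: np.ndarray
    selected: np.ndarray  # boolean mask over the rows above
    slope: float
    intercept: float
    slope_se: float

    @property
    def z(self) -> float:
        return -self.slope

    @property
    def z_se(self) -> float:
        return self.slope_se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "midpoint": self.midpoints,
                "t": self.t,
                "dt": self.dt,
                "ln_n_dt": self.ln_n_dt,
                "selected": self.selected,
            }
        )


def length_converted_catch_curve(
    lfq, p: VBGFParams, limb: tuple | None = None
) -> CatchCurveData:
    """Fit ln(N/Δt) ~ t over the descending limb; Z = −slope.

    ``lfq`` is a LengthFrequencyTable (pooled over dates) or a tuple
    ``(bin_lower, counts_vector)``. By default the regression points run from
    the bin after the maximum of ln(N/Δt) through the last non-empty bin with
    midpoint < 0.9·L∞; ``limb=(i, j)`` overrides with an inclusive index range
    into the usable bins.
    """
    if isinstance(lfq, LengthFrequencyTable):
        bin_lower = lfq.bin_lower
        counts = lfq.pooled()
        width = lfq.bin_width
    else:
        bin_lower, counts = lfq
        bin_lower = np.asarray(bin_lower, dtype=float)
        counts = np.asarray(counts, dtype=float)
        width = float(bin_lower[1] - bin_lower[0])

    upper = bin_lower + width
    if p.linf <= upper.max():
        usable = upper < p.linf
        if not usable.any():
            raise ValueError("linf must exceed the upper edge of some used bin")
    else:
        usable = np.ones_like(bin_lower, dtype=bool)

    bl, up, cnt = bin_lower[usable], upper[usable], counts[usable]
    mid = (bl + up) / 2.0
    t_lo = inverse_vbgf_age_at_length(p, bl)
    t_up = inverse_vbgf_age_at_length(p, up)
    t_mid = inverse_vbgf_age_at_length(p, mid)
    dt = t_up - t_lo

    with np.errstate(divide="ignore"):
        ln_n_dt = np.where(cnt > 0, np.log(np.maximum(cnt, 1e-300) / dt), -np.inf)

    nonzero = cnt > 0
    if limb is None:
        if not nonzero.any():
            raise ValueError("catch curve needs non-empty bins")
        peak = int(np.argmax(np.where(nonzero, ln_n_dt, -np.inf)))
        sel = np.zeros_like(nonzero)
        sel[peak + 1:] = True
        sel &= nonzero & (mid < 0.9 * p.linf)
    else:
        i, j = limb
        sel = np.zeros_like(nonzero)
        sel[i : j + 1] = True
        dropped = sel & ~nonzero
        if dropped.any():
            warnings.warn(
                f"{int(dropped.sum())} selected bin(s) with zero count excluded "
                "from the catch-curve regression"
            )
        sel &= nonzero

    if sel.sum() < 3:
        raise ValueError(
            f"catch curve needs at least 3 selectable points, got {int(sel.sum())}"
        )
    reg = stats.linregress(t_mid[sel], ln_n_dt[sel])
    return CatchCurveData(
        midpoints=mid,
        t=t_mid,
        dt=dt,
        ln_n_dt=ln_n_dt,
        selected=sel,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        slope_se=float(reg.stderr),
    )


# the fourteen empirical natural-mortality estimators, exactly as tabulated
# (longevity rules use tmax; Pauly's uses base-10 logs inside an exp)
M_METHODS = {
    "Beverton and Holt (1959)": lambda linf, k, tmax, T: 5.0 / tmax,
    "Taylor (1960)": lambda linf, k, tmax, T: 2.996 / tmax,
    "Tanaka (1960)": lambda linf, k, tmax, T: 3.0 / tmax,
    "Alverson and Carney (1975)": lambda linf, k, tmax, T: 3.0 * k
    / math.exp(0.38 * tmax * k - 1.0),
    "Pauly (1980)": lambda linf, k, tmax, T: math.exp(
        -0.0066
        - 0.279 * math.log10(linf)
        + 0.6543 * math.log10(k)
        + 0.4634 * math.log10(T)
    ),
    "Hoenig (1983)": lambda linf, k, tmax, T: 3.0 / tmax,
    "Alagaraja (1984)": lambda linf, k, tmax, T: 4.6 / tmax,
    "Djabali et al. (1993)": lambda linf, k, tmax, T: 1.0661
    * linf ** -0.1172
    * k ** 0.5092,
    "Pauly and Binohlan (1996)": lambda linf, k, tmax, T: -0.1778 + 3.1687 * k,
    "Jensen (1996) 1.6k": lambda linf, k, tmax, T: 1.6 * k,
    "Jensen (1996) 1.5k": lambda linf, k, tmax, T: 1.5 * k,
    "Cubillos et al. (1999)": lambda linf, k, tmax, T: 1.4 * k,
    "Frisk et al. (2001)": lambda linf, k, tmax, T: 4.22 / tmax,
    "Hewitt and Hoenig (2005)": lambda linf, k, tmax, T: 4.22 / tmax,
}


@dataclass
class NaturalMortalityTable:
    estimates: pd.Series  # method -> M (year⁻¹)
    linf: float
    k: float
    tmax: float
    temperature: float

    @property
    def mean_m(self) -> float:
        return float(self.estimates.mean())

    def to_frame(self) -> pd.DataFrame:
        df = self.estimates.rename("m").to_frame()
        df.loc["Mean"] = self.mean_m
        return df


def natural_mortality_battery(
    linf: float, k: float, tmax: float | None = None, temperature: float = 18.0
) -> NaturalMortalityTable:
    """Evaluate the fourteen empirical M estimators and their arithmetic mean.

    ``tmax`` defaults to 3/k (approximate maximum age), carried at full
    precision; ``temperature`` is the mean water temperature (°C) used by
    Pauly's estimator.
    """
    if tmax is None:
        tmax = 3.0 / k
    if linf <= 0 or k <= 0 or tmax <= 0 or temperature <= 0:
        raise ValueError("linf, k, tmax and temperature must all be > 0")
    vals = pd.Series(
        {name: fn(linf, k, tmax, temperature) for name, fn in M_METHODS.items()}
    )
    return NaturalMortalityTable(vals, linf, k, tmax, temperature)


@dataclass(frozen=True)
class MortalityEstimates:
    z: float
    z_se: float
    m: float
    f: float
    e: float
    f_implausible: bool  # True when M > Z (negative F)


def fishing_mortality(z: float, m: float) -> tuple:
    """F = Z − M; returns (f, implausible) where implausible flags M > Z.

    A negative F is returned as-is (never clipped) so the caller can see the
    inconsistency between the Z and M inputs.
    """
    if z < 0 or m < 0:
        raise ValueError("z and m must be >= 0")
    f = z - m
    return f, f < 0


def exploitation_rate(f: float, m: float) -> float:
    """E = F/(F + M), the fraction of total deaths caused by fishing."""
    if f < 0:
        raise ValueError("f must be >= 0")
    if m <= 0:
        raise ValueError("m must be > 0")
    return f / (f + m)


def mortality_estimates(
    lfq, p: VBGFParams, tmax: float | None = None, temperature: float = 18.0,
    limb: tuple | None = None,
) -> MortalityEstimates:
    """Full Z → M → F → E chain from a pooled LFQ and growth parameters."""
    cc = length_converted_catch_curve(lfq, p, limb=limb)
    nm = natural_mortality_battery(p.linf, p.k, tmax=tmax, temperature=temperature)
    f, bad = fishing_mortality(max(cc.z, 0.0), nm.mean_m)
    f_raw = cc.z - nm.mean_m
    e = exploitation_rate(max(f_raw, 0.0), nm.mean_m)
    return MortalityEstimates(
        z=cc.z, z_se=cc.z_se, m=nm.mean_m, f=f_raw, e=e, f_implausible=f_raw < 0
    )
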