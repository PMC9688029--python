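"""Seeded generators for populations, length-frequency samples, survey stations
and fishing-trip records.

These emulate the three data streams a length-based assessment of a deep-water
demersal stock consumes: (1) individual fish growing by a von Bertalanffy curve
with individual variability in asymptotic length and dying at a constant total
mortality rate; (2) a bottom-longline survey whose station catch rates are
zero-inflated, peaked in depth and nudged by substrate; (3) commercial trip
records whose catches mix year/quarter/vessel/gear multipliers with lognormal
noise and occasional zero trips.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lfq import LengthFrequencyTable

__all__ = [
    "SUBSTRATE_LEVELS",
    "PopulationParams",
    "SpatialFieldParams",
    "FleetParams",
    "LogisticSelectivity",
    "simulate_population",
    "sample_lfq",
    "simulate_lfq",
    "simulate_fish_records",
    "simulate_survey_records",
    "simulate_trip_records",
]

# seven-level seabed classification used throughout
SUBSTRATE_LEVELS = ("C.Sed", "Mix.Sed", "Mud", "Mud.S", "Rock", "Sand", "Sand.M")


@dataclass(frozen=True)
class PopulationParams:
    """Generative parameters of the simulated stock.

    linf_mean : mean asymptotic fork length (cm); individual L∞ is lognormal
        with this mean and coefficient of variation ``linf_cv``.
    k : von Bertalanffy growth coefficient (year⁻¹), shared by all fish.
    z : total mortality rate (year⁻¹); survival to age t is exp(−z·t).
    recruits_per_pulse : fish entering per annual recruitment pulse.
    pulse_month : calendar month (1–12) of the pulse.
    n_years : simulated horizon (years).
    selectivity_l50, selectivity_slope : default logistic gear retention.
    prop_female : probability a fish is female.
    """

    linf_mean: float = 170.0
    linf_cv: float = 0.07
    k: float = 0.12
    z: float = 0.47
    recruits_per_pulse: int = 4500
    pulse_month: int = 3
    n_years: int = 30
    selectivity_l50: float = 40.0
    selectivity_slope: float = 0.25
    prop_female: float = 0.685

    def validate(self) -> None:
        for name in ("linf_mean", "linf_cv", "k", "z", "selectivity_l50",
                     "selectivity_slope"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.linf_mean <= 0:
            raise ValueError("linf_mean must be > 0")
        if self.linf_cv < 0:
            raise ValueError("linf_cv must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.z < 0:
            raise ValueError("z must be >= 0")
        if self.selectivity_slope <= 0:
            raise ValueError("selectivity_slope must be > 0")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must be in [0, 1]")
        if not 1 <= self.pulse_month <= 12:
            raise ValueError("pulse_month must be in 1..12")
        if self.recruits_per_pulse <= 0 or self.n_years <= 0:
            raise ValueError("recruits_per_pulse and n_years must be positive")


@dataclass(frozen=True)
class SpatialFieldParams:
    """Depth-peaked, zero-inflated abundance field with a substrate effect.

    The presence probability at the depth optimum on the reference substrate is
    1 − zero_inflation; it decays along a Gaussian-in-depth logit with scale
    ``depth_sd`` and amplitude ``depth_amplitude`` (logit units). Positive catch
    rates are lognormal around a deterministic depth/substrate surface.
    """

    depth_opt: float = 300.0
    depth_sd: float = 80.0
    substrate_effects: dict = field(default_factory=lambda: {"Sand": 1.0})
    zero_inflation: float = 0.5
    noise_sd: float = 0.6
    depth_amplitude: float = 4.0
    rpn_scale: float = 20.0  # median positive catch rate at the optimum

    def validate(self) -> None:
        if not 0 <= self.depth_opt <= 600:
            raise ValueError("depth_opt must lie in the surveyed range [0, 600] m")
        if self.depth_sd <= 0:
            raise ValueError("depth_sd must be > 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bad = set(self.substrate_effects) - set(SUBSTRATE_LEVELS)
        if bad:
            raise ValueError(
                f"unknown substrate categories {sorted(bad)}; "
                f"allowed: {SUBSTRATE_LEVELS}"
            )


@dataclass(frozen=True)
class FleetParams:
    """Multiplicative factor structure of trip-level catches."""

    year_effects: dict = field(
        default_factory=lambda: {y: 1.0 for y in range(2010, 2018)}
    )
    quarter_effects: dict = field(default_factory=lambda: {q: 1.0 for q in (1, 2, 3, 4)})
    vessel_effects: dict = field(default_factory=lambda: {"small": 1.0, "large": 1.0})
    gear_effects: dict = field(
        default_factory=lambda: {"bottom_longline": 1.0, "handline": 1.0}
    )
    lognormal_sd: float = 0.5
    p_zero: float = 0.2
    base_catch: float = 100.0  # kg, at unit multipliers

    def validate(self) -> None:
        if not self.year_effects:
            raise ValueError("year_effects must not be empty")
        for name in ("year_effects", "quarter_effects", "vessel_effects",
                     "gear_effects"):
            d = getattr(self, name)
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"all multipliers in {name} must be > 0")
        if not 0 <= self.p_zero < 1:
            raise ValueError("p_zero must be in [0, 1)")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be >= 0")


@dataclass(frozen=True)
class LogisticSelectivity:
    """Retention probability 1 / (1 + exp(−slope·(L − l50))).

    ``slope=np.inf`` gives knife-edge retention at l50.
    """

    l50: float
    slope: float

    def retention(self, length) -> np.ndarray:
        length = np.asarray(length, dtype=float)
        if np.isinf(self.slope):
            return (length >= self.l50).astype(float)
        x = np.clip(self.slope * (length - self.l50), -700, 700)
        return 1.0 / (1.0 + np.exp(-x))


def vbgf_mean_length(linf, k, age):
    return linf * (1.0 - np.exp(-k * np.asarray(age, dtype=float)))


def _lognormal_linf(rng, mean, cv, n):
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def simulate_population(
    params: PopulationParams, seed: int, sample_times=None, drop_dead: bool = False
) -> pd.DataFrame:
    """Track the population of individuals across one or more sampling times.

    Recruitment is one pulse per year at ``pulse_month`` (mid-month) over the
    ``n_years`` horizon. Each recruit draws an individual asymptotic length
    (lognormal around ``linf_mean``) and a death age (exponential with rate
    ``z``), so survival to age t is exp(−z·t) and the *same* cohort progresses
    coherently from one sampling time to the next. At each sampling time every
    past recruit is aged and given its current von Bertalanffy length.

    Returns a DataFrame with columns
    ``sample_time, age, length, linf_i, sex, alive``; ``sample_time`` is in
    decimal years on the simulation clock (origin 0). ``drop_dead=True``
    returns only the rows alive at their sampling time.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    if sample_times is None:
        sample_times = [float(params.n_years)]
    sample_times = [float(t) for t in sample_times]

    pulse_frac = (params.pulse_month - 0.5) / 12.0
    pulses = np.array([y + pulse_frac for y in range(params.n_years)])
    n_total = pulses.size * params.recruits_per_pulse

    birth = np.repeat(pulses, params.recruits_per_pulse)
    linf_i = _lognormal_linf(rng, params.linf_mean, params.linf_cv, n_total)
    sex = np.where(rng.random(n_total) < params.prop_female, "F", "M")
    death_age = (
        rng.exponential(1.0 / params.z, n_total)
        if params.z > 0
        else np.full(n_total, np.inf)
    )

    blocks = []
    for st in sample_times:
        born = birth <= st
        if not born.any():
            continue
        ages = st - birth[born]
        alive = death_age[born] > ages
        if drop_dead:
            keep = alive
            ages, al = ages[keep], np.ones(int(keep.sum()), dtype=bool)
            li, sx = linf_i[born][keep], sex[born][keep]
        else:
            al = alive
            li, sx = linf_i[born], sex[born]
        blocks.append(
            pd.DataFrame(
                {
                    "sample_time": st,
                    "age": ages,
                    "length": li * (1.0 - np.exp(-params.k * ages)),
                    "linf_i": li,
                    "sex": sx,
                    "alive": al,
                }
            )
        )
    if not blocks:
        return pd.DataFrame(
            columns=["sample_time", "age", "length", "linf_i", "sex", "alive"]
        )
    return pd.concat(blocks, ignore_index=True)


def sample_lfq(
    individuals: pd.DataFrame,
    selectivity: LogisticSelectivity | None,
    bin_width: float,
    dates,
    seed: int = 0,
    bin_range: tuple | None = None,
) -> LengthFrequencyTable:
    """Thin individuals by gear selectivity and bin them into an LFQ table.

    ``dates`` are calendar months, one per distinct ``sample_time`` in the
    individuals table (sorted); rows without a ``sample_time`` column all fall
    on the first date. Rows with ``alive == False`` never enter the sample.
    ``bin_range=(lo, hi)`` declares the bin grid explicitly (required to get a
    well-defined empty table from an empty input).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    dates = list(dates)
    if not dates:
        raise ValueError("dates must be non-empty")
    rng = np.random.default_rng(seed)

    df = individuals
    if df is None or len(df) == 0:
        lo = 0.0 if bin_range is None else math.floor(bin_range[0] / bin_width) * bin_width
        hi = lo + bin_width if bin_range is None else bin_range[1]
        edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
        lowers = edges[:-1] if edges.size > 1 else np.array([lo])
        t = LengthFrequencyTable(lowers, dates, np.zeros((lowers.size, len(dates))))
        t.set_width(bin_width)
        return t

    if "alive" in df.columns:
        df = df[df["alive"].astype(bool)]
    lengths = df["length"].to_numpy(dtype=float)
    if selectivity is not None:
        keep = rng.random(lengths.size) < selectivity.retention(lengths)
        df = df.iloc[np.flatnonzero(keep)]
        lengths = df["length"].to_numpy(dtype=float)

    if "sample_time" in df.columns:
        uniq = np.unique(individuals["sample_time"].to_numpy(dtype=float))
        if uniq.size != len(dates):
            raise ValueError(
                f"{uniq.size} distinct sample times but {len(dates)} dates given"
            )
        col_of = {t: j for j, t in enumerate(uniq)}
        cols = np.array([col_of[t] for t in df["sample_time"].to_numpy(dtype=float)],
                        dtype=int) if len(df) else np.array([], dtype=int)
    else:
        cols = np.zeros(len(df), dtype=int)

    if bin_range is not None:
        lo = math.floor(bin_range[0] / bin_width) * bin_width
        hi = bin_range[1]
    elif lengths.size:
        lo = math.floor(lengths.min() / bin_width) * bin_width
        hi = lengths.max()
    else:
        lo, hi = 0.0, bin_width
    n_bins = max(1, int(math.floor((hi - lo) / bin_width)) + 1)
    lowers = lo + bin_width * np.arange(n_bins)

    counts = np.zeros((n_bins, len(dates)))
    if lengths.size:
        idx = np.floor((lengths - lo) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        np.add.at(counts, (idx[ok], cols[ok]), 1.0)
    t = LengthFrequencyTable(lowers, dates, counts)
    t.set_width(bin_width)
    return t


def simulate_lfq(
    params: PopulationParams,
    dates,
    seed: int,
    bin_width: float = 5.0,
    selectivity: LogisticSelectivity | None = None,
) -> LengthFrequencyTable:
    """Monthly LFQ straight from the population model (convenience wrapper).

    ``dates`` are calendar months; the first is mapped to the end of the
    simulated horizon so the stock is at its stationary age structure.
    """
    dates = [pd.Period(d, freq="M") for d in dates]
    base = dates[0]
    offs = [(p.year - base.year) + (p.month - base.month) / 12.0 for p in dates]
    times = [params.n_years + o for o in offs]
    pop = simulate_population(params, seed, sample_times=times, drop_dead=True)
    if selectivity is None:
        selectivity = LogisticSelectivity(params.selectivity_l50,
                                          params.selectivity_slope)
    return sample_lfq(pop, selectivity, bin_width, dates, seed=seed + 1)


def simulate_fish_records(
    params: PopulationParams, n_fish: int, seed: int
) -> pd.DataFrame:
    """Per-fish survey biological records: fork length, sex, area, depth stratum.

    Fish are a random draw from the standing population; depth follows a
    bigger-deeper trend (depth increases with length plus noise) and is binned
    into 50 m strata, mirroring how survey specimens are recorded.
    """
    if n_fish <= 0:
        raise ValueError("n_fish must be > 0")
    rng = np.random.default_rng(seed)
    pop = simulate_population(params, seed, drop_dead=True)
    take = rng.choice(len(pop), size=min(n_fish, len(pop)), replace=False)
    df = pop.iloc[take].reset_index(drop=True)
    depth = np.clip(100.0 + 1.8 * df["length"] + rng.normal(0, 60, len(df)), 0, 599)
    stratum = (np.floor(depth / 50.0) * 50).astype(int)
    return pd.DataFrame(
        {
            "length": df["length"],
            "sex": df["sex"],
            "area": rng.choice(["islands", "seamounts"], len(df)),
            "depth_stratum": [f"{s}-{s + 50}" for s in stratum],
        }
    )


def simulate_survey_records(
    spatial: SpatialFieldParams,
    n_stations: int,
    seed: int,
    lon_range=(-32.0, -24.0),
    lat_range=(36.0, 40.0),
    depth_range=(30.0, 600.0),
    substrate_probs: dict | None = None,
) -> pd.DataFrame:
    """Draw survey station records (station, position, depth, substrate, rpn).

    Presence is Bernoulli with logit = logit(1 − zero_inflation)
    + depth_amplitude·(gauss(depth) − 1) + substrate effect, where gauss is a
    Gaussian bump of scale depth_sd peaking (=1) at depth_opt. Positive catch
    rates (rpn, individuals per 10³ hooks) are lognormal around
    rpn_scale·exp(depth/substrate surface).
    """
    spatial.validate()
    if n_stations <= 0:
        raise ValueError("n_stations must be > 0")
    rng = np.random.default_rng(seed)

    lon = rng.uniform(*lon_range, n_stations)
    lat = rng.uniform(*lat_range, n_stations)
    depth = rng.uniform(*depth_range, n_stations)
    if substrate_probs is None:
        levels, probs = list(SUBSTRATE_LEVELS), None
    else:
        bad = set(substrate_probs) - set(SUBSTRATE_LEVELS)
        if bad:
            raise ValueError(f"unknown substrate categories {sorted(bad)}")
        levels = list(substrate_probs)
        p = np.array([substrate_probs[k] for k in levels], dtype=float)
        probs = p / p.sum()
    substrate = rng.choice(levels, size=n_stations, p=probs)
    sub_eff = np.array([spatial.substrate_effects.get(s, 0.0) for s in substrate])

    bump = np.exp(-0.5 * ((depth - spatial.depth_opt) / spatial.depth_sd) ** 2)
    p_opt = min(1.0 - spatial.zero_inflation, 1.0 - 1e-12)
    base_logit = math.log(p_opt / (1.0 - p_opt)) if p_opt > 0 else -np.inf
    logit = base_logit + spatial.depth_amplitude * (bump - 1.0) + sub_eff
    presence = rng.random(n_stations) < 1.0 / (1.0 + np.exp(-logit))

    log_mu = math.log(spatial.rpn_scale) + spatial.depth_amplitude * (bump - 1.0) + sub_eff
    rpn = np.where(
        presence, np.exp(log_mu + spatial.noise_sd * rng.standard_normal(n_stations)), 0.0
    )
    return pd.DataFrame(
        {
            "station": np.arange(1, n_stations + 1),
            "longitude": lon,
            "latitude": lat,
            "depth": depth,
            "substrate": substrate,
            "rpn": rpn,
        }
    )


def simulate_trip_records(
    fleet: FleetParams,
    n_trips: int,
    seed: int,
    balanced: bool = False,
    vessel_trend: float = 0.0,
    effort: float = 1.0,
) -> pd.DataFrame:
    """Draw commercial trip records (year, quarter, vessel, gear, catch, effort).

    ``balanced=True`` lays trips on a full factorial of the four factors,
    repeated to at least ``n_trips`` rows (exact balance, for closed-form
    checks). ``vessel_trend`` tilts the probability of the last vessel class
    linearly across years (a deliberate catchability confounder);
    the true year effects are untouched.
    """
    fleet.validate()
    if n_trips <= 0:
        raise ValueError("n_trips must be > 0")
    rng = np.random.default_rng(seed)

    years = sorted(fleet.year_effects)
    quarters = sorted(fleet.quarter_effects)
    vessels = list(fleet.vessel_effects)
    gears = list(fleet.gear_effects)

    if balanced:
        grid = [
            (y, q, v, g) for y in years for q in quarters for v in vessels for g in gears
        ]
        reps = max(1, math.ceil(n_trips / len(grid)))
        rows = grid * reps
        year = np.array([r[0] for r in rows])
        quarter = np.array([r[1] for r in rows])
        vessel = np.array([r[2] for r in rows])
        gear = np.array([r[3] for r in rows])
        n = len(rows)
    else:
        n = n_trips
        year = rng.choice(years, n)
        quarter = rng.choice(quarters, n)
        gear = rng.choice(gears, n)
        if vessel_trend != 0.0 and len(vessels) >= 2:
            yi = np.array([years.index(y) for y in year], dtype=float)
            mid = (len(years) - 1) / 2.0
            p_last = np.clip(0.5 + vessel_trend * (yi - mid), 0.05, 0.95)
            vessel = np.where(rng.random(n) < p_last, vessels[-1], vessels[0])
        else:
            vessel = rng.choice(vessels, n)

    mult = (
        np.array([fleet.year_effects[y] for y in year])
        * np.array([fleet.quarter_effects[q] for q in quarter])
        * np.array([fleet.vessel_effects[v] for v in vessel])
        * np.array([fleet.gear_effects[g] for g in gear])
    )
    noise = (
        np.exp(fleet.lognormal_sd * rng.standard_normal(n))
        if fleet.lognormal_sd > 0
        else np.ones(n)
    )
    catch = fleet.base_catch * mult * noise
    if fleet.p_zero > 0:
        catch = np.where(rng.random(n) < fleet.p_zero, 0.0, catch)

    depth_zone = rng.choice(["0-200m", "200-400m", "400-600m"], n)
    target = rng.beta(2.0, 2.0, n)
    return pd.DataFrame(
        {
            "year": year,
            "quarter": quarter,
            "vessel": vessel,
            "gear": gear,
            "depth_zone": depth_zone,
            "target_fraction": target,
            "catch": catch,
            "effort": float(effort) * np.ones(n),
        }
    )
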