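"""Growth estimation from length frequencies (ELEFAN with a genetic algorithm).

The von Bertalanffy growth function is used in its t0-free form
L(t) = L∞·(1 − e^(−k·t)), with a third parameter ``t_anchor`` — the fraction of
the calendar year at which each annual cohort is born — standing in for t0 so
that growth curves can be aligned with calendar sampling dates.

ELEFAN (electronic length-frequency analysis) proceeds in two steps:

1. *Restructuring*: each monthly column of the length-frequency table is
   turned into peak/trough scores by dividing counts by a centred moving
   average over ``ma`` bins and subtracting one, then deflating isolated
   peaks and rescaling positives so they balance the negatives. The sum of
   positive scores is the available sum of peaks (ASP).
2. *Scoring*: a candidate (L∞, k, t_anchor) defines one growth curve per
   annual cohort; every (bin, month) cell a curve passes through contributes
   its score (once) to the explained sum of peaks (ESP). The goodness of fit
   is Rn = 10^(ESP/ASP) / 10 ∈ (0, 1].

A small generational genetic algorithm maximizes Rn, and within-month
multinomial bootstrap resampling of the counts gives percentile confidence
intervals for L∞, k and the growth performance index Φ′ = 2·log10 L∞ + log10 k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lfq import LengthFrequencyTable

__all__ = [
    "VBGFParams",
    "RestructuredLFQ",
    "GrowthFit",
    "SearchSpace",
    "GASettings",
    "vbgf_length_at_age",
    "inverse_vbgf_age_at_length",
    "restructure_lfq",
    "elefan_score",
    "fit_growth_ga",
    "growth_performance_phi",
]


@dataclass(frozen=True)
class VBGFParams:
    """Von Bertalanffy parameters: L∞ (cm), k (year⁻¹), within-year cohort
    birth fraction t_anchor ∈ [0, 1)."""

    linf: float
    k: float
    t_anchor: float = 0.0

    def __post_init__(self):
        if not (self.linf > 0 and math.isfinite(self.linf)):
            raise ValueError("linf must be positive and finite")
        if not (self.k > 0 and math.isfinite(self.k)):
            raise ValueError("k must be positive and finite")
        if not 0 <= self.t_anchor < 1:
            raise ValueError("t_anchor must be in [0, 1)")


def vbgf_length_at_age(p: VBGFParams, t):
    """Mean length at (relative) age t: L∞·(1 − e^(−k·t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    return p.linf * (1.0 - np.exp(-p.k * t))


def inverse_vbgf_age_at_length(p: VBGFParams, length):
    """Relative age at length: t = −ln(1 − L/L∞)/k. Requires 0 ≤ L < L∞."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0) or np.any(length >= p.linf):
        raise ValueError("length must satisfy 0 <= L < linf")
    return -np.log(1.0 - length / p.linf) / p.k


def growth_performance_phi(linf: float, k: float) -> float:
    """Growth performance index Φ′ = 2·log10(L∞) + log10(k)."""
    if linf <= 0 or k <= 0:
        raise ValueError("linf and k must be > 0")
    return 2.0 * math.log10(linf) + math.log10(k)


@dataclass
class RestructuredLFQ:
    """Peak/trough scores on the same (bin × date) grid as the source LFQ."""

    bin_lower: np.ndarray
    dates: list
    scores: np.ndarray
    asp: float
    bin_width: float

    def date_fracs(self) -> np.ndarray:
        return np.array([p.year + (p.month - 0.5) / 12.0 for p in self.dates])


def _moving_average(col: np.ndarray, ma: int) -> np.ndarray:
    """Centred moving average with edge-window truncation."""
    h = ma // 2
    n = col.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(col)])
    for i in range(n):
        a, b = max(0, i - h), min(n, i + h + 1)
        out[i] = (csum[b] - csum[a]) / (b - a)
    return out


def restructure_lfq(lfq: LengthFrequencyTable, ma: int = 5) -> RestructuredLFQ:
    """Moving-average restructuring of an LFQ into peak/trough scores.

    Per date column: score = count / (centred MA over ``ma`` bins) − 1, with
    zero-MA cells defined as 0; positive scores of peaks flanked by zero-count
    bins are halved per adjacent zero (isolated-peak deflation); positives are
    then rescaled so their sum balances the summed magnitude of negatives.
    ASP is the grand sum of positive scores.
    """
    if ma < 3 or ma % 2 == 0:
        raise ValueError("ma must be an odd integer >= 3")
    if ma > lfq.n_bins:
        raise ValueError(f"ma={ma} exceeds the number of bins ({lfq.n_bins})")
    scores = np.zeros_like(lfq.counts)
    for j in range(lfq.n_dates):
        col = lfq.counts[:, j]
        mav = _moving_average(col, ma)
        s = np.zeros_like(col)
        nz = mav > 0
        s[nz] = col[nz] / mav[nz] - 1.0
        # isolated-peak deflation: halve a positive score per zero-count
        # immediate neighbour
        for i in np.flatnonzero(s > 0):
            n_zero = 0
            if i > 0 and col[i - 1] == 0:
                n_zero += 1
            if i < col.size - 1 and col[i + 1] == 0:
                n_zero += 1
            s[i] /= 2.0 ** n_zero
        pos, neg = s[s > 0].sum(), -s[s < 0].sum()
        if pos > 0 and neg > 0:
            s[s > 0] *= neg / pos
        scores[:, j] = s
    asp = float(scores[scores > 0].sum())
    return RestructuredLFQ(
        lfq.bin_lower.copy(), list(lfq.dates), scores, asp, lfq.bin_width
    )


def elefan_score(r: RestructuredLFQ, p: VBGFParams) -> float:
    """Rn = 10^(ESP/ASP)/10 for growth curves implied by ``p``.

    One curve per annual cohort, born at calendar fraction ``t_anchor``; a
    curve crossing a (bin, date) cell collects that cell's score, each cell at
    most once overall.
    """
    if r.asp <= 0:
        raise ValueError("ASP is zero: no peaks to explain")
    dates = r.date_fracs()
    e0 = r.bin_lower[0]
    w = r.bin_width
    n_bins = r.bin_lower.size
    upper_max = r.bin_lower[-1] + w

    # oldest age a curve can be inside the bin grid
    l_cap = min(upper_max, 0.999 * p.linf)
    t_max = -math.log(1.0 - l_cap / p.linf) / p.k
    first_birth = math.floor(dates.min() - t_max)
    last_birth = math.floor(dates.max())
    births = np.arange(first_birth, last_birth + 1) + p.t_anchor

    ages = dates[None, :] - births[:, None]  # cohorts × dates
    valid = ages > 0
    lengths = p.linf * (1.0 - np.exp(-p.k * np.where(valid, ages, 0.0)))
    idx = np.floor((lengths - e0) / w).astype(int)
    valid &= (idx >= 0) & (idx < n_bins)
    cohort, datecol = np.nonzero(valid)
    cells = np.unique(idx[cohort, datecol] * len(dates) + datecol)
    esp = float(r.scores.ravel()[
        np.ravel_multi_index(
            (cells // len(dates), cells % len(dates)), r.scores.shape
        )
    ].sum()) if cells.size else 0.0
    return 10.0 ** (esp / r.asp) / 10.0


@dataclass(frozen=True)
class SearchSpace:
    """GA box constraints; defaults follow the observed size range."""

    linf: tuple = None
    k: tuple = (0.01, 1.0)
    t_anchor: tuple = (0.0, 1.0)

    @staticmethod
    def default_for(lfq: LengthFrequencyTable) -> "SearchSpace":
        used = lfq.midpoints[lfq.pooled() > 0]
        lmax = float(used.max()) if used.size else float(lfq.midpoints.max())
        return SearchSpace(linf=(0.8 * lmax, 1.3 * lmax))


@dataclass(frozen=True)
class GASettings:
    pop_size: int = 50
    generations: int = 100
    tournament: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.25
    mutation_sigma: float = 0.1  # fraction of each parameter range, decays 5x
    elitism: int = 2


def _ga_maximize(score_fn, bounds, settings: GASettings, rng) -> tuple:
    """Generational GA with tournament selection, blend crossover, Gaussian
    mutation; ties in fitness broken by smaller L∞ (first coordinate)."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo
    npop, d = settings.pop_size, len(bounds)
    pop = lo + rng.random((npop, d)) * span
    fit = np.array([score_fn(ind) for ind in pop])

    def better(i, j):
        if fit[i] != fit[j]:
            return i if fit[i] > fit[j] else j
        return i if pop[i, 0] <= pop[j, 0] else j

    for g in range(settings.generations):
        order = sorted(
            range(npop), key=lambda i: (-fit[i], pop[i, 0])
        )
        elite = [pop[i].copy() for i in order[: settings.elitism]]
        elite_fit = [fit[i] for i in order[: settings.elitism]]
        children, child_fit = [], []
        sigma = settings.mutation_sigma * span * (0.2 ** (g / max(1, settings.generations)))
        while len(children) < npop - settings.elitism:
            cand = rng.integers(0, npop, settings.tournament)
            p1 = cand[0]
            for c in cand[1:]:
                p1 = better(p1, c)
            cand = rng.integers(0, npop, settings.tournament)
            p2 = cand[0]
            for c in cand[1:]:
                p2 = better(p2, c)
            a, b = pop[p1].copy(), pop[p2].copy()
            if rng.random() < settings.crossover_rate:
                u = rng.random(d)
                child = u * a + (1 - u) * b
            else:
                child = a
            mut = rng.random(d) < settings.mutation_rate
            child = np.where(mut, child + rng.normal(0, 1, d) * sigma, child)
            child = np.clip(child, lo, hi)
            children.append(child)
            child_fit.append(score_fn(child))
        pop = np.vstack(elite + children)
        fit = np.array(elite_fit + child_fit)
    order = sorted(range(npop), key=lambda i: (-fit[i], pop[i, 0]))
    best = order[0]
    return pop[best], float(fit[best])


@dataclass
class GrowthFit:
    """Point estimates with bootstrap percentile intervals."""

    point: VBGFParams
    rn_score: float
    phi_prime: float
    ci_linf: tuple | None
    ci_k: tuple | None
    ci_phi: tuple | None
    n_bootstrap: int
    bootstrap_samples: pd.DataFrame | None = None


def _fit_once(lfq, space, settings, ma, rng):
    r = restructure_lfq(lfq, ma=ma)
    bounds = [space.linf, space.k, (space.t_anchor[0], space.t_anchor[1] - 1e-9)]

    def score(vec):
        try:
            return elefan_score(r, VBGFParams(vec[0], vec[1], vec[2] % 1.0))
        except ValueError:
            return 0.0

    best, rn = _ga_maximize(score, bounds, settings, rng)
    return VBGFParams(best[0], best[1], best[2] % 1.0), rn


def fit_growth_ga(
    lfq: LengthFrequencyTable,
    search_space: SearchSpace | None = None,
    ga_settings: GASettings | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
    ma: int = 5,
    ci_level: float = 0.95,
) -> GrowthFit:
    """Maximize Rn over (L∞, k, t_anchor) with a GA; bootstrap the counts
    within each month (multinomial) for percentile confidence intervals."""
    if lfq.n_dates < 2:
        raise ValueError("growth fitting needs at least 2 sampling dates")
    space = search_space or SearchSpace.default_for(lfq)
    if space.linf is None:
        space = SearchSpace(
            linf=SearchSpace.default_for(lfq).linf, k=space.k, t_anchor=space.t_anchor
        )
    for b in (space.linf, space.k):
        if not (np.isfinite(b).all() and b[0] < b[1]):
            raise ValueError("search-space bounds must be finite with lower < upper")
    settings = ga_settings or GASettings()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    point, rn = _fit_once(lfq, space, settings, ma, rng)
    phi = growth_performance_phi(point.linf, point.k)

    ci_linf = ci_k = ci_phi = None
    samples = None
    if n_bootstrap > 0:
        boot_ss = ss.spawn(n_bootstrap + 1)[1:]
        rows = []
        for b in range(n_bootstrap):
            brng = np.random.default_rng(boot_ss[b])
            bcounts = np.zeros_like(lfq.counts)
            for j in range(lfq.n_dates):
                tot = int(round(lfq.counts[:, j].sum()))
                if tot == 0:
                    continue
                pcol = lfq.counts[:, j] / lfq.counts[:, j].sum()
                bcounts[:, j] = brng.multinomial(tot, pcol)
            blfq = LengthFrequencyTable(lfq.bin_lower, lfq.dates, bcounts)
            blfq.set_width(lfq.bin_width)
            bp, brn = _fit_once(blfq, space, settings, ma, brng)
            rows.append(
                (bp.linf, bp.k, bp.t_anchor,
                 growth_performance_phi(bp.linf, bp.k), brn)
            )
        samples = pd.DataFrame(
            rows, columns=["linf", "k", "t_anchor", "phi_prime", "rn"]
        )
        a = (1.0 - ci_level) / 2.0
        qs = [a, 1.0 - a]
        ci_linf = tuple(np.quantile(samples["linf"], qs))
        ci_k = tuple(np.quantile(samples["k"], qs))
        ci_phi = tuple(np.quantile(samples["phi_prime"], qs))
    return GrowthFit(point, rn, phi, ci_linf, ci_k, ci_phi, n_bootstrap, samples)
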