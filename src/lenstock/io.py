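"""CSV readers/writers and run configuration.

Three CSV dialects are exchanged, all snake_case:

* length-frequency: ``date`` (ISO month), ``length_lower`` (cm), ``count``;
* survey stations: ``station, longitude, latitude, depth, substrate, rpn``;
* trip records: ``year, quarter, vessel, gear, depth_zone, target_fraction,
  catch, effort``.

Readers validate and name the offending row on error; the LFQ reader
gap-fills missing bins and months with zeros. All defaults applied from a
config file are logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .lfq import LengthFrequencyTable
from .synthetic import SUBSTRATE_LEVELS

log = logging.getLogger("lenstock")

__all__ = [
    "RunConfig",
    "read_lfq",
    "write_lfq",
    "read_survey",
    "write_survey",
    "read_trips",
    "write_trips",
]


@dataclass
class RunConfig:
    """Pipeline settings; field defaults are the analysis defaults.

    bin width 5 cm, moving-average window 5, 1000 bootstrap resamples,
    depth basis dimension 4, mean temperature 18 °C, tmax = 3/k,
    α = 0.05.
    """

    lfq_path: str | None = None
    survey_path: str | None = None
    trips_path: str | None = None
    fish_path: str | None = None  # per-fish length/sex records
    bin_width: float = 5.0
    ma: int = 5
    n_bootstrap: int = 1000
    ga_pop_size: int = 50
    ga_generations: int = 100
    depth_basis_dim: int = 4
    temperature: float = 18.0
    tmax: float | None = None  # None -> 3/k
    alpha: float = 0.05
    seed: int = 1
    linf: float | None = None  # explicit growth params bypass the growth stage
    k: float | None = None
    stages: list = field(
        default_factory=lambda: ["growth", "mortality", "sdm", "structure", "abundance"]
    )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                log.info("config default applied: %s = %r", f.name, getattr(cfg, f.name))
        return cfg


def _fail(path, row, msg):
    raise ValueError(f"{path}, row {row}: {msg}")


def read_lfq(path: str) -> LengthFrequencyTable:
    """Read a length-frequency CSV; gap-fill missing bins/months with zeros."""
    df = pd.read_csv(path)
    req = {"date", "length_lower", "count"}
    if not req <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(req)}")
    dates = []
    for i, d in enumerate(df["date"]):
        try:
            p = pd.Period(str(d), freq="M")
        except Exception:
            _fail(path, i + 2, f"unparseable date {d!r}")
        dates.append(p)
    df = df.assign(_month=dates)
    for i, c in enumerate(df["count"]):
        if not np.isfinite(c):
            _fail(path, i + 2, f"non-finite count {c!r}")
        if c < 0:
            _fail(path, i + 2, f"negative count {c!r}")

    lowers = np.sort(df["length_lower"].unique().astype(float))
    if lowers.size > 1:
        steps = np.unique(np.round(np.diff(lowers), 9))
        width = steps.min()
        if np.any(np.abs(np.diff(lowers) / width - np.round(np.diff(lowers) / width)) > 1e-9):
            raise ValueError(f"{path}: non-uniform bin widths {sorted(steps)}")
        # fill missing bins on the uniform grid
        lowers = np.arange(lowers[0], lowers[-1] + width / 2, width)
    else:
        width = 5.0

    pmin, pmax = min(df["_month"]), max(df["_month"])
    months = pd.period_range(pmin, pmax, freq="M").tolist()
    counts = np.zeros((lowers.size, len(months)))
    col = {m: j for j, m in enumerate(months)}
    bin_of = {round(lo, 9): i for i, lo in enumerate(lowers)}
    for idx, r in df.iterrows():
        key = round(float(r["length_lower"]), 9)
        if key not in bin_of:
            _fail(path, idx + 2, f"length_lower {r['length_lower']} off the bin grid")
        counts[bin_of[key], col[r["_month"]]] += float(r["count"])
    t = LengthFrequencyTable(lowers, months, counts)
    t.set_width(width)
    return t


def write_lfq(lfq: LengthFrequencyTable, path: str) -> None:
    lfq.to_frame().to_csv(path, index=False)


def read_survey(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"longitude", "latitude", "depth", "substrate", "rpn"}
    if not req <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(req)}")
    for i, r in df.iterrows():
        if r["substrate"] not in SUBSTRATE_LEVELS:
            _fail(path, i + 2, f"unknown substrate {r['substrate']!r}")
        if not 0 <= r["depth"] <= 600:
            _fail(path, i + 2, f"depth {r['depth']} outside [0, 600] m")
        if r["rpn"] < 0:
            _fail(path, i + 2, f"negative rpn {r['rpn']}")
    return df


def write_survey(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_trips(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"year", "quarter", "catch", "effort"}
    if not req <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(req)}")
    for i, r in df.iterrows():
        if r["catch"] < 0:
            _fail(path, i + 2, f"negative catch {r['catch']}")
        if r["effort"] <= 0:
            _fail(path, i + 2, f"non-positive effort {r['effort']}")
        if "target_fraction" in df.columns and not 0 <= r["target_fraction"] <= 1:
            _fail(path, i + 2, f"target_fraction {r['target_fraction']} outside [0, 1]")
    return df


def write_trips(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)
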