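"""Reduction of supernatant-depletion time courses to uptake rates.

An uptake assay follows the concentration of one sugar in the culture
supernatant over time after a fixed induction.  The uptake rate per biomass
is computed from the depletion between two time points:

    rate = (C(0) - C(t_end)) [uM] * V [L] * 1000 / (t_end [min] * DW [mg])

in nmol min^-1 mg DW^-1 (1 uM * 1 L = 1 umol = 1000 nmol).  The default
window is 0-15 min, the protocol the rate matrices are built on; longer
series are only used for percent-remaining curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UptakeAssay",
    "RateResult",
    "UptakeRateMatrix",
    "compute_uptake_rate",
    "build_uptake_matrix",
    "percent_remaining",
    "read_assays_csv",
    "write_assays_csv",
]

_TIME_TOL = 1e-6

NEGATIVE_CLIPPED = "negative_clipped"
DEPLETED = "depleted"


@dataclass(frozen=True)
class UptakeAssay:
    """A single replicate depletion time course for one sugar/condition."""

    sugar: str
    condition: str
    replicate: int
    volume_L: float
    biomass_mg: float
    time_min: tuple[float, ...]
    conc_uM: tuple[float, ...]
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_min", tuple(float(t) for t in self.time_min))
        object.__setattr__(self, "conc_uM", tuple(float(c) for c in self.conc_uM))
        if self.volume_L <= 0:
            raise ValueError(f"{self._name()}: volume must be positive")
        if self.biomass_mg <= 0:
            raise ValueError(f"{self._name()}: biomass must be positive")
        if len(self.time_min) != len(self.conc_uM):
            raise ValueError(f"{self._name()}: time/concentration length mismatch")
        if len(self.time_min) < 2:
            raise ValueError(f"{self._name()}: need >= 2 time points")
        if self.time_min[0] != 0:
            raise ValueError(f"{self._name()}: time course must start at 0")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"{self._name()}: time points must be strictly increasing")
        if any(c < 0 for c in self.conc_uM):
            raise ValueError(f"{self._name()}: negative concentration")

    def _name(self) -> str:
        return f"assay({self.sugar}, {self.condition}, rep {self.replicate})"

    def conc_at(self, t: float) -> float:
        for ti, ci in zip(self.time_min, self.conc_uM):
            if abs(ti - t) <= _TIME_TOL:
                return ci
        raise ValueError(f"{self._name()}: missing required time point {t} min")


@dataclass(frozen=True)
class RateResult:
    rate: float  # raw rate, may be negative
    flags: frozenset[str]


def compute_uptake_rate(assay: UptakeAssay, t_end_min: float = 15.0) -> RateResult:
    """Two-point uptake rate in nmol min^-1 mg DW^-1.

    Negative raw rates (concentration rising, e.g. evaporation exceeding
    uptake of a non-transported sugar) are returned as-is but flagged; the
    matrix aggregation step clips them to zero.
    """
    c0 = assay.conc_at(0.0)
    ct = assay.conc_at(t_end_min)
    rate = (c0 - ct) * assay.volume_L * 1000.0 / (t_end_min * assay.biomass_mg)
    flags = set(assay.flags)
    if rate < 0:
        flags.add(NEGATIVE_CLIPPED)
    return RateResult(float(rate), frozenset(flags))


@dataclass(frozen=True)
class UptakeRateMatrix:
    """Replicate-averaged uptake rates U(sugar, condition).

    ``rates`` is sugars x conditions (nmol min^-1 mg^-1), ``n_replicates``
    the per-cell replicate count, ``flags`` per-cell provenance flags
    (negative_clipped / depleted).  Cells absent from the assay design are
    NaN with replicate count 0, never silently zero.
    """

    rates: pd.DataFrame
    n_replicates: pd.DataFrame
    flags: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rates.index.equals(self.n_replicates.index) or not self.rates.columns.equals(
            self.n_replicates.columns
        ):
            raise ValueError("rates / n_replicates shape mismatch")
        present = self.rates.notna().to_numpy()
        if np.any(self.n_replicates.to_numpy()[present] < 1):
            raise ValueError("present rate cell with n_replicates < 1")

    @property
    def sugars(self) -> list[str]:
        return [str(s) for s in self.rates.index]

    @property
    def conditions(self) -> list[str]:
        return [str(c) for c in self.rates.columns]

    @classmethod
    def from_tsv(cls, path, flags_path=None) -> "UptakeRateMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        flags: dict[tuple[str, str], frozenset[str]] = {}
        if flags_path is not None:
            with open(flags_path) as fh:
                raw = json.load(fh)
            flags = {(s, c): frozenset(v) for s, c, v in raw}
        n = df.notna().astype(int)
        return cls(df.astype(float), n, flags)

    def to_tsv(self, path, flags_path=None) -> None:
        out = self.rates.copy()
        out.index.name = "sugar"
        out.to_csv(path, sep="\t", float_format="%.10g")
        if flags_path is not None:
            raw = [[s, c, sorted(v)] for (s, c), v in sorted(self.flags.items())]
            with open(flags_path, "w") as fh:
                json.dump(raw, fh, indent=1)


def build_uptake_matrix(
    assays: list[UptakeAssay], t_end_min: float = 15.0
) -> UptakeRateMatrix:
    """Aggregate replicate assays into a sugars x conditions rate matrix.

    Per cell: arithmetic mean of replicate rates after clipping negatives to
    zero.  Row/column order follows first appearance in the assay list, which
    makes the output deterministic for a deterministically ordered design.
    """
    if not assays:
        raise ValueError("no assays given")
    sugars: list[str] = []
    conditions: list[str] = []
    per_cell: dict[tuple[str, str], list[float]] = {}
    cell_flags: dict[tuple[str, str], set[str]] = {}
    for a in assays:
        if a.sugar not in sugars:
            sugars.append(a.sugar)
        if a.condition not in conditions:
            conditions.append(a.condition)
        res = compute_uptake_rate(a, t_end_min=t_end_min)
        key = (a.sugar, a.condition)
        per_cell.setdefault(key, []).append(max(res.rate, 0.0))
        cell_flags.setdefault(key, set()).update(res.flags)
    rates = pd.DataFrame(np.nan, index=sugars, columns=conditions, dtype=float)
    nrep = pd.DataFrame(0, index=sugars, columns=conditions, dtype=int)
    for (s, c), vals in per_cell.items():
        rates.loc[s, c] = float(np.mean(vals))
        nrep.loc[s, c] = len(vals)
    flags = {k: frozenset(v) for k, v in cell_flags.items() if v}
    return UptakeRateMatrix(rates, nrep, flags)


def percent_remaining(
    assays: list[UptakeAssay], sugar: str, condition: str
) -> pd.DataFrame:
    """Percent of the initial supernatant concentration left at each time.

    Returns a time_min x replicate table with 100 * C(t)/C(0) per replicate;
    row 0 is exactly 100 for every replicate.
    """
    selected = [a for a in assays if a.sugar == sugar and a.condition == condition]
    if not selected:
        raise ValueError(f"no assays for ({sugar!r}, {condition!r})")
    cols = {}
    for a in selected:
        c0 = a.conc_uM[0]
        if c0 <= 0:
            raise ValueError(f"{a._name()}: C(0) must be > 0 for percent_remaining")
        cols[a.replicate] = pd.Series(
            [100.0 * c / c0 for c in a.conc_uM], index=list(a.time_min)
        )
    out = pd.DataFrame(cols)
    out.index.name = "time_min"
    out.columns.name = "replicate"
    return out


# ---------------------------------------------------------------------------
# long-format CSV I/O (one row per time point per replicate)

_ASSAY_COLS = ["sugar", "condition", "replicate", "volume_L", "biomass_mg", "time_min", "conc_uM"]


def write_assays_csv(assays: list[UptakeAssay], path) -> None:
    rows = []
    for a in assays:
        for t, c in zip(a.time_min, a.conc_uM):
            rows.append(
                dict(
                    sugar=a.sugar,
                    condition=a.condition,
                    replicate=a.replicate,
                    volume_L=a.volume_L,
                    biomass_mg=a.biomass_mg,
                    time_min=t,
                    conc_uM=c,
                    flags=";".join(sorted(a.flags)),
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assays_csv(path) -> list[UptakeAssay]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in _ASSAY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"assay CSV missing columns: {missing}")
    assays = []
    for (sugar, condition, rep), sub in df.groupby(
        ["sugar", "condition", "replicate"], sort=False
    ):
        sub = sub.sort_values("time_min")
        flags: frozenset[str] = frozenset()
        if "flags" in sub.columns:
            joined = {f for cell in sub["flags"].astype(str) for f in cell.split(";") if f}
            flags = frozenset(joined)
        assays.append(
            UptakeAssay(
                sugar=str(sugar),
                condition=str(condition),
                replicate=int(rep),
                volume_L=float(sub["volume_L"].iloc[0]),
                biomass_mg=float(sub["biomass_mg"].iloc[0]),
                time_min=tuple(sub["time_min"].astype(float)),
                conc_uM=tuple(sub["conc_uM"].astype(float)),
                flags=flags,
            )
        )
    return assays
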