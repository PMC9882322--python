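"""EMSA binding-curve quantification: fraction bound, C_50 by linear
interpolation, and replicate aggregation.

C_50 — the protein concentration at which half the DNA substrate is shifted —
is a relative-affinity proxy used when true K_d estimation is not meaningful
(unknown stoichiometry and binding-site count). It is read off the titration
by linear interpolation between the first pair of points that bracket 50%
bound. Replicates are aggregated with the conventions: two replicates give
mean +/- half the absolute difference (labeled "range"); three or more give
mean +/- sample SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import C50UndefinedError, ParameterError

__all__ = [
    "BindingTable",
    "AggregateResult",
    "fraction_bound",
    "c50",
    "aggregate_replicates",
    "c50_by_substrate",
]


@dataclass
class BindingTable:
    """One replicate's titration: ascending concentrations and fractions bound."""

    concentrations: np.ndarray  # nM
    fractions: np.ndarray  # 0..1
    replicate: int = 0
    substrate: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.concentrations.shape != self.fractions.shape:
            raise ParameterError("concentrations and fractions must align")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ParameterError("concentrations must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ParameterError("fractions bound must lie in [0, 1]")


@dataclass
class AggregateResult:
    center: float
    spread: float | None
    convention: str  # "single" | "range" | "sd"
    n: int


def fraction_bound(free_band_intensity: float, zero_protein_intensity: float) -> float:
    """Fraction bound from free-band densitometry: 1 - free/reference, clipped."""
    if zero_protein_intensity <= 0:
        raise ParameterError("zero-protein reference intensity must be positive")
    return float(np.clip(1.0 - free_band_intensity / zero_protein_intensity, 0.0, 1.0))


def c50(table: BindingTable) -> float:
    """C_50 (nM) by linear interpolation at the first crossing of 0.5.

    Requires at least one point below 0.5 and one at or above it; otherwise a
    :class:`C50UndefinedError` is raised carrying the maximum fraction bound
    attained (reported for unsaturated titrations). If the noisy curve
    crosses 0.5 more than once, the first crossing from below is used and a
    warning is emitted.
    """
    c, f = table.concentrations, table.fractions
    crossings = [
        i for i in range(len(f) - 1) if f[i] < 0.5 <= f[i + 1]
    ]
    exact = np.nonzero(f == 0.5)[0]
    if not crossings and exact.size:
        return float(c[exact[0]])
    if not crossings or not np.any(f < 0.5):
        raise C50UndefinedError(
            f"50% bound never bracketed (max fraction {f.max():.3f})",
            max_fraction=float(f.max()),
        )
    if len(crossings) > 1:
        warnings.warn(
            "fraction bound crosses 0.5 more than once; using the first "
            "crossing from below",
            stacklevel=2,
        )
    i = crossings[0]
    if f[i + 1] == f[i]:  # unreachable given the bracket, defensive
        return float(c[i + 1])
    return float(c[i] + (0.5 - f[i]) * (c[i + 1] - c[i]) / (f[i + 1] - f[i]))


def aggregate_replicates(values: list[float] | np.ndarray) -> AggregateResult:
    """Aggregate replicate C_50 values with the n-dependent convention.

    n = 1: the value itself, spread undefined; n = 2: mean +/- half the
    absolute difference ("range"); n >= 3: mean +/- sample SD ("sd").
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ParameterError("need at least one replicate value")
    if vals.size == 1:
        return AggregateResult(float(vals[0]), None, "single", 1)
    if vals.size == 2:
        return AggregateResult(
            float(vals.mean()), float(abs(vals[1] - vals[0]) / 2.0), "range", 2
        )
    return AggregateResult(
        float(vals.mean()), float(vals.std(ddof=1)), "sd", int(vals.size)
    )


def c50_by_substrate(df: pd.DataFrame) -> pd.DataFrame:
    """Per-substrate C_50 aggregation from a tidy binding table.

    Expects columns concentration_nM, fraction_bound, replicate, substrate.
    Unsaturated replicates (0.5 never bracketed) are reported with the
    maximum fraction attained instead of a C_50.
    """
    required = {"concentration_nM", "fraction_bound", "replicate", "substrate"}
    if not required.issubset(df.columns):
        raise ParameterError(f"binding table must have columns {sorted(required)}")
    rows = []
    for substrate, sub in df.groupby("substrate", sort=True):
        values = []
        unsaturated = []
        for rep, repdf in sub.groupby("replicate", sort=True):
            repdf = repdf.sort_values("concentration_nM")
            table = BindingTable(
                repdf["concentration_nM"].to_numpy(),
                repdf["fraction_bound"].to_numpy(),
                replicate=int(rep),
                substrate=str(substrate),
            )
            try:
                values.append(c50(table))
            except C50UndefinedError as exc:
                unsaturated.append(exc.max_fraction)
        if values:
            agg = aggregate_replicates(values)
            rows.append(
                {
                    "substrate": substrate,
                    "c50_nM": agg.center,
                    "spread_nM": agg.spread if agg.spread is not None else float("nan"),
                    "convention": agg.convention,
                    "n_replicates": agg.n,
                    "max_fraction_bound": float("nan"),
                }
            )
        else:
            rows.append(
                {
                    "substrate": substrate,
                    "c50_nM": float("nan"),
                    "spread_nM": float("nan"),
                    "convention": "unsaturated",
                    "n_replicates": len(unsaturated),
                    "max_fraction_bound": max(unsaturated) if unsaturated else float("nan"),
                }
            )
    return pd.DataFrame(rows)
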