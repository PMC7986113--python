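"""Gross N mineralization and NH4+ consumption by 15N pool dilution.

A 15NH4+ label is added to the soil NH4+ pool; unlabelled NH4+ produced by
gross mineralization dilutes the label while consumption removes labelled
and unlabelled N alike. Under constant rates (the Kirkham-Bartholomew
assumptions) the paired observations (A0, APE0) and (At, APEt) identify the
gross rates analytically:

    net_min   = (At - A0) / t
    gross_min = (At - A0)/t * ln(APE0/APEt) / ln(At/A0)
    gross_con = gross_min - net_min

with the L'Hopital limit  gross_min = A0 * ln(APE0/APEt) / t  when the pool
is (numerically) unchanged. Rates are per day internally; pools in ug N per
g (OM or DW, carried explicitly on the assay).

``simulate_constant_rate`` is the exact forward model of the same two-pool
ODE system and is what the synthetic-experiment generator uses; the
estimator inverts it exactly in the noiseless case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DilutionAssay",
    "GrossRates",
    "estimate_gross_rates",
    "simulate_constant_rate",
    "rates_per_area",
    "days_to_mineralize",
    "rates_table",
]

#: |ln(At/A0)| below which the unchanged-pool limit form is used.
POOL_RATIO_EPSILON = 1e-8


@dataclass
class DilutionAssay:
    """Paired-time-point pool-dilution observations for one sample.

    a0, at: NH4+-N pools (ug N per g) at the initial and final time;
    ape0, apet: atom percent excess 15N of the NH4+ pool at those times;
    t: elapsed incubation time in days; unit: per-gram basis ("OM" or "DW").
    """

    a0: float
    at: float
    ape0: float
    apet: float
    t: float
    unit: str = "OM"

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.at <= 0:
            raise ValueError("NH4+ pools must be positive")
        if self.t <= 0:
            raise ValueError("incubation time must be positive")

    @classmethod
    def from_hours(cls, a0, at, ape0, apet, hours, unit="OM"):
        return cls(a0=a0, at=at, ape0=ape0, apet=apet, t=hours / 24.0, unit=unit)


@dataclass
class GrossRates:
    """Gross/net mineralization and gross NH4+ consumption (ug N g-1 d-1)."""

    gross_min: float
    net_min: float
    gross_cons: float
    unit: str = "OM"
    qc_flags: set = field(default_factory=set)


def estimate_gross_rates(assay: DilutionAssay,
                         pool_ratio_epsilon: float = POOL_RATIO_EPSILON) -> GrossRates:
    """Analytical constant-rate estimator for one pool-dilution assay.

    Degenerate cases are flagged, never raised: an unchanged pool switches
    to the limit form (``pool_unchanged_limit``), an APE that *rose* during
    incubation (``ape_increase``) or a negative gross rate
    (``negative_rate``) marks a violated assumption. Only a non-positive
    APE, for which the logarithm is undefined, is an error.
    """
    if assay.ape0 <= 0 or assay.apet <= 0:
        raise ValueError("APE values must be positive for rate estimation")
    flags: set = set()
    log_dilution = math.log(assay.ape0 / assay.apet)
    log_pool = math.log(assay.at / assay.a0)
    net_min = (assay.at - assay.a0) / assay.t
    if abs(log_pool) > pool_ratio_epsilon:
        gross_min = net_min * log_dilution / log_pool
    else:
        gross_min = assay.a0 * log_dilution / assay.t
        flags.add("pool_unchanged_limit")
    if assay.apet > assay.ape0:
        flags.add("ape_increase")
    if gross_min < 0:
        flags.add("negative_rate")
    return GrossRates(gross_min=gross_min, net_min=net_min,
                      gross_cons=gross_min - net_min,
                      unit=assay.unit, qc_flags=flags)


def simulate_constant_rate(gross_min: float, gross_cons: float,
                           a0: float, ape0: float, t: float) -> tuple[float, float]:
    """Exact (At, APEt) for constant gross rates m and c.

    Solves  dA/dt = m - c  and  dH/dt = -c*H/A  (H the excess-15N amount in
    the pool) in closed form:  A(t) = A0 + (m-c)t  and

        H(t) = H0 * (A(t)/A0)^(-c/(m-c))    (m != c)
        H(t) = H0 * exp(-c t / A0)          (m == c)

    Returns the observable pair (At, APEt = 100*H/A*...) with APE on the
    same percent scale as ape0.
    """
    if a0 <= 0 or ape0 <= 0 or t <= 0:
        raise ValueError("a0, ape0 and t must be positive")
    if gross_min < 0 or gross_cons < 0:
        raise ValueError("rates must be non-negative")
    m, c = gross_min, gross_cons
    at = a0 + (m - c) * t
    if at <= 0:
        raise ValueError("consumption empties the pool within t")
    h0 = a0 * ape0 / 100.0
    if abs(m - c) < 1e-12 * max(m, c, 1.0):
        ht = h0 * math.exp(-c * t / a0)
    else:
        ht = h0 * (at / a0) ** (-c / (m - c))
    return at, 100.0 * ht / at


def rates_per_area(rate_ug_per_g_day: float, bulk_om_g_per_m2: float) -> float:
    """Convert a per-gram rate to g N m-2 day-1 given the OM (or soil) stock."""
    return rate_ug_per_g_day * bulk_om_g_per_m2 * 1e-6


def days_to_mineralize(n_load_g_per_m2: float, rate_g_per_m2_day: float,
                       round_to: int | None = 5) -> tuple[float, float | None]:
    """Days for gross mineralization to turn over a given N load.

    Returns (raw_days, rounded_days); ``round_to`` rounds to the nearest
    multiple (default 5, producing 'about N days' figures), or None to skip.
    """
    if rate_g_per_m2_day <= 0:
        raise ValueError("rate must be positive")
    if n_load_g_per_m2 < 0:
        raise ValueError("n_load must be non-negative")
    raw = n_load_g_per_m2 / rate_g_per_m2_day
    rounded = None if round_to is None else round_to * round(raw / round_to)
    return raw, rounded


def rates_table(assays: pd.DataFrame, pool_ratio_epsilon: float = POOL_RATIO_EPSILON
                ) -> pd.DataFrame:
    """Estimate gross rates for a tidy assay table (one row per sample).

    Requires columns plot_id, a0, at, ape0, apet, t_days (optional: unit).
    Flagged estimates are retained in the output, flags joined with ';'.
    """
    required = ["plot_id", "a0", "at", "ape0", "apet", "t_days"]
    missing = [c for c in required if c not in assays.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    rows = []
    for _, r in assays.iterrows():
        assay = DilutionAssay(a0=r["a0"], at=r["at"], ape0=r["ape0"],
                              apet=r["apet"], t=r["t_days"],
                              unit=r.get("unit", "OM"))
        g = estimate_gross_rates(assay, pool_ratio_epsilon)
        rows.append({"plot_id": r["plot_id"], "gross_min": g.gross_min,
                     "net_min": g.net_min, "gross_cons": g.gross_cons,
                     "unit": g.unit, "qc_flags": ";".join(sorted(g.qc_flags))})
    return pd.DataFrame(rows)
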