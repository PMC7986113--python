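"""Deterministic wet-lab assay reductions.

Covers the bench chemistry downstream of the raw instrument readings:

* dissolved pools — DON by difference (TDN minus inorganic N) and the
  dissolved C:N ratio;
* chloroform fumigation-extraction microbial biomass C and N, scaled by
  extraction coefficients (0.45 for C, 0.40 for N);
* fluorometric (MUF) hydrolytic enzyme activities from microplate reads
  against an in-suspension standard curve;
* DOPA peroxidase activity from paired +-H2O2 absorbances divided by the
  extinction coefficient (7.9);
* PLFA concentrations against a 19:0 internal standard, with the standard
  bacterial/fungal marker sums.

Negative derived quantities are flagged, never clamped; a log-transforming
statistics layer downstream then fails loudly instead of silently digesting
an impossible value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DissolvedPools",
    "BiomassExtract",
    "EnzymePlate",
    "AssayError",
    "BACTERIAL_MARKERS",
    "FUNGAL_MARKERS",
    "derive_dissolved_pools",
    "microbial_biomass",
    "hydrolytic_activity",
    "peroxidase_activity",
    "plfa_concentration",
    "plfa_group_sums",
]

#: fumigation-extraction coefficients for incomplete biomass extraction
KEC_DEFAULT = 0.45
KEN_DEFAULT = 0.40
#: DOPA oxidation extinction coefficient (absorbance per umol per mL,
#: path-normalized), used as a unitless divisor
PEROXIDASE_EXTINCTION = 7.9

BACTERIAL_MARKERS = ("i15:0", "a15:0", "i16:0", "i17:0", "a17:0", "17:0",
                     "16:1w9", "16:1w7", "cy17:0", "cy19:0")
FUNGAL_MARKERS = ("18:2w6,9",)


class AssayError(ValueError):
    """A plate or extract that cannot be reduced (e.g. failed standards)."""


@dataclass
class DissolvedPools:
    nh4: float
    no3: float
    tdn: float
    doc: float
    don: float
    cn_ratio: float | None
    qc_flags: set = field(default_factory=set)


@dataclass
class BiomassExtract:
    """Fumigated / unfumigated extract pair (ug per g OM)."""

    c_fumigated: float
    c_unfumigated: float
    n_fumigated: float
    n_unfumigated: float
    kec: float = KEC_DEFAULT
    ken: float = KEN_DEFAULT

    def __post_init__(self) -> None:
        if not (0 < self.kec <= 1) or not (0 < self.ken <= 1):
            raise ValueError("extraction coefficients must lie in (0, 1]")


@dataclass
class EnzymePlate:
    """One fluorometric plate: sample replicates, an in-suspension MUF
    standard series (six levels), and substrate blanks.

    ``soil_g_per_well`` is the dry-soil equivalent pipetted per well (a
    1 g / 100 mL suspension at 200 uL per well and 40 % dry matter gives
    0.0008 g); the standard curve is prepared in soil suspension so sample
    and standard share the same quench by construction.
    """

    sample_rfu: Sequence[float]
    standard_nmol: Sequence[float]
    standard_rfu: Sequence[float]
    blank_rfu: Sequence[float]
    incubation_h: float
    soil_g_per_well: float

    def __post_init__(self) -> None:
        if len(self.sample_rfu) < 3:
            raise AssayError("need >=3 analytical replicates per sample")
        if len(self.standard_nmol) != 6 or len(self.standard_rfu) != 6:
            raise AssayError("standard curve requires six concentration levels")
        if self.incubation_h <= 0 or self.soil_g_per_well <= 0:
            raise ValueError("incubation time and soil mass must be positive")


def derive_dissolved_pools(nh4: float, no3: float, tdn: float, doc: float
                           ) -> DissolvedPools:
    """DON by difference and dissolved C:N from the four measured pools.

    don = tdn - (nh4 + no3); a negative DON (inorganic N exceeding TDN,
    an analytical inconsistency) is retained with a flag. cn_ratio is
    doc/tdn, undefined (None, flagged) at tdn = 0.
    """
    if min(nh4, no3, tdn, doc) < 0:
        raise ValueError("measured pools must be non-negative")
    flags: set = set()
    don = tdn - (nh4 + no3)
    if don < 0:
        flags.add("negative_don")
    if tdn > 0:
        cn = doc / tdn
    else:
        cn = None
        if doc > 0:
            flags.add("cn_undefined")
    return DissolvedPools(nh4=nh4, no3=no3, tdn=tdn, doc=doc, don=don,
                          cn_ratio=cn, qc_flags=flags)


def microbial_biomass(extract: BiomassExtract) -> tuple[float, float, float | None, set]:
    """Fumigation-extraction biomass C and N (ug per g OM) and their ratio.

    biomass = (fumigated - unfumigated) / extraction coefficient. A
    fumigated extract below its unfumigated pair is flagged (the chloroform
    lysis released nothing — measurement noise), not clamped.
    """
    flags: set = set()
    bc = (extract.c_fumigated - extract.c_unfumigated) / extract.kec
    bn = (extract.n_fumigated - extract.n_unfumigated) / extract.ken
    if bc < 0:
        flags.add("negative_biomass_c")
    if bn < 0:
        flags.add("negative_biomass_n")
    cn = bc / bn if bn > 0 else None
    if cn is None:
        flags.add("cn_undefined")
    return bc, bn, cn, flags


def hydrolytic_activity(plate: EnzymePlate) -> tuple[float, set]:
    """Potential hydrolytic activity in nmol MUF g-1 dry soil h-1.

    Fits the six-point standard curve (RFU vs nmol MUF per well) by
    ordinary least squares; activity is the blank-corrected mean sample
    signal divided by the slope, the incubation time and the dry-soil
    equivalent per well. Standards prepared in soil suspension make the
    fit quench-corrected by construction, and any common detector gain
    cancels between sample and slope.
    """
    x = np.asarray(plate.standard_nmol, dtype=float)
    y = np.asarray(plate.standard_rfu, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise AssayError(f"non-positive standard-curve slope ({slope:.3g} RFU/nmol)")
    flags: set = set()
    mean_sample = float(np.mean(plate.sample_rfu))
    mean_blank = float(np.mean(plate.blank_rfu))
    if not (y.min() <= mean_sample <= y.max()):
        flags.add("extrapolation")
    nmol_per_well = (mean_sample - mean_blank) / slope
    activity = nmol_per_well / plate.incubation_h / plate.soil_g_per_well
    if activity < 0:
        flags.add("negative_activity")
    return activity, flags


def peroxidase_activity(with_h2o2: float, without_h2o2: float, blanks: float = 0.0,
                        extinction: float = PEROXIDASE_EXTINCTION,
                        incubation_h: float = 1.0, soil_mass_g: float = 1.0,
                        assay_volume_ml: float = 1.0) -> tuple[float, set]:
    """Peroxidase activity in umol g-1 h-1 from DOPA absorbances.

    activity = (A_with - A_without - blank difference) / extinction,
    scaled by assay volume and normalized per hour and per g dry soil.
    The peroxide-free tube controls for phenol-oxidase background, so the
    difference isolates H2O2-dependent oxidation.
    """
    if extinction <= 0:
        raise ValueError("extinction coefficient must be positive")
    if incubation_h <= 0 or soil_mass_g <= 0 or assay_volume_ml <= 0:
        raise ValueError("time, mass and volume must be positive")
    flags: set = set()
    delta_a = with_h2o2 - without_h2o2 - blanks
    activity = delta_a / extinction * assay_volume_ml / incubation_h / soil_mass_g
    if activity < 0:
        flags.add("negative_activity")
    return activity, flags


def plfa_concentration(peak_area: float, is_area: float, is_amount_nmol: float,
                       soil_mass_g_om: float) -> float:
    """FAME concentration (nmol g-1 OM) from the 19:0 internal standard:
    peak_area / IS_area * IS_amount / soil_mass."""
    if is_area <= 0:
        raise ValueError("internal-standard peak area must be positive")
    if soil_mass_g_om <= 0:
        raise ValueError("soil mass must be positive")
    if peak_area < 0:
        raise ValueError("peak area must be non-negative")
    return peak_area / is_area * is_amount_nmol / soil_mass_g_om


def plfa_group_sums(profile: pd.DataFrame, is_amount_nmol: float,
                    soil_mass_g_om: float, is_column: str = "19:0") -> pd.DataFrame:
    """Bacterial / fungal / total PLFA sums from a peak-area table.

    ``profile`` has one row per sample, one column per FAME marker (peak
    areas in arbitrary units) including the internal-standard column.
    Returns nmol g-1 OM sums over the standard marker sets plus their
    fungal:bacterial ratio. A missing marker column is a configuration
    error — silent partial sums would be wrong, not approximate.
    """
    needed = set(BACTERIAL_MARKERS) | set(FUNGAL_MARKERS) | {is_column}
    missing = sorted(needed - set(profile.columns))
    if missing:
        raise KeyError(f"PLFA table missing marker column(s): {missing}")
    out = {}
    isa = profile[is_column].astype(float)
    conc = profile.drop(columns=[is_column]).astype(float) \
        .div(isa, axis=0) * is_amount_nmol / soil_mass_g_om
    out["bacterial_plfa"] = conc[list(BACTERIAL_MARKERS)].sum(axis=1)
    out["fungal_plfa"] = conc[list(FUNGAL_MARKERS)].sum(axis=1)
    out["total_plfa"] = conc.sum(axis=1)
    res = pd.DataFrame(out, index=profile.index)
    res["fungal_bacterial_ratio"] = res["fungal_plfa"] / res["bacterial_plfa"]
    return res
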