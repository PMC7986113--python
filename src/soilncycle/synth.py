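"""Synthetic moss-removal / soil-cover / 15N-fertilization experiment.

Generates a complete experiment with known ground truth: a fully crossed
design of four soil-cover types (moss, bare soil, foam, fleece) and two
fertilization levels in six blocks (48 plots), with

* cover-specific soil thermal regimes (30-min logger series: seasonal +
  diurnal sinusoids, AR(1) noise, explicit autumn freeze-thaw episodes);
* a 15N tracer budget per fertilized plot, split between the cover layer
  and the soil by cover-specific sequestration fractions (the remainder is
  an explicit "lost" fraction so mass conservation is testable);
* pool-dilution assays integrated exactly from constant true gross rates;
* raw assay data (dissolved pools, fumigation extracts, enzyme plates,
  PLFA peak areas) built by inverting the corresponding reductions, so a
  noiseless experiment round-trips exactly through the analysis pipeline;
* plot-level responses drawn lognormally around cover x fertilization
  means with additive block effects on the log scale.

Every observable is reproducible from (config, seed). The hidden
parameters are returned as a ``SyntheticTruth`` for use in tests only.

Default parameter values follow the published design where the study
states them (doses, label strength, plot geometry, sequestration
fractions, summer temperature means, the bare:moss amplitude ratio,
per-area gross mineralization); remaining magnitudes are realistic
order-of-magnitude choices documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays as assays_mod
from . import dilution as dilution_mod
from .climate import TemperatureSeries
from .tracer import AppliedTracer

__all__ = [
    "ExperimentConfig",
    "SyntheticTruth",
    "SyntheticExperiment",
    "default_config",
    "null_config",
    "generate_experiment",
    "generate_response_table",
    "generate_temperature_series",
    "generate_dilution_assay",
    "generate_tracer_distribution",
    "rainfall_equivalent_mm",
    "annual_n_load",
]

COVERS = ("moss", "bare", "foam", "fleece")
FERT_LEVELS = ("control", "fertilized")


def rainfall_equivalent_mm(volume_ml: float, area_m2: float) -> float:
    """Depth of water (mm) delivered by a volume over a plot area."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return volume_ml / (area_m2 * 1000.0)


def annual_n_load(doses_g_per_m2) -> float:
    """Total annual N load from the individual doses (g N m-2 yr-1)."""
    return float(sum(doses_g_per_m2))


def _default_thermal() -> dict:
    # summer means from the observed treatment means; bare amplitude twice
    # the moss/foam value; freeze-event counts reproduce the ranking
    # bare >> foam > fleece > moss
    return {
        "moss":   {"summer_mean": 8.7, "winter_mean": 0.3, "amplitude": 1.5,
                   "ar_coeff": 0.8, "noise_sd": 0.3, "freeze_events": 5},
        "bare":   {"summer_mean": 9.1, "winter_mean": 0.3, "amplitude": 3.0,
                   "ar_coeff": 0.8, "noise_sd": 0.3, "freeze_events": 22},
        "foam":   {"summer_mean": 8.7, "winter_mean": 0.3, "amplitude": 1.5,
                   "ar_coeff": 0.8, "noise_sd": 0.3, "freeze_events": 12},
        "fleece": {"summer_mean": 8.9, "winter_mean": 0.3, "amplitude": 1.75,
                   "ar_coeff": 0.8, "noise_sd": 0.3, "freeze_events": 8},
    }


def _default_sequestration() -> dict:
    # fraction of applied N retained in the cover layer and in the soil
    return {
        "moss":   {"cover": 0.89, "soil": 0.04},
        "bare":   {"cover": 0.0, "soil": 0.51},
        "foam":   {"cover": 0.005, "soil": 0.18},
        "fleece": {"cover": 0.002, "soil": 0.24},
    }


def _default_gross_rates() -> dict:
    # ug N g-1 OM d-1; bare-soil gross mineralization of 1.0 corresponds to
    # 0.041 g N m-2 d-1 at the default OM stock of 41 kg m-2
    return {
        "moss":   {"gross_min": 0.76, "gross_cons": 0.60},
        "bare":   {"gross_min": 1.00, "gross_cons": 1.20},
        "foam":   {"gross_min": 0.85, "gross_cons": 0.80},
        "fleece": {"gross_min": 0.85, "gross_cons": 0.80},
    }


def _default_responses() -> dict:
    # natural-scale means per cover with a multiplicative fertilization
    # effect; noise is lognormal so responses stay positive
    def resp(means, fert_mult, block_sd=0.15, resid_sd=0.30):
        return {"cover_means": dict(zip(COVERS, means)),
                "fert_mult": (dict(zip(COVERS, fert_mult))
                              if isinstance(fert_mult, (list, tuple))
                              else {c: fert_mult for c in COVERS}),
                "block_sd": block_sd, "resid_sd": resid_sd}

    return {
        # dissolved pools, ug per g OM
        "nh4": resp([3.0, 15.0, 4.0, 4.0], [1.0, 0.9, 1.5, 1.5]),
        "no3": resp([0.5, 0.6, 0.5, 0.5], [1.0, 5.0, 4.0, 4.0]),
        "don": resp([60.0, 80.0, 55.0, 55.0], [1.0, 0.9, 1.3, 1.3]),
        "doc": resp([600.0, 560.0, 580.0, 580.0], 1.0),
        # fumigation-extraction biomass, ug per g OM
        "biomass_c": resp([8000.0, 8500.0, 7300.0, 7800.0], 1.0,
                          block_sd=0.08, resid_sd=0.12),
        "biomass_n": resp([1380.0, 1510.0, 1190.0, 1320.0], 1.0,
                          block_sd=0.08, resid_sd=0.15),
        # enzyme activities: hydrolytic nmol g-1 h-1, peroxidase umol g-1 h-1
        "chitinase": resp([60.0, 33.0, 50.0, 50.0], 1.0),
        "phosphatase": resp([100.0, 80.0, 90.0, 90.0], 1.0),
        "cellobiosidase": resp([30.0, 20.0, 25.0, 25.0], 1.0),
        "peroxidase": resp([0.5, 1.0, 0.6, 0.6], 1.0),
        # PLFA sums, nmol g-1 OM
        "bacterial_plfa": resp([338.0, 412.0, 193.0, 286.0], [0.8, 0.8, 1.25, 1.05],
                               block_sd=0.10, resid_sd=0.20),
        "fungal_plfa": resp([160.0, 177.0, 148.0, 124.0], 1.0,
                            block_sd=0.10, resid_sd=0.25),
        "other_plfa": resp([481.0, 560.0, 294.0, 375.0], 1.0,
                           block_sd=0.10, resid_sd=0.20),
    }


def _default_compartments() -> dict:
    # per-plot dry masses (g) and N contents (% DW) of the tracer
    # compartments; the artificial materials hold almost no N
    return {
        "soil": {"dry_mass_g": 1600.0, "n_content_pct": 1.35},
        "moss": {"dry_mass_g": 200.0, "n_content_pct": 1.2},
        "foam": {"dry_mass_g": 120.0, "n_content_pct": 0.1},
        "fleece": {"dry_mass_g": 100.0, "n_content_pct": 0.1},
    }


def _default_assay_constants() -> dict:
    return {
        "plate_gain_rfu_per_nmol": 200.0,
        "plate_blank_rfu": 100.0,
        "standard_nmol": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
        "incubation_h": {"chitinase": 4.0, "phosphatase": 3.0,
                         "cellobiosidase": 4.0},
        # 1 g fresh soil / 100 mL buffer, 200 uL per well, 40 % dry matter
        "soil_g_per_well": 0.0008,
        "plate_noise_rel": 0.02,
        "peroxidase_extinction": 7.9,
        "peroxidase_incubation_h": 4.0,
        "peroxidase_soil_mass_g": 0.004,
        "peroxidase_assay_volume_ml": 2.0,
        "kec": 0.45,
        "ken": 0.40,
        "unfumigated_c": 2000.0,
        "unfumigated_n": 300.0,
        "plfa_is_amount_nmol": 25.0,
        "plfa_is_area": 1.0e6,
        "plfa_soil_mass_g_om": 0.5,
    }


@dataclass
class ExperimentConfig:
    """All knobs of the synthetic experiment; serializable to/from YAML."""

    n_blocks: int = 6
    covers: tuple = COVERS
    fert_levels: tuple = FERT_LEVELS
    plot_area_m2: float = 0.25
    n_doses_g_per_m2: tuple = (0.75, 0.75)
    label_atom_percent: float = 10.0
    background_atom_percent: float = 0.3663
    background_deposition_g_m2: float = 0.15
    irrigation_volume_ml: float = 300.0
    bulk_om_g_per_m2: float = 41000.0
    # lognormal scale on per-plot sequestration fractions (field recoveries
    # scatter strongly between plots)
    tracer_noise_sd: float = 0.3
    dilution: dict = field(default_factory=lambda: {
        "a0": 10.0, "ape0": 5.0, "t_days": 20.0 / 24.0, "noise_sd": 0.05})
    sequestration: dict = field(default_factory=_default_sequestration)
    thermal: dict = field(default_factory=_default_thermal)
    gross_rates: dict = field(default_factory=_default_gross_rates)
    responses: dict = field(default_factory=_default_responses)
    compartments: dict = field(default_factory=_default_compartments)
    assay_constants: dict = field(default_factory=_default_assay_constants)
    loggers_per_cover: int = 3
    series_start: str = "2016-09-01"
    series_days: int = 365
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cover, fr in self.sequestration.items():
            s = fr["cover"] + fr["soil"]
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"sequestration fractions for {cover!r} sum to {s}, "
                    "must lie in [0, 1]")
        for spec in self.responses.values():
            if spec["block_sd"] < 0 or spec["resid_sd"] < 0:
                raise ValueError("response SDs must be non-negative")

    @property
    def n_load_g_per_m2(self) -> float:
        return annual_n_load(self.n_doses_g_per_m2)

    def applied_tracer(self) -> AppliedTracer:
        return AppliedTracer(
            n_load_g_per_m2=self.n_load_g_per_m2,
            plot_area_m2=self.plot_area_m2,
            label_atom_percent=self.label_atom_percent,
            background_atom_percent=self.background_atom_percent)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(dataclasses.asdict(self)),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("covers", "fert_levels", "n_doses_g_per_m2"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def default_config(**overrides) -> ExperimentConfig:
    return ExperimentConfig(**overrides)


def null_config(block_sd: float = 0.15, resid_sd: float = 0.30) -> ExperimentConfig:
    """Configuration with no treatment effects: every response has equal
    cover means and no fertilization effect, noise retained."""
    cfg = ExperimentConfig()
    for name, spec in cfg.responses.items():
        base = float(np.mean(list(spec["cover_means"].values())))
        spec["cover_means"] = {c: base for c in cfg.covers}
        spec["fert_mult"] = {c: 1.0 for c in cfg.covers}
        spec["block_sd"] = block_sd
        spec["resid_sd"] = resid_sd
    rates = {c: dict(cfg.gross_rates[cfg.covers[0]]) for c in cfg.covers}
    cfg.gross_rates = rates
    return cfg


@dataclass
class SyntheticTruth:
    """The generator's hidden parameters; test-only recovery targets."""

    response_means: dict          # response -> {(cover, fert): mean}
    gross_rates: dict             # cover -> {gross_min, gross_cons}
    sequestration: dict           # cover -> {cover, soil, lost}
    thermal: dict                 # cover -> regime parameters
    activities: pd.DataFrame      # plot-level true values of every response


@dataclass
class SyntheticExperiment:
    config: ExperimentConfig
    seed: int
    plots: pd.DataFrame           # plot_id, block, cover, fert
    responses: pd.DataFrame       # plot-level noisy response values
    pools_raw: pd.DataFrame       # nh4, no3, tdn, doc per plot
    biomass_raw: pd.DataFrame     # fumigated/unfumigated extracts per plot
    plates: pd.DataFrame          # tidy enzyme plate wells
    plfa_areas: pd.DataFrame      # peak-area table incl. 19:0 IS
    tracer: pd.DataFrame          # compartment atom% table, fertilized plots
    dilution_assays: pd.DataFrame
    temperature: dict             # logger_id -> TemperatureSeries
    spot_temperature: pd.DataFrame
    moisture: pd.DataFrame
    truth: SyntheticTruth

    def write(self, out_dir) -> list[str]:
        """Write all pipeline input tables (CSV) plus truth.json; returns
        the file names written."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(df: pd.DataFrame, name: str):
            df.to_csv(out / name, index=False)
            written.append(name)

        _w(self.plots, "plots.csv")
        _w(self.pools_raw, "pools_raw.csv")
        _w(self.biomass_raw, "biomass_raw.csv")
        _w(self.plates, "plates.csv")
        _w(self.plfa_areas.reset_index(), "plfa_areas.csv")
        _w(self.tracer, "tracer.csv")
        _w(self.dilution_assays, "dilution_assays.csv")
        _w(self.spot_temperature, "spot_temperature.csv")
        _w(self.moisture, "moisture.csv")
        temp_rows = []
        for lid, series in self.temperature.items():
            temp_rows.append(pd.DataFrame({
                "logger_id": lid,
                "cover": lid.split("-")[0],
                "timestamp": series.data.index,
                "temp_c": series.data.to_numpy()}))
        _w(pd.concat(temp_rows, ignore_index=True), "temperature.csv")
        self.config.to_yaml(out / "config.yaml")
        written.append("config.yaml")
        truth = {
            "response_means": {k: {f"{c}|{f}": v for (c, f), v in d.items()}
                               for k, d in self.truth.response_means.items()},
            "gross_rates": self.truth.gross_rates,
            "sequestration": self.truth.sequestration,
            "thermal": self.truth.thermal,
        }
        (out / "truth.json").write_text(json.dumps(_plain(truth), indent=1))
        written.append("truth.json")
        return written


def generate_temperature_series(regime: dict, plot_id: str = "logger",
                                start: str = "2016-09-01", n_days: int = 365,
                                seed: int = 0) -> TemperatureSeries:
    """One 30-min soil temperature series for a cover regime.

    Seasonal mean runs between ``winter_mean`` and ``summer_mean`` (annual
    sinusoid peaking mid-July), a diurnal sinusoid of half-range
    ``amplitude`` (peaking 14:00, scaled down in winter) rides on top, plus
    AR(1) noise. ``freeze_events`` autumn days get an explicit dip below
    -0.5 degC (one freeze-thaw cycle each); with zero events the series is
    floored just above 0 degC, emulating a snowpack-insulated winter.
    """
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start=start, periods=n_days * 48, freq="30min")
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    seasonal01 = 0.5 * (1.0 - np.cos(2 * np.pi * (doy - 196) / 365.25 + np.pi))
    # scale so the configured summer_mean is the Jun-Aug *average*, not the
    # mid-July peak of the seasonal sinusoid
    summer_doys = np.arange(152, 244)
    f_summer = float(np.mean(
        0.5 * (1.0 - np.cos(2 * np.pi * (summer_doys - 196) / 365.25 + np.pi))))
    mean = regime["winter_mean"] + \
        (regime["summer_mean"] - regime["winter_mean"]) / f_summer * seasonal01
    diurnal = regime["amplitude"] * (0.25 + 0.75 * seasonal01) * \
        np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    noise = np.zeros(len(idx))
    if regime["noise_sd"] > 0:
        eps = rng.normal(0.0, regime["noise_sd"] * np.sqrt(1 - regime["ar_coeff"] ** 2),
                         size=len(idx))
        phi = regime["ar_coeff"]
        for i in range(1, len(idx)):
            noise[i] = phi * noise[i - 1] + eps[i]
        noise[0] = eps[0]
    temps = mean + diurnal + noise

    n_events = int(regime.get("freeze_events", 0))
    if n_events == 0:
        temps = np.maximum(temps, 0.05)
    else:
        # event days in the autumn shoulder season (relative day 30..110
        # after the September start)
        lo, hi = 30, min(110, n_days - 1)
        days = rng.choice(np.arange(lo, hi + 1), size=min(n_events, hi - lo + 1),
                          replace=False)
        temps = np.maximum(temps, 0.4)  # positive baseline between events
        day_index = np.arange(len(idx)) // 48
        for d in days:
            sel = day_index == d
            hours = hour[sel]
            # one night-time dip per event day (02:00-10:00 window)
            in_window = (hours >= 2.0) & (hours <= 10.0)
            dip = np.where(in_window,
                           np.sin(np.pi * (hours - 2.0) / 8.0), 0.0)
            base = temps[sel]
            temps[sel] = base - (base + 1.0) * dip
    return TemperatureSeries.from_arrays(plot_id, idx, temps)


def generate_dilution_assay(true_m: float, true_c: float, a0: float,
                            ape0: float, t: float, noise_sd: float,
                            seed: int = 0) -> dilution_mod.DilutionAssay:
    """One pool-dilution assay from constant true rates.

    (At, APEt) come from the exact integral of the constant-rate two-pool
    system; multiplicative lognormal noise of scale ``noise_sd`` is applied
    to both observed quantities.
    """
    if true_m < 0 or true_c < 0:
        raise ValueError("true rates must be non-negative")
    at, apet = dilution_mod.simulate_constant_rate(true_m, true_c, a0, ape0, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        at *= float(np.exp(rng.normal(0.0, noise_sd)))
        apet *= float(np.exp(rng.normal(0.0, noise_sd)))
    return dilution_mod.DilutionAssay(a0=a0, at=at, ape0=ape0, apet=apet, t=t)


def generate_tracer_distribution(config: ExperimentConfig, plot: dict,
                                 rng: np.random.Generator | None = None
                                 ) -> list[dict]:
    """Compartment 15N measurements for one fertilized plot.

    The applied excess 15N is split by the cover's sequestration fractions
    into the cover layer and the soil; each compartment's excess
    concentration is converted back to an atom % 15N given its mass and N
    content — the exact inverse of the recovery mass balance. Lognormal
    noise of scale ``config.tracer_noise_sd`` perturbs the fractions.
    """
    cover = plot["cover"]
    fractions = config.sequestration[cover]
    tracer = config.applied_tracer()
    from .tracer import applied_15n_mg_per_plot
    applied = applied_15n_mg_per_plot(tracer)
    rows = []
    compartments = [("soil", fractions["soil"])]
    if cover != "bare":
        compartments.insert(0, (cover, fractions["cover"]))
    for comp_name, frac in compartments:
        f = frac
        if config.tracer_noise_sd > 0 and rng is not None and f > 0:
            f *= float(np.exp(rng.normal(0.0, config.tracer_noise_sd)))
        geom = config.compartments[comp_name]
        conc = f * applied / geom["dry_mass_g"]          # mg 15N / g DW
        ape = conc * 10.0 / geom["n_content_pct"]        # atom % excess
        rows.append({
            "plot_id": plot["plot_id"],
            "compartment": comp_name,
            "atom_percent_sample": config.background_atom_percent + ape,
            "atom_percent_background": config.background_atom_percent,
            "n_content_pct": geom["n_content_pct"],
            "dry_mass_g": geom["dry_mass_g"],
            "true_fraction": frac,
        })
    return rows


def _draw_responses(config: ExperimentConfig, plots: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Lognormal plot-level responses with additive block effects on the
    log scale; returns the noisy table and the truth means."""
    out = plots.copy()
    means: dict = {}
    for name, spec in config.responses.items():
        block_eff = {b: (rng.normal(0.0, spec["block_sd"])
                         if spec["block_sd"] > 0 else 0.0)
                     for b in range(1, config.n_blocks + 1)}
        vals = []
        means[name] = {}
        for _, row in plots.iterrows():
            mu = spec["cover_means"][row["cover"]]
            if row["fert"] == "fertilized":
                mu = mu * spec["fert_mult"][row["cover"]]
            means[name][(row["cover"], row["fert"])] = mu
            eps = rng.normal(0.0, spec["resid_sd"]) if spec["resid_sd"] > 0 else 0.0
            vals.append(mu * np.exp(block_eff[row["block"]] + eps))
        out[name] = vals
    return out, means


def generate_response_table(config: ExperimentConfig | None = None,
                            seed: int | None = None,
                            responses: list[str] | None = None
                            ) -> tuple[pd.DataFrame, dict]:
    """Plot design plus lognormal plot-level responses only (no raw assay
    or logger data) — the light entry point for simulation studies that
    need many replicate experiments of the response layer.

    Returns (table, truth_means); ``responses`` restricts the drawn
    columns (default: all configured responses).
    """
    config = config or ExperimentConfig()
    if responses is not None:
        config = dataclasses.replace(
            config, responses={k: config.responses[k] for k in responses})
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    plots = pd.DataFrame(
        [{"plot_id": f"B{b}-{c}-{f[0].upper()}", "block": b, "cover": c, "fert": f}
         for b in range(1, config.n_blocks + 1)
         for c in config.covers for f in config.fert_levels])
    return _draw_responses(config, plots, rng)


def generate_experiment(config: ExperimentConfig | None = None,
                        seed: int | None = None) -> SyntheticExperiment:
    """Generate the full synthetic experiment (deterministic in seed)."""
    config = config or ExperimentConfig()
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cons = config.assay_constants

    plots = pd.DataFrame(
        [{"plot_id": f"B{b}-{c}-{f[0].upper()}", "block": b, "cover": c, "fert": f}
         for b in range(1, config.n_blocks + 1)
         for c in config.covers for f in config.fert_levels])

    responses, response_means = _draw_responses(config, plots, rng)

    # --- raw dissolved pools (TDN reconstructed so DON-by-difference holds)
    pools_raw = responses[["plot_id"]].copy()
    pools_raw["nh4"] = responses["nh4"]
    pools_raw["no3"] = responses["no3"]
    pools_raw["tdn"] = responses["nh4"] + responses["no3"] + responses["don"]
    pools_raw["doc"] = responses["doc"]

    # --- fumigation extracts inverted from true biomass
    biomass_raw = responses[["plot_id"]].copy()
    biomass_raw["c_unfumigated"] = cons["unfumigated_c"]
    biomass_raw["c_fumigated"] = cons["unfumigated_c"] + responses["biomass_c"] * cons["kec"]
    biomass_raw["n_unfumigated"] = cons["unfumigated_n"]
    biomass_raw["n_fumigated"] = cons["unfumigated_n"] + responses["biomass_n"] * cons["ken"]

    # --- enzyme plates inverted from true activities
    plate_rows = []
    gain, blank = cons["plate_gain_rfu_per_nmol"], cons["plate_blank_rfu"]
    noise_rel = cons["plate_noise_rel"]
    for _, row in responses.iterrows():
        for enzyme in ("chitinase", "phosphatase", "cellobiosidase"):
            inc_h = cons["incubation_h"][enzyme]
            true_nmol = row[enzyme] * inc_h * cons["soil_g_per_well"]
            for nmol in cons["standard_nmol"]:
                plate_rows.append({"plot_id": row["plot_id"], "enzyme": enzyme,
                                   "role": "standard", "conc_nmol": nmol,
                                   "value": blank + gain * nmol,
                                   "incubation_h": inc_h,
                                   "soil_g_per_well": cons["soil_g_per_well"]})
            for _rep in range(3):
                rfu = blank + gain * true_nmol
                if noise_rel > 0:
                    rfu *= float(np.exp(rng.normal(0.0, noise_rel)))
                plate_rows.append({"plot_id": row["plot_id"], "enzyme": enzyme,
                                   "role": "sample", "conc_nmol": np.nan,
                                   "value": rfu, "incubation_h": inc_h,
                                   "soil_g_per_well": cons["soil_g_per_well"]})
            for _rep in range(4):
                plate_rows.append({"plot_id": row["plot_id"], "enzyme": enzyme,
                                   "role": "blank", "conc_nmol": np.nan,
                                   "value": blank, "incubation_h": inc_h,
                                   "soil_g_per_well": cons["soil_g_per_well"]})
        # peroxidase tubes: absorbance difference inverted from activity
        delta_a = (row["peroxidase"] * cons["peroxidase_extinction"]
                   * cons["peroxidase_incubation_h"] * cons["peroxidase_soil_mass_g"]
                   / cons["peroxidase_assay_volume_ml"])
        base = 0.2
        for role, val in (("with_h2o2", base + delta_a), ("without_h2o2", base),
                          ("blank", 0.0)):
            v = val
            if noise_rel > 0 and role != "blank":
                v *= float(np.exp(rng.normal(0.0, noise_rel)))
            plate_rows.append({"plot_id": row["plot_id"], "enzyme": "peroxidase",
                               "role": role, "conc_nmol": np.nan, "value": v,
                               "incubation_h": cons["peroxidase_incubation_h"],
                               "soil_g_per_well": cons["peroxidase_soil_mass_g"]})
    plates = pd.DataFrame(plate_rows)

    # --- PLFA peak areas inverted from true group sums
    area_per_nmol_g = (cons["plfa_is_area"] / cons["plfa_is_amount_nmol"]
                       * cons["plfa_soil_mass_g_om"])
    plfa_rows = []
    for _, row in responses.iterrows():
        areas = {"plot_id": row["plot_id"], "19:0": cons["plfa_is_area"]}
        per_marker = row["bacterial_plfa"] / len(assays_mod.BACTERIAL_MARKERS)
        for m in assays_mod.BACTERIAL_MARKERS:
            areas[m] = per_marker * area_per_nmol_g
        areas[assays_mod.FUNGAL_MARKERS[0]] = row["fungal_plfa"] * area_per_nmol_g
        areas["16:0"] = row["other_plfa"] * area_per_nmol_g
        plfa_rows.append(areas)
    plfa_areas = pd.DataFrame(plfa_rows).set_index("plot_id")

    # --- tracer distribution for fertilized plots
    tracer_rows = []
    for _, plot in plots[plots["fert"] == "fertilized"].iterrows():
        tracer_rows.extend(generate_tracer_distribution(config, plot.to_dict(), rng))
    tracer = pd.DataFrame(tracer_rows)

    # --- pool-dilution assays
    dil = config.dilution
    assay_rows = []
    for _, plot in plots.iterrows():
        rates = config.gross_rates[plot["cover"]]
        sub = rng.integers(0, 2 ** 31 - 1)
        assay = generate_dilution_assay(rates["gross_min"], rates["gross_cons"],
                                        dil["a0"], dil["ape0"], dil["t_days"],
                                        dil["noise_sd"], seed=int(sub))
        assay_rows.append({"plot_id": plot["plot_id"], "a0": assay.a0,
                           "at": assay.at, "ape0": assay.ape0,
                           "apet": assay.apet, "t_days": assay.t, "unit": "OM"})
    dilution_assays = pd.DataFrame(assay_rows)

    # --- temperature loggers (subset of plots, as in the field campaign)
    temperature = {}
    for cover in config.covers:
        for i in range(config.loggers_per_cover):
            lid = f"{cover}-L{i + 1}"
            sub = rng.integers(0, 2 ** 31 - 1)
            temperature[lid] = generate_temperature_series(
                config.thermal[cover], plot_id=lid, start=config.series_start,
                n_days=config.series_days, seed=int(sub))

    # --- spot measurements: July afternoon temperature and moisture,
    # three visits x three within-plot replicates
    afternoon = {"moss": 11.6, "bare": 14.5, "foam": 11.9, "fleece": 13.0}
    moisture_mean = {"moss": 64.0, "bare": 56.0, "foam": 60.0, "fleece": 56.0}
    spot_rows, moist_rows = [], []
    for _, plot in plots.iterrows():
        for visit in (1, 2, 3):
            for _rep in range(3):
                spot_rows.append({"plot_id": plot["plot_id"], "visit": visit,
                                  "value": afternoon[plot["cover"]]
                                  + rng.normal(0.0, 0.5)})
                moist_rows.append({"plot_id": plot["plot_id"], "visit": visit,
                                   "value": moisture_mean[plot["cover"]]
                                   + rng.normal(0.0, 3.0)})
    spot_temperature = pd.DataFrame(spot_rows)
    moisture = pd.DataFrame(moist_rows)

    truth = SyntheticTruth(
        response_means=response_means,
        gross_rates={c: dict(v) for c, v in config.gross_rates.items()},
        sequestration={c: {"cover": v["cover"], "soil": v["soil"],
                           "lost": 1.0 - v["cover"] - v["soil"]}
                       for c, v in config.sequestration.items()},
        thermal={c: dict(v) for c, v in config.thermal.items()},
        activities=responses.copy(),
    )
    return SyntheticExperiment(
        config=config, seed=seed, plots=plots, responses=responses,
        pools_raw=pools_raw, biomass_raw=biomass_raw, plates=plates,
        plfa_areas=plfa_areas, tracer=tracer, dilution_assays=dilution_assays,
        temperature=temperature, spot_temperature=spot_temperature,
        moisture=moisture, truth=truth)
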