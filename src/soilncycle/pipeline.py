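"""End-to-end orchestration: climate -> assays -> recovery -> dilution -> stats.

Runs the full analysis on a directory of plain-CSV input tables (as written
by :meth:`soilncycle.synth.SyntheticExperiment.write` or assembled from real
measurements), writes every stage's output CSV plus a deterministic
``manifest.json`` (config hash, seed, input/output checksums, per-stage QC
flag counts). Schema violations are reported with file, column and row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays as assays_mod
from . import climate as climate_mod
from . import dilution as dilution_mod
from . import stats as stats_mod
from . import tracer as tracer_mod
from .synth import ExperimentConfig

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "SchemaReport", "validate_inputs", "run_pipeline"]

#: required input files and the columns each must provide
SCHEMAS = {
    "plots.csv": ["plot_id", "block", "cover", "fert"],
    "temperature.csv": ["logger_id", "cover", "timestamp", "temp_c"],
    "pools_raw.csv": ["plot_id", "nh4", "no3", "tdn", "doc"],
    "biomass_raw.csv": ["plot_id", "c_fumigated", "c_unfumigated",
                        "n_fumigated", "n_unfumigated"],
    "plates.csv": ["plot_id", "enzyme", "role", "value", "conc_nmol",
                   "incubation_h", "soil_g_per_well"],
    "plfa_areas.csv": ["plot_id", "19:0"],
    "tracer.csv": ["plot_id", "compartment", "atom_percent_sample",
                   "atom_percent_background", "n_content_pct", "dry_mass_g"],
    "dilution_assays.csv": ["plot_id", "a0", "at", "ape0", "apet", "t_days"],
}

HYDROLYTIC = ("chitinase", "phosphatase", "cellobiosidase")

STATS_RESPONSES = ["nh4", "no3", "don", "doc", "cn_ratio", "biomass_c",
                   "biomass_n", "chitinase", "phosphatase", "cellobiosidase",
                   "peroxidase", "bacterial_plfa", "fungal_plfa", "total_plfa",
                   "gross_min", "gross_cons"]


@dataclass
class SchemaReport:
    passed: dict = field(default_factory=dict)   # file -> True/False
    reasons: dict = field(default_factory=dict)  # file -> message

    @property
    def ok(self) -> bool:
        return all(self.passed.values()) and len(self.passed) > 0


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    inputs: dict        # file -> sha256
    outputs: dict       # file -> sha256
    qc_flags: dict      # stage -> {flag: count}

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(input_dir) -> SchemaReport:
    """Per-file schema check: presence, parseability, required columns."""
    input_dir = Path(input_dir)
    report = SchemaReport()
    for name, cols in SCHEMAS.items():
        path = input_dir / name
        if not path.exists():
            report.passed[name] = False
            report.reasons[name] = "missing file"
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            report.passed[name] = False
            report.reasons[name] = f"unreadable: {exc}"
            continue
        if df.empty:
            report.passed[name] = False
            report.reasons[name] = "empty file"
            continue
        missing = [c for c in cols if c not in df.columns]
        if missing:
            report.passed[name] = False
            report.reasons[name] = f"missing column(s) {missing}"
        else:
            report.passed[name] = True
            report.reasons[name] = "ok"
    return report


def _count_flags(series: pd.Series) -> dict:
    counts: dict = {}
    for entry in series.dropna():
        for flag in str(entry).split(";"):
            if flag:
                counts[flag] = counts.get(flag, 0) + 1
    return counts


def _stage_climate(input_dir: Path, out_dir: Path, threshold: float) -> dict:
    df = pd.read_csv(input_dir / "temperature.csv", parse_dates=["timestamp"])
    rows = []
    for (lid, cover), sub in df.groupby(["logger_id", "cover"]):
        series = climate_mod.TemperatureSeries.from_arrays(
            str(lid), sub["timestamp"], sub["temp_c"])
        s = climate_mod.climate_summary(series, threshold=threshold)
        rows.append({"logger_id": lid, "cover": cover,
                     "summer_mean": s.summer_mean,
                     "afternoon_mean_july": s.afternoon_mean,
                     "freeze_thaw_raw": s.freeze_thaw_raw,
                     "freeze_thaw_thresholded": s.freeze_thaw_thresholded})
        for month, val in s.monthly_mean.items():
            amp = s.monthly_amplitude.get(month)
            rows[-1][f"mean_{month}"] = val
            if amp is not None:
                rows[-1][f"amp_{month}"] = amp
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "climate_summary.csv", index=False)

    # tidy monthly means for the repeated-measures stage
    monthly = []
    for (lid, cover), sub in df.groupby(["logger_id", "cover"]):
        s = pd.Series(sub["temp_c"].to_numpy(),
                      index=pd.DatetimeIndex(sub["timestamp"]))
        for (yr, mo), m in s.groupby([s.index.year, s.index.month]).mean().items():
            monthly.append({"plot_id": lid, "cover": cover, "year": yr,
                            "month": mo, "value": m})
    pd.DataFrame(monthly).to_csv(out_dir / "climate_monthly.csv", index=False)
    return {}


def _stage_assays(input_dir: Path, out_dir: Path) -> tuple[pd.DataFrame, dict]:
    qc: dict = {}
    pools_raw = pd.read_csv(input_dir / "pools_raw.csv")
    pool_rows = []
    for _, r in pools_raw.iterrows():
        p = assays_mod.derive_dissolved_pools(r["nh4"], r["no3"], r["tdn"], r["doc"])
        pool_rows.append({"plot_id": r["plot_id"], "nh4": p.nh4, "no3": p.no3,
                          "tdn": p.tdn, "doc": p.doc, "don": p.don,
                          "cn_ratio": p.cn_ratio,
                          "qc_flags": ";".join(sorted(p.qc_flags))})
    pools = pd.DataFrame(pool_rows)
    pools.to_csv(out_dir / "pools.csv", index=False)
    qc.update(_count_flags(pools["qc_flags"]))

    bio_raw = pd.read_csv(input_dir / "biomass_raw.csv")
    bio_rows = []
    for _, r in bio_raw.iterrows():
        ext = assays_mod.BiomassExtract(
            c_fumigated=r["c_fumigated"], c_unfumigated=r["c_unfumigated"],
            n_fumigated=r["n_fumigated"], n_unfumigated=r["n_unfumigated"])
        bc, bn, cn, flags = assays_mod.microbial_biomass(ext)
        bio_rows.append({"plot_id": r["plot_id"], "biomass_c": bc,
                         "biomass_n": bn, "biomass_cn": cn,
                         "qc_flags": ";".join(sorted(flags))})
    biomass = pd.DataFrame(bio_rows)
    biomass.to_csv(out_dir / "biomass.csv", index=False)
    qc.update(_count_flags(biomass["qc_flags"]))

    plates = pd.read_csv(input_dir / "plates.csv")
    act_rows = []
    for (pid, enzyme), sub in plates.groupby(["plot_id", "enzyme"]):
        if enzyme in HYDROLYTIC:
            std = sub[sub["role"] == "standard"]
            plate = assays_mod.EnzymePlate(
                sample_rfu=sub.loc[sub["role"] == "sample", "value"].tolist(),
                standard_nmol=std["conc_nmol"].tolist(),
                standard_rfu=std["value"].tolist(),
                blank_rfu=sub.loc[sub["role"] == "blank", "value"].tolist(),
                incubation_h=float(sub["incubation_h"].iloc[0]),
                soil_g_per_well=float(sub["soil_g_per_well"].iloc[0]))
            activity, flags = assays_mod.hydrolytic_activity(plate)
        elif enzyme == "peroxidase":
            with_p = float(sub.loc[sub["role"] == "with_h2o2", "value"].mean())
            without = float(sub.loc[sub["role"] == "without_h2o2", "value"].mean())
            blank = float(sub.loc[sub["role"] == "blank", "value"].mean())
            activity, flags = assays_mod.peroxidase_activity(
                with_p, without, blanks=blank,
                incubation_h=float(sub["incubation_h"].iloc[0]),
                soil_mass_g=float(sub["soil_g_per_well"].iloc[0]),
                assay_volume_ml=2.0)
        else:
            raise ValueError(f"plates.csv: unknown enzyme {enzyme!r}")
        act_rows.append({"plot_id": pid, "enzyme": enzyme, "activity": activity,
                         "qc_flags": ";".join(sorted(flags))})
    activities = pd.DataFrame(act_rows)
    activities.to_csv(out_dir / "activities.csv", index=False)
    qc.update(_count_flags(activities["qc_flags"]))
    act_wide = activities.pivot(index="plot_id", columns="enzyme",
                                values="activity").reset_index()

    plfa_raw = pd.read_csv(input_dir / "plfa_areas.csv").set_index("plot_id")
    plfa = assays_mod.plfa_group_sums(plfa_raw, is_amount_nmol=25.0,
                                      soil_mass_g_om=0.5)
    plfa.reset_index().to_csv(out_dir / "plfa.csv", index=False)

    merged = pools.drop(columns="qc_flags") \
        .merge(biomass[["plot_id", "biomass_c", "biomass_n", "biomass_cn"]],
               on="plot_id") \
        .merge(act_wide, on="plot_id") \
        .merge(plfa.reset_index()[["plot_id", "bacterial_plfa", "fungal_plfa",
                                   "total_plfa"]], on="plot_id")
    return merged, qc


def _stage_recovery(input_dir: Path, out_dir: Path,
                    tracer_cfg: tracer_mod.AppliedTracer) -> dict:
    samples = pd.read_csv(input_dir / "tracer.csv")
    table = tracer_mod.recovery_table(samples, tracer_cfg)
    table.to_csv(out_dir / "recovery.csv", index=False)
    # treatment summary mirroring the published recovery rows
    merged = table.merge(samples[["plot_id", "compartment"]].drop_duplicates(),
                         on=["plot_id", "compartment"])
    merged["cover"] = merged["plot_id"].str.split("-").str[1]
    summary = merged.groupby(["cover", "compartment"])["recovery_pct"] \
        .agg(["mean", "sem", "count"]).reset_index()
    summary.to_csv(out_dir / "recovery_summary.csv", index=False)
    return _count_flags(table["qc_flags"])


def _stage_dilution(input_dir: Path, out_dir: Path) -> tuple[pd.DataFrame, dict]:
    assays = pd.read_csv(input_dir / "dilution_assays.csv")
    rates = dilution_mod.rates_table(assays)
    rates.to_csv(out_dir / "gross_rates.csv", index=False)
    return rates, _count_flags(rates["qc_flags"])


def _stage_stats(responses: pd.DataFrame, out_dir: Path, alpha: float = 0.05
                 ) -> dict:
    qc: dict = {}
    results = {}
    letters_rows = []
    for resp in STATS_RESPONSES:
        if resp not in responses.columns:
            continue
        vals = responses[resp].dropna()
        log = bool((vals > 0).all())  # log-transform positive responses
        if not log:
            qc[f"untransformed:{resp}"] = 1
        res = stats_mod.fit_cover_fert_model(responses, resp, log_transform=log)
        results[resp] = res
        letters = stats_mod.tukey_letters(res, "cover", alpha=alpha)
        for level, letter in letters.letters.items():
            letters_rows.append({"response": resp, "cover": level,
                                 "emm": letters.means[level], "letters": letter})
    anova = stats_mod.build_anova_table(results)
    anova.to_csv(out_dir / "anova_table.csv")
    pd.DataFrame(letters_rows).to_csv(out_dir / "posthoc_letters.csv", index=False)

    variables = [r for r in STATS_RESPONSES if r in responses.columns]
    rho, pvals, flags = stats_mod.spearman_matrix(responses, variables)
    rho.to_csv(out_dir / "correlations.csv")
    pvals.to_csv(out_dir / "correlations_p.csv")
    for f in flags:
        qc[f] = 1
    return qc


def run_pipeline(input_dir, out_dir, config: ExperimentConfig | None = None,
                 seed: int | None = None, freeze_threshold: float = 0.1,
                 alpha: float = 0.05) -> RunManifest:
    """Run every stage on an input directory; returns the run manifest.

    ``config`` supplies the tracer/application parameters (defaults match
    the published design); a ``config.yaml`` in the input directory is
    used when present. Raises on schema violations or hard stage errors.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(input_dir)
    if not report.ok:
        bad = {k: v for k, v in report.reasons.items() if not report.passed[k]}
        raise ValueError(f"input validation failed: {bad}")
    if config is None:
        cfg_path = input_dir / "config.yaml"
        config = (ExperimentConfig.from_yaml(cfg_path) if cfg_path.exists()
                  else ExperimentConfig())

    qc_all: dict = {}
    logger.info("stage climate")
    qc_all["climate"] = _stage_climate(input_dir, out_dir, freeze_threshold)
    logger.info("stage assays")
    merged, qc_all["assays"] = _stage_assays(input_dir, out_dir)
    logger.info("stage recovery")
    qc_all["recovery"] = _stage_recovery(input_dir, out_dir, config.applied_tracer())
    logger.info("stage dilution")
    rates, qc_all["dilution"] = _stage_dilution(input_dir, out_dir)

    plots = pd.read_csv(input_dir / "plots.csv")
    responses = plots.merge(merged, on="plot_id") \
        .merge(rates[["plot_id", "gross_min", "gross_cons"]], on="plot_id")
    responses.to_csv(out_dir / "responses.csv", index=False)
    logger.info("stage stats")
    qc_all["stats"] = _stage_stats(responses, out_dir, alpha=alpha)

    for stage, flags in qc_all.items():
        if flags:
            logger.warning("QC flags in stage %s: %s", stage, flags)

    config_hash = hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        seed=seed,
        inputs={p.name: _sha256(p) for p in sorted(input_dir.glob("*.csv"))},
        outputs={p.name: _sha256(p)
                 for p in sorted(out_dir.glob("*.csv"))},
        qc_flags=qc_all)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _config_dict(config: ExperimentConfig) -> dict:
    import dataclasses

    def plain(o):
        if isinstance(o, dict):
            return {str(k): plain(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [plain(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    return plain(dataclasses.asdict(config))
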