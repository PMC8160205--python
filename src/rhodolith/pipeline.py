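"""End-to-end pipeline: read a study directory, run every applicable stage.

The input directory may contain any subset of the four input kinds
(``profiles/*.csv``, ``titrations/*.csv``, ``incubations.csv``,
``volumes/*.tif``). Each present kind is processed into tidy result tables;
per-file parse errors are collected and reported without stopping the run.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import stats as rstats
from .carbonate import gran_alkalinity
from .incubation import Photoperiod, rates_from_records, rates_dataframe, summarize_rates, oa_comparison
from .morphology import measure, median_filter, segment, unsharp_mask
from .profiles import (DEFAULT_D_O2, average_profiles, delta_ph, estimate_bulk,
                       estimate_dbl, fick_flux)
from .synthetic import PRESETS


@dataclass
class PipelineConfig:
    """Run-wide defaults; every value is overridable per run."""

    salinity: float = 35.0
    ph_scale_offset: float = 0.0
    diffusion_coefficient: float = DEFAULT_D_O2
    photoperiod: Photoperiod = field(default_factory=Photoperiod)
    fit_window_um: float = 100.0
    gran_ph_window: tuple[float, float] = (3.0, 3.5)
    alpha: float = 0.05
    seed: int = 0
    k1k2: str = "dm87"
    median_radius: int = 1
    unsharp_sigma: float = 1.0
    unsharp_amount: float = 0.5
    fill_holes: bool = False
    #: species -> protuberance length (mm), for the DBL-vs-length regression
    protuberance_lengths: dict = field(
        default_factory=lambda: {k: v.protuberance_length for k, v in PRESETS.items()})

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat ``key: value`` config file; unknown keys rejected."""
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition(":")
                key = key.strip()
                value = value.strip()
                if key == "photoperiod":
                    h_l, h_d = (float(x) for x in value.split("/"))
                    kwargs[key] = Photoperiod(h_l, h_d)
                elif key == "gran_ph_window":
                    lo, hi = (float(x) for x in value.split(","))
                    kwargs[key] = (lo, hi)
                elif key in ("seed", "median_radius"):
                    kwargs[key] = int(value)
                elif key == "fill_holes":
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif key == "k1k2":
                    kwargs[key] = value
                elif key == "protuberance_lengths":
                    kwargs[key] = json.loads(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """Everything a run produced, plus per-file errors."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    n_inputs: int = 0

    @property
    def ok(self) -> bool:
        return self.n_inputs > 0


def run_pipeline(config: PipelineConfig, input_dir, output_dir=None) -> PipelineReport:
    """Run every stage for which inputs exist; optionally write result CSVs."""
    input_dir = Path(input_dir)
    report = PipelineReport()

    profile_files = sorted((input_dir / "profiles").glob("*.csv")) \
        if (input_dir / "profiles").is_dir() else []
    titration_files = sorted((input_dir / "titrations").glob("*.csv")) \
        if (input_dir / "titrations").is_dir() else []
    incubation_file = input_dir / "incubations.csv"
    volume_files = sorted((input_dir / "volumes").glob("*.tif")) \
        if (input_dir / "volumes").is_dir() else []

    if profile_files:
        _run_profiles(config, profile_files, report)
    if titration_files:
        _run_titrations(config, titration_files, report)
    if incubation_file.is_file():
        _run_incubations(config, incubation_file, report)
    if volume_files:
        _run_volumes(config, volume_files, report)

    report.n_inputs = (len(profile_files) + len(titration_files)
                       + int(incubation_file.is_file()) + len(volume_files))
    if output_dir is not None:
        _write_report(report, config, output_dir)
    return report


def _run_profiles(config, files, report):
    spots = defaultdict(list)
    for path in files:
        try:
            profile, meta = rio.read_profile_csv(path)
        except Exception as exc:           # per-file failures never stop a run
            report.errors.append(f"{path.name}: {exc}")
            continue
        key = (profile.species_id, meta.get("individual", "0"),
               meta.get("spot", "0"), profile.location, profile.condition,
               profile.analyte)
        spots[key].append((profile, meta))

    dbl_rows, dph_rows = [], []
    for key, entries in sorted(spots.items()):
        species, individual, spot, location, condition, analyte = key
        try:
            prof = average_profiles([p for p, _ in entries])
            meta = entries[0][1]
            bulk = float(meta["bulk"]) if "bulk" in meta else None
            if analyte == "oxygen":
                be = estimate_bulk(prof)
                bulk_val = bulk if bulk is not None else be.value
                dbl = estimate_dbl(prof, bulk=bulk_val,
                                   fit_window_um=config.fit_window_um)
                flux = fick_flux(dbl, D=config.diffusion_coefficient)
                dbl_rows.append({
                    "species": species, "individual": individual, "spot": spot,
                    "location": location, "condition": condition,
                    "dbl_thickness_um": dbl.thickness,
                    "surface_o2_umol_L": dbl.surface_value,
                    "bulk_o2_umol_L": dbl.bulk_value,
                    "flux_umol_cm2_h": flux.flux,
                    "flux_magnitude_umol_cm2_h": flux.magnitude,
                    "direction": flux.direction,
                    "fit_r2": dbl.fit_r2, "n_fit": dbl.n_fit,
                    "outer_stationary": be.stationary,
                })
            else:
                bulk_ph = bulk if bulk is not None else estimate_bulk(prof).value
                dp = delta_ph(prof, bulk_ph)
                dph_rows.append({
                    "species": species, "individual": individual, "spot": spot,
                    "location": location, "condition": condition,
                    "ph_surface": dp.ph_surface, "ph_bulk": dp.ph_bulk,
                    "delta_ph": dp.delta_ph,
                })
        except Exception as exc:
            report.errors.append(f"profile spot {key}: {exc}")

    if dbl_rows:
        dbl_df = pd.DataFrame(dbl_rows)
        report.tables["dbl_flux"] = dbl_df
        base_light = dbl_df[(dbl_df.location == "base") & (dbl_df.condition == "light")]
        lengths = config.protuberance_lengths
        known = base_light[base_light.species.isin(lengths)]
        per_ind = known.groupby(["species", "individual"])["dbl_thickness_um"].mean()
        if per_ind.index.get_level_values("species").nunique() >= 3:
            x = np.array([lengths[s] for s, _ in per_ind.index])
            reg = rstats.linear_regression(x, per_ind.to_numpy())
            report.stats["dbl_vs_length"] = reg
    if dph_rows:
        dph_df = pd.DataFrame(dph_rows)
        report.tables["delta_ph"] = dph_df
        piv = (dph_df.groupby(["species", "location", "condition"])["delta_ph"]
               .mean().unstack("condition"))
        if {"light", "dark"} <= set(piv.columns):
            piv["diel_range"] = piv["light"] - piv["dark"]
        report.tables["delta_ph_summary"] = piv.reset_index()


def _run_titrations(config, files, report):
    rows = []
    for path in files:
        try:
            curve, meta = rio.read_titration_csv(path)
            res = gran_alkalinity(curve, ph_window=config.gran_ph_window)
            rows.append({
                "file": path.name,
                "species": meta.get("species", ""),
                "treatment": meta.get("treatment", ""),
                "phase": meta.get("phase", ""),
                "replicate": meta.get("replicate", ""),
                "endpoint": meta.get("endpoint", ""),
                "tube": meta.get("tube", ""),
                "at_umol_kg": res.at, "v_eq_ml": res.v_eq,
                "gran_fit_r2": res.gran_fit_r2, "n_used": res.n_used,
            })
        except Exception as exc:
            report.errors.append(f"{path.name}: {exc}")
    if rows:
        df = pd.DataFrame(rows)
        report.tables["alkalinity"] = df
        sample_cols = [c for c in ("species", "treatment", "phase", "replicate",
                                   "endpoint") if df[c].astype(str).str.len().gt(0).any()]
        if sample_cols:
            report.tables["alkalinity_means"] = (
                df.groupby(sample_cols)["at_umol_kg"]
                .agg(["mean", "std", "count"]).reset_index())


def _run_incubations(config, path, report):
    try:
        records = rio.read_incubations_csv(path)
    except Exception as exc:
        report.errors.append(f"{path.name}: {exc}")
        return
    try:
        rate_sets = rates_from_records(records, pp=config.photoperiod)
    except Exception as exc:
        report.errors.append(f"incubation rates: {exc}")
        return
    report.tables["rates"] = rates_dataframe(rate_sets)
    report.tables["rates_summary"] = summarize_rates(rate_sets)
    ambient = [r for r in rate_sets if r.treatment == "ambient"]
    species = sorted({r.species_id for r in ambient})
    if len(species) >= 2 and all(
            sum(r.species_id == s for r in ambient) >= 2 for s in species):
        species_stats = {}
        for resp in ("p_max_gross", "dark_respiration", "g_light", "g_dark",
                     "g_net_daily"):
            groups = [np.array([getattr(r, resp) for r in ambient
                                if r.species_id == s]) for s in species]
            an = rstats.one_way_anova(groups)
            letters = rstats.newman_keuls(groups, alpha=config.alpha)
            species_stats[resp] = {
                "anova": an, "letters": dict(zip(species, letters)),
            }
        report.stats["species_anova"] = species_stats
    treatments = {r.treatment for r in rate_sets}
    if treatments == {"ambient", "low_ph"} and len(species) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.stats["oa_comparison"] = oa_comparison(rate_sets,
                                                          alpha=config.alpha)


def _run_volumes(config, files, report):
    rows = []
    for path in files:
        try:
            vol = rio.read_volume_tiff(path)
            filtered = median_filter(vol, radius=config.median_radius)
            sharp = unsharp_mask(filtered, sigma=config.unsharp_sigma,
                                 amount=config.unsharp_amount)
            mask = segment(sharp, method="otsu", fill_holes=config.fill_holes)
            metrics = measure(mask)
            species = path.stem.rsplit("_rep", 1)[0]
            rows.append({
                "file": path.name, "species": species,
                "surface_area_mm2": metrics.surface_area,
                "volume_mm3": metrics.volume, "sa_v_mm_1": metrics.sa_v,
            })
        except Exception as exc:
            report.errors.append(f"{path.name}: {exc}")
    if rows:
        df = pd.DataFrame(rows)
        report.tables["morphometrics"] = df
        by_sp = df.groupby("species")["sa_v_mm_1"]
        if df["species"].nunique() >= 2 and (by_sp.count() >= 2).all():
            groups = [g.to_numpy() for _, g in by_sp]
            report.stats["sa_v_anova"] = {
                "anova": rstats.one_way_anova(groups),
                "letters": dict(zip(by_sp.groups.keys(),
                                    rstats.newman_keuls(groups, alpha=config.alpha))),
            }


def _write_report(report: PipelineReport, config: PipelineConfig, output_dir):
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    summary = {"config": _config_dict(config), "errors": report.errors,
               "stats": _stats_dict(report.stats)}
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)


def _config_dict(config):
    d = asdict(config)
    d["photoperiod"] = [config.photoperiod.h_light, config.photoperiod.h_dark]
    return d


def _stats_dict(stats):
    def conv(obj):
        if isinstance(obj, rstats.AnovaResult):
            return [asdict(t) for t in obj.terms]
        if isinstance(obj, rstats.RegressionResult):
            return {"slope": obj.slope, "intercept": obj.intercept,
                    "r2": obj.r2, "p": obj.p_value}
        if isinstance(obj, rstats.PosthocLetters):
            return list(obj.group_labels)
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        return obj
    return conv(stats)
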