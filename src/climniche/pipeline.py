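"""End-to-end pipeline orchestration.

Stages run in fixed order: simulate (or load) inputs -> occurrence QC
-> ensemble fitting -> scenario projection -> range-change accounting
-> jurisdiction summaries.  A run manifest records package and library
versions, every seed and threshold, and per-stage record counts;
rerunning with the same config reproduces identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .change import classify_change, compare_ranges, export_table, richness, richness_change
from .grid import SCENARIOS, ClimateGrid
from .jurisdiction import elevation_shift, state_presence, state_turnover
from .models import ClimateNicheModel, NotEnsembleableError, count_model_runs
from .qc import run_qc
from .synthetic import (
    GridConfig,
    JurisdictionSet,
    generate_climate_grids,
    generate_jurisdictions,
    make_virtual_species,
    sample_occurrences,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; absent values use the defaults
    below, which are all recorded in the emitted run manifest."""

    output_dir: str = "climniche_run"
    seed: int = 0

    # -- synthetic inputs (simulate=True) or external paths
    simulate: bool = True
    n_species: int = 3
    n_occurrences: int = 400
    n_jurisdictions: int = 9
    prevalence: float = 0.15
    artifact_rates: dict = field(
        default_factory=lambda: {
            "duplicate": 0.05,
            "missing_year": 0.03,
            "centroid_snap": 0.03,
            "far_outlier": 0.02,
        }
    )
    grid: GridConfig = field(default_factory=GridConfig)
    occurrences_csv: str | None = None
    climate_dir: str | None = None
    jurisdictions_geojson: str | None = None

    # -- QC thresholds
    year_window: tuple[int, int] = (1981, 2018)
    max_range_km: float = 200.0
    max_centroid_m: float = 300.0
    min_points: int = 50

    # -- modelling
    techniques: tuple[str, ...] = ("GLM", "RF", "SRE")
    n_pseudo_absences: int = 2000
    pa_replicates: int = 2
    holdout: float = 0.30
    split_repeats: int = 2
    tss_cutoff: float = 0.7
    min_members: int = 3
    sre_quantile: float = 0.025

    # -- change classification
    net_thresh: float = 10.0
    turnover_thresh: float = 50.0
    centroid_thresh_km: float = 100.0
    scenario_pair: tuple[str, str] = ("recent", "late85")
    min_state_pixels: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grid_raw = raw.pop("grid", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in _FIELD_NAMES})
        if grid_raw:
            cfg.grid = GridConfig(**grid_raw)
        if isinstance(cfg.techniques, list):
            cfg.techniques = tuple(cfg.techniques)
        if isinstance(cfg.year_window, list):
            cfg.year_window = tuple(cfg.year_window)
        if isinstance(cfg.scenario_pair, list):
            cfg.scenario_pair = tuple(cfg.scenario_pair)
        return cfg

    def manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.grid).items()
            if k != "scenarios"
        }
        d["grid"]["scenarios"] = {
            sid: [s.temp_offset, s.prec_multiplier]
            for sid, s in self.grid.scenarios.items()
        }
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def _versions() -> dict:
    out = {}
    for pkg in ("climniche", "numpy", "scipy", "pandas", "scikit-learn", "shapely"):
        try:
            out[pkg] = importlib.metadata.version(pkg)
        except importlib.metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the pipeline and write all outputs under ``config.output_dir``.

    Returns a dict with the manifest and the main result frames.
    ``stages`` limits execution to a prefix of (simulate, qc, fit,
    project, change, states); later stages pull in the earlier ones
    they depend on.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = ("simulate", "qc", "fit", "project", "change", "states")
    if stages is None:
        stages = all_stages
    last = max(all_stages.index(s) for s in stages)
    manifest = {
        "config": config.manifest_dict(),
        "versions": _versions(),
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    # ---------------- inputs ----------------
    if config.simulate:
        grids = generate_climate_grids(config.grid, seed=config.seed)
        jset = generate_jurisdictions(
            grids["recent"], config.n_jurisdictions, seed=config.seed + 1
        )
        rng = np.random.default_rng(config.seed + 2)
        species = []
        tables = []
        for i in range(config.n_species):
            sp = make_virtual_species(
                grids["recent"],
                species_id=f"virtualis_{i:02d}",
                variables=("tmean_01", "prec_06"),
                optimum_quantiles=(rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)),
                prevalence_target=config.prevalence,
                seed=config.seed + 10 + i,
            )
            species.append(sp)
            tables.append(
                sample_occurrences(
                    sp,
                    grids["recent"],
                    n=config.n_occurrences,
                    artifact_rates=config.artifact_rates,
                    seed=config.seed + 100 + i,
                    jurisdictions=jset,
                )
            )
        occurrences = pd.concat(tables, ignore_index=True)
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        cio.write_occurrences(inputs_dir / "occurrences.csv", occurrences)
        cio.write_jurisdictions(inputs_dir / "jurisdictions.geojson", jset)
        for g in grids.values():
            cio.write_climate_grid(inputs_dir / "climate", g)
        results["species"] = species
    else:
        if not (
            config.occurrences_csv and config.climate_dir and config.jurisdictions_geojson
        ):
            raise FileNotFoundError(
                "simulate=False requires occurrences_csv, climate_dir and "
                "jurisdictions_geojson paths"
            )
        for p in (
            config.occurrences_csv,
            config.climate_dir,
            config.jurisdictions_geojson,
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
        grids = {
            sid: cio.read_climate_grid(config.climate_dir, sid)
            for sid in SCENARIOS
            if (Path(config.climate_dir) / sid).exists()
        }
        occurrences = cio.read_occurrences(config.occurrences_csv)
        jset = cio.read_jurisdictions(config.jurisdictions_geojson, grids["recent"])

    results["grids"] = grids
    results["jurisdictions"] = jset
    results["occurrences"] = occurrences
    manifest["stages"]["simulate"] = {"n_records": int(len(occurrences))}
    if last < 1:
        _write_manifest(out, manifest)
        return results

    # ---------------- qc ----------------
    recent = grids["recent"]
    kept, report = run_qc(
        occurrences,
        recent,
        centroids=jset.centroids,
        year_window=config.year_window,
        max_range_km=config.max_range_km,
        max_centroid_m=config.max_centroid_m,
        min_points=config.min_points,
    )
    report_frame = report.to_frame()
    report_frame.to_csv(out / "qc_report.csv")
    kept.to_csv(out / "occurrences_qc.csv", index=False)
    modelable = sorted(report.modelable[report.modelable].index)
    results["qc_table"] = kept
    results["qc_report"] = report_frame
    results["modelable"] = modelable
    manifest["stages"]["qc"] = {
        "input": int(len(occurrences)),
        "retained": int(len(kept)),
        "modelable_species": modelable,
    }
    if last < 2:
        _write_manifest(out, manifest)
        return results

    # ---------------- fit ----------------
    fitted = {}
    eval_rows = []
    imp_rows = []
    for i, sp in enumerate(modelable):
        model = ClimateNicheModel.from_dataframe(
            kept,
            recent,
            species=sp,
            techniques=config.techniques,
            n_pseudo_absences=config.n_pseudo_absences,
            pa_replicates=config.pa_replicates,
            holdout=config.holdout,
            split_repeats=config.split_repeats,
            tss_cutoff=config.tss_cutoff,
            min_members=config.min_members,
            sre_quantile=config.sre_quantile,
        )
        try:
            res = model.fit(seed=config.seed + 1000 + i)
        except NotEnsembleableError:
            manifest["stages"].setdefault("fit", {}).setdefault(
                "non_ensembleable", []
            ).append(sp)
            continue
        fitted[sp] = res
        f = res.fits_frame()
        f.insert(0, "species", sp)
        eval_rows.append(f)
        imp = res.variable_importance.rename("importance").to_frame()
        imp.insert(0, "species", sp)
        imp_rows.append(imp)
    pd.concat(eval_rows).to_csv(out / "model_eval.csv", index=False)
    pd.concat(imp_rows).to_csv(out / "variable_importance.csv")
    results["fitted"] = fitted
    manifest["stages"].setdefault("fit", {})
    manifest["stages"]["fit"].update(
        {
            "n_species_fitted": len(fitted),
            "single_models_per_species": len(config.techniques)
            * config.pa_replicates
            * config.split_repeats,
            "total_model_runs": count_model_runs(
                len(fitted),
                n_techniques=len(config.techniques),
                pa_replicates=config.pa_replicates,
                split_repeats=config.split_repeats,
            ),
        }
    )
    if last < 3:
        _write_manifest(out, manifest)
        return results

    # ---------------- project ----------------
    binary_maps: dict[str, dict[str, object]] = {}
    size_rows = []
    for sp, res in fitted.items():
        binary_maps[sp] = {}
        for sid, g in grids.items():
            bmap = res.binary_map(g)
            binary_maps[sp][sid] = bmap
            size_rows.append(
                {
                    "species": sp,
                    "scenario": sid,
                    "threshold": res.threshold,
                    "range_size": bmap.range_size,
                }
            )
    pd.DataFrame(size_rows).to_csv(out / "range_sizes.csv", index=False)
    results["binary_maps"] = binary_maps
    manifest["stages"]["project"] = {"n_maps": len(size_rows)}
    if last < 4:
        _write_manifest(out, manifest)
        return results

    # ---------------- change ----------------
    s_from, s_to = config.scenario_pair
    summaries = []
    class_rows = []
    for sp in sorted(binary_maps):
        summ = compare_ranges(binary_maps[sp][s_from], binary_maps[sp][s_to])
        summaries.append(summ)
        class_rows.append(
            {
                "species": sp,
                "class": classify_change(
                    summ,
                    net_thresh=config.net_thresh,
                    turnover_thresh=config.turnover_thresh,
                    centroid_thresh_km=config.centroid_thresh_km,
                ),
                "shift_km": summ.shift_km,
                "bearing_deg": summ.shift_bearing_deg,
            }
        )
    table = export_table(summaries).merge(pd.DataFrame(class_rows), on="species")
    table.to_csv(out / "range_change.csv", index=False)
    results["range_change"] = table
    results["summaries"] = summaries

    for sid in (s_from, s_to):
        rich = richness([binary_maps[sp][sid] for sp in sorted(binary_maps)])
        cio.write_ascii_grid(
            out / f"richness_{sid}.asc", rich.values, recent.cell_size, recent.origin
        )
    for mode in ("full", "none"):
        delta = richness_change(
            [binary_maps[sp][s_from] for sp in sorted(binary_maps)],
            [binary_maps[sp][s_to] for sp in sorted(binary_maps)],
            dispersal=mode,
        )
        cio.write_ascii_grid(
            out / f"richness_change_{mode}.asc", delta, recent.cell_size, recent.origin
        )
    manifest["stages"]["change"] = {"n_species": len(summaries)}
    if last < 5:
        _write_manifest(out, manifest)
        return results

    # ---------------- states ----------------
    pres_frames = {s_from: [], s_to: []}
    for sp in sorted(binary_maps):
        for sid in (s_from, s_to):
            pres_frames[sid].append(
                state_presence(binary_maps[sp][sid], jset, config.min_state_pixels)
            )
    presence = pd.concat(pres_frames[s_from] + pres_frames[s_to], ignore_index=True)
    presence.to_csv(out / "state_presence.csv", index=False)
    turnover = state_turnover(
        pd.concat(pres_frames[s_from], ignore_index=True),
        pd.concat(pres_frames[s_to], ignore_index=True),
    )
    turnover.to_csv(out / "state_turnover.csv", index=False)

    elev_rows = []
    for sp in sorted(binary_maps):
        for name in jset.names:
            shift = elevation_shift(
                binary_maps[sp][s_from],
                binary_maps[sp][s_to],
                jset,
                name,
                recent.elevation,
            )
            elev_rows.append(dataclasses.asdict(shift))
    elevation = pd.DataFrame(elev_rows)
    elevation.to_csv(out / "elevation_shift.csv", index=False)
    results["state_presence"] = presence
    results["state_turnover"] = turnover
    results["elevation_shift"] = elevation
    manifest["stages"]["states"] = {
        "n_jurisdictions": jset.n_jurisdictions,
        "n_presence_rows": int(len(presence)),
    }
    _write_manifest(out, manifest)
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
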