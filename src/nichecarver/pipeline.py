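"""File-based pipeline stages.

Stages communicate through plain artifacts in the run directory (ASCII-grid
rasters, CSV tables, GeoJSON polygons, NetCDF profiles, JSON summaries), so
any stage can be re-run or swapped independently.  Every stage writes a
manifest with the config hash, the master seed and its inputs, making a run
reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from . import brt, cv, ensemble, niche, occurrences, predictors, pseudoabsence, synthetic
from .config import PipelineConfig
from .grids import Raster, read_ascii_grid, write_ascii_grid
from .profiles import EnvProfileSet

logger = logging.getLogger(__name__)

STAGES = ["simulate", "predictors", "clean", "thin", "pseudoabs",
          "cv", "ensemble", "report"]

_NEEDS = {
    "predictors": ("simulate", ["bathymetry.asc", "profiles.nc"]),
    "clean": ("simulate", ["presences.csv", "bathymetry.asc"]),
    "thin": ("clean", ["occ_clean.csv"]),
    "pseudoabs": ("thin", ["occ_thinned.csv", "thin.json"]),
    "cv": ("pseudoabs", ["occ_model.csv"]),
    "ensemble": ("cv", ["cv_summary.json"]),
    "report": ("ensemble", ["binary.asc"]),
}


class MissingArtifactError(RuntimeError):
    pass


def _require(cfg: PipelineConfig, stage: str) -> None:
    if stage not in _NEEDS:
        return
    producer, files = _NEEDS[stage]
    for f in files:
        if not (Path(cfg.out_dir) / f).exists():
            raise MissingArtifactError(
                f"stage '{stage}' needs artifact '{f}'; run stage "
                f"'{producer}' first")


def _config_hash(cfg: PipelineConfig) -> str:
    doc = yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _manifest(cfg: PipelineConfig, stage: str, inputs: list[str],
              outputs: list[str], extra: dict | None = None) -> None:
    from . import __version__
    man = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "inputs": inputs,
        "outputs": outputs,
        "version": __version__,
    }
    if extra:
        man.update(extra)
    path = Path(cfg.out_dir) / f"{stage}.manifest.json"
    path.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _write_mpas(mpas, path: Path) -> None:
    fc = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": {"id": i},
                        "geometry": mapping(p)} for i, p in enumerate(mpas)]}
    path.write_text(json.dumps(fc) + "\n")


def _read_mpas(path: Path):
    fc = json.loads(path.read_text())
    return [shape(f["geometry"]) for f in fc["features"]]


def _load_predictors(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    meta = json.loads((out / "predictors.json").read_text())
    plist = []
    for m in meta:
        raster = read_ascii_grid(out / "predictors" / f"{m['name']}.asc")
        plist.append(predictors.PredictorRaster(raster, m["name"], m["statistic"]))
    return plist


# ---------------------------------------------------------------------------
# Stages


def run_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w = cfg.world
    niche_fn = synthetic.NicheFunction(responses={
        "temperature_min": synthetic.PlateauResponse(lo=w.niche_lo, hi=None,
                                                     softness=w.niche_softness),
        "temperature_max": synthetic.PlateauResponse(lo=None, hi=w.niche_hi,
                                                     softness=w.niche_softness),
    })
    world = synthetic.generate_world(
        seed=cfg.seed, extent=w.extent, resolution=w.resolution,
        n_presences=w.n_presences, n_seamounts=w.n_seamounts, niche=niche_fn,
        effort_west_bias=w.effort_west_bias,
        depth_window=(cfg.depth_min_m, cfg.depth_max_m))
    write_ascii_grid(world.bathymetry, out / "bathymetry.asc")
    world.profiles.to_netcdf(out / "profiles.nc")
    world.presences.to_csv(out / "presences.csv", index=False)
    write_ascii_grid(world.suitability, out / "suitability_true.asc")
    write_ascii_grid(world.effort_bias, out / "effort_bias.asc")
    write_ascii_grid(world.hard_bottom, out / "hard_bottom.asc")
    _write_mpas(world.mpas, out / "mpas.geojson")
    bottles = synthetic.generate_bottle_samples(
        world.profiles, n=w.n_bottles, noise_sd=w.bottle_noise_sd,
        seed=_stage_seed(cfg, "bottles"))
    bottles.to_csv(out / "bottles.csv", index=False)
    truth = {"niche_limits": {"temperature_min": [w.niche_lo, None],
                              "temperature_max": [None, w.niche_hi]},
             "softness": w.niche_softness, "seed": cfg.seed}
    (out / "world.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    _manifest(cfg, "simulate", [], ["bathymetry.asc", "profiles.nc",
                                    "presences.csv", "hard_bottom.asc",
                                    "mpas.geojson", "bottles.csv"])


def run_predictors(cfg: PipelineConfig) -> None:
    _require(cfg, "predictors")
    out = Path(cfg.out_dir)
    bathy = read_ascii_grid(out / "bathymetry.asc")
    profiles = EnvProfileSet.from_netcdf(out / "profiles.nc")
    (out / "predictors").mkdir(exist_ok=True)
    window = (cfg.depth_min_m, cfg.depth_max_m)
    plist = [predictors.build_predictor(profiles, bathy, var, stat, window)
             for var, stat in cfg.predictor_spec]
    if cfg.include_slope:
        slope = predictors.compute_slope(bathy)
        # slope is a terrain predictor; restrict it to the depth window
        mask = (np.isfinite(bathy.values) & (bathy.values >= cfg.depth_min_m)
                & (bathy.values <= cfg.depth_max_m))
        slope.raster.values[~mask] = np.nan
        plist.append(slope)
    meta = []
    for p in plist:
        write_ascii_grid(p.raster, out / "predictors" / f"{p.name}.asc")
        meta.append({"name": p.name, "statistic": p.statistic})
    (out / "predictors.json").write_text(json.dumps(meta, indent=2) + "\n")
    bottles_path = out / "bottles.csv"
    if bottles_path.exists():
        bottles = pd.read_csv(bottles_path)
        qc = predictors.quality_control(profiles, bottles)
        qc.to_csv(out / "qc_report.csv", index=False)
    _manifest(cfg, "predictors", ["bathymetry.asc", "profiles.nc"],
              ["predictors.json", "qc_report.csv"])


def run_clean(cfg: PipelineConfig) -> None:
    _require(cfg, "clean")
    out = Path(cfg.out_dir)
    occ = pd.read_csv(out / "presences.csv")
    bathy = read_ascii_grid(out / "bathymetry.asc")
    cleaned = occurrences.clean_and_grid(occ, bathy, max_depth=cfg.depth_max_m)
    cleaned.to_csv(out / "occ_clean.csv", index=False)
    _manifest(cfg, "clean", ["presences.csv"], ["occ_clean.csv"],
              {"n_in": len(occ), "n_out": len(cleaned)})


def run_thin(cfg: PipelineConfig) -> None:
    _require(cfg, "thin")
    out = Path(cfg.out_dir)
    occ = pd.read_csv(out / "occ_clean.csv")
    plist = _load_predictors(cfg)
    cor = occurrences.mantel_correlogram(
        occ, plist, class_width_km=cfg.mantel_class_width_km,
        max_dist_km=cfg.mantel_max_dist_km, n_perm=cfg.mantel_n_perm,
        seed=_stage_seed(cfg, "mantel"))
    cor.to_frame().to_csv(out / "correlogram.csv", index=False)
    range_km = cor.autocorrelation_range_km(cfg.mantel_alpha)
    thinned = occurrences.thin_records(occ, range_km,
                                       seed=_stage_seed(cfg, "thin"))
    thinned.to_csv(out / "occ_thinned.csv", index=False)
    (out / "thin.json").write_text(json.dumps(
        {"autocorrelation_range_km": range_km,
         "n_before": len(occ), "n_after": len(thinned)}, indent=2) + "\n")
    _manifest(cfg, "thin", ["occ_clean.csv"],
              ["correlogram.csv", "occ_thinned.csv", "thin.json"],
              {"range_km": range_km})


def run_pseudoabs(cfg: PipelineConfig) -> None:
    _require(cfg, "pseudoabs")
    out = Path(cfg.out_dir)
    pres = pd.read_csv(out / "occ_thinned.csv")
    plist = _load_predictors(cfg)
    thin_info = json.loads((out / "thin.json").read_text())
    bw = cfg.effort_bandwidth_km or max(thin_info["autocorrelation_range_km"],
                                        cfg.mantel_class_width_km)
    esm = pseudoabsence.esm_mahalanobis(plist, pres)
    write_ascii_grid(esm, out / "esm.asc")
    pool = pseudoabsence.candidate_pool(esm, pres, cfg.esm_threshold)
    effort = pseudoabsence.effort_surface(pres, esm.grid, bandwidth_km=bw)
    write_ascii_grid(effort, out / "effort.asc")
    absences = pseudoabsence.draw_pseudo_absences(
        pool, plist, len(pres), effort, seed=_stage_seed(cfg, "pseudoabs"))
    model_data = pd.concat([pres, absences], ignore_index=True)
    model_data.to_csv(out / "occ_model.csv", index=False)
    _manifest(cfg, "pseudoabs", ["occ_thinned.csv"],
              ["esm.asc", "effort.asc", "occ_model.csv"],
              {"bandwidth_km": bw, "pool_size": int(len(pool)),
               "n_presences": len(pres)})


def _model_frame(occ: pd.DataFrame, plist) -> pd.DataFrame:
    """Predictor values + y + lon for each record; drops incomplete rows."""
    data = pd.DataFrame({
        "lon": occ["lon"].to_numpy(),
        "y": (occ["label"] == "presence").astype(float).to_numpy(),
    })
    for p in plist:
        data[p.name] = p.raster.sample(occ["lon"].to_numpy(),
                                       occ["lat"].to_numpy())
    before = len(data)
    data = data.dropna().reset_index(drop=True)
    if len(data) < before:
        logger.warning("dropped %d records with incomplete predictors",
                       before - len(data))
    return data


def run_cv(cfg: PipelineConfig) -> None:
    _require(cfg, "cv")
    out = Path(cfg.out_dir)
    occ = pd.read_csv(out / "occ_model.csv")
    plist = _load_predictors(cfg)
    data = _model_frame(occ, plist)
    combos = cv.correlation_filter(
        plist, r_max=cfg.r_max, min_size=cfg.min_combo_size,
        max_size=cfg.max_combo_size, max_combinations=cfg.max_combinations,
        seed=_stage_seed(cfg, "combos"))
    monotone = {p.name: p.monotone_sign for p in plist}
    results = cv.tune_and_cross_validate(
        data, combos, monotone, lr_grid=tuple(cfg.lr_grid), tc_max=cfg.tc_max,
        n_trees=cfg.n_trees, bag_fraction=cfg.bag_fraction,
        n_folds=cfg.n_folds, seed=_stage_seed(cfg, "cv"))
    rows = []
    for r in results:
        for k in range(len(r.fold_tss)):
            rows.append({"combination": "+".join(r.combination), "fold": k,
                         "tss": r.fold_tss[k], "deviance": r.fold_deviance[k],
                         "dev_explained": r.fold_dev_explained[k]})
    pd.DataFrame(rows).to_csv(out / "cv_results.csv", index=False)
    contrib = cv.predictor_contribution(results)
    contrib.to_csv(out / "contributions.csv", index=False)
    # overfitting guard: combinations using predictors with null
    # contribution are dropped before the member selection
    candidates = cv.discard_null_contributors(results, contrib)
    selected = cv.select_models(candidates, alpha=cfg.alpha)
    summary = {
        "selected": [{
            "combination": list(r.combination),
            "learning_rate": r.best_params.learning_rate,
            "tree_complexity": r.best_params.tree_complexity,
            "n_trees": r.best_params.n_trees,
            "bag_fraction": r.best_params.bag_fraction,
            "seed": r.best_params.seed,
            "mean_tss": r.mean_tss,
            "mean_dev_explained": r.mean_dev_explained,
            "fold_tss": [None if not np.isfinite(v) else v
                         for v in r.fold_tss],
        } for r in selected.members],
        "n_evaluated": len(results),
    }
    (out / "cv_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _manifest(cfg, "cv", ["occ_model.csv"],
              ["cv_results.csv", "cv_summary.json", "contributions.csv"],
              {"n_combinations": len(combos)})


def _selected_from_summary(path: Path) -> list[cv.CVResult]:
    summary = json.loads(path.read_text())
    out = []
    for m in summary["selected"]:
        params = brt.BRTParams(
            learning_rate=m["learning_rate"], n_trees=m["n_trees"],
            tree_complexity=m["tree_complexity"],
            bag_fraction=m["bag_fraction"], seed=m["seed"])
        fold_tss = np.array([np.nan if v is None else v for v in m["fold_tss"]])
        out.append(cv.CVResult(combination=tuple(m["combination"]),
                               best_params=params, fold_tss=fold_tss,
                               fold_deviance=np.full(fold_tss.size, np.nan),
                               fold_dev_explained=np.full(fold_tss.size, np.nan)))
    return out


def run_ensemble(cfg: PipelineConfig) -> None:
    _require(cfg, "ensemble")
    out = Path(cfg.out_dir)
    occ = pd.read_csv(out / "occ_model.csv")
    plist = _load_predictors(cfg)
    data = _model_frame(occ, plist)
    selected = _selected_from_summary(out / "cv_summary.json")
    monotone = {p.name: p.monotone_sign for p in plist}
    rock = read_ascii_grid(out / "hard_bottom.asc") \
        if (out / "hard_bottom.asc").exists() else None
    ens = ensemble.build_ensemble(selected, data, plist, monotone,
                                  hard_bottom=rock)
    write_ascii_grid(ens.median, out / "ensemble_median.asc")
    write_ascii_grid(ens.sd, out / "ensemble_sd.asc")
    write_ascii_grid(ens.binary, out / "binary.asc")
    if ens.binary_rock is not None:
        write_ascii_grid(ens.binary_rock, out / "binary_rock.asc")
    for mi, model in enumerate(ens.members):
        (out / f"member_{mi}.json").write_text(model.to_json())
    bathy = read_ascii_grid(out / "bathymetry.asc")
    mpas = _read_mpas(out / "mpas.geojson") \
        if (out / "mpas.geojson").exists() else []
    report = ensemble.area_report(ens, bathy, mpas,
                                  mesophotic_cutoff=cfg.mesophotic_cutoff_m)
    doc = {"threshold": ens.threshold,
           "sensitivity": ens.stats.sensitivity,
           "specificity": ens.stats.specificity,
           "tss": ens.stats.tss,
           "members": [list(c) for c in ens.member_combos],
           "area_report": report.to_dict()}
    (out / "ensemble.json").write_text(json.dumps(doc, indent=2) + "\n")
    _manifest(cfg, "ensemble", ["cv_summary.json", "occ_model.csv"],
              ["ensemble_median.asc", "ensemble_sd.asc", "binary.asc",
               "ensemble.json"])


def run_report(cfg: PipelineConfig) -> None:
    _require(cfg, "report")
    out = Path(cfg.out_dir)
    plist = _load_predictors(cfg)
    binary = read_ascii_grid(out / "binary.asc")
    occ = pd.read_csv(out / "occ_model.csv")
    pres = occ[occ["label"] == "presence"]
    lp = niche.limiting_points(binary, plist, occurrences=pres)
    contrib_path = out / "contributions.csv"
    if contrib_path.exists():
        contrib = pd.read_csv(contrib_path)[["predictor", "contribution_pct"]]
        lp = lp.merge(contrib, on="predictor", how="left")
    lp.to_csv(out / "limiting_points.csv", index=False)
    (out / "limiting_points.json").write_text(
        lp.to_json(orient="records", indent=2) + "\n")
    bean = niche.bean_data(occ, plist)
    bean.to_csv(out / "bean_data.csv", index=False)
    niche.bean_summary(bean).to_csv(out / "bean_summary.csv", index=False)

    data = _model_frame(occ, plist)
    members = []
    combos = []
    mi = 0
    while (out / f"member_{mi}.json").exists():
        model = brt.BRTModel.from_json((out / f"member_{mi}.json").read_text())
        members.append(model)
        combos.append(tuple(model.feature_names))
        mi += 1
    if members:
        pd_table = niche.partial_dependence_table(members, combos, data)
        pd_table.to_csv(out / "pd_curves.csv", index=False)
    if len(bean):
        niche.plot_beans(bean, out / "beans.png")
    _manifest(cfg, "report", ["binary.asc", "occ_model.csv"],
              ["limiting_points.csv", "bean_data.csv", "pd_curves.csv"])


_RUNNERS = {
    "simulate": run_simulate,
    "predictors": run_predictors,
    "clean": run_clean,
    "thin": run_thin,
    "pseudoabs": run_pseudoabs,
    "cv": run_cv,
    "ensemble": run_ensemble,
    "report": run_report,
}


def run(stage: str, cfg: PipelineConfig) -> None:
    """Run one stage, or 'all' for the full chain."""
    if stage == "all":
        for s in STAGES:
            logger.info("=== stage %s ===", s)
            _RUNNERS[s](cfg)
        return
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{STAGES + ['all']}")
    _RUNNERS[stage](cfg)
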