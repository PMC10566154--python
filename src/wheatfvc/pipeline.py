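"""End-to-end orchestration of the ground-UAS-satellite FVC workflow.

``run_pipeline`` executes, per growth stage (jointing and booting by
default):

1. synthetic scene generation — FVC truth field, UAS reflectance,
   satellite reflectance (block-mean of the fine grid plus sensor noise);
2. ground sampling — five-point sites, rendered photos, per-photo FVC via
   the two-Gaussian a* fit, aggregation to 2 m / 10 m reference samples;
3. scale bridging — zonal upscaling of UAS imagery and the truth field to
   the 2 m grid, cubic-convolution downscaling of satellite rasters to 2 m;
4. FVC_UAS label production — an RFR (or SVR) model trained on the ground
   samples, predicted wall-to-wall at 2 m;
5. satellite model — BPNN trained on (downscaled satellite reflectance,
   FVC_UAS) pairs pooled over stages, predicted wall-to-wall;
6. evaluation — held-out RMSE against labels and against synthetic truth,
   10 m aggregation, NDVI-dichotomy baseline, boundary/interior strata and
   the upscale-only strategy comparator.

Every stage is seeded from the single pipeline seed; two runs with the same
config produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluate, groundfvc, satmodel, scale, synth, uasmodels
from .raster import GridSpec, Raster, fvc_raster, write_geotiff
from .satmodel import BPNN, BPNNConfig
from .synth import (
    SAT_BANDS,
    UAS_BANDS,
    EndmemberSpectra,
    PhotoColorModel,
    SceneConfig,
)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-scene pipeline run."""

    scenes: dict  # stage -> SceneConfig
    spectra: EndmemberSpectra = field(default_factory=EndmemberSpectra.default)
    photo_model: PhotoColorModel = field(default_factory=PhotoColorModel)
    n_sites: int = 30
    n_bare_sites: int = 10
    bare_manual_threshold: float = -5.0  # a* cutoff judged from the photo set
    photo_size: tuple = (96, 96)
    uas_model: str = "rfr"
    rfr_mtry_grid: tuple = (1, 2, 3, 4)
    rfr_ntree_grid: tuple = (100, 350)
    cv_folds: int = 10
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    sat_noise_sd: float = 0.01
    boundary_radius_m: float = 5.0
    n_eval_points: int = 150
    seed: int = 0

    @classmethod
    def default(cls, seed=0) -> "PipelineConfig":
        """Default study conditions: two growth stages over a 300 x 150 m
        scene of two large wheat fields split by a 10 m bare corridor
        (~22,500 2 m cells in total), at a 0.2 m UAS working GSD."""
        scenes = {}
        for i, stage in enumerate(("jointing", "booting")):
            scenes[stage] = SceneConfig.grid_layout(
                n_plot_rows=1,
                n_plot_cols=2,
                plot_w=145.0,
                plot_h=150.0,
                path_w=10.0,
                margin=0.0,
                pad_to=10.0,
                stage=stage,
                uas_gsd=0.2,
                correlation_length_m=25.0,
                edge_taper_m=15.0,
                seed=seed * 1000 + i,
            )
        return cls(scenes=scenes, seed=seed)

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        blob = json.dumps(asdict_safe(self), sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(obj):
    """dataclasses.asdict that tolerates numpy payloads and nested configs."""
    if hasattr(obj, "__dataclass_fields__"):
        return {k: asdict_safe(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: asdict_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [asdict_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class StageArtifacts:
    """Per-stage rasters and tables produced by the pipeline."""

    scene: SceneConfig
    fvc_fine: Raster
    uas_2m: Raster
    truth_2m: Raster
    truth_10m: Raster
    sat_10m: Raster
    sat_2m: Raster = None
    labels_2m: Raster = None
    labels_10m: Raster = None
    fvc_sat_2m: Raster = None
    fvc_sat_10m: Raster = None
    ground: pd.DataFrame = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    stages: dict
    ground: pd.DataFrame
    uas_cv: uasmodels.CVResult
    bpnn: BPNN
    bpnn_trace: pd.DataFrame
    bpnn_uponly: BPNN
    pairs: pd.DataFrame
    pairs_10m: pd.DataFrame
    reports: dict
    manifest: dict


def _seed_table(seed, n=64):
    return (np.random.SeedSequence(seed).generate_state(n) % (2**31)).astype(int)


def _stage_synthesis(scene, spectra, sat_noise_sd, seeds) -> StageArtifacts:
    fvc_fine = synth.generate_fvc_field(scene)
    uas_fine = synth.render_reflectance(fvc_fine, spectra, UAS_BANDS, seed=seeds[0])
    cell_grid = GridSpec(
        0.0,
        0.0,
        scene.cell_m,
        int(round(scene.height_m / scene.cell_m)),
        int(round(scene.width_m / scene.cell_m)),
    )
    uas_2m = scale.upscale_zonal(uas_fine, cell_grid)
    truth_2m = scale.upscale_zonal(fvc_fine, cell_grid)
    truth_10m = scale.upscale_fvc_10m(truth_2m, int(round(scene.sat_gsd / scene.cell_m)))
    noiseless = EndmemberSpectra(spectra.vegetation, spectra.soil, 0.0)
    sat_fine = synth.render_reflectance(fvc_fine, noiseless, SAT_BANDS, seed=seeds[1])
    factor = int(round(scene.sat_gsd / scene.uas_gsd))
    sat_10m = synth.render_satellite_from_fine(sat_fine, factor)
    sat_10m = synth.add_sensor_noise(sat_10m, sat_noise_sd, seed=seeds[2])
    return StageArtifacts(
        scene=scene,
        fvc_fine=fvc_fine,
        uas_2m=uas_2m,
        truth_2m=truth_2m,
        truth_10m=truth_10m,
        sat_10m=sat_10m,
    )


def _stage_ground(art: StageArtifacts, config: PipelineConfig, seeds) -> pd.DataFrame:
    scene = art.scene
    table = synth.place_ground_samples(scene, config.n_sites, seed=seeds[0])
    table = synth.sample_truth(art.fvc_fine, table, box_m=scene.cell_m)
    ests, thr_ests = [], []
    for k, rec in table.reset_index(drop=True).iterrows():
        photo, _, _ = synth.render_ground_photo(
            rec.truth_fvc, config.photo_model, config.photo_size, seed=seeds[1] + k
        )
        try:
            res = groundfvc.photo_fvc(photo)
            est = res.fvc_weight
        except ValueError:
            # nearly single-class photo: fall back to the fixed, visually
            # judged a* cutoff, as done for plots that defeat the fit
            res = groundfvc.photo_fvc(
                photo,
                estimator="threshold",
                manual_threshold=config.bare_manual_threshold,
            )
            est = res.fvc_threshold
        ests.append(est)
        thr_ests.append(res.fvc_threshold)
    table["fvc_weight"] = ests
    table["fvc_threshold"] = thr_ests
    # per-site aggregation: centre sub-square -> 2 m, five-photo mean -> 10 m
    agg = []
    for site_id, grp in table.groupby("site_id"):
        vals = dict(zip(grp.subsample_id, grp.fvc_weight))
        fvc_2m, fvc_10m = groundfvc.aggregate_site(vals)
        centre = grp[grp.is_center].iloc[0]
        agg.append(
            {
                "site_id": site_id,
                "x": centre.x,
                "y": centre.y,
                "fvc_2m": fvc_2m,
                "fvc_10m": fvc_10m,
                "truth_2m": centre.truth_fvc,
                "truth_10m": grp.truth_fvc.mean(),
            }
        )
    sites = pd.DataFrame(agg)

    # bare-path reference squares: all-background photos defeat the mixture
    # fit, so they use the threshold estimator with a fixed visually-judged
    # a* cutoff (greener than any soil pixel)
    if config.n_bare_sites > 0:
        bare = synth.place_bare_samples(scene, config.n_bare_sites, seed=seeds[2])
        bare = synth.sample_truth(art.fvc_fine, bare, box_m=scene.cell_m)
        best = []
        for k, rec in bare.reset_index(drop=True).iterrows():
            photo, _, _ = synth.render_ground_photo(
                rec.truth_fvc, config.photo_model, config.photo_size,
                seed=seeds[3] + k,
            )
            res = groundfvc.photo_fvc(
                photo,
                estimator="threshold",
                manual_threshold=config.bare_manual_threshold,
            )
            best.append(res.fvc)
        bare["fvc_weight"] = best
        bare["fvc_threshold"] = best
        table = pd.concat([table, bare], ignore_index=True)
        bare_sites = pd.DataFrame(
            {
                "site_id": bare.site_id,
                "x": bare.x,
                "y": bare.y,
                "fvc_2m": best,
                "fvc_10m": np.nan,
                "truth_2m": bare.truth_fvc,
                "truth_10m": np.nan,
            }
        )
        sites = pd.concat([sites, bare_sites], ignore_index=True)
    return table, sites


def _site_features(art: StageArtifacts, sites: pd.DataFrame):
    g = art.uas_2m.grid
    rows, cols = g.cell_of(sites.x.to_numpy(), sites.y.to_numpy())
    X = np.stack([art.uas_2m.band(b)[rows, cols] for b in UAS_BANDS], axis=1)
    return X, sites.fvc_2m.to_numpy()


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full workflow; optionally persist artifacts under out_dir."""
    seeds = _seed_table(config.seed)
    stages = {}
    ground_tables = []
    site_tables = []
    for i, (stage, scene) in enumerate(sorted(config.scenes.items())):
        art = _stage_synthesis(scene, config.spectra, config.sat_noise_sd, seeds[8 * i : 8 * i + 4])
        ground, sites = _stage_ground(art, config, seeds[8 * i + 4 : 8 * i + 8])
        ground["stage"] = stage
        art.ground = ground
        stages[stage] = art
        ground_tables.append(ground)
        sites = sites.copy()
        sites["stage"] = stage
        site_tables.append((stage, art, sites))

    # --- FVC_UAS model on pooled ground samples -------------------------------
    Xs, ys = [], []
    for stage, art, sites in site_tables:
        X, y = _site_features(art, sites)
        Xs.append(X)
        ys.append(y)
    X_train = np.vstack(Xs)
    y_train = np.clip(np.concatenate(ys), 0.0, 1.0)
    if config.uas_model == "rfr":
        uas_cv = uasmodels.train_rfr(
            X_train,
            y_train,
            mtry_grid=config.rfr_mtry_grid,
            ntree_grid=config.rfr_ntree_grid,
            k_folds=config.cv_folds,
            seed=int(seeds[32]),
        )
    elif config.uas_model == "svr":
        uas_cv = uasmodels.train_svr(
            X_train, y_train, k_folds=config.cv_folds, seed=int(seeds[32])
        )
    else:
        raise ValueError(f"unknown uas_model {config.uas_model!r}")

    # --- labels, downscaled satellite, training pairs -------------------------
    pair_frames, pair10_frames = [], []
    for stage, art in stages.items():
        art.labels_2m = uasmodels.predict_fvc_map(uas_cv.model, art.uas_2m, UAS_BANDS)
        art.labels_10m = scale.upscale_fvc_10m(
            art.labels_2m, int(round(art.scene.sat_gsd / art.scene.cell_m))
        )
        art.sat_2m = scale.downscale_bicubic(
            art.sat_10m, int(round(art.scene.sat_gsd / art.scene.cell_m))
        )
        pair_frames.append(satmodel.build_pairs(art.sat_2m, art.labels_2m, stage=stage))
        pair10_frames.append(
            satmodel.build_pairs(art.sat_10m, art.labels_10m, stage=stage)
        )
    pairs = pd.concat(pair_frames, ignore_index=True)
    pairs_10m = pd.concat(pair10_frames, ignore_index=True)

    # --- BPNN training (up-down) and up-only comparator -----------------------
    bands = list(SAT_BANDS)
    bpnn_cfg = replace(config.bpnn, seed=int(seeds[33]))
    model, trace = satmodel.train_bpnn(
        pairs[bands].to_numpy(), pairs["label"].to_numpy(), bpnn_cfg, bands=bands
    )
    uponly_cfg = replace(config.bpnn, seed=int(seeds[34]))
    model_10m, trace_10m = satmodel.train_bpnn(
        pairs_10m[bands].to_numpy(),
        pairs_10m["label"].to_numpy(),
        uponly_cfg,
        bands=bands,
    )

    # --- prediction and evaluation --------------------------------------------
    reports = {"stages": {}, "per_model": {}}
    strat_records = []
    test_idx = trace.attrs["test_idx"]
    test_pairs = pairs.iloc[test_idx]
    pred_test = model.predict(test_pairs[bands].to_numpy())
    reports["heldout_rmse_vs_labels"] = evaluate.rmse(
        pred_test, test_pairs["label"].to_numpy()
    )
    truth_test = np.concatenate(
        [
            stages[stage].truth_2m.band("fvc")[grp.row.to_numpy(), grp.col.to_numpy()]
            for stage, grp in test_pairs.groupby("stage")
        ]
    )
    pred_test_by_stage = np.concatenate(
        [
            model.predict(grp[bands].to_numpy())
            for _, grp in test_pairs.groupby("stage")
        ]
    )
    reports["heldout_rmse_vs_truth"] = evaluate.rmse(pred_test_by_stage, truth_test)
    reports["bpnn_stop_reason"] = trace.attrs["stop_reason"]
    reports["bpnn_iterations"] = int(trace["iter"].iloc[-1])
    reports["uponly_stop_reason"] = trace_10m.attrs["stop_reason"]
    reports["n_pairs"] = int(len(pairs))
    reports["n_pairs_per_stage"] = {
        s: int(n) for s, n in pairs.groupby("stage").size().items()
    }
    reports["uas_cv_rmse"] = uas_cv.cv_rmse
    reports["uas_best_params"] = uas_cv.best_params

    all_ground = pd.concat(ground_tables, ignore_index=True)
    reports["ground_photo_mae"] = float(
        np.mean(np.abs(all_ground.fvc_weight - all_ground.truth_fvc))
    )

    rmse_2m_list, rmse_10m_list = [], []
    for stage, art in stages.items():
        art.fvc_sat_2m = satmodel.predict_raster(model, art.sat_2m)
        art.fvc_sat_10m = scale.upscale_fvc_10m(
            art.fvc_sat_2m, int(round(art.scene.sat_gsd / art.scene.cell_m))
        )
        fvc_uponly_10m = satmodel.predict_raster(model_10m, art.sat_10m)
        v2 = art.truth_2m.valid_mask() & art.fvc_sat_2m.valid_mask()
        v10 = art.truth_10m.valid_mask() & art.fvc_sat_10m.valid_mask()
        r2m = evaluate.rmse(art.fvc_sat_2m.band("fvc")[v2], art.truth_2m.band("fvc")[v2])
        r10m = evaluate.rmse(
            art.fvc_sat_10m.band("fvc")[v10], art.truth_10m.band("fvc")[v10]
        )
        rmse_2m_list.append(r2m)
        rmse_10m_list.append(r10m)
        strata = evaluate.boundary_interior_eval(
            art.fvc_sat_2m,
            art.truth_2m,
            art.scene,
            radius_m=config.boundary_radius_m,
            n_points=config.n_eval_points,
            seed=int(seeds[40]),
        )
        # NDVI-dichotomy baseline on the upscaled UAS bands
        ndvi = uasmodels.compute_ndvi(art.uas_2m)
        params = uasmodels.select_endmembers(ndvi)
        dich = uasmodels.dichotomy_fvc(ndvi, params)
        vd = dich.valid_mask() & art.truth_2m.valid_mask()
        reports["stages"][stage] = {
            "rmse_2m_vs_truth": r2m,
            "rmse_10m_vs_truth": r10m,
            "boundary_rmse": strata["boundary"].rmse,
            "interior_rmse": strata["interior"].rmse,
            "dichotomy_rmse_2m": evaluate.rmse(
                dich.band("fvc")[vd], art.truth_2m.band("fvc")[vd]
            ),
        }
        strat_records += [
            {
                "strategy": "up-down",
                "stage": stage,
                "scale": "2m",
                "pred": art.fvc_sat_2m,
                "truth": art.truth_2m,
            },
            {
                "strategy": "up-down",
                "stage": stage,
                "scale": "10m",
                "pred": art.fvc_sat_10m,
                "truth": art.truth_10m,
            },
            {
                "strategy": "up-only",
                "stage": stage,
                "scale": "10m",
                "pred": fvc_uponly_10m,
                "truth": art.truth_10m,
            },
            # the up-only product judged at the 2 m reference scale: every
            # 2 m cell inherits its containing 10 m prediction, exposing the
            # block-representativeness error at field boundaries
            {
                "strategy": "up-only",
                "stage": stage,
                "scale": "2m",
                "pred": scale.block_expand(
                    fvc_uponly_10m, int(round(art.scene.sat_gsd / art.scene.cell_m))
                ),
                "truth": art.truth_2m,
            },
        ]
    reports["rmse_2m_vs_truth"] = float(np.mean(rmse_2m_list))
    reports["rmse_10m_vs_truth"] = float(np.mean(rmse_10m_list))
    strategy_table = evaluate.strategy_comparison(strat_records)
    reports["strategy_table"] = strategy_table
    reports["strategy_reduction_pct_2m"] = {
        stage: float(
            strategy_table.loc[
                (strategy_table.stage == stage)
                & (strategy_table.scale == "2m")
                & (strategy_table.strategy == "up-down"),
                "rmse_change_pct",
            ].iloc[0]
        )
        for stage in stages
    }

    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "stages": list(stages),
        "n_pairs": int(len(pairs)),
        "outputs": [],
    }
    result = PipelineResult(
        config=config,
        stages=stages,
        ground=all_ground,
        uas_cv=uas_cv,
        bpnn=model,
        bpnn_trace=trace,
        bpnn_uponly=model_10m,
        pairs=pairs,
        pairs_10m=pairs_10m,
        reports=reports,
        manifest=manifest,
    )
    if out_dir is not None:
        _persist(result, out_dir)
    return result


def _persist(result: PipelineResult, out_dir):
    import os

    os.makedirs(out_dir, exist_ok=True)
    outputs = []

    def save_raster(name, raster):
        path = os.path.join(out_dir, name)
        write_geotiff(path, raster)
        outputs.append(name)

    for stage, art in result.stages.items():
        save_raster(f"{stage}_truth_2m.tif", art.truth_2m)
        save_raster(f"{stage}_uas_2m.tif", art.uas_2m)
        save_raster(f"{stage}_sat_10m.tif", art.sat_10m)
        save_raster(f"{stage}_sat_2m.tif", art.sat_2m)
        save_raster(f"{stage}_labels_2m.tif", art.labels_2m)
        save_raster(f"{stage}_fvc_sat_2m.tif", art.fvc_sat_2m)
    result.ground.to_csv(os.path.join(out_dir, "ground_samples.csv"), index=False)
    outputs.append("ground_samples.csv")
    result.pairs.to_csv(os.path.join(out_dir, "training_pairs.csv"), index=False)
    outputs.append("training_pairs.csv")
    result.bpnn.save(os.path.join(out_dir, "bpnn_model.json"))
    outputs.append("bpnn_model.json")
    reports = {
        k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
        for k, v in result.reports.items()
    }
    result.manifest["outputs"] = outputs
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump({"reports": reports, "manifest": result.manifest}, fh, indent=1)
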