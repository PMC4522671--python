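"""End-to-end orchestration across scales and distance sources.

``run_simulation`` writes a complete synthetic input set to disk in the
formats :mod:`forestbeta.io` reads; ``run_analysis`` consumes such a
file set (synthetic or real) and produces, per spatial scale and per
species-distance source (phylogeny, trait dendrogram): beta tables, SES
tables, SES-negative proportions, an MRM variation-partition table, and
(at the habitat scale) the within- vs across-habitat contrast.  A run
manifest records the config snapshot, seeds, input digests, per-stage
timing and every output file, so each output is traceable to a config
plus seed and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta as beta_mod
from . import grid as grid_mod
from . import habitat as habitat_mod
from . import io as io_mod
from . import mrm as mrm_mod
from . import nullses as nullses_mod
from . import simulate as sim_mod
from . import soilenv as soilenv_mod
from . import traitspace as traitspace_mod
from .io import ValidationError, logger

DEFAULT_ANALYSIS = {
    "scales": [10.0, 20.0, 50.0, 100.0],
    "habitat_scale": 20.0,
    "habitat_method": "kmeans3",
    "weighted": True,
    "n_null": 999,
    "n_perm": 999,
    "n_trait_axes": 3,
    "n_env_axes": 3,
    "variogram_family": "exponential",
    "variogram_bins": 12,
    "block_discretization": 4,
    "seed": 0,
}

INPUT_FILES = {
    "tree": "tree.nwk",
    "traits": "traits.csv",
    "census": "census.csv",
    "soil": "soil.csv",
    "elevation": "elevation.csv",
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_simulation(config: sim_mod.ScenarioConfig, outdir: str | Path) -> dict:
    """Generate one synthetic plot and write the full analysis input set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    phylo, traits, landscape, census, soil = sim_mod.simulate_all(config)

    phylo.write_newick(outdir / INPUT_FILES["tree"])
    traits.write_csv(outdir / INPUT_FILES["traits"])
    census.write_csv(outdir / INPUT_FILES["census"])
    soil.write_csv(outdir / INPUT_FILES["soil"])
    io_mod.write_elevation(landscape, outdir / INPUT_FILES["elevation"])

    cfg = asdict(config)
    cfg["soil_params"] = {k: asdict(v) for k, v in config.soil_params.items()}
    cfg["elevation_params"] = asdict(config.elevation_params)
    cfg["relief"] = list(config.relief)
    io_mod.dump_config({"scenario": cfg}, outdir / "scenario.yaml")

    manifest = {
        "stage": "simulate",
        "scenario": config.scenario,
        "seed": config.seed,
        "n_stems": census.n_stems,
        "n_species": len(census.species),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {k: _digest(outdir / f) for k, f in INPUT_FILES.items()},
    }
    (outdir / "manifest_simulate.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    return manifest


def _beta_distance_matrix(mats: dict, ids: list[str], occupied: np.ndarray,
                          metric: str) -> io_mod.DistanceMatrix:
    occ = np.flatnonzero(occupied)
    vals = mats[metric][np.ix_(occ, occ)].copy()
    np.fill_diagonal(vals, 0.0)
    return io_mod.DistanceMatrix([ids[i] for i in occ], vals)


def run_analysis(indir: str | Path, outdir: str | Path,
                 width: float, height: float, **options) -> dict:
    """Full multi-scale analysis over one input file set.

    Options override :data:`DEFAULT_ANALYSIS`.  Returns the run manifest
    (also written to ``manifest_analysis.json``).
    """
    opts = {**DEFAULT_ANALYSIS, **options}
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    outputs: list[str] = []
    summary: dict = {"negative_proportions": {}, "habitat": {}}

    def _save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        outputs.append(name)

    # ---- read + reconcile -------------------------------------------------
    t0 = time.time()
    phylo = io_mod.read_newick(indir / INPUT_FILES["tree"])
    traits = io_mod.read_traits(indir / INPUT_FILES["traits"])
    census = io_mod.read_census(indir / INPUT_FILES["census"], width, height)
    soil = io_mod.read_soil(indir / INPUT_FILES["soil"],
                            width=width, height=height)
    elev_path = indir / INPUT_FILES["elevation"]
    elevation = io_mod.read_elevation(elev_path) if elev_path.exists() else None
    rec = io_mod.reconcile_species(census, phylo, traits)
    timings["read"] = time.time() - t0

    # ---- species distance matrices ---------------------------------------
    t0 = time.time()
    phylo_delta = io_mod.cophenetic_distance(phylo).submatrix(
        sorted(set(rec.phylo_species) & set(phylo.tip_labels)))
    pca = traitspace_mod.trait_pca(
        io_mod.TraitTable(traits.table.loc[sorted(rec.trait_species)]),
        n_axes=opts["n_trait_axes"])
    tdist = traitspace_mod.trait_distance(pca.scores)
    dend = traitspace_mod.upgma(tdist)
    func_delta = traitspace_mod.dendrogram_cophenetic(dend)
    (outdir / "trait_dendrogram.nwk").write_text(dend.newick + "\n")
    outputs.append("trait_dendrogram.nwk")
    deltas = {"phylo": phylo_delta, "func": func_delta}
    timings["distance_sources"] = time.time() - t0

    seed = int(opts["seed"])
    mrm_results: list[mrm_mod.MrmResult] = []
    ses_at_habitat_scale: dict[str, pd.DataFrame] = {}
    habitat_grid = None

    for scale in opts["scales"]:
        t0 = time.time()
        grd = grid_mod.subdivide_plot(width, height, scale)
        cm_all = grid_mod.build_community_matrix(census, grd)
        geo = grid_mod.geographic_distances(grd)

        env_table = soilenv_mod.krige_all(
            soil, grd, family=opts["variogram_family"],
            n_bins=opts["variogram_bins"],
            discretization=opts["block_discretization"])
        env_table.to_csv(outdir / f"soil_kriged_{scale:g}m.csv")
        outputs.append(f"soil_kriged_{scale:g}m.csv")
        env, _ = soilenv_mod.environment_distance(env_table,
                                                  n_axes=opts["n_env_axes"])
        timings[f"krige_{scale:g}m"] = time.time() - t0

        for source, delta in deltas.items():
            t0 = time.time()
            cm = cm_all.restrict_species(delta.labels)
            pair_table = beta_mod.all_pairs(cm, delta,
                                            weighted=opts["weighted"])
            _save(pair_table, f"beta_{source}_{scale:g}m.csv")

            ses_table = nullses_mod.ses(
                cm, delta, weighted=opts["weighted"],
                n_null=opts["n_null"],
                seed=seed + int(scale) * 17 + (0 if source == "phylo" else 1))
            _save(ses_table, f"ses_{source}_{scale:g}m.csv")
            neg = nullses_mod.negative_proportion(ses_table)
            summary["negative_proportions"][f"{source}_{scale:g}m"] = \
                {k: round(v, 4) for k, v in neg.items()}
            if scale == opts["habitat_scale"]:
                ses_at_habitat_scale[source] = ses_table
                habitat_grid = grd

            counts = cm.abundance[
                [s for s in cm.species if s in delta._index]].to_numpy(float)
            occupied = counts.sum(axis=1) > 0
            mats = beta_mod.pair_beta_matrices(counts, delta.submatrix(
                [s for s in cm.species if s in delta._index]).values,
                weighted=opts["weighted"])
            ids = cm.abundance.index.to_list()
            occ_labels = [ids[i] for i in np.flatnonzero(occupied)]
            geo_occ = geo.submatrix(occ_labels)
            env_occ = env.submatrix(occ_labels)
            for metric in beta_mod.METRICS:
                d = _beta_distance_matrix(mats, ids, occupied, metric)
                part = mrm_mod.variation_partition(
                    d, geo_occ, env_occ, n_perm=opts["n_perm"],
                    seed=seed + int(scale) * 31)
                part.scale = scale
                part.metric = f"{source}_{metric}" + (
                    "'" if opts["weighted"] else "")
                mrm_results.append(part)
            timings[f"beta_{source}_{scale:g}m"] = time.time() - t0

    _save(pd.DataFrame([r.to_row() for r in mrm_results]), "mrm_partition.csv")
    _save(mrm_mod.partition_table(mrm_results), "mrm_table.csv")

    # ---- habitat contrast at the habitat scale ---------------------------
    if elevation is not None and habitat_grid is not None:
        t0 = time.time()
        metrics = habitat_mod.topo_metrics(elevation, habitat_grid)
        hmap = habitat_mod.classify_habitats(metrics,
                                             method=opts["habitat_method"],
                                             seed=seed)
        hmap.write_csv(outdir / "habitat_map.csv")
        outputs.append("habitat_map.csv")
        rows = []
        for source, ses_table in ses_at_habitat_scale.items():
            for metric in beta_mod.METRICS:
                contrast = habitat_mod.within_across_test(
                    ses_table, hmap, metric=metric)
                rows.append({
                    "source": source, "metric": metric,
                    "mean_within": contrast.mean_within,
                    "mean_across": contrast.mean_across,
                    "t": contrast.t, "df": contrast.df, "p": contrast.p,
                    "n_within": contrast.n_within,
                    "n_across": contrast.n_across,
                })
                summary["habitat"][f"{source}_{metric}"] = {
                    "mean_within": round(contrast.mean_within, 4),
                    "mean_across": round(contrast.mean_across, 4),
                    "p": contrast.p,
                }
        _save(pd.DataFrame(rows), "habitat_contrast.csv")
        timings["habitat"] = time.time() - t0

    manifest = {
        "stage": "analysis",
        "options": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                    for k, v in opts.items()},
        "inputs": {k: _digest(indir / f) for k, f in INPUT_FILES.items()
                   if (indir / f).exists()},
        "dropped_from_tree": len(rec.missing_from_tree),
        "dropped_from_traits": len(rec.missing_from_traits),
        "summary": summary,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t_start, 2),
        "outputs": outputs,
    }
    (outdir / "manifest_analysis.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_scenario(cfg: dict) -> sim_mod.ScenarioConfig:
    """Build a ScenarioConfig from a config mapping (preset or explicit)."""
    cfg = dict(cfg)
    preset = cfg.pop("preset", None)
    scaled = cfg.pop("scaled", preset is not None)
    if "soil_params" in cfg:
        cfg["soil_params"] = {k: sim_mod.FieldParams(**v)
                              for k, v in cfg["soil_params"].items()}
    if "elevation_params" in cfg and cfg["elevation_params"] is not None:
        cfg["elevation_params"] = sim_mod.FieldParams(**cfg["elevation_params"])
    if "relief" in cfg:
        cfg["relief"] = tuple(cfg["relief"])
    if preset is not None and scaled:
        return sim_mod.ScenarioConfig.scaled(preset, **cfg)
    if preset is not None:
        cfg.setdefault("scenario", preset)
    return sim_mod.ScenarioConfig(**cfg)


def run_all(config: dict, outdir: str | Path) -> dict:
    """Simulate (if configured) then analyze; the one-command entry point."""
    outdir = Path(outdir)
    sim_cfg = config.get("simulate")
    analysis_cfg = dict(config.get("analysis", {}))
    if sim_cfg is not None:
        scenario = load_scenario(sim_cfg)
        indir = outdir / "inputs"
        run_simulation(scenario, indir)
        analysis_cfg.setdefault("width", scenario.width)
        analysis_cfg.setdefault("height", scenario.height)
    else:
        indir = Path(config["inputs"])
    width = analysis_cfg.pop("width")
    height = analysis_cfg.pop("height")
    return run_analysis(indir, outdir / "analysis", width, height,
                        **analysis_cfg)
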