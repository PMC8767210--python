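"""End-to-end orchestration: simulate -> tracks -> dives -> foraging ->
energy -> clustering -> overlap -> mortality, with serialized interfaces.

Every stage reads only the tables earlier stages wrote (or returned), so
any stage can be rerun from its inputs alone.  Outputs carry the run
seed and a config hash in ``metadata.json``; reruns with the same config
are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    bioenergetics,
    dive_processing,
    foraging_analysis,
    mortality_analysis,
    space_overlap,
    strategy_clustering,
    synthetic_data,
    track_processing,
)

log = logging.getLogger("mirounga")

ALL_STAGES = ("simulate", "tracks", "dives", "forage", "energy", "cluster", "overlap", "mortality")

_KNOWN_KEYS = {
    "seed",
    "output_dir",
    "trip_days",
    "n_males",
    "n_females_pb",
    "n_females_pm",
    "stages",
    "filter",
    "detection",
    "classifier",
    "foraging",
    "overlap_cell_km",
    "depth_cell_km",
    "ud_levels",
    "planted_strategies",
}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/mirounga"
    trip_days: float | None = 6.0  # None = full-length default trips
    n_males: int = 4
    n_females_pb: int = 6
    n_females_pm: int = 4
    stages: tuple = ALL_STAGES
    filter: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    foraging: dict = field(default_factory=dict)
    overlap_cell_km: float = 5.0
    depth_cell_km: float = 0.05
    ud_levels: tuple = (0.95, 0.50)
    # use the generously separated three-strategy parameter sets
    planted_strategies: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> synthetic_data.SimConfig:
    n = {"male": cfg.n_males, "female_pb": cfg.n_females_pb, "female_pm": cfg.n_females_pm}
    maker = synthetic_data.planted_config if cfg.planted_strategies else synthetic_data.scaled_config
    return maker(seed=cfg.seed, trip_days=cfg.trip_days, n_per_strategy=n)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages in dependency order; returns all outputs."""
    t_start = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stages = tuple(cfg.stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")

    sim_cfg = _sim_config(cfg)
    geom = sim_cfg.geometry
    colony = (geom.colony_lat, geom.colony_lon)
    shelf_lats, shelf_lons = geom.shelf_polyline()

    def stage(name):
        return name in stages

    cohort = None
    if stage("simulate"):
        t0 = time.time()
        cohort = synthetic_data.simulate_cohort(sim_cfg)
        cohort.write(outdir / "simulated")
        results["cohort"] = cohort
        log.info("stage simulate done in %.1fs (%d deployments)", time.time() - t0, len(cohort.deployments))
    if cohort is None:
        raise ValueError("stages after 'simulate' need simulated inputs in this run")

    filt = track_processing.FilterParams(**cfg.filter) if cfg.filter else track_processing.FilterParams()
    hourly_by_dep = {}
    if stage("tracks"):
        t0 = time.time()
        for dep in cohort.deployments:
            fixes = cohort.fixes[cohort.fixes["deployment_id"] == dep.deployment_id]
            try:
                clean = track_processing.sda_filter(fixes, filt)
                hourly = track_processing.smooth_track(clean, colony=colony)
            except Exception as exc:  # halt with a named diagnostic
                raise RuntimeError(f"stage tracks failed for {dep.deployment_id}: {exc}") from exc
            hourly["deployment_id"] = dep.deployment_id
            hourly_by_dep[dep.deployment_id] = hourly
        pd.concat(hourly_by_dep.values(), ignore_index=True).to_csv(
            outdir / "hourly_positions.csv", index=False
        )
        results["hourly"] = hourly_by_dep
        log.info("stage tracks done in %.1fs", time.time() - t0)

    detection = dive_processing.DiveDetectionParams(**cfg.detection) if cfg.detection else None
    classifier = dive_processing.ClassifierParams(**cfg.classifier) if cfg.classifier else None
    dives_by_dep = {}
    if stage("dives"):
        t0 = time.time()
        for dep in cohort.deployments:
            hourly = hourly_by_dep.get(dep.deployment_id)
            dives = dive_processing.process_deployment(
                cohort.dive_series[dep.deployment_id],
                hourly=hourly,
                seafloor_fn=geom.seafloor_depth_m,
                detection=detection,
                classifier=classifier,
            )
            dives["deployment_id"] = dep.deployment_id
            dives_by_dep[dep.deployment_id] = dives
        pd.concat(dives_by_dep.values(), ignore_index=True).to_csv(
            outdir / "dive_records.csv", index=False
        )
        results["dives"] = dives_by_dep
        log.info("stage dives done in %.1fs", time.time() - t0)

    fparams = foraging_analysis.ForagingParams(**cfg.foraging) if cfg.foraging else foraging_analysis.ForagingParams()
    flags_by_dep = {}
    summaries = None
    if stage("forage"):
        t0 = time.time()
        rows = []
        ecoregions = geom.ecoregion_geojson()
        for dep in cohort.deployments:
            hourly = hourly_by_dep[dep.deployment_id]
            dives = dives_by_dep[dep.deployment_id]
            flags = foraging_analysis.detect_foraging_locations(hourly, dives, fparams)
            flags_by_dep[dep.deployment_id] = flags
            rows.append(
                foraging_analysis.trip_summary(
                    dep.deployment_id,
                    dep.sex,
                    dep.trip,
                    flags,
                    dives,
                    colony,
                    shelf_lats,
                    shelf_lons,
                    ecoregions,
                    fparams,
                )
            )
        summaries = foraging_analysis.trip_summary_table(rows)
        summaries.to_csv(outdir / "trip_summaries.csv", index=False)
        results["summaries"] = summaries
        results["flags"] = flags_by_dep
        log.info("stage forage done in %.1fs", time.time() - t0)

    if stage("energy"):
        t0 = time.time()
        erows = []
        for _, b in cohort.body.iterrows():
            did = b["deployment_id"]
            feeding_prop = (
                float(summaries.loc[summaries["deployment_id"] == did, "proportion_time_feeding"].iloc[0])
                if summaries is not None and did in set(summaries["deployment_id"])
                else 0.5
            )
            gain = bioenergetics.corrected_trip_gain(
                b["departure_mass_kg"],
                b["arrival_mass_measured_kg"],
                b["sex"],
                b["trip"],
                b["days_ashore"],
                pup_mass_kg=b["pup_mass_kg"],
            )
            budget = bioenergetics.foraging_success(
                b["departure_mass_kg"],
                gain,
                b["trip_days"],
                feeding_prop * b["trip_days"],
                b["adipose_fraction_of_gain"],
            )
            erows.append({"deployment_id": did, "sex": b["sex"], "trip": b["trip"],
                          **dataclasses.asdict(budget)})
        energy = pd.DataFrame(erows)
        energy.to_csv(outdir / "energy_budgets.csv", index=False)
        results["energy"] = energy
        log.info("stage energy done in %.1fs", time.time() - t0)

    if stage("cluster") and summaries is not None and len(summaries) >= 4:
        t0 = time.time()
        matrix = strategy_clustering.assemble_matrix(summaries)
        pca = strategy_clustering.run_pca(matrix)
        retained = pca.retained if len(pca.retained) else np.array([0])
        sol = strategy_clustering.cluster(pca.scores[:, retained])
        assign = pd.DataFrame(
            {
                "deployment_id": summaries.loc[matrix.index, "deployment_id"].to_numpy(),
                "cluster": sol.assignments,
            }
        )
        assign.to_csv(outdir / "cluster_assignments.csv", index=False)
        disc = strategy_clustering.discrimination_table(matrix, sol.assignments)
        disc.to_csv(outdir / "cluster_discrimination.csv", index=False)
        results["pca"] = pca
        results["clusters"] = sol
        results["assignments"] = assign
        log.info("stage cluster done in %.1fs (k=%d)", time.time() - t0, sol.k)

    if stage("overlap") and flags_by_dep:
        t0 = time.time()
        results["overlap"] = sex_overlap(
            cohort, flags_by_dep, dives_by_dep, cfg.overlap_cell_km, cfg.depth_cell_km, cfg.ud_levels
        )
        with open(outdir / "overlap.json", "w") as fh:
            json.dump(results["overlap"], fh, indent=2)
        log.info("stage overlap done in %.1fs", time.time() - t0)

    if stage("mortality"):
        t0 = time.time()
        attributed = mortality_analysis.attribute_cohort(
            cohort.fates.rename(columns={"trip_days": "trip_days"}),
            cohort.transmissions,
            cohort.resights,
        )
        attributed.to_csv(outdir / "tag_fate_attribution.csv", index=False)
        results["attributed"] = attributed
        results["accounting"] = mortality_analysis.cohort_accounting(attributed)
        models = None
        if attributed["died"].nunique() == 2:
            try:
                models = mortality_analysis.fit_mortality_models(attributed)
            except ValueError as exc:  # e.g. complete separation on tiny cohorts
                log.warning("mortality models skipped: %s", exc)
        if models is not None:
            ranking = pd.DataFrame(
                [
                    {"terms": "+".join(m.terms), "aic": m.aic, "delta_aic": m.delta_aic,
                     "lrt_p_vs_null": m.lrt_p_vs_null, "hosmer_lemeshow_p": m.hosmer_lemeshow_p}
                    for m in models
                ]
            )
            ranking.to_csv(outdir / "mortality_model_ranking.csv", index=False)
            results["mortality_models"] = models
            results["mortality_probability"] = {
                sex: mortality_analysis.mortality_probability(models[0], attributed, sex)
                for sex in ("male", "female")
            }
        log.info("stage mortality done in %.1fs", time.time() - t0)

    meta = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": list(stages),
        "elapsed_s": round(time.time() - t_start, 2),
        "bandwidth_rule_note": "UD bandwidths: diagonal plug-in (overlap stage); Silverman (trip areas)",
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    results["metadata"] = meta
    return results


def sex_overlap(cohort, flags_by_dep, dives_by_dep, cell_km, depth_cell_km, levels):
    """2D and 3D UD overlap between the sexes over foraging locations.

    The 3D dataset attaches the maximum foraging-dive depth (km) to each
    2D foraging location.  Returns a JSON-serializable summary.
    """
    from .geometry import AzimuthalEquidistant

    geom = cohort.config.geometry
    proj = AzimuthalEquidistant(geom.colony_lat, geom.colony_lon)
    pts2 = {"male": [], "female": []}
    pts3 = {"male": [], "female": []}
    sex_of = {d.deployment_id: d.sex for d in cohort.deployments}
    for did, flags in flags_by_dep.items():
        sex = sex_of[did]
        forage = flags[flags["is_foraging"]]
        if forage.empty:
            continue
        x, y = proj.to_xy(forage["lat"].to_numpy(float), forage["lon"].to_numpy(float))
        pts2[sex].append(np.column_stack([x, y]))
        dives = dives_by_dep.get(did)
        if dives is None or dives.empty:
            continue
        fd = dives[dives["dive_type"].isin(foraging_analysis.FORAGING_DIVE_TYPES)]
        if fd.empty:
            continue
        ts = forage["timestamp"].to_numpy().astype("datetime64[s]").astype(float)
        mid = fd["mid_timestamp"].to_numpy().astype("datetime64[s]").astype(float)
        idx = np.clip(np.round((mid - ts[0]) / 3600.0).astype(int), 0, len(forage) - 1)
        depth = np.zeros(len(forage))
        np.maximum.at(depth, idx, fd["max_depth_m"].to_numpy(float))
        has = depth > 0
        pts3[sex].append(np.column_stack([x[has], y[has], depth[has] / 1000.0]))
    out = {}
    for dims, pts, cells in (
        (2, pts2, (cell_km, cell_km)),
        (3, pts3, (cell_km, cell_km, depth_cell_km)),
    ):
        if not pts["male"] or not pts["female"]:
            continue
        male = np.vstack(pts["male"])
        female = np.vstack(pts["female"])
        if len(male) < 10 or len(female) < 10:
            continue
        gm = space_overlap.kde_ud(male, cell_sizes=cells)
        gf = space_overlap.kde_ud(female, cell_sizes=cells)
        for level in levels:
            ov = space_overlap.overlap(gm, gf, level=level)
            out[f"{dims}d_{int(level * 100)}"] = {
                "male_measure": ov.measure_a,
                "female_measure": ov.measure_b,
                "intersection": ov.intersection,
                "percent_overlap_male": ov.percent_overlap_a,
                "percent_overlap_female": ov.percent_overlap_b,
                "udoi": ov.udoi,
            }
    return out
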