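"""End-to-end orchestration: simulate -> phases -> fit -> validate ->
friction -> corridors -> road impact.

Each stage reads its upstream artifacts from the run directory, writes its
outputs plus a manifest (seed, parameter echo, input hashes) and is
deterministic for a fixed config: per-stage seeds are derived from the
master seed by hashing the stage name, so re-running any stage reproduces
it bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import models as mdl
from . import movement as mov
from . import simulate as sim
from .geo import density_isopleth, extract_covariates, minimum_convex_polygon
from .raster import LandscapeStack, Raster, VectorLayer
from .roads import corridor_overlap_length, paired_t_test, split_highways

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "derive_seed", "run_stage", "run_all", "STAGES"]


def derive_seed(master: int, tag: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of the full analysis, with the study defaults.

    Defaults follow the emulated study design wherever it states a value
    (availability ratio 10, 800/600 steps per animal, 10 random steps in
    50 m / 10 degree bins, 5-fold/10-bin RSF validation, 100-rep SSF
    validation, upper-quartile cores, 80 km pairing, 20 highway segments).
    ``cwd_cutoff`` is friction-scale dependent; the default suits the
    synthetic landscape (see docs/methods.md), the emulated study's
    200,000 applies to its own friction scale.
    """

    seed: int = 1
    out_dir: str = "run"
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    # RSF settings
    max_rsf_used: int = 3000
    availability_ratio: int = 10
    rsf_winter_terms: dict = field(
        default_factory=lambda: {
            "continuous": {"dem": True, "ruggedness": True, "ndvi_winter": True, "canopy": True},
            "categorical": {"landcover": 1.0},
        }
    )
    rsf_summer_terms: dict = field(
        default_factory=lambda: {
            "continuous": {"dem": True, "ruggedness": True, "ndvi_summer": True, "canopy": True},
            "categorical": {"landcover": 1.0},
        }
    )
    # SSF settings
    n_spring_steps: int = 800
    n_autumn_steps: int = 600
    broken_stick_bins: int = 50
    R_random_steps: int = 10
    bin_len: float = 50.0
    bin_turn: float = 10.0
    ssf_spring_terms: dict = field(
        default_factory=lambda: {
            "continuous": {
                "ruggedness": True,
                "canopy": True,
                "ndvi_summer": True,
                "dist_highway": True,
                "dist_gravel": True,
            },
            "categorical": {"landcover": 1.0},
        }
    )
    ssf_autumn_terms: dict = field(
        default_factory=lambda: {
            "continuous": {
                "ruggedness": True,
                "canopy": True,
                "ndvi_winter": True,
                "dist_highway": True,
                "dist_gravel": True,
            },
            "categorical": {"landcover": 1.0},
        }
    )
    road_caps: dict = field(default_factory=lambda: dict(sim.ROAD_CAPS))
    wald_alpha: float = 0.05
    # validation
    boyce_k: int = 5
    boyce_bins: int = 10
    fortin_reps: int = 100
    fortin_train_frac: float = 0.8
    # connectivity
    core_quantile: float = 0.75
    core_min_cells: int = 500  # 31 km^2 at 250 m cells: discrete seasonal ranges
    isopleth_level: float = 0.5
    max_pair_km: float = 80.0
    cwd_cutoff: float = 5_000.0  # CWD budget on the synthetic friction scale
    epsilon: float = 1e-6
    scenarios: tuple = ("actual", "no_roads")
    # road impact
    n_road_segments: int = 20

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(self.scenarios)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = sim.SimulationConfig(**d["sim"])
        if "scenarios" in d:
            d["scenarios"] = tuple(d["scenarios"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def path(self, *parts) -> str:
        return os.path.join(self.out_dir, *parts)

    def design_spec(self, terms: dict, caps: bool = True) -> mdl.DesignSpec:
        return mdl.DesignSpec(
            continuous=dict(terms.get("continuous", {})),
            categorical=dict(terms.get("categorical", {})),
            caps=dict(self.road_caps) if caps else {},
            ratio=self.availability_ratio,
        )


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------
def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, stage: str, inputs: list, params: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": derive_seed(config.seed, stage),
        "master_seed": config.seed,
        "params": params,
        "inputs": {os.path.basename(p): _sha256(p) for p in inputs if os.path.exists(p)},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(config.path(f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _require(config: PipelineConfig, stage: str, *paths) -> None:
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(
                f"stage {stage!r} needs missing artifact {p!r}; run its upstream stage first"
            )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def _stage_simulate(config: PipelineConfig) -> dict:
    os.makedirs(config.path("landscape"), exist_ok=True)
    scfg = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "simulate"))
    stack = sim.generate_landscape(scfg)
    stack.write(config.path("landscape"))
    # start animals in good winter habitat so residency ranges are coherent
    starts = sim.simulate_residency_fixes(
        stack, scfg.beta_rsf_winter, scfg.n_animals, seed=derive_seed(config.seed, "start-draw")
    )
    tracks = sim.simulate_tracks(stack, scfg, starts, seed=derive_seed(config.seed, "tracks"))
    sim.write_telemetry_csv(tracks, config.path("telemetry.csv"))
    truth = pd.concat(
        {
            "rsf_winter": pd.Series(scfg.beta_rsf_winter),
            "rsf_summer": pd.Series(scfg.beta_rsf_summer),
            "ssf_spring": pd.Series(scfg.beta_ssf_spring),
            "ssf_autumn": pd.Series(scfg.beta_ssf_autumn),
        },
        names=["model", "term"],
    )
    truth.rename("beta").to_csv(config.path("true_beta.csv"))
    _write_manifest(config, "simulate", [], {"n_animals": scfg.n_animals, "extent": [scfg.n_rows, scfg.n_cols]})
    return {"n_fixes": len(tracks), "n_animals": tracks["animal_id"].nunique()}


def _stage_phases(config: PipelineConfig) -> dict:
    _require(config, "phases", config.path("telemetry.csv"))
    tracks = sim.read_telemetry_csv(config.path("telemetry.csv"))
    tracks = mov.assign_phase(tracks)
    steps = mov.compute_steps(tracks, nominal_interval=config.sim.fix_interval)
    steps.to_csv(config.path("steps.csv"), index=False)
    _write_manifest(config, "phases", [config.path("telemetry.csv")], {})
    return {"n_steps": len(steps)}


def _load_stack(config: PipelineConfig) -> LandscapeStack:
    return LandscapeStack.read(config.path("landscape"))


def _fit_one_rsf(config: PipelineConfig, season: str) -> dict:
    stage = f"rsf_{season}"
    _require(config, stage, config.path("telemetry.csv"), config.path("landscape"))
    stack = _load_stack(config)
    tracks = mov.assign_phase(sim.read_telemetry_csv(config.path("telemetry.csv")))
    window = "winter_residency" if season == "winter" else "summer_residency"
    used_fixes = tracks[tracks[f"in_{window}"]]
    rng = np.random.default_rng(derive_seed(config.seed, f"{stage}-thin"))
    if len(used_fixes) > config.max_rsf_used:
        used_fixes = used_fixes.iloc[
            np.sort(rng.choice(len(used_fixes), size=config.max_rsf_used, replace=False))
        ]
    mcp = minimum_convex_polygon(tracks[["x", "y"]].to_numpy())
    avail_pts = mdl.sample_availability(
        used_fixes[["x", "y"]].to_numpy(),
        mcp,
        ratio=config.availability_ratio,
        seed=derive_seed(config.seed, f"{stage}-avail"),
    )
    used = extract_covariates(used_fixes[["x", "y"]].to_numpy(), stack)
    used["animal_id"] = used_fixes["animal_id"].to_numpy()
    avail = extract_covariates(avail_pts, stack)
    avail["animal_id"] = np.resize(used["animal_id"].to_numpy(), len(avail))
    used = used[~used["missing"]]
    avail = avail[~avail["missing"]]

    terms = config.rsf_winter_terms if season == "winter" else config.rsf_summer_terms
    spec = config.design_spec(terms, caps=False)
    pooled = pd.concat([used, avail], ignore_index=True)
    keep, drops = mdl.screen_collinearity(pooled[list(spec.continuous)])
    spec.continuous = {k: v for k, v in spec.continuous.items() if k in keep}

    model = mdl.fit_rsf(used, avail, spec)
    model, trace = mdl.eliminate_by_wald(
        model, lambda s: mdl.fit_rsf(used, avail, s), alpha=config.wald_alpha
    )
    model.meta["collinearity_drops"] = drops
    model.meta["elimination_trace"] = [[t, float(p)] for t, p in trace]
    model.to_json(config.path(f"{stage}_model.json"))
    coef = pd.DataFrame({"beta": model.beta, "se": model.se, "p": model.wald_p()})
    coef.to_csv(config.path(f"{stage}_coefficients.csv"))
    used.to_csv(config.path(f"{stage}_used.csv"), index=False)
    avail.to_csv(config.path(f"{stage}_available.csv"), index=False)
    _write_manifest(
        config,
        stage,
        [config.path("telemetry.csv")],
        {"n_used": len(used), "ratio": config.availability_ratio, "dropped": drops},
    )
    return {"terms": list(model.beta.index), "loglik": model.loglik}


def _stage_rsf_winter(config: PipelineConfig) -> dict:
    return _fit_one_rsf(config, "winter")


def _stage_rsf_summer(config: PipelineConfig) -> dict:
    return _fit_one_rsf(config, "summer")


def _fit_one_ssf(config: PipelineConfig, season: str) -> dict:
    stage = f"ssf_{season}"
    _require(config, stage, config.path("steps.csv"), config.path("landscape"))
    stack = _load_stack(config)
    steps = pd.read_csv(config.path("steps.csv"), parse_dates=["t_start", "t_end"])
    window = "in_spring_movement" if season == "spring" else "in_autumn_movement"
    phase_steps = steps[steps[window]]
    n_per = config.n_spring_steps if season == "spring" else config.n_autumn_steps
    sub = mov.subsample_steps(phase_steps, n_per, seed=derive_seed(config.seed, f"{stage}-sub"))
    fit = mov.broken_stick_threshold(sub["speed"].to_numpy(), n_bins=config.broken_stick_bins)
    long_steps = mov.filter_long_steps(phase_steps, fit)
    strata = mdl.sample_random_steps(
        long_steps,
        R=config.R_random_steps,
        bin_len=config.bin_len,
        bin_turn=config.bin_turn,
        seed=derive_seed(config.seed, f"{stage}-random-steps"),
        stack=stack,
    )
    cov = extract_covariates(strata[["x_end", "y_end"]].to_numpy(), stack)
    strata = pd.concat([strata.reset_index(drop=True), cov.reset_index(drop=True)], axis=1)
    # drop strata touching nodata cells
    bad = strata.loc[strata["missing"], "stratum_id"].unique()
    strata = strata[~strata["stratum_id"].isin(bad)]

    terms = config.ssf_spring_terms if season == "spring" else config.ssf_autumn_terms
    spec = config.design_spec(terms)
    keep, drops = mdl.screen_collinearity(strata[list(spec.continuous)])
    spec.continuous = {k: v for k, v in spec.continuous.items() if k in keep}

    model = mdl.fit_ssf(strata, spec)
    model, trace = mdl.eliminate_by_wald(
        model, lambda s: mdl.fit_ssf(strata, s), alpha=config.wald_alpha
    )
    model.meta["broken_stick_threshold"] = fit.threshold
    model.meta["collinearity_drops"] = drops
    model.meta["elimination_trace"] = [[t, float(p)] for t, p in trace]
    model.to_json(config.path(f"{stage}_model.json"))
    pd.DataFrame({"beta": model.beta, "se": model.se, "p": model.wald_p()}).to_csv(
        config.path(f"{stage}_coefficients.csv")
    )
    strata.to_csv(config.path(f"{stage}_strata.csv"), index=False)
    _write_manifest(
        config,
        stage,
        [config.path("steps.csv")],
        {"threshold_m_per_min": fit.threshold, "n_strata": int(strata["stratum_id"].nunique())},
    )
    return {"threshold": fit.threshold, "n_strata": int(strata["stratum_id"].nunique())}


def _stage_ssf_spring(config: PipelineConfig) -> dict:
    return _fit_one_ssf(config, "spring")


def _stage_ssf_autumn(config: PipelineConfig) -> dict:
    return _fit_one_ssf(config, "autumn")


def _stage_validation(config: PipelineConfig) -> dict:
    out = {}
    for season in ("winter", "summer"):
        stage = f"rsf_{season}"
        _require(
            config,
            "validation",
            config.path(f"{stage}_model.json"),
            config.path(f"{stage}_used.csv"),
            config.path(f"{stage}_available.csv"),
        )
        model = mdl.FittedModel.from_json(config.path(f"{stage}_model.json"))
        used = pd.read_csv(config.path(f"{stage}_used.csv"))
        avail = pd.read_csv(config.path(f"{stage}_available.csv"))
        rhos = mdl.boyce_cv(
            used,
            avail,
            model.spec,
            k=config.boyce_k,
            n_bins=config.boyce_bins,
            seed=derive_seed(config.seed, f"boyce-{season}"),
        )
        out[f"boyce_{season}"] = rhos
    for season in ("spring", "autumn"):
        stage = f"ssf_{season}"
        _require(config, "validation", config.path(f"{stage}_strata.csv"), config.path(f"{stage}_model.json"))
        strata = pd.read_csv(config.path(f"{stage}_strata.csv"))
        model = mdl.FittedModel.from_json(config.path(f"{stage}_model.json"))
        out[f"fortin_{season}"] = mdl.fortin_cv(
            strata,
            model.spec,
            train_frac=config.fortin_train_frac,
            reps=config.fortin_reps,
            seed=derive_seed(config.seed, f"fortin-{season}"),
        )
    with open(config.path("validation.json"), "w") as fh:
        json.dump(out, fh, indent=1)
    _write_manifest(config, "validation", [], {"boyce_k": config.boyce_k, "fortin_reps": config.fortin_reps})
    return out


def _stage_friction(config: PipelineConfig) -> dict:
    stack = _load_stack(config)
    written = []
    for season in ("spring", "autumn"):
        _require(config, "friction", config.path(f"ssf_{season}_model.json"))
        model = mdl.FittedModel.from_json(config.path(f"ssf_{season}_model.json"))
        for scenario in config.scenarios:
            if scenario == "actual":
                surface = conn.prediction_surface(model, stack)
            else:
                surface = conn.no_roads_surface(model, stack, caps=config.road_caps)
            fr = conn.friction_from_surface(
                surface, epsilon=config.epsilon, scenario=scenario, season=season
            )
            path = config.path(f"friction_{season}_{scenario}.asc")
            fr.raster.write_ascii(path)
            written.append(path)
    _write_manifest(config, "friction", written, {"epsilon": config.epsilon})
    return {"rasters": [os.path.basename(p) for p in written]}


def _core_sets(config: PipelineConfig, stack: LandscapeStack) -> dict:
    """Winter cores (RSF quantile + 50% winter-fix isopleths) and summer cores."""
    cores = {}
    for season in ("winter", "summer"):
        model = mdl.FittedModel.from_json(config.path(f"rsf_{season}_model.json"))
        surface = conn.prediction_surface(model, stack)
        cores[season] = conn.extract_cores(
            surface, quantile=config.core_quantile, min_cells=config.core_min_cells
        )
    tracks = mov.assign_phase(sim.read_telemetry_csv(config.path("telemetry.csv")))
    winter_fixes = tracks[tracks["in_winter_residency"]][["x", "y"]].to_numpy()
    if len(winter_fixes) >= 10:
        cores["winter"] = cores["winter"] + density_isopleth(
            winter_fixes, config.isopleth_level, stack.grid
        )
    return cores


def _stage_corridors(config: PipelineConfig) -> dict:
    _require(
        config,
        "corridors",
        config.path("rsf_winter_model.json"),
        config.path("rsf_summer_model.json"),
        config.path("friction_spring_actual.asc"),
    )
    stack = _load_stack(config)
    cores = _core_sets(config, stack)
    summary = {}
    for season, (src, dst) in {
        "spring": ("winter", "summer"),
        "autumn": ("summer", "winter"),
    }.items():
        for scenario in config.scenarios:
            fr_path = config.path(f"friction_{season}_{scenario}.asc")
            _require(config, "corridors", fr_path)
            fr = conn.FrictionSurface(
                Raster.read_ascii(fr_path), scenario=scenario, season=season, epsilon=config.epsilon
            )
            cs = conn.build_corridors(
                fr,
                cores[src],
                cores[dst],
                max_km=config.max_pair_km,
                cwd_cutoff=config.cwd_cutoff,
            )
            tag = f"{season}_{scenario}"
            if cs.mosaic is not None:
                cs.mosaic.write_ascii(config.path(f"corridor_mosaic_{tag}.asc"))
                cs.cwd_mosaic.write_ascii(config.path(f"corridor_cwd_{tag}.asc"))
                cs.cropped().write_ascii(config.path(f"corridor_cropped_{tag}.asc"))
            summary[tag] = {
                "n_pairs": len(cs.pairs),
                "n_cores_from": len(cores[src]),
                "n_cores_to": len(cores[dst]),
            }
    with open(config.path("corridors.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    _write_manifest(config, "corridors", [], {"cwd_cutoff": config.cwd_cutoff})
    return summary


def _stage_roads(config: PipelineConfig) -> dict:
    _require(config, "roads", config.path("landscape", "highways.geojson"))
    highways = VectorLayer.read_geojson(config.path("landscape", "highways.geojson"))
    segments = split_highways(highways, n_segments=config.n_road_segments)
    report = {}
    rows = []
    for season in ("spring", "autumn"):
        overlaps = {}
        for scenario in config.scenarios:
            path = config.path(f"corridor_cropped_{season}_{scenario}.asc")
            _require(config, "roads", path)
            corridor = Raster.read_ascii(path)
            overlaps[scenario] = corridor_overlap_length(segments, corridor)
        actual = [o.length_in_corridor for o in overlaps["actual"]]
        counterfactual = [o.length_in_corridor for o in overlaps["no_roads"]]
        t, df, p = paired_t_test(actual, counterfactual)
        report[season] = {
            "total_km_actual": float(np.sum(actual)),
            "total_km_no_roads": float(np.sum(counterfactual)),
            "t": t,
            "df": df,
            "p": p,
        }
        for o_a, o_n in zip(overlaps["actual"], overlaps["no_roads"]):
            rows.append(
                {
                    "season": season,
                    "segment_id": o_a.segment_id,
                    "length_total_km": o_a.length_total,
                    "length_in_corridor_actual_km": o_a.length_in_corridor,
                    "length_in_corridor_no_roads_km": o_n.length_in_corridor,
                }
            )
    pd.DataFrame(rows).to_csv(config.path("segment_overlaps.csv"), index=False)
    with open(config.path("road_impact.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    lines = ["Corridor-highway permeability (paired t-test, actual vs no-roads)"]
    for season, r in report.items():
        lines.append(
            f"  {season}: {r['total_km_actual']:.1f} km vs {r['total_km_no_roads']:.1f} km, "
            f"t = {r['t']:.3f}, df = {r['df']}, p = {r['p']:.4g}"
        )
    with open(config.path("road_impact.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    _write_manifest(config, "roads", [], {"n_segments": config.n_road_segments})
    return report


STAGES = {
    "simulate": _stage_simulate,
    "phases": _stage_phases,
    "rsf_winter": _stage_rsf_winter,
    "rsf_summer": _stage_rsf_summer,
    "ssf_spring": _stage_ssf_spring,
    "ssf_autumn": _stage_ssf_autumn,
    "validation": _stage_validation,
    "friction": _stage_friction,
    "corridors": _stage_corridors,
    "roads": _stage_roads,
}


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one named stage; artifacts land under ``config.out_dir``."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; valid stages: {', '.join(STAGES)}")
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    result = STAGES[name](config)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)
    return result


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and return the per-stage summaries."""
    os.makedirs(config.out_dir, exist_ok=True)
    config.save(os.path.join(config.out_dir, "config.yaml"))
    results = {}
    for name in STAGES:
        try:
            results[name] = run_stage(name, config)
        except Exception:
            log.error("stage %s failed; see traceback", name)
            raise
    with open(config.path("summary.json"), "w") as fh:
        json.dump(results, fh, indent=1, default=str)
    return results
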