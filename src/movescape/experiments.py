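"""Self-contained validation experiments on the synthetic world.

Each experiment generates its own inputs from a seed, runs the relevant
pipeline stages and returns the measured quantities.  They back the
property-based acceptance checks and the narrative examples:

* parameter recovery for the residency (RSF) and movement (SSF) models,
* calibration of both cross-validation procedures,
* the roads-vs-no-roads corridor permeability comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import models as mdl
from . import simulate as sim
from .connectivity import (
    build_corridors,
    extract_cores,
    friction_from_surface,
    no_roads_surface,
    prediction_surface,
)
from .geo import extract_covariates
from .pipeline import derive_seed
from .roads import corridor_overlap_length, paired_t_test, split_highways

__all__ = [
    "ROAD_DOMINATED_BETA",
    "recover_rsf",
    "recover_ssf",
    "road_counterfactual",
]

#: Stated world for the road-barrier experiment: road avoidance dominates
#: habitat effects, so the highway is a genuine movement barrier.
ROAD_DOMINATED_BETA = {
    "canopy": 0.05,
    "ndvi_summer": 0.05,
    "dist_highway": 3.0,
    "dist_gravel": 1.0,
}


def _truth_design_rows(stack, beta, points):
    """Covariates at points, transformed to the generator's truth scale
    (capped road distances, z-standardized over valid cells)."""
    rows = extract_covariates(points, stack)
    z = sim.standardized_covariates(stack, list(beta))
    grid = stack.grid
    r, c, _ = grid.index_of(points[:, 0], points[:, 1])
    return pd.DataFrame({name: z[name][r, c] for name in beta}), rows


def recover_rsf(seed: int, n_used: int = 5000, config: sim.SimulationConfig | None = None) -> dict:
    """Simulate residency fixes with known coefficients and refit the RSF.

    Used points are drawn with density proportional to exp(beta.x); the
    availability sample is uniform over valid cells.  Covariates enter on
    the generator's truth scale, so the fitted coefficients estimate beta
    directly.  Returns per-term estimates, standard errors and whether the
    95% CI covers truth.
    """
    config = config or sim.SimulationConfig()
    config = dataclasses.replace(config, seed=derive_seed(seed, "rsf-landscape"))
    stack = sim.generate_landscape(config)
    beta = config.beta_rsf_winter
    used_pts = sim.simulate_residency_fixes(stack, beta, n_used, seed=derive_seed(seed, "rsf-used"))
    avail_pts = sim.simulate_residency_fixes(
        stack, {k: 0.0 for k in beta}, 10 * n_used, seed=derive_seed(seed, "rsf-avail")
    )
    rng = np.random.default_rng(derive_seed(seed, "rsf-ids"))
    zu, _ = _truth_design_rows(stack, beta, used_pts)
    za, _ = _truth_design_rows(stack, beta, avail_pts)
    zu["animal_id"] = rng.integers(config.n_animals, size=len(zu))
    za["animal_id"] = rng.integers(config.n_animals, size=len(za))
    spec = mdl.DesignSpec(
        continuous={k: False for k in beta}, intercept=True, standardize=False
    )
    model = mdl.fit_rsf(zu.dropna(), za.dropna(), spec)
    out = {"beta_true": dict(beta), "beta_hat": {}, "se": {}, "covered": {}, "sign_ok": {}}
    for term, b in beta.items():
        bh, se = model.beta[term], model.se[term]
        out["beta_hat"][term] = float(bh)
        out["se"][term] = float(se)
        out["covered"][term] = bool(abs(bh - b) <= 1.96 * se)
        out["sign_ok"][term] = bool(np.sign(bh) == np.sign(b))
    return out


def recover_ssf(seed: int, config: sim.SimulationConfig | None = None, R: int = 10) -> dict:
    """Simulate one year of travel for all animals and refit the spring SSF.

    Tracks are generated with known step-selection coefficients and the
    generator records each travel step's candidate choice set.  The
    conditional logit is fitted on the chosen endpoint plus ``R`` candidates
    sampled from the rest of its own choice set (uniform sampling of
    alternatives keeps the estimator consistent), with covariates on the
    generator's truth scale.  The pipeline's empirical matched-step
    availability is deliberately *not* used here: rebuilding availability
    from observed (already selected) steps attenuates coefficients, a known
    property of step-selection designs, documented in the methods note.
    """
    config = config or sim.SimulationConfig()
    config = dataclasses.replace(config, seed=derive_seed(seed, "ssf-landscape"))
    stack = sim.generate_landscape(config)
    beta = config.beta_ssf_spring
    starts = sim.simulate_residency_fixes(
        stack, config.beta_rsf_winter, config.n_animals, seed=derive_seed(seed, "ssf-starts")
    )
    _, candidates = sim.simulate_tracks(
        stack, config, starts, seed=derive_seed(seed, "ssf-tracks"), record_candidates=True
    )
    cand = candidates[candidates["regime"] == "spring"]
    rng = np.random.default_rng(derive_seed(seed, "ssf-thin"))
    rows = []
    for sid, g in cand.groupby("stratum_id"):
        g = g.reset_index(drop=True)
        chosen = int(g["chosen"].idxmax())
        others = rng.choice([i for i in g.index if i != chosen], size=R, replace=False)
        rows.append(g.loc[[chosen, *others]].assign(used=[1] + [0] * R))
    strata = pd.concat(rows, ignore_index=True)
    pts = strata[["x_end", "y_end"]].to_numpy()
    z, _ = _truth_design_rows(stack, beta, pts)
    strata = pd.concat([strata.reset_index(drop=True), z.reset_index(drop=True)], axis=1)
    bad = strata.loc[strata[list(beta)].isna().any(axis=1), "stratum_id"].unique()
    strata = strata[~strata["stratum_id"].isin(bad)]
    spec = mdl.DesignSpec(continuous={k: False for k in beta}, standardize=False)
    model = mdl.fit_ssf(strata, spec)
    # profile-likelihood intervals: the short-capped gravel-road distance is
    # informative in few strata, where Wald intervals undercover
    ci = mdl.ssf_profile_ci(strata, spec, model)
    out = {
        "n_strata": int(strata["stratum_id"].nunique()),
        "beta_true": dict(beta),
        "beta_hat": {},
        "se": {},
        "ci": {},
        "covered": {},
        "sign_ok": {},
    }
    for term, b in beta.items():
        bh, se = model.beta[term], model.se[term]
        out["beta_hat"][term] = float(bh)
        out["se"][term] = float(se)
        out["ci"][term] = (float(ci.loc[term, "lo"]), float(ci.loc[term, "hi"]))
        out["covered"][term] = bool(ci.loc[term, "lo"] <= b <= ci.loc[term, "hi"])
        out["sign_ok"][term] = bool(np.sign(bh) == np.sign(b))
    return out


def road_counterfactual(
    seed: int,
    cwd_cutoff: float = 5000.0,
    min_cells: int = 1000,
    n_segments: int = 20,
    config: sim.SimulationConfig | None = None,
) -> dict:
    """Corridor-highway permeability with and without the road barrier.

    A landscape is generated; movement selection follows the road-dominated
    coefficients (strong avoidance of both road classes, weak habitat
    effects).  Corridors between upper-quartile winter and summer cores are
    cropped at the CWD budget under the actual and the no-roads friction,
    and per-segment highway overlap lengths are compared by paired t-test.
    """
    config = config or sim.SimulationConfig()
    config = dataclasses.replace(config, seed=derive_seed(seed, "road-landscape"))
    stack = sim.generate_landscape(config)
    move_model = sim.true_selection_model(stack, ROAD_DOMINATED_BETA)
    fr_actual = friction_from_surface(prediction_surface(move_model, stack))
    fr_counter = friction_from_surface(
        no_roads_surface(move_model, stack), scenario="no_roads"
    )
    cores_w = extract_cores(
        prediction_surface(sim.true_selection_model(stack, config.beta_rsf_winter), stack),
        quantile=0.75,
        min_cells=min_cells,
    )
    cores_s = extract_cores(
        prediction_surface(sim.true_selection_model(stack, config.beta_rsf_summer), stack),
        quantile=0.75,
        min_cells=min_cells,
    )
    segs = split_highways(stack.vectors["highways"], n_segments)
    out = {}
    overlaps = {}
    for scen, fr in (("actual", fr_actual), ("no_roads", fr_counter)):
        cs = build_corridors(fr, cores_w, cores_s, max_km=80.0, cwd_cutoff=cwd_cutoff)
        overlaps[scen] = [o.length_in_corridor for o in corridor_overlap_length(segs, cs.cropped())]
        out[f"total_km_{scen}"] = float(np.sum(overlaps[scen]))
        out[f"n_pairs_{scen}"] = len(cs.pairs)
    t, df, p = paired_t_test(overlaps["actual"], overlaps["no_roads"])
    out.update({"t": t, "df": df, "p": p})
    return out
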