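"""Selection models: design construction, RSF/SSF estimation and both
cross-validation procedures, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from shapely.geometry import Polygon

import movescape.models as mdl
from movescape.models import (
    DesignSpec,
    boyce_cv,
    build_design,
    eliminate_by_wald,
    fit_rsf,
    fit_ssf,
    fortin_cv,
    rsf_score,
    sample_availability,
    sample_random_steps,
    screen_collinearity,
)


def simulate_used_available(beta, n_used=1500, ratio=10, seed=0, n_animals=8):
    """Logistic-selection oracle data: availability ~ N(0, I); used points
    accepted proportionally to exp(beta.x) by rejection sampling."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    beta = np.asarray(beta, dtype=float)
    avail = rng.normal(size=(n_used * ratio, p))
    cand = rng.normal(size=(n_used * 40, p))
    w = np.exp(cand @ beta)
    keep = rng.uniform(size=len(cand)) < w / w.max()
    used = cand[keep][:n_used]
    cols = [f"x{i}" for i in range(p)]
    u = pd.DataFrame(used, columns=cols)
    a = pd.DataFrame(avail, columns=cols)
    u["animal_id"] = rng.integers(n_animals, size=len(u))
    a["animal_id"] = rng.integers(n_animals, size=len(a))
    return u, a, cols


def make_strata(beta, n_strata=300, R=10, seed=0):
    """Conditional-choice oracle data: R+1 candidates per stratum, the used
    one drawn with probability softmax(beta.x)."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    beta = np.asarray(beta, dtype=float)
    rows = []
    for s in range(n_strata):
        X = rng.normal(size=(R + 1, p))
        pr = np.exp(X @ beta)
        pr /= pr.sum()
        pick = rng.choice(R + 1, p=pr)
        for j in range(R + 1):
            row = {"stratum_id": s, "used": int(j == pick), "animal_id": s % 5}
            row.update({f"x{i}": X[j, i] for i in range(p)})
            rows.append(row)
    return pd.DataFrame(rows), [f"x{i}" for i in range(p)]


def spec_for(cols, quad=False, standardize=False):
    return DesignSpec(continuous={c: quad for c in cols}, standardize=standardize)


class TestScreenCollinearity:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        t = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        kept, log = screen_collinearity(t)
        assert kept == ["a", "c"]

    def test_independent_all_kept(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        kept, _ = screen_collinearity(t)
        assert kept == list("abcd")

    def test_near_collinear_dropped_per_oracle(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=300)
        x2 = x1 + 0.3 * rng.normal(size=300)
        t = pd.DataFrame({"x1": x1, "x2": x2, "x3": rng.normal(size=300)})
        r = np.corrcoef(x1, x2)[0, 1]
        kept, _ = screen_collinearity(t)
        if abs(r) > 0.7:
            assert "x2" not in kept and "x1" in kept
        else:
            assert set(kept) == {"x1", "x2", "x3"}

    def test_vif_agrees_with_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(3)
        z = rng.normal(size=(300, 2))
        t = pd.DataFrame(
            {"a": z[:, 0], "b": z[:, 1], "c": z[:, 0] + z[:, 1] + 0.4 * rng.normal(size=300)}
        )
        X = np.column_stack([np.ones(len(t)), t.to_numpy()])
        sm_vif = {c: variance_inflation_factor(X, i + 1) for i, c in enumerate(t.columns)}
        kept, dropped = screen_collinearity(t, vif_max=3.0)
        worst = max(sm_vif, key=sm_vif.get)
        if sm_vif[worst] > 3:
            assert worst not in kept

    def test_constant_column_warned_out(self):
        t = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0), "c": np.arange(50.0) ** 2})
        kept, log = screen_collinearity(t)
        assert "a" not in kept


class TestBuildDesign:
    def test_road_caps(self):
        spec = DesignSpec(
            continuous={"dist_highway": False, "dist_gravel": False},
            caps={"dist_highway": 2000.0, "dist_gravel": 1000.0},
            standardize=False,
        )
        rows = pd.DataFrame({"dist_highway": [5000.0, 100.0], "dist_gravel": [1500.0, 20.0]})
        X, _, _ = build_design(rows, spec)
        assert X["dist_highway"].tolist() == [2000.0, 100.0]
        assert X["dist_gravel"].tolist() == [1000.0, 20.0]

    def test_reference_category_all_zero(self):
        spec = DesignSpec(categorical={"landcover": 1.0})
        rows = pd.DataFrame({"landcover": [1.0, 3.0, 1.0]})
        X, _, terms = build_design(rows, spec)
        dummies = terms["landcover"]["columns"]
        assert (X.loc[[0, 2], dummies].to_numpy() == 0).all()
        assert X.loc[1, "landcover[3.0]"] == 1.0

    def test_unseen_level_rejected(self):
        spec = DesignSpec(categorical={"lc": "conifer"})
        X, st, _ = build_design(pd.DataFrame({"lc": ["conifer", "bog"]}), spec)
        with pytest.raises(ValueError, match="unseen"):
            build_design(pd.DataFrame({"lc": ["alpine"]}), spec, stats_in=st)

    def test_standardization_learned_then_applied(self):
        spec = DesignSpec(continuous={"a": True})
        train = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
        X, st, _ = build_design(train, spec)
        X2, _, _ = build_design(pd.DataFrame({"a": [2.0]}), spec, stats_in=st)
        assert X2["a"].iloc[0] == pytest.approx(0.0)
        assert X2["a^2"].iloc[0] == pytest.approx(0.0)


class TestSampleAvailability:
    def test_count_and_containment(self):
        poly = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        pts = sample_availability(np.zeros((100, 2)), poly, ratio=10, seed=0)
        assert pts.shape == (1000, 2)
        assert (pts >= 0).all() and (pts <= 100).all()

    def test_uniformity_chi2(self):
        poly = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        pts = sample_availability(np.zeros((4000, 2)), poly, ratio=10, seed=1)
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=4, range=[[0, 100], [0, 100]])
        e = len(pts) / 16
        chi2 = ((counts - e) ** 2 / e).sum()
        assert stats.chi2.sf(chi2, df=15) > 0.01

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            sample_availability(np.zeros((5, 2)), Polygon([(0, 0), (1, 1), (2, 2)]), seed=0)


class TestFitRsf:
    def test_single_animal_equals_plain_logistic(self):
        u, a, cols = simulate_used_available([0.8, -0.5], n_used=800, n_animals=1, seed=4)
        spec = spec_for(cols)
        m = fit_rsf(u, a, spec)
        m2 = fit_rsf(u, a, spec, method="logistic")
        assert np.allclose(m.beta.to_numpy(), m2.beta.to_numpy(), atol=1e-6)

    def test_null_simulation_betas_near_zero(self):
        rng = np.random.default_rng(8)
        cols = ["x0", "x1"]
        u = pd.DataFrame(rng.normal(size=(800, 2)), columns=cols)
        a = pd.DataFrame(rng.normal(size=(4000, 2)), columns=cols)
        u["animal_id"] = rng.integers(6, size=len(u))
        a["animal_id"] = rng.integers(6, size=len(a))
        m = fit_rsf(u, a, spec_for(cols))
        for c in cols:
            assert abs(m.beta[c]) <= 2 * m.se[c]

    def test_recovery_coverage(self):
        """2-se intervals cover the truth at roughly their nominal rate."""
        beta = [0.8, -0.5, 0.3]
        covered = total = 0
        for seed in range(6):
            u, a, cols = simulate_used_available(beta, n_used=2500, seed=seed)
            m = fit_rsf(u, a, spec_for(cols), method="logistic")
            for c, b in zip(cols, beta):
                covered += abs(m.beta[c] - b) <= 2 * m.se[c]
                total += 1
        assert covered / total >= 0.85

    def test_agrees_with_lme4_glmer(self, tmp_path):
        """Independent mixed-model oracle: lme4::glmer on the same data."""
        rng = np.random.default_rng(21)
        n, n_animals = 1200, 6
        x = rng.normal(size=n)
        animal = rng.integers(n_animals, size=n)
        u_re = rng.normal(0, 0.8, size=n_animals)
        eta = -1.0 + 0.9 * x + u_re[animal]
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame({"x0": x, "animal_id": animal, "y": y.astype(int)})
        m = fit_rsf(df[df.y == 1], df[df.y == 0], spec_for(["x0"]))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        import subprocess

        r = subprocess.run(
            [
                "Rscript",
                "-e",
                f'd <- read.csv("{csv}"); suppressMessages(library(lme4));'
                'm <- glmer(y ~ x0 + (1 | animal_id), data=d, family=binomial());'
                'cat(fixef(m)["x0"], sqrt(diag(vcov(m)))["x0"], as.numeric(VarCorr(m)$animal_id))',
            ],
            capture_output=True,
            text=True,
            timeout=300,
        )
        b_r, se_r, var_r = map(float, r.stdout.split())
        assert m.beta["x0"] == pytest.approx(b_r, abs=0.02)
        assert m.se["x0"] == pytest.approx(se_r, rel=0.15)
        assert m.random_intercept_variance == pytest.approx(var_r, rel=0.25)


class TestEliminateByWald:
    def test_intercept_only_unchanged(self):
        rng = np.random.default_rng(0)
        u = pd.DataFrame({"animal_id": np.zeros(200, dtype=int)})
        a = pd.DataFrame({"animal_id": np.zeros(800, dtype=int)})
        spec = DesignSpec()
        m = fit_rsf(u, a, spec, method="logistic")
        out, trace = eliminate_by_wald(m, lambda s: fit_rsf(u, a, s, method="logistic"))
        assert trace == [] and list(out.beta.index) == ["Intercept"]

    def test_strong_terms_survive_noise_dropped(self):
        beta = [1.0, -0.8, 0.0]
        u, a, cols = simulate_used_available(beta, n_used=2500, seed=14)
        spec = spec_for(cols)
        m = fit_rsf(u, a, spec, method="logistic")
        out, trace = eliminate_by_wald(
            m, lambda s: fit_rsf(u, a, s, method="logistic")
        )
        assert "x0" in out.beta.index and "x1" in out.beta.index

    def test_quadratic_drops_before_linear(self):
        beta = [0.9]
        u, a, cols = simulate_used_available(beta, n_used=3000, seed=15)
        spec = spec_for(cols, quad=True)
        m = fit_rsf(u, a, spec, method="logistic")
        out, trace = eliminate_by_wald(m, lambda s: fit_rsf(u, a, s, method="logistic"))
        if trace:
            assert trace[0][0] == "x0^2"


class TestRsfScore:
    def test_examples(self):
        u, a, cols = simulate_used_available([0.5], n_used=300, seed=3)
        m = fit_rsf(u, a, spec_for(cols), method="logistic")
        m.beta[:] = 0.0
        assert np.allclose(rsf_score(m, a), 1.0)
        m.beta["x0"] = np.log(2.0)
        rows = pd.DataFrame({"x0": [0.0, 1.0], "animal_id": [0, 0]})
        s = rsf_score(m, rows)
        assert np.allclose(s, [0.5, 1.0])
        assert rsf_score(m, a).max() == 1.0


class TestBoyceCV:
    def test_informative_model_high_rho(self):
        u, a, cols = simulate_used_available([1.5], n_used=5000, seed=16)
        rhos = boyce_cv(u, a, spec_for(cols), seed=0, method="logistic")
        assert np.mean(rhos) >= 0.9

    def test_determinism(self):
        u, a, cols = simulate_used_available([1.0], n_used=600, seed=17)
        r1 = boyce_cv(u, a, spec_for(cols), seed=5, method="logistic")
        r2 = boyce_cv(u, a, spec_for(cols), seed=5, method="logistic")
        assert r1 == r2


class TestSampleRandomSteps:
    def _long_steps(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        lengths = rng.exponential(3000, size=n)
        turns = np.degrees(rng.vonmises(0, 4, size=n))
        bearing = np.cumsum(turns)
        x0, y0 = rng.uniform(2e4, 6e4, size=(2, n))
        return pd.DataFrame(
            {
                "animal_id": "a",
                "x_start": x0,
                "y_start": y0,
                "x_end": x0 + lengths * np.cos(np.radians(bearing)),
                "y_end": y0 + lengths * np.sin(np.radians(bearing)),
                "length": lengths,
                "turn_angle": turns % 360 - 180,
            }
        )

    def test_stratum_composition(self):
        strata = sample_random_steps(self._long_steps(), R=10, seed=0)
        sizes = strata.groupby("stratum_id").size()
        assert (sizes == 11).all()
        assert (strata.groupby("stratum_id")["used"].sum() == 1).all()

    def test_drawn_lengths_follow_source_bins(self):
        src = self._long_steps(n=500, seed=1)
        strata = sample_random_steps(src, R=10, bin_len=50.0, seed=2)
        drawn = strata.loc[strata["used"] == 0, "length"].to_numpy()
        edges = np.arange(0, src["length"].max() + 50.0, 50.0)
        p_src, _ = np.histogram(src["length"], bins=edges)
        c_drawn, _ = np.histogram(drawn, bins=edges)
        exp = p_src / p_src.sum() * len(drawn)
        keep = exp >= 5
        chi2 = ((c_drawn[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_forward_concentration_preserved(self):
        rng = np.random.default_rng(3)
        src = self._long_steps(n=500, seed=4)
        src["turn_angle"] = np.degrees(rng.vonmises(0, 6, size=len(src)))
        strata = sample_random_steps(src, R=10, seed=5)
        drawn = strata.loc[strata["used"] == 0, "turn_angle"].to_numpy()
        assert np.abs(drawn) .mean() < 60  # concentrated forward, not uniform (90)


class TestFitSsf:
    def test_null_loglik_exact(self):
        strata, cols = make_strata([0.0], n_strata=60, seed=5)
        m = fit_ssf(strata, spec_for(cols))
        assert m.meta["loglik_null"] == pytest.approx(60 * np.log(1 / 11), abs=1e-9)

    def test_matches_1d_likelihood_scan(self):
        """Newton solution equals a brute-force scan of the explicit
        conditional-logit likelihood, to 1e-6."""
        strata, cols = make_strata([0.7], n_strata=3, R=1, seed=6)
        m = fit_ssf(strata, spec_for(cols))
        x = strata[cols[0]].to_numpy().reshape(3, 2)
        used = strata["used"].to_numpy().reshape(3, 2).argmax(axis=1)

        def nll(b):
            e = b * x
            return -(e[np.arange(3), used] - np.log(np.exp(e).sum(axis=1))).sum()

        grid = np.linspace(-10, 10, 4001)
        b0 = grid[np.argmin([nll(b) for b in grid])]
        res = optimize.minimize_scalar(nll, bounds=(b0 - 0.1, b0 + 0.1), method="bounded",
                                       options={"xatol": 1e-10})
        assert m.beta[cols[0]] == pytest.approx(res.x, abs=1e-6)
        assert m.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_recovery_and_agreement_with_survival_clogit(self, tmp_path):
        strata, cols = make_strata([0.8, -0.5], n_strata=400, seed=7)
        m = fit_ssf(strata, spec_for(cols))
        assert abs(m.beta["x0"] - 0.8) <= 2.5 * m.se["x0"]
        assert abs(m.beta["x1"] + 0.5) <= 2.5 * m.se["x1"]
        csv = tmp_path / "s.csv"
        strata.to_csv(csv, index=False)
        import subprocess

        r = subprocess.run(
            [
                "Rscript",
                "-e",
                f'd <- read.csv("{csv}"); suppressMessages(library(survival));'
                'm <- clogit(used ~ x0 + x1 + strata(stratum_id), data=d);'
                'cat(coef(m), sqrt(diag(vcov(m))))',
            ],
            capture_output=True,
            text=True,
            timeout=300,
        )
        b0, b1, s0, s1 = map(float, r.stdout.split())
        assert m.beta["x0"] == pytest.approx(b0, abs=1e-5)
        assert m.beta["x1"] == pytest.approx(b1, abs=1e-5)
        assert m.se["x0"] == pytest.approx(s0, rel=1e-3)

    def test_stratum_constant_shift_invariance(self):
        """Shifting a covariate by a per-stratum constant leaves the fit
        unchanged (the conditional likelihood cannot see it)."""
        strata, cols = make_strata([0.6], n_strata=100, seed=8)
        m1 = fit_ssf(strata, spec_for(cols))
        shifted = strata.copy()
        offsets = {s: o for s, o in zip(range(100), np.random.default_rng(0).normal(size=100))}
        shifted[cols[0]] = shifted[cols[0]] + shifted["stratum_id"].map(offsets)
        m2 = fit_ssf(shifted, spec_for(cols))
        assert m1.beta[cols[0]] == pytest.approx(m2.beta[cols[0]], abs=1e-8)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-8)

    def test_profile_ci_matches_wald_when_well_identified(self):
        from movescape.models import ssf_profile_ci

        strata, cols = make_strata([0.8, -0.5], n_strata=300, seed=7)
        m = fit_ssf(strata, spec_for(cols))
        ci = ssf_profile_ci(strata, spec_for(cols), m)
        for c in cols:
            assert ci.loc[c, "lo"] == pytest.approx(m.beta[c] - 1.96 * m.se[c], abs=0.02)
            assert ci.loc[c, "hi"] == pytest.approx(m.beta[c] + 1.96 * m.se[c], abs=0.02)
            assert ci.loc[c, "lo"] < m.beta[c] < ci.loc[c, "hi"]

    def test_firth_shrinks_toward_zero(self):
        strata, cols = make_strata([0.8], n_strata=150, seed=3)
        m0 = fit_ssf(strata, spec_for(cols))
        m1 = fit_ssf(strata, spec_for(cols), firth=True)
        assert 0 < m1.beta[cols[0]] <= m0.beta[cols[0]] + 1e-9

    def test_cluster_robust_se_available(self):
        strata, cols = make_strata([0.6], n_strata=120, seed=4)
        m = fit_ssf(strata, spec_for(cols), robust_cluster="animal_id")
        assert m.meta["robust_cluster"] == "animal_id"
        assert np.isfinite(m.se[cols[0]]) and m.se[cols[0]] > 0

    def test_stratum_constant_covariate_rejected(self):
        strata, cols = make_strata([0.5], n_strata=50, seed=9)
        strata["const"] = strata["stratum_id"] * 1.0
        with pytest.raises(ValueError, match="constant within every stratum"):
            fit_ssf(strata, spec_for(cols + ["const"]))


class TestFortinCV:
    def test_decisive_covariate_strong_negative_rho(self):
        strata, cols = make_strata([2.0], n_strata=400, seed=10)
        out = fortin_cv(strata, spec_for(cols), reps=10, seed=0)
        assert out["mean"] <= -0.9  # rank 1 = highest score convention

    def test_null_ci_contains_zero(self):
        strata, cols = make_strata([1.5], n_strata=150, seed=11)
        out = fortin_cv(strata, spec_for(cols), reps=25, seed=1)
        lo, hi = out["null_ci"]
        assert lo <= 0.0 <= hi

    def test_determinism(self):
        strata, cols = make_strata([1.0], n_strata=80, seed=12)
        a = fortin_cv(strata, spec_for(cols), reps=5, seed=3)
        b = fortin_cv(strata, spec_for(cols), reps=5, seed=3)
        assert a == b
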