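"""Habitat-selection models: used-available RSFs and matched-step SSFs.

Both model families share the exponential form

    w(x) = exp(b1*x1 + b2*x2 + ... + bi*xi)

where ``w(x)`` is proportional to the probability of selecting resource
unit ``x``.  The resource selection function (RSF) is estimated from used
vs available locations with a binomial GLMM carrying a per-animal random
intercept (Laplace approximation); the step selection function (SSF) is a
conditional logistic regression in which each observed travel step is
contrasted with matched random steps sharing its start point, strata
treated independently.

Model evaluation follows two case-control cross-validation designs: the
5-fold area-adjusted-frequency procedure of Boyce for RSFs, and the
rank-of-used-step procedure of Fortin for SSFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import optimize, stats
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "FittedModel",
    "screen_collinearity",
    "build_design",
    "sample_availability",
    "fit_rsf",
    "fit_ssf",
    "eliminate_by_wald",
    "rsf_score",
    "boyce_cv",
    "sample_random_steps",
    "fortin_cv",
]


# ---------------------------------------------------------------------------
# design specification and construction
# ---------------------------------------------------------------------------
@dataclass
class DesignSpec:
    """Model terms and how they enter the design matrix.

    ``continuous`` maps a covariate name to whether its quadratic is
    included; ``categorical`` maps a covariate to its reference level;
    ``caps`` gives per-term ceilings (metres) applied before
    standardization — road effects are held at level beyond the distance
    where traffic stops influencing behaviour (2 km highways, 1 km gravel).
    """

    continuous: dict = field(default_factory=dict)  # name -> include quadratic?
    categorical: dict = field(default_factory=dict)  # name -> reference level
    caps: dict = field(default_factory=dict)  # name -> cap (m)
    ratio: int = 10  # availability points per used point
    intercept: bool = True
    standardize: bool = True

    def term_names(self) -> list[str]:
        return list(self.continuous) + list(self.categorical)


def build_design(rows: pd.DataFrame, spec: DesignSpec, stats_in: dict | None = None):
    """Design matrix from covariate rows.

    Continuous terms are capped (where a cap is specified), standardized
    (mean/sd learned from ``rows`` unless ``stats_in`` carries training
    statistics) and optionally squared; categorical terms are dummy-coded
    against their reference level.  Returns ``(X, stats, terms)`` where
    ``terms`` maps each model term to its design columns.
    """
    learn = stats_in is None
    st = {"mu": {}, "sd": {}, "levels": {}, "zlo": {}, "zhi": {}} if learn else stats_in
    cols: dict[str, np.ndarray] = {}
    terms: dict[str, dict] = {}
    if spec.intercept:
        cols["Intercept"] = np.ones(len(rows))
        terms["Intercept"] = {"columns": ["Intercept"], "kind": "intercept"}
    for name, quad in spec.continuous.items():
        if name not in rows:
            raise KeyError(f"design term {name!r} missing from rows")
        v = rows[name].to_numpy(dtype=float)
        if name in spec.caps:
            v = np.minimum(v, spec.caps[name])
        if spec.standardize:
            if learn:
                st["mu"][name] = float(v.mean())
                st["sd"][name] = float(v.std()) or 1.0
            v = (v - st["mu"][name]) / st["sd"][name]
            if learn:
                st["zlo"][name] = float(v.min())
                st["zhi"][name] = float(v.max())
            else:
                # never extrapolate beyond the training range: quadratic
                # terms explode on unseen extremes when mapped over a grid
                lo = st.get("zlo", {}).get(name)
                if lo is not None:
                    v = np.clip(v, lo, st["zhi"][name])
        cols[name] = v
        tcols = [name]
        if quad:
            cols[f"{name}^2"] = v**2
            tcols.append(f"{name}^2")
        terms[name] = {"columns": tcols, "kind": "continuous", "quadratic": quad}
    for name, ref in spec.categorical.items():
        if name not in rows:
            raise KeyError(f"design term {name!r} missing from rows")
        v = rows[name].to_numpy()
        if learn:
            st["levels"][name] = sorted(set(v.tolist()) | {ref})
        levels = st["levels"][name]
        unseen = set(v.tolist()) - set(levels)
        if unseen:
            raise ValueError(f"unseen {name} level(s) at prediction time: {sorted(unseen)}")
        tcols = []
        for lev in levels:
            if lev == ref:
                continue
            cname = f"{name}[{lev}]"
            cols[cname] = (v == lev).astype(float)
            tcols.append(cname)
        terms[name] = {"columns": tcols, "kind": "categorical", "reference": ref}
    X = pd.DataFrame(cols, index=rows.index)
    return X, st, terms


def screen_collinearity(
    table: pd.DataFrame, r_max: float = 0.7, vif_max: float = 3.0
) -> tuple[list[str], list[str]]:
    """Drop collinear covariates: pairwise |r| then variance inflation.

    First, for every pair with |Pearson r| > ``r_max`` the later column (the
    lower-priority member of the pair — callers order columns by priority)
    is dropped; then the highest-VIF covariate is dropped repeatedly until
    all VIF <= ``vif_max``.  Returns the retained names and a drop log.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to screen collinearity")
    dropped: list[str] = []
    names = []
    for c in table.columns:
        if table[c].std() == 0:
            log.warning("constant covariate %s dropped", c)
            dropped.append(f"{c}: constant")
        else:
            names.append(c)
    # pairwise correlation screen
    changed = True
    while changed:
        changed = False
        corr = table[names].corr().abs()
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if corr.loc[a, b] > r_max:
                    names.remove(b)
                    dropped.append(f"{b}: |r|={corr.loc[a, b]:.3f} with {a}")
                    changed = True
                    break
            if changed:
                break
    # VIF screen
    def vif(name, others):
        y = table[name].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y))] + [table[o].to_numpy(dtype=float) for o in others])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return 1.0 / max(1 - r2, 1e-12)

    while len(names) > 1:
        vifs = {n: vif(n, [o for o in names if o != n]) for n in names}
        worst = max(vifs, key=vifs.get)
        if vifs[worst] <= vif_max:
            break
        names.remove(worst)
        dropped.append(f"{worst}: VIF={vifs[worst]:.2f}")
    return names, dropped


def sample_availability(
    used_points: np.ndarray, mcp: Polygon, ratio: int = 10, seed: int = 0
) -> np.ndarray:
    """Uniform availability sample: ``ratio`` random points per used point
    inside the 100% minimum convex polygon."""
    if mcp.area <= 0:
        raise ValueError("degenerate availability polygon")
    n = int(ratio * len(used_points))
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = mcp.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(n - len(out), 1000)
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, size=2 * m), rng.uniform(ymin, ymax, size=2 * m)]
        )
        inside = shapely.contains_xy(mcp, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    return out[:n]


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------
@dataclass
class FittedModel:
    """Estimated selection model: coefficients, uncertainty and metadata."""

    beta: pd.Series
    se: pd.Series
    loglik: float
    vcov: pd.DataFrame
    model_kind: str  # "rsf_glmm" | "rsf_logistic" | "ssf_clogit"
    spec: DesignSpec
    stats: dict
    terms: dict
    random_intercept_variance: float | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        payload = {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "loglik": None if not np.isfinite(self.loglik) else self.loglik,
            "vcov": {"index": list(self.vcov.index), "values": self.vcov.to_numpy().tolist()},
            "model_kind": self.model_kind,
            "spec": {
                "continuous": self.spec.continuous,
                "categorical": self.spec.categorical,
                "caps": self.spec.caps,
                "ratio": self.spec.ratio,
                "intercept": self.spec.intercept,
                "standardize": self.spec.standardize,
            },
            "stats": self.stats,
            "terms": self.terms,
            "random_intercept_variance": self.random_intercept_variance,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        import json

        with open(path) as fh:
            d = json.load(fh)
        idx = d["vcov"]["index"]
        return cls(
            beta=pd.Series(d["beta"]).reindex(idx),
            se=pd.Series(d["se"]).reindex(idx),
            loglik=d["loglik"] if d["loglik"] is not None else np.nan,
            vcov=pd.DataFrame(d["vcov"]["values"], index=idx, columns=idx),
            model_kind=d["model_kind"],
            spec=DesignSpec(**d["spec"]),
            stats=d["stats"],
            terms=d["terms"],
            random_intercept_variance=d["random_intercept_variance"],
            meta=d["meta"],
        )

    def wald_p(self) -> pd.Series:
        z = self.beta / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.beta.index)

    def block_p(self, columns) -> float:
        """Wald chi-square test that a block of coefficients is zero.

        Falls back to the largest per-column Wald p when the covariance
        block is singular or non-finite (ill-conditioned fits).
        """
        b = self.beta[columns].to_numpy()
        V = self.vcov.loc[columns, columns].to_numpy()
        if np.all(np.isfinite(b)) and np.all(np.isfinite(V)):
            try:
                W = float(b @ np.linalg.solve(V, b))
                if W >= 0:
                    return float(stats.chi2.sf(W, df=len(columns)))
            except np.linalg.LinAlgError:
                pass
        return float(self.wald_p()[columns].max())

    def design(self, rows: pd.DataFrame) -> pd.DataFrame:
        X, _, _ = build_design(rows, self.spec, stats_in=self.stats)
        return X[self.beta.index]

    def linear_predictor(self, rows: pd.DataFrame, include_intercept: bool = True) -> np.ndarray:
        X = self.design(rows)
        b = self.beta.copy()
        if not include_intercept and "Intercept" in b.index:
            b["Intercept"] = 0.0
        return X.to_numpy() @ b.to_numpy()


def rsf_score(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Relative selection scores w(x)=exp(b.x) (no intercept), rescaled so
    the maximum over the scored set is exactly 1."""
    lin = model.linear_predictor(rows, include_intercept=False)
    w = np.exp(lin - np.nanmax(lin))
    return w


# ---------------------------------------------------------------------------
# plain and mixed logistic regression (RSF)
# ---------------------------------------------------------------------------
def _sigmoid(eta):
    return 0.5 * (1 + np.tanh(0.5 * eta))


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Newton-Raphson logistic regression; returns (beta, vcov, loglik)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError as e:
            raise RuntimeError("singular information matrix in logistic fit") from e
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if np.max(np.abs(beta)) > 50:
        big = int(np.argmax(np.abs(beta)))
        raise RuntimeError(
            f"logistic fit diverged (possible complete separation) on column index {big}"
        )
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    mu = _sigmoid(eta)
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    vcov = np.linalg.inv(H)
    return beta, vcov, ll


def _cluster_robust_vcov(X, y, beta, vcov, clusters):
    mu = _sigmoid(X @ beta)
    U = X * (y - mu)[:, None]
    df = pd.DataFrame(U)
    df["c"] = clusters
    S = df.groupby("c").sum().to_numpy()
    meat = S.T @ S
    return vcov @ meat @ vcov


def _laplace_loglik(theta, X, y, cluster_idx, n_clusters, u_cache):
    """Laplace-approximated marginal loglik of the random-intercept logistic
    model; inner Newton for the per-cluster modes is warm-started."""
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma2 = np.exp(2 * log_sigma)
    eta0 = X @ beta
    u = u_cache.copy()
    for _ in range(50):
        eta = eta0 + u[cluster_idx]
        mu = _sigmoid(eta)
        g = np.bincount(cluster_idx, weights=y - mu, minlength=n_clusters) - u / sigma2
        h = np.bincount(cluster_idx, weights=mu * (1 - mu), minlength=n_clusters) + 1 / sigma2
        step = g / h
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    u_cache[:] = u
    eta = eta0 + u[cluster_idx]
    mu = _sigmoid(eta)
    ll_data = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    h = np.bincount(cluster_idx, weights=mu * (1 - mu), minlength=n_clusters) + 1 / sigma2
    ll = ll_data - float(np.sum(u**2) / (2 * sigma2)) - 0.5 * float(np.sum(np.log(sigma2 * h)))
    return ll


def _num_hess(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_rsf(
    used: pd.DataFrame,
    available: pd.DataFrame,
    spec: DesignSpec,
    method: str = "glmm",
) -> FittedModel:
    """Used-available RSF: binomial GLMM with a per-animal random intercept.

    ``used`` and ``available`` carry covariate columns plus ``animal_id``.
    The mixed model is maximised under the Laplace approximation; when the
    intercept-variance estimate collapses to zero the fit falls back to
    plain logistic regression with cluster-robust (per-animal) standard
    errors, flagged in ``meta['fallback']``.  ``method='logistic'`` forces
    the fallback path.
    """
    if len(used) == 0 or len(available) == 0:
        raise ValueError("both used and available samples must be non-empty")
    rows = pd.concat([used, available], ignore_index=True)
    y = np.concatenate([np.ones(len(used)), np.zeros(len(available))])
    X, st, terms = build_design(rows, spec)
    Xv = X.to_numpy()
    clusters = rows["animal_id"].to_numpy() if "animal_id" in rows else np.zeros(len(rows))
    codes, uniq = pd.factorize(clusters)
    meta: dict = {"n_used": len(used), "n_available": len(available)}

    def finish_logistic(note):
        beta, vcov, ll = _logistic_fit(Xv, y)
        rvcov = _cluster_robust_vcov(Xv, y, beta, vcov, clusters) if len(uniq) > 1 else vcov
        meta["fallback"] = note
        return FittedModel(
            beta=pd.Series(beta, index=X.columns),
            se=pd.Series(np.sqrt(np.diag(rvcov)), index=X.columns),
            loglik=ll,
            vcov=pd.DataFrame(rvcov, index=X.columns, columns=X.columns),
            model_kind="rsf_logistic",
            spec=spec,
            stats=st,
            terms=terms,
            random_intercept_variance=0.0,
            meta=meta,
        )

    if method == "logistic" or len(uniq) < 2:
        return finish_logistic("logistic requested" if method == "logistic" else "single cluster")

    beta0, _, _ = _logistic_fit(Xv, y)
    u_cache = np.zeros(len(uniq))
    obj = lambda th: -_laplace_loglik(th, Xv, y, codes, len(uniq), u_cache)
    th0 = np.concatenate([beta0, [np.log(0.3)]])
    res = optimize.minimize(obj, th0, method="L-BFGS-B", options={"maxiter": 300})
    p = Xv.shape[1]
    sigma2 = float(np.exp(2 * res.x[p]))
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError("GLMM optimisation failed to converge")
    if sigma2 < 1e-6:
        return finish_logistic("intercept variance estimated at zero")
    H = _num_hess(lambda th: _laplace_loglik(th, Xv, y, codes, len(uniq), u_cache), res.x)
    try:
        vcov_full = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov_full = np.linalg.pinv(-H)
    vcov = vcov_full[:p, :p]
    beta = res.x[:p]
    if np.max(np.abs(beta)) > 50:
        bad = X.columns[int(np.argmax(np.abs(beta)))]
        raise RuntimeError(f"non-convergence (possible complete separation) on term {bad!r}")
    diag = np.diag(vcov).copy()
    diag[diag < 0] = np.nan
    return FittedModel(
        beta=pd.Series(beta, index=X.columns),
        se=pd.Series(np.sqrt(diag), index=X.columns),
        loglik=float(-res.fun),
        vcov=pd.DataFrame(vcov, index=X.columns, columns=X.columns),
        model_kind="rsf_glmm",
        spec=spec,
        stats=st,
        terms=terms,
        random_intercept_variance=sigma2,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# conditional logistic regression (SSF)
# ---------------------------------------------------------------------------
def _clogit_loglik_parts(beta, X, strata_slices, used_pos):
    eta = X @ beta
    sizes = {b - a for a, b in strata_slices}
    if len(sizes) == 1:
        # balanced strata: fully vectorised over (stratum, candidate)
        m = sizes.pop()
        S = len(strata_slices)
        E = eta.reshape(S, m)
        Xs = X.reshape(S, m, X.shape[1])
        mx = E.max(axis=1, keepdims=True)
        w = np.exp(E - mx)
        tot = w.sum(axis=1, keepdims=True)
        pr = w / tot
        used = np.asarray(used_pos)
        ll = float(np.sum(E[np.arange(S), used] - (mx[:, 0] + np.log(tot[:, 0]))))
        xbar = np.einsum("sm,smp->sp", pr, Xs)
        grad = Xs[np.arange(S), used].sum(axis=0) - xbar.sum(axis=0)
        H = -(np.einsum("smp,sm,smq->pq", Xs, pr, Xs) - xbar.T @ xbar)
        return ll, grad, H
    ll = 0.0
    grad = np.zeros(X.shape[1])
    H = np.zeros((X.shape[1], X.shape[1]))
    for (a, b), u in zip(strata_slices, used_pos):
        e = eta[a:b]
        m = e.max()
        w = np.exp(e - m)
        s = w.sum()
        pr = w / s
        ll += e[u] - (m + np.log(s))
        Xs = X[a:b]
        xbar = pr @ Xs
        grad += Xs[u] - xbar
        H -= (Xs * pr[:, None]).T @ Xs - np.outer(xbar, xbar)
    return ll, grad, H


def fit_ssf(
    strata: pd.DataFrame,
    spec: DesignSpec,
    robust_cluster: str | None = None,
    firth: bool = False,
) -> FittedModel:
    """Conditional logistic SSF over matched strata.

    ``strata`` has one row per (used or random) step with ``stratum_id``, a
    boolean/0-1 ``used`` column and covariates.  Maximises the conditional
    likelihood  prod_s exp(b.x_used) / sum_j exp(b.x_j)  by Newton-Raphson;
    standard errors come from the observed information.  The intercept (and
    any stratum-constant covariate) is unidentifiable and excluded.

    Strata contributed by the same animal are not independent (consecutive
    steps share terrain).  Passing ``robust_cluster`` (a column name,
    typically ``'animal_id'``) replaces the information-based covariance
    with a cluster-robust sandwich, the standard correction for matched
    step designs; the information-based ``vcov`` remains in
    ``meta['vcov_information']``.

    ``firth=True`` applies Firth's bias-reducing score modification
    (penalizing by half the log determinant of the information), which
    removes the order-1/n bias of the MLE — material when a covariate is
    informative in only a small fraction of strata, e.g. a short-capped
    road distance.
    """
    spec = replace(spec, intercept=False)
    df = strata.sort_values(["stratum_id"]).reset_index(drop=True)
    n_strata = df["stratum_id"].nunique()
    if n_strata < 3:
        raise ValueError("need at least 3 strata")
    X, st, terms = build_design(df, spec)
    Xv = X.to_numpy()
    # stratum bookkeeping
    sid = df["stratum_id"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1], True])
    strata_slices = list(zip(bounds[:-1], bounds[1:]))
    usedv = df["used"].to_numpy().astype(bool)
    used_pos = []
    for a, b in strata_slices:
        w = np.flatnonzero(usedv[a:b])
        if len(w) != 1:
            raise ValueError("each stratum must contain exactly one used step")
        used_pos.append(int(w[0]))
    # a covariate constant within every stratum is inestimable
    for c in X.columns:
        v = X[c].to_numpy()
        if all(np.ptp(v[a:b]) == 0 for a, b in strata_slices):
            raise ValueError(f"term {c!r} is constant within every stratum and inestimable")
    beta = np.zeros(Xv.shape[1])
    loglik_null, _, _ = _clogit_loglik_parts(beta, Xv, strata_slices, used_pos)

    def firth_adjustment(b, H):
        # a_k = 1/2 tr(H^-1 dH/db_k), dH by central differences
        p = len(b)
        a = np.zeros(p)
        Hinv = np.linalg.inv(H)
        eps = 1e-5
        for k in range(p):
            e = np.zeros(p)
            e[k] = eps
            _, _, Hp = _clogit_loglik_parts(b + e, Xv, strata_slices, used_pos)
            _, _, Hm = _clogit_loglik_parts(b - e, Xv, strata_slices, used_pos)
            a[k] = 0.5 * np.trace(Hinv @ ((Hp - Hm) / (2 * eps)))
        return a

    for _ in range(60):
        ll, grad, H = _clogit_loglik_parts(beta, Xv, strata_slices, used_pos)
        if firth:
            grad = grad + firth_adjustment(beta, H)
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError as e:
            raise RuntimeError("singular information in conditional logit") from e
        beta = beta - step
        if np.max(np.abs(step)) < (1e-8 if firth else 1e-11):
            break
    ll, _, H = _clogit_loglik_parts(beta, Xv, strata_slices, used_pos)
    vcov = np.linalg.inv(-H)
    meta = {"n_strata": n_strata, "loglik_null": float(loglik_null)}
    if robust_cluster is not None:
        # per-stratum scores, summed within cluster: sandwich H^-1 M H^-1
        eta = Xv @ beta
        scores = np.empty((len(strata_slices), Xv.shape[1]))
        clusters = np.empty(len(strata_slices), dtype=object)
        cl = df[robust_cluster].to_numpy()
        for k, ((a, b), u) in enumerate(zip(strata_slices, used_pos)):
            e = eta[a:b]
            w = np.exp(e - e.max())
            pr = w / w.sum()
            scores[k] = Xv[a:b][u] - pr @ Xv[a:b]
            clusters[k] = cl[a]
        sdf = pd.DataFrame(scores)
        sdf["c"] = clusters
        S = sdf.groupby("c").sum().to_numpy()
        meat = S.T @ S
        meta["vcov_information"] = vcov.tolist()
        meta["robust_cluster"] = robust_cluster
        vcov = vcov @ meat @ vcov
    return FittedModel(
        beta=pd.Series(beta, index=X.columns),
        se=pd.Series(np.sqrt(np.diag(vcov)), index=X.columns),
        loglik=float(ll),
        vcov=pd.DataFrame(vcov, index=X.columns, columns=X.columns),
        model_kind="ssf_clogit",
        spec=spec,
        stats=st,
        terms=terms,
        meta=meta,
    )


def ssf_profile_ci(
    strata: pd.DataFrame, spec: DesignSpec, model: FittedModel, level: float = 0.95
) -> pd.DataFrame:
    """Profile-likelihood confidence intervals for a fitted conditional logit.

    Wald intervals rely on a quadratic log-likelihood, which fails for
    covariates informative in few strata; the profile interval inverts the
    likelihood-ratio test instead: bounds are where the profile
    log-likelihood drops by chi2_{1,level}/2 from the maximum.  Returns a
    frame with ``lo``/``hi`` per coefficient.
    """
    spec = replace(spec, intercept=False)
    df = strata.sort_values(["stratum_id"]).reset_index(drop=True)
    X, _, _ = build_design(df, spec, stats_in=model.stats)
    X = X[model.beta.index]
    Xv = X.to_numpy()
    sid = df["stratum_id"].to_numpy()
    bounds_ix = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1], True])
    slices = list(zip(bounds_ix[:-1], bounds_ix[1:]))
    usedv = df["used"].to_numpy().astype(bool)
    used_pos = [int(np.flatnonzero(usedv[a:b])[0]) for a, b in slices]
    beta_hat = model.beta.to_numpy().astype(float)
    ll_max, _, _ = _clogit_loglik_parts(beta_hat, Xv, slices, used_pos)
    drop = 0.5 * stats.chi2.ppf(level, df=1)
    p = len(beta_hat)

    def profile_ll(k, val, start):
        """Maximize over the other coefficients with beta_k fixed."""
        free = [i for i in range(p) if i != k]
        b = start.copy()
        b[k] = val
        for _ in range(40):
            _, g, H = _clogit_loglik_parts(b, Xv, slices, used_pos)
            gf = g[free]
            Hf = H[np.ix_(free, free)]
            step = np.linalg.solve(Hf - 1e-10 * np.eye(len(free)), gf)
            b[free] = b[free] - step
            if np.max(np.abs(step)) < 1e-9:
                break
        ll, _, _ = _clogit_loglik_parts(b, Xv, slices, used_pos)
        return ll, b

    out = {}
    for k, name in enumerate(model.beta.index):
        se = model.se.iloc[k] if np.isfinite(model.se.iloc[k]) else 0.1
        ci = []
        for direction in (-1.0, 1.0):
            lo_val = beta_hat[k]
            ll_lo = ll_max
            b_warm = beta_hat.copy()
            hi_val = beta_hat[k]
            # march outward until the LR bound is bracketed
            for _ in range(60):
                hi_val = hi_val + direction * 0.5 * se
                ll_hi, b_warm = profile_ll(k, hi_val, b_warm)
                if ll_max - ll_hi >= drop:
                    break
                lo_val, ll_lo = hi_val, ll_hi
            # bisect the crossing
            for _ in range(30):
                mid = 0.5 * (lo_val + hi_val)
                ll_mid, b_warm = profile_ll(k, mid, b_warm)
                if ll_max - ll_mid >= drop:
                    hi_val = mid
                else:
                    lo_val = mid
                if abs(hi_val - lo_val) < 1e-4 * max(se, 1e-6):
                    break
            ci.append(0.5 * (lo_val + hi_val))
        out[name] = {"lo": min(ci), "hi": max(ci)}
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------
def eliminate_by_wald(model: FittedModel, refit, alpha: float = 0.05):
    """Backward elimination on Wald statistics.

    ``refit`` is a callable ``spec -> FittedModel``.  At each round the
    least-significant droppable unit with p > alpha is removed and the model
    refitted: a quadratic column drops before its linear term, a categorical
    term drops as a block, the intercept never drops.  Ties on p are broken
    by the larger standard error.  Returns ``(final_model, trace)``.
    """
    trace: list[tuple[str, float]] = []
    while True:
        pvals = model.wald_p()
        candidates: list[tuple[float, float, str, str]] = []  # (-p, -se, unit, kind)
        for name, info in model.terms.items():
            if info["kind"] == "intercept" or not info["columns"]:
                continue
            if info["kind"] == "continuous":
                col = info["columns"][-1]  # quadratic before linear
                candidates.append((pvals[col], model.se[col], name, "quad" if info.get("quadratic") else "linear"))
            else:
                candidates.append((model.block_p(info["columns"]), 0.0, name, "categorical"))
        droppable = [c for c in candidates if c[0] > alpha]
        if not droppable:
            return model, trace
        p, _, unit, kind = max(droppable, key=lambda c: (c[0], c[1]))
        spec = model.spec
        if kind == "quad":
            new_cont = dict(spec.continuous)
            new_cont[unit] = False
            spec = replace(spec, continuous=new_cont)
            trace.append((f"{unit}^2", p))
        elif kind == "linear":
            new_cont = {k: v for k, v in spec.continuous.items() if k != unit}
            spec = replace(spec, continuous=new_cont)
            trace.append((unit, p))
        else:
            new_cat = {k: v for k, v in spec.categorical.items() if k != unit}
            spec = replace(spec, categorical=new_cat)
            trace.append((unit, p))
        if not spec.continuous and not spec.categorical:
            return model if not spec.intercept else refit(spec), trace
        model = refit(spec)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------
def boyce_cv(
    used: pd.DataFrame,
    available: pd.DataFrame,
    spec: DesignSpec,
    k: int = 5,
    n_bins: int = 10,
    seed: int = 0,
    method: str = "glmm",
) -> list[float]:
    """Boyce-style k-fold cross-validation of an RSF.

    Used points are split into ``k`` folds; for each fold the model is
    refitted on the remaining folds (with the full availability sample),
    scores of the withheld used points and of the availability sample are
    binned into ``n_bins`` quantile bins of the availability scores, and
    the Spearman rank correlation between bin rank and area-adjusted
    frequency (withheld-used frequency / available frequency per bin) is
    returned per fold.
    """
    if len(used) < k * n_bins:
        raise ValueError("too few used points for the requested folds and bins")
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(len(used)) % k)
    rhos = []
    for f in range(k):
        train = used[fold != f]
        test = used[fold == f]
        m = fit_rsf(train, available, spec, method=method)
        # linear predictors: same scale for both samples, and quantile bins
        # plus Spearman are invariant to the monotone exp transform
        s_avail = m.linear_predictor(available, include_intercept=False)
        s_test = m.linear_predictor(test, include_intercept=False)
        edges = np.unique(np.quantile(s_avail, np.linspace(0, 1, n_bins + 1)))
        if len(edges) - 1 < n_bins:
            log.info("boyce_cv: %d empty/tied bins merged", n_bins - (len(edges) - 1))
        edges[0], edges[-1] = -np.inf, np.inf
        a_freq = np.histogram(s_avail, bins=edges)[0] / len(s_avail)
        u_freq = np.histogram(s_test, bins=edges)[0] / max(len(test), 1)
        adj = u_freq / np.where(a_freq > 0, a_freq, np.nan)
        ok = np.isfinite(adj)
        rho = stats.spearmanr(np.arange(1, len(adj) + 1)[ok], adj[ok]).statistic
        rhos.append(float(rho))
    return rhos


# ---------------------------------------------------------------------------
# matched random steps and Fortin CV
# ---------------------------------------------------------------------------
def sample_random_steps(
    long_steps: pd.DataFrame,
    R: int = 10,
    bin_len: float = 50.0,
    bin_turn: float = 10.0,
    seed: int = 0,
    stack=None,
) -> pd.DataFrame:
    """Match each observed travel step with ``R`` random steps.

    Pooled empirical distributions of the observed long-step lengths
    (``bin_len``-metre bins) and turn angles (``bin_turn``-degree bins) are
    built; each random step shares the observed step's start point, with a
    length and a turn angle drawn from the binned distributions (uniform
    within bin) and an endpoint at bearing (previous absolute bearing +
    drawn turn).  Random endpoints falling off the landscape are redrawn up
    to 20 times, after which the stratum is dropped with a log entry.

    Returns one row per step (used and random) with ``stratum_id``,
    ``used``, geometry, ``length`` and ``turn_angle``.
    """
    steps = long_steps.dropna(subset=["turn_angle"]).reset_index(drop=True)
    if len(steps) < 50:
        raise ValueError("need at least 50 long steps to form empirical distributions")
    rng = np.random.default_rng(seed)
    lengths = steps["length"].to_numpy()
    turns = steps["turn_angle"].to_numpy()
    len_edges = np.arange(0, lengths.max() + bin_len, bin_len)
    turn_edges = np.arange(-180.0, 180.0 + bin_turn, bin_turn)
    len_counts, _ = np.histogram(lengths, bins=len_edges)
    turn_counts, _ = np.histogram(turns, bins=turn_edges)
    len_p = len_counts / len_counts.sum()
    turn_p = turn_counts / turn_counts.sum()

    def draw(edges, p, size):
        b = rng.choice(len(p), p=p, size=size)
        return edges[b] + rng.uniform(size=size) * (edges[b + 1] - edges[b])

    bearing = np.degrees(
        np.arctan2(
            steps["y_end"].to_numpy() - steps["y_start"].to_numpy(),
            steps["x_end"].to_numpy() - steps["x_start"].to_numpy(),
        )
    )
    prev_bearing = bearing - turns

    n = len(steps)
    x0 = np.repeat(steps["x_start"].to_numpy(), R)
    y0 = np.repeat(steps["y_start"].to_numpy(), R)
    pb = np.repeat(prev_bearing, R)
    L = draw(len_edges, len_p, n * R)
    T = draw(turn_edges, turn_p, n * R)
    xe = x0 + L * np.cos(np.radians(pb + T))
    ye = y0 + L * np.sin(np.radians(pb + T))
    if stack is not None:
        bad = ~stack.grid.contains(xe, ye)
        for _ in range(20):
            if not bad.any():
                break
            k = int(bad.sum())
            L[bad] = draw(len_edges, len_p, k)
            T[bad] = draw(turn_edges, turn_p, k)
            xe[bad] = x0[bad] + L[bad] * np.cos(np.radians(pb[bad] + T[bad]))
            ye[bad] = y0[bad] + L[bad] * np.sin(np.radians(pb[bad] + T[bad]))
            bad = ~stack.grid.contains(xe, ye)
        drop_strata = np.unique(np.flatnonzero(bad) // R)
    else:
        drop_strata = np.array([], dtype=int)

    used_rows = pd.DataFrame(
        {
            "stratum_id": np.arange(n),
            "animal_id": steps["animal_id"].to_numpy(),
            "used": 1,
            "x_start": steps["x_start"].to_numpy(),
            "y_start": steps["y_start"].to_numpy(),
            "x_end": steps["x_end"].to_numpy(),
            "y_end": steps["y_end"].to_numpy(),
            "length": lengths,
            "turn_angle": turns,
        }
    )
    rand_rows = pd.DataFrame(
        {
            "stratum_id": np.repeat(np.arange(n), R),
            "animal_id": np.repeat(steps["animal_id"].to_numpy(), R),
            "used": 0,
            "x_start": x0,
            "y_start": y0,
            "x_end": xe,
            "y_end": ye,
            "length": L,
            "turn_angle": T,
        }
    )
    out = pd.concat([used_rows, rand_rows], ignore_index=True)
    if len(drop_strata):
        log.warning("dropped %d strata whose random endpoints could not be placed", len(drop_strata))
        out = out[~out["stratum_id"].isin(drop_strata)]
    return out.sort_values(["stratum_id", "used"], ascending=[True, False]).reset_index(drop=True)


def fortin_cv(
    strata: pd.DataFrame,
    spec: DesignSpec,
    train_frac: float = 0.8,
    reps: int = 100,
    seed: int = 0,
) -> dict:
    """Case-control k-fold cross-validation of an SSF (Fortin design).

    Per repetition: fit on ``train_frac`` of randomly selected strata; on
    each withheld stratum rank the used step's SSF score among its random
    steps (rank 1 = highest score, ties averaged) and tally rank
    frequencies; the statistic is the Spearman correlation between rank and
    frequency.  The null repeats the procedure ranking one withheld random
    step against the remaining random steps.  Returns means and percentile
    95% CIs over repetitions.

    With rank 1 = highest, a well-performing model yields a strongly
    *negative* correlation (used steps concentrate in the top ranks).
    """
    if strata["stratum_id"].nunique() < 50:
        raise ValueError("need at least 50 strata")
    rng = np.random.default_rng(seed)
    sids = np.sort(strata["stratum_id"].unique())
    obs, null = [], []
    for _ in range(reps):
        train_ids = rng.choice(sids, size=int(train_frac * len(sids)), replace=False)
        train = strata[strata["stratum_id"].isin(train_ids)]
        test = strata[~strata["stratum_id"].isin(train_ids)]
        m = fit_ssf(train, spec)
        scores = m.linear_predictor(test)
        t = test.assign(score=scores)
        obs_ranks, null_ranks = [], []
        for _, g in t.groupby("stratum_id"):
            r = stats.rankdata(-g["score"].to_numpy(), method="average")
            used_mask = g["used"].to_numpy().astype(bool)
            obs_ranks.append(r[used_mask][0])
            # null: one random step ranked against the other random steps
            rand = g[~used_mask]
            pick = rng.integers(len(rand))
            rr = stats.rankdata(-rand["score"].to_numpy(), method="average")
            null_ranks.append(rr[pick])
        n_ranks = int(t.groupby("stratum_id").size().max())
        obs.append(_rank_freq_spearman(obs_ranks, n_ranks))
        null.append(_rank_freq_spearman(null_ranks, n_ranks - 1))
    return {
        "mean": float(np.mean(obs)),
        "ci": (float(np.percentile(obs, 2.5)), float(np.percentile(obs, 97.5))),
        "null_mean": float(np.mean(null)),
        "null_ci": (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5))),
        "rank_convention": "rank 1 = highest score",
    }


def _rank_freq_spearman(ranks, n_ranks: int) -> float:
    freq = np.array([np.sum(np.floor(ranks) == r) for r in range(1, n_ranks + 1)], dtype=float)
    return float(stats.spearmanr(np.arange(1, n_ranks + 1), freq).statistic)
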