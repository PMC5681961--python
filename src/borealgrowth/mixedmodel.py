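"""Two-level linear mixed-effects growth model with AR(1) errors, fit by REML.

The model for the ring index I of tree j at site i in year k is

    I_ijk = (b₁+β₁ᵢ+β₁ᵢⱼ) + (b₂+β₂ᵢ+β₂ᵢⱼ)·A_ik + (b₃+β₃ᵢ+β₃ᵢⱼ)·D_ik + ε_ijk

with fixed effects b, mutually uncorrelated Gaussian random intercepts and
slopes at the site level (β·ᵢ) and the tree-within-site level (β·ᵢⱼ), and a
within-tree stationary AR(1) error ε with autoregressive coefficient φ and
marginal standard deviation σ.  A_ik is annual photosynthetic production (on
its scaled axis) and D_ik the annual maximum drought code, both entered in raw
units.  Across a gap of g missing years the error correlation is φᵍ.

Estimation maximizes the restricted likelihood over the variance parameters
(log-SD scale, atanh-φ scale) with the fixed effects profiled out by
generalized least squares.  The likelihood is evaluated exactly and in O(N)
by exploiting the nesting: the AR(1) correlation matrix of a Markov chain has
a closed-form tridiagonal inverse, and the two layers of low-rank random
effects are folded in by nested 3×3 Woodbury identities per tree and per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: fixed-effect / random-effect term order used throughout
TERMS = ("intercept", "gpp", "drought")

PANEL_COLUMNS = ["site_id", "tree_id", "year", "index", "gpp", "drought"]

LOG2PI = np.log(2.0 * np.pi)

#: AIC parameter count: 3 fixed + 6 random-effect SDs + φ + σ
N_PARAMETERS = 11

_SD_FLOOR = 1e-12  # SDs below this are treated as structurally zero


class MixedModelError(ValueError):
    pass


@dataclass
class MixedModelSpec:
    """Variance-parameter values for the two-level AR(1) growth model.

    SD vectors are ordered (intercept, gpp, drought); random effects are
    uncorrelated with each other and across levels, so each level's covariance
    is diagonal.
    """

    sd_site: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sd_tree: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phi: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        self.sd_site = np.asarray(self.sd_site, dtype=float)
        self.sd_tree = np.asarray(self.sd_tree, dtype=float)
        if self.sd_site.shape != (3,) or self.sd_tree.shape != (3,):
            raise MixedModelError("sd_site and sd_tree must each hold 3 values")
        if np.any(self.sd_site < 0) or np.any(self.sd_tree < 0):
            raise MixedModelError("random-effect SDs must be non-negative")
        if not abs(self.phi) < 1:
            raise MixedModelError("|phi| must be < 1")
        if self.sigma <= 0:
            raise MixedModelError("sigma must be positive")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise MixedModelError(f"growth panel missing columns: {missing}")
    out = panel.sort_values(["site_id", "tree_id", "year"]).reset_index(drop=True)
    if out.duplicated(subset=["site_id", "tree_id", "year"]).any():
        raise MixedModelError("duplicate (site, tree, year) rows in growth panel")
    if out["index"].isna().any() or out[["gpp", "drought"]].isna().any().any():
        raise MixedModelError("NaNs in growth panel response or covariates")
    return out


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


@dataclass
class _Tree:
    X: np.ndarray  # n × 3 design [1, gpp, drought]
    y: np.ndarray
    gaps: np.ndarray  # year differences between consecutive observations
    tree_id: str = ""


@dataclass
class _Site:
    site_id: str
    trees: list[_Tree]


def _structure(panel: pd.DataFrame) -> list[_Site]:
    sites = []
    for site_id, sgrp in panel.groupby("site_id", sort=True):
        trees = []
        for tree_id, tgrp in sgrp.groupby("tree_id", sort=True):
            years = tgrp["year"].to_numpy(float)
            gaps = np.diff(years)
            if np.any(gaps < 1):
                raise MixedModelError(f"tree {tree_id}: non-increasing years")
            if np.any(gaps > 1):
                logger.warning("tree %s: %d year gaps; AR(1) bridged as phi^gap",
                               tree_id, int((gaps > 1).sum()))
            X = np.column_stack(
                [np.ones(len(tgrp)), tgrp["gpp"].to_numpy(float), tgrp["drought"].to_numpy(float)]
            )
            trees.append(_Tree(X=X, y=tgrp["index"].to_numpy(float), gaps=gaps, tree_id=str(tree_id)))
        sites.append(_Site(site_id=str(site_id), trees=trees))
    return sites


def _ar1_quad(W: np.ndarray, gaps: np.ndarray, phi: float) -> tuple[np.ndarray, float]:
    """(WᵀR⁻¹W, log det R) for the unit-variance AR(1)/Markov correlation R.

    R_st = φ^{|year_s − year_t|}; its inverse is tridiagonal with entries given
    by the chain factorization, so the quadratic form costs O(n).
    """
    n = W.shape[0]
    if n == 1:
        return W.T @ W, 0.0
    rho = phi**gaps
    f = 1.0 - rho**2
    d = np.ones(n)
    d[:-1] += rho**2 / f
    d[1:] += 1.0 / f - 1.0
    e = -rho / f
    WtRW = W.T @ (d[:, None] * W)
    cross = W[:-1].T @ (e[:, None] * W[1:])
    WtRW += cross + cross.T
    return WtRW, float(np.sum(np.log(f)))


def _ar1_apply(x: np.ndarray, gaps: np.ndarray, phi: float) -> np.ndarray:
    """R⁻¹x for the same Markov correlation matrix (x may be a matrix)."""
    n = x.shape[0]
    if n == 1:
        return x.copy()
    rho = phi**gaps
    f = 1.0 - rho**2
    if x.ndim == 2:
        rho, f = rho[:, None], f[:, None]
    out = x.astype(float).copy()
    out[:-1] += rho**2 / f * x[:-1] - rho / f * x[1:]
    out[1:] += (1.0 / f - 1.0) * x[1:] - rho / f * x[:-1]
    return out


def _fold_random_effects(P: np.ndarray, sd: np.ndarray):
    """One Woodbury fold: P − P[:,a]·K⁻¹·P[a,:] over the active RE columns.

    ``P`` is the 4×4 Gram matrix of [X | y] under the current inner metric and
    the random-effect design equals the first three columns.  Returns the
    folded Gram matrix and the log-det increment log(|G|·|K|).
    """
    active = np.nonzero(sd > _SD_FLOOR)[0]
    if active.size == 0:
        return P, 0.0
    K = np.diag(1.0 / sd[active] ** 2) + P[np.ix_(active, active)]
    sign, logdet_k = np.linalg.slogdet(K)
    if sign <= 0:
        raise MixedModelError("non-positive-definite inner matrix in likelihood")
    folded = P - P[:, active] @ np.linalg.solve(K, P[active, :])
    logdet = float(2.0 * np.sum(np.log(sd[active])) + logdet_k)
    return folded, logdet


def _reml_pieces(sites: list[_Site], spec: MixedModelSpec):
    """Accumulate Σ [X|y]ᵀV⁻¹[X|y] and log|V| over site blocks."""
    sigma2 = spec.sigma**2
    H = np.zeros((4, 4))
    logdet_v = 0.0
    n_total = 0
    for site in sites:
        Q_site = np.zeros((4, 4))
        for tree in site.trees:
            W = np.column_stack([tree.X, tree.y])
            P, logdet_r = _ar1_quad(W, tree.gaps, spec.phi)
            P = P / sigma2
            n = len(tree.y)
            n_total += n
            logdet_v += n * np.log(sigma2) + logdet_r
            Q, ld = _fold_random_effects(P, spec.sd_tree)
            logdet_v += ld
            Q_site += Q
        Hs, ld = _fold_random_effects(Q_site, spec.sd_site)
        logdet_v += ld
        H += Hs
    return H, logdet_v, n_total


def loglik_reml(spec: MixedModelSpec, panel: pd.DataFrame) -> float:
    """Restricted log-likelihood at the given variance parameters.

    Fixed effects are profiled out by generalized least squares; the value is
    −½·[log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r + (n−p)·log 2π].
    """
    panel = validate_panel(panel)
    sites = _structure(panel)
    return _loglik_from_structure(sites, spec)[0]


def _loglik_from_structure(sites, spec):
    H, logdet_v, n = _reml_pieces(sites, spec)
    A = H[:3, :3]
    u = H[:3, 3]
    yy = H[3, 3]
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise MixedModelError("singular XᵀV⁻¹X: fixed effects not identifiable")
    beta = np.linalg.solve(A, u)
    rss = yy - beta @ u
    ll = -0.5 * (logdet_v + logdet_a + rss + (n - 3) * LOG2PI)
    if not np.isfinite(ll):
        raise MixedModelError("non-finite restricted likelihood")
    return float(ll), beta, A


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """REML fit summary: fixed effects, variance components, BLUPs, diagnostics."""

    fixed: pd.DataFrame  # term, estimate, se, t, df, p
    sd_site: np.ndarray
    sd_tree: np.ndarray
    phi: float
    sigma: float
    loglik: float
    aic: float
    blups_site: pd.DataFrame
    blups_tree: pd.DataFrame
    converged: bool
    n_obs: int
    n_sites: int
    n_trees: int
    optimizer_message: str = ""
    gradient_norm: float = np.nan
    boundary_terms: list[str] = field(default_factory=list)

    @property
    def fixed_effects(self) -> dict[str, float]:
        return dict(zip(self.fixed["term"], self.fixed["estimate"]))

    def summary(self) -> str:
        lines = [
            "Linear mixed-effects model fit by REML",
            f"  observations: {self.n_obs}   sites: {self.n_sites}   trees: {self.n_trees}",
            f"  log-restricted-likelihood: {self.loglik:.2f}   AIC: {self.aic:.2f}",
            f"  AR(1) phi: {self.phi:.6f}   residual SD: {self.sigma:.6f}",
            "  Fixed effects:",
        ]
        for _, r in self.fixed.iterrows():
            lines.append(
                f"    {r['term']:<10} {r['estimate']:>12.6f}  SE {r['se']:.6f}  p {r['p']:.4f}"
            )
        lines.append("  Random-effect SDs (site / tree):")
        for i, term in enumerate(TERMS):
            lines.append(f"    {term:<10} {self.sd_site[i]:>12.6f} / {self.sd_tree[i]:.6f}")
        if self.boundary_terms:
            lines.append(f"  boundary (near-zero) variance terms: {', '.join(self.boundary_terms)}")
        if not self.converged:
            lines.append(f"  WARNING: optimizer did not converge ({self.optimizer_message})")
        return "\n".join(lines)


def _pack(spec: MixedModelSpec) -> np.ndarray:
    return np.concatenate(
        [
            np.log(np.maximum(spec.sd_site, 1e-8)),
            np.log(np.maximum(spec.sd_tree, 1e-8)),
            [np.arctanh(np.clip(spec.phi, -0.999, 0.999)), np.log(spec.sigma)],
        ]
    )


def _unpack(theta: np.ndarray) -> MixedModelSpec:
    return MixedModelSpec(
        sd_site=np.exp(theta[0:3]),
        sd_tree=np.exp(theta[3:6]),
        phi=float(np.tanh(theta[6])),
        sigma=float(np.exp(theta[7])),
    )


def _moment_start(sites: list[_Site]) -> MixedModelSpec:
    """Cheap moment-based starting point: OLS residual scale and lag-1 correlation."""
    X = np.vstack([t.X for s in sites for t in s.trees])
    y = np.concatenate([t.y for s in sites for t in s.trees])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sd = float(np.std(y - X @ beta)) or 1.0
    num = den = 0.0
    for s in sites:
        for t in s.trees:
            r = t.y - t.X @ beta
            if len(r) > 2:
                r = r - r.mean()
                num += np.sum(r[:-1] * r[1:])
                den += np.sum(r**2)
    phi = float(np.clip(num / den if den > 0 else 0.0, -0.95, 0.95))
    scales = np.maximum(np.abs(X).mean(axis=0), 1e-8)
    re_sd = 0.5 * sd / scales  # half the residual scale, per covariate unit
    return MixedModelSpec(sd_site=re_sd, sd_tree=re_sd, phi=phi, sigma=0.7 * sd)


def fit_reml(panel: pd.DataFrame, start: MixedModelSpec | None = None,
             n_starts: int = 3, maxiter: int = 500, seed: int = 0) -> MixedModelFit:
    """Maximize the restricted likelihood over the variance parameters.

    Optimization runs on transformed parameters (log SDs, atanh φ, log σ) with
    L-BFGS-B from ``n_starts`` deterministic starting points (a moment-based
    start plus seeded perturbations of it).  Fixed effects are profiled by
    GLS at every evaluation; their SEs come from (XᵀV⁻¹X)⁻¹ at the optimum.
    Boundary variance estimates (SD → 0) are flagged, not hidden.
    """
    panel = validate_panel(panel)
    n_sites_ = panel["site_id"].nunique()
    if n_sites_ < 2:
        raise MixedModelError("need ≥ 2 sites to identify site-level variance components")
    if (panel.groupby("site_id")["tree_id"].nunique() < 2).any():
        raise MixedModelError("need ≥ 2 trees per site to identify both random-effect levels")
    sites = _structure(panel)

    base = start or _moment_start(sites)
    rng = np.random.default_rng(seed)
    theta0s = [_pack(base)]
    for _ in range(n_starts - 1):
        theta0s.append(_pack(base) + rng.normal(0.0, 0.7, size=8))

    bounds = [(-18.0, 6.0)] * 6 + [(-4.0, 4.0), (-12.0, 6.0)]

    def objective(theta):
        try:
            ll, _, _ = _loglik_from_structure(sites, _unpack(theta))
        except MixedModelError:
            return 1e12  # barrier for degenerate variance proposals
        return -ll

    best = None
    for theta0 in theta0s:
        res = optimize.minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    spec = _unpack(best.x)
    ll, beta, A = _loglik_from_structure(sites, spec)

    cov_beta = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    n_obs = len(panel)
    n_trees = int(panel.groupby("site_id")["tree_id"].nunique().sum())
    # containment-style degrees of freedom: all covariates vary within tree
    df = max(n_obs - n_trees - 2, 1)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    fixed = pd.DataFrame(
        {"term": TERMS, "estimate": beta, "se": se, "t": tvals, "df": df, "p": pvals}
    )

    boundary = [
        f"{lvl}:{TERMS[i]}"
        for lvl, sds in (("site", spec.sd_site), ("tree", spec.sd_tree))
        for i in range(3)
        if sds[i] < 1e-6
    ]
    grad_norm = float(np.linalg.norm(best.jac)) if getattr(best, "jac", None) is not None else np.nan

    blups_site, blups_tree = _blups(sites, spec, beta)
    fit = MixedModelFit(
        fixed=fixed,
        sd_site=spec.sd_site,
        sd_tree=spec.sd_tree,
        phi=spec.phi,
        sigma=spec.sigma,
        loglik=ll,
        aic=2.0 * N_PARAMETERS - 2.0 * ll,
        blups_site=blups_site,
        blups_tree=blups_tree,
        converged=bool(best.success),
        n_obs=n_obs,
        n_sites=int(n_sites_),
        n_trees=n_trees,
        optimizer_message=str(best.message),
        gradient_norm=grad_norm,
        boundary_terms=boundary,
    )
    if not fit.converged:
        logger.warning("REML optimizer not converged: %s (|grad| = %.3g)",
                       fit.optimizer_message, grad_norm)
    return fit


# ---------------------------------------------------------------------------
# BLUPs and prediction
# ---------------------------------------------------------------------------


def _tree_cinv_apply(tree: _Tree, spec: MixedModelSpec, M: np.ndarray) -> np.ndarray:
    """C⁻¹M for one tree's marginal covariance C = Z·G_t·Zᵀ + σ²R."""
    sigma2 = spec.sigma**2
    BM = _ar1_apply(M, tree.gaps, spec.phi) / sigma2
    active = np.nonzero(spec.sd_tree > _SD_FLOOR)[0]
    if active.size == 0:
        return BM
    Z = tree.X[:, active]
    BZ = _ar1_apply(Z, tree.gaps, spec.phi) / sigma2
    K = np.diag(1.0 / spec.sd_tree[active] ** 2) + Z.T @ BZ
    return BM - BZ @ np.linalg.solve(K, Z.T @ BM)


def _site_vinv_apply(site: _Site, spec: MixedModelSpec, r: np.ndarray) -> np.ndarray:
    """V⁻¹r for one site block, via the site-level Woodbury identity."""
    offset = 0
    slices = []
    for tree in site.trees:
        n = len(tree.y)
        slices.append(slice(offset, offset + n))
        offset += n
    Ar = np.concatenate([_tree_cinv_apply(t, spec, r[sl]) for t, sl in zip(site.trees, slices)])
    active = np.nonzero(spec.sd_site > _SD_FLOOR)[0]
    if active.size == 0:
        return Ar
    AU = np.vstack([_tree_cinv_apply(t, spec, t.X[:, active]) for t in site.trees])
    U = np.vstack([t.X[:, active] for t in site.trees])
    K = np.diag(1.0 / spec.sd_site[active] ** 2) + U.T @ AU
    return Ar - AU @ np.linalg.solve(K, U.T @ Ar)


def _blups(sites: list[_Site], spec: MixedModelSpec, beta: np.ndarray):
    """Empirical-Bayes BLUPs per term at both levels: G·Zᵀ·V⁻¹·(y − Xβ̂)."""
    site_rows, tree_rows = [], []
    g_site = spec.sd_site**2
    g_tree = spec.sd_tree**2
    for site in sites:
        r = np.concatenate([t.y - t.X @ beta for t in site.trees])
        v = _site_vinv_apply(site, spec, r)
        U = np.vstack([t.X for t in site.trees])
        bs = g_site * (U.T @ v)
        site_rows.append({"site_id": site.site_id, **dict(zip(TERMS, bs))})
        offset = 0
        for tree in site.trees:
            n = len(tree.y)
            bt = g_tree * (tree.X.T @ v[offset : offset + n])
            tree_rows.append({"site_id": site.site_id, "tree_id": tree.tree_id,
                              **dict(zip(TERMS, bt))})
            offset += n
    return pd.DataFrame(site_rows), pd.DataFrame(tree_rows)


def predict_indices(fit: MixedModelFit, panel: pd.DataFrame, conditional: bool = True) -> pd.DataFrame:
    """Fitted indices per (site, tree, year).

    Population-level predictions are Xβ̂; with ``conditional=True`` the site
    and tree BLUP contributions are added.  Unknown site or tree ids fall back
    to the population level and are flagged in the ``population_only`` column.
    """
    panel = validate_panel(panel)
    X = np.column_stack([np.ones(len(panel)), panel["gpp"], panel["drought"]])
    beta = fit.fixed["estimate"].to_numpy()
    pred = X @ beta
    flag = np.zeros(len(panel), dtype=bool)
    if conditional:
        bs = fit.blups_site.set_index("site_id")
        bt = fit.blups_tree.set_index(["site_id", "tree_id"])
        terms = list(TERMS)
        for i, row in enumerate(panel.itertuples(index=False)):
            known = False
            if row.site_id in bs.index:
                pred[i] += X[i] @ bs.loc[row.site_id, terms].to_numpy(float)
                known = True
            if (row.site_id, row.tree_id) in bt.index:
                pred[i] += X[i] @ bt.loc[(row.site_id, row.tree_id), terms].to_numpy(float)
                known = True
            flag[i] = not known
    out = panel[["site_id", "tree_id", "year"]].copy()
    out["fitted"] = pred
    out["population_only"] = flag if conditional else True
    return out


def extract_random_effects(fit: MixedModelFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(site-level, tree-level) BLUP tables with one column per model term."""
    return fit.blups_site.copy(), fit.blups_tree.copy()


def posthoc_correlation(blups: pd.DataFrame, term: str, covariate):
    """Pearson correlation of a per-tree (or per-site) BLUP term with a covariate.

    Returns ``(r, p, scatter)`` where ``scatter`` is the aligned two-column
    table exported for plotting.
    """
    if term not in blups.columns:
        raise MixedModelError(f"unknown BLUP term {term!r}")
    x = np.asarray(covariate, dtype=float)
    y = blups[term].to_numpy(float)
    if len(x) != len(y):
        raise MixedModelError("covariate length does not match BLUP table")
    if len(x) < 3:
        raise MixedModelError("need at least 3 pairs for a correlation")
    if np.std(x) == 0:
        raise MixedModelError("zero-variance covariate")
    r, p = stats.pearsonr(x, y)
    scatter = pd.DataFrame({"covariate": x, term: y})
    return float(r), float(p), scatter
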