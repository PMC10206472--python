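"""Phylogenetic mixed models: REML/ML variance components and H².

Model
-----
For egg-level observations ``y`` grouped by species,

    y = X beta + Z u + eps,    u ~ N(0, sigma2_p * A),   eps ~ N(0, sigma2_e * I)

where ``Z`` is the observation->species incidence matrix and ``A`` is
either a diagonal-standardized phylogenetic covariance (Brownian motion;
see :mod:`eggshell.phylo`) or the identity (an ordinary species random
intercept).  Phylogenetic heritability is

    H2 = sigma2_p / (sigma2_p + sigma2_e),

0 meaning no phylogenetic signal, 1 meaning trait covariance fully
consistent with Brownian motion on the tree.

Estimation profiles the variance ratio ``theta = sigma2_p / sigma2_e``:
for fixed theta, the GLS coefficients and the residual variance have
closed forms in the eigenbasis of ``Z A Z'``, so the (restricted)
likelihood is a smooth 1-D function of theta which is maximized by a
deterministic log-spaced grid pass followed by bounded scalar refinement.
No random initialization is involved: fits are reproducible bit-for-bit.

Likelihood-ratio tests of fixed effects compare ML fits of nested models
on a chi-square reference distribution; REML likelihoods are not
comparable across fixed-effect structures and are never used for that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import PhyloCovariance

__all__ = [
    "ModelSpec",
    "PmmFit",
    "LrtResult",
    "CorrelationResult",
    "NonIdentifiableError",
    "fit_mixed",
    "heritability",
    "lrt_fixed_effect",
    "pearson_ci",
]

THETA_MIN = 1e-6
THETA_MAX = 1e6
_GRID_POINTS = 201
_REFINE_XATOL = 1e-8  # absolute tolerance on log10(theta)


class NonIdentifiableError(ValueError):
    """Variance components cannot be separated for this design."""


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed_effects`` are column names of the egg table (numeric or
    boolean; booleans are coded 0/1); an intercept is always included.
    ``species_cov=None`` requests an identity species covariance (plain
    species random intercept).
    """

    response: str
    fixed_effects: list[str] = field(default_factory=list)
    species_col: str = "species"
    species_cov: PhyloCovariance | None = None


@dataclass
class PmmFit:
    """Result of one REML/ML mixed-model fit."""

    beta: pd.DataFrame  # index: term; columns: estimate, se, t
    sigma2_p: float
    sigma2_e: float
    H2: float
    loglik_reml: float
    loglik_ml: float
    theta: float
    criterion: str
    n_obs: int
    n_species: int
    converged: bool
    boundary: bool

    def to_dict(self) -> dict:
        return {
            "beta": {
                term: {k: float(v) for k, v in row.items()}
                for term, row in self.beta.iterrows()
            },
            "sigma2_p": self.sigma2_p,
            "sigma2_e": self.sigma2_e,
            "H2": self.H2,
            "loglik_reml": self.loglik_reml,
            "loglik_ml": self.loglik_ml,
            "theta": self.theta,
            "criterion": self.criterion,
            "n_obs": self.n_obs,
            "n_species": self.n_species,
            "converged": self.converged,
            "boundary": self.boundary,
        }


@dataclass
class LrtResult:
    """Chi-square likelihood-ratio test of nested fixed effects."""

    chi2: float
    df: int
    p_value: float


@dataclass
class CorrelationResult:
    """Pearson correlation with a Fisher-z 95% confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    n: int


def _design(spec: ModelSpec, data: pd.DataFrame):
    cols = [spec.response, spec.species_col, *spec.fixed_effects]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from egg table: {missing}")
    sub = data.dropna(subset=[spec.response, *spec.fixed_effects])
    y = sub[spec.response].to_numpy(dtype=float)
    n = len(y)
    X_cols = [np.ones(n)]
    names = ["(Intercept)"]
    for c in spec.fixed_effects:
        col = sub[c]
        if col.dtype == bool or col.dtype == object:
            col = col.astype(bool).astype(float)
        X_cols.append(col.to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    groups = sub[spec.species_col].astype(str).to_numpy()
    return y, X, names, groups


def _species_kernel(groups: np.ndarray, cov: PhyloCovariance | None):
    """Eigendecomposition of K = Z A Z' for the profiling transform."""
    species = list(dict.fromkeys(groups))  # stable first-appearance order
    if len(species) < 2:
        raise NonIdentifiableError("need at least 2 species")
    if cov is None:
        counts = pd.Series(groups).value_counts()
        if counts.max() < 2:
            raise NonIdentifiableError(
                "identity species covariance with one observation per species: "
                "sigma2_p and sigma2_e are not separable"
            )
        A = np.eye(len(species))
    else:
        missing = set(species) - set(cov.species_order)
        if missing:
            raise KeyError(f"species absent from covariance: {sorted(missing)}")
        sub = cov.submatrix(species)
        A = sub.A
        w = np.linalg.eigvalsh(A)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("species covariance is not positive semi-definite")
    Z = (groups[:, None] == np.asarray(species)[None, :]).astype(float)
    K = Z @ A @ Z.T
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    return lam, U


class _ProfiledModel:
    """y, X rotated into the eigenbasis of K; likelihoods as functions of theta."""

    def __init__(self, y, X, lam, U):
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.lam = lam
        self.n, self.p = X.shape

    def _gls(self, theta: float):
        w = 1.0 + theta * self.lam
        Xw = self.Xt / w[:, None]
        XtWX = self.Xt.T @ Xw
        XtWy = Xw.T @ self.yt
        beta = np.linalg.solve(XtWX, XtWy)
        resid = self.yt - self.Xt @ beta
        rss = float(resid @ (resid / w))
        return w, XtWX, beta, rss

    def loglik(self, theta: float, criterion: str) -> float:
        w, XtWX, _, rss = self._gls(theta)
        logdet_w = float(np.sum(np.log(w)))
        n, p = self.n, self.p
        if criterion == "ML":
            s2 = rss / n
            return -0.5 * (n * np.log(2 * np.pi * s2) + logdet_w + n)
        s2 = rss / (n - p)
        sign, logdet_info = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (
            (n - p) * np.log(2 * np.pi * s2) + logdet_w + logdet_info + (n - p)
        )

    def estimates(self, theta: float, criterion: str):
        w, XtWX, beta, rss = self._gls(theta)
        s2e = rss / (self.n if criterion == "ML" else self.n - self.p)
        cov_beta = s2e * np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov_beta))
        return beta, se, s2e


def fit_mixed(spec: ModelSpec, data: pd.DataFrame, criterion: str = "REML") -> PmmFit:
    """Fit the species-level mixed model by profiled REML or ML.

    Returns a :class:`PmmFit` carrying the fixed effects with standard
    errors and t ratios, both variance components, H², and both the REML
    and ML log-likelihoods evaluated at the optimum of the requested
    criterion.  ``boundary`` flags an estimate pinned at theta = 0 or at
    the search bounds [1e-6, 1e6].
    """
    criterion = criterion.upper()
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be 'REML' or 'ML'")
    y, X, names, groups = _design(spec, data)
    if len(y) <= X.shape[1] + 1:
        raise NonIdentifiableError("too few observations for the design")
    lam, U = _species_kernel(groups, spec.species_cov)
    prob = _ProfiledModel(y, X, lam, U)

    log_grid = np.linspace(np.log10(THETA_MIN), np.log10(THETA_MAX), _GRID_POINTS)
    values = np.array([prob.loglik(10.0**g, criterion) for g in log_grid])
    best = int(np.argmax(values))

    lo = log_grid[max(best - 1, 0)]
    hi = log_grid[min(best + 1, _GRID_POINTS - 1)]
    res = optimize.minimize_scalar(
        lambda g: -prob.loglik(10.0**g, criterion),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _REFINE_XATOL},
    )
    converged = bool(res.success)
    theta = float(10.0**res.x)
    ll_opt = -float(res.fun)
    if values[best] > ll_opt:  # grid point beat the refinement
        theta, ll_opt = float(10.0 ** log_grid[best]), float(values[best])

    boundary = False
    ll_zero = prob.loglik(0.0, criterion)
    if ll_zero >= ll_opt - 1e-10 and theta <= THETA_MIN * 10:
        theta, ll_opt, boundary = 0.0, float(ll_zero), True
    elif theta <= THETA_MIN * 1.001 or theta >= THETA_MAX * 0.999:
        boundary = True

    beta, se, s2e = prob.estimates(theta, criterion)
    s2p = theta * s2e
    h2 = 0.0 if theta == 0.0 else theta / (1.0 + theta)
    beta_df = pd.DataFrame(
        {"estimate": beta, "se": se, "t": beta / se}, index=names
    )
    return PmmFit(
        beta=beta_df,
        sigma2_p=float(s2p),
        sigma2_e=float(s2e),
        H2=float(h2),
        loglik_reml=float(prob.loglik(theta, "REML")),
        loglik_ml=float(prob.loglik(theta, "ML")),
        theta=theta,
        criterion=criterion,
        n_obs=prob.n,
        n_species=len(set(groups)),
        converged=converged,
        boundary=boundary,
    )


def heritability(fit: PmmFit) -> float:
    """Phylogenetic heritability H2 = sigma2_p/(sigma2_p + sigma2_e)."""
    total = fit.sigma2_p + fit.sigma2_e
    if total <= 0:
        raise ValueError("both variance components are zero; H2 undefined")
    if fit.sigma2_p == 0:
        return 0.0
    if fit.sigma2_e == 0:
        return 1.0
    return fit.sigma2_p / total


def lrt_fixed_effect(
    full: ModelSpec, reduced: ModelSpec, data: pd.DataFrame
) -> LrtResult:
    """Chi-square LRT of nested fixed-effect structures (both fit by ML).

    The statistic 2*(l_full - l_reduced) is clamped at zero; the degrees
    of freedom are the number of dropped fixed-effect terms.
    """
    if not set(reduced.fixed_effects) <= set(full.fixed_effects):
        raise ValueError("reduced fixed effects must nest within the full model")
    if (
        reduced.response != full.response
        or reduced.species_col != full.species_col
        or (reduced.species_cov is None) != (full.species_cov is None)
    ):
        raise ValueError("models must share response and random structure")
    df = len(full.fixed_effects) - len(reduced.fixed_effects)
    if df < 1:
        df = max(df, 0)
    fit_full = fit_mixed(full, data, criterion="ML")
    fit_reduced = fit_mixed(reduced, data, criterion="ML")
    chi2 = max(0.0, 2.0 * (fit_full.loglik_ml - fit_reduced.loglik_ml))
    if df == 0:
        return LrtResult(chi2=chi2, df=0, p_value=1.0)
    p = float(stats.chi2.sf(chi2, df))
    return LrtResult(chi2=float(chi2), df=df, p_value=p)


def pearson_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval (default 95%)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 4:
        raise ValueError("need at least 4 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # r = +-1 gives a degenerate interval
        ci = res.confidence_interval(confidence_level=confidence)
    return CorrelationResult(
        r=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n=int(len(x)),
    )
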