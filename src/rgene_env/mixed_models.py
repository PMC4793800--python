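"""Linear mixed models with crossed random intercepts, fitted by REML.

The response is a per-replicate log2 normalized expression value; fixed
effects are experimental design factors (accession, treatment and their
interaction) and random effects are independent Gaussian intercepts, one
variance per grouping factor (e.g. gene, gene x accession).  The model is

    y = X beta + sum_k Z_k b_k + e,   b_k ~ N(0, sigma2_k I),  e ~ N(0, sigma2_e I)

Variance components are estimated by maximizing the restricted likelihood
profiled over the fixed effects and the residual variance, so the free
parameters are the variance ratios theta_k = sigma2_k / sigma2_e.  The
criterion is evaluated from cross-product matrices of [Z X y], which makes
a single evaluation O((p+q)^3) regardless of the number of observations --
cheap enough that parametric-bootstrap confidence intervals refit the model
thousands of times.

The profiled REML deviance follows the standard penalized-least-squares
formulation: with Lambda = diag(sqrt(theta)) and the bordered system

    A = [[L'Z'Z L + I,  L'Z'X],        rhs = [L'Z'y]
         [X'Z L,        X'X   ]]              [X'y ]

a Cholesky factor of A yields the penalized RSS and the two log-determinant
terms, and

    -2 l_R(theta) = log|L'Z'ZL + I| + log|R_X|^2
                    + (n-p) (1 + log(2 pi pwrss / (n-p))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.linalg.lapack import dpotrf as _dpotrf, dtrtrs as _dtrtrs

__all__ = [
    "ModelSpec",
    "LmmFit",
    "VarianceProportions",
    "AnovaTable",
    "fit_lmm",
    "variance_proportions",
    "bootstrap_ci",
    "anova_table",
    "compare_models",
    "ConvergenceError",
    "SingularDesignError",
]

_VAR_FLOOR = 1e-10  # floor on variance ratios, avoids boundary pathologies


class ConvergenceError(RuntimeError):
    """REML/ML optimization failed to converge; carries the criterion trace."""


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Model formula: which columns are fixed factors and which are random
    grouping factors.  Interactions are written ``"a:b"``.  An empty
    ``fixed`` tuple means intercept-only."""

    response: str = "value"
    fixed: tuple[str, ...] = ("accession", "treatment", "accession:treatment")
    random: tuple[str, ...] = ("gene", "gene:accession")

    def __post_init__(self) -> None:
        overlap = set(self.fixed) & set(self.random)
        if overlap:
            raise ValueError(f"factors cannot be both fixed and random: {sorted(overlap)}")


@dataclass
class LmmFit:
    spec: ModelSpec
    fixed_estimates: dict[str, float]
    variance_estimates: dict[str, float]  # per random term, plus "residual"
    theta: np.ndarray  # variance ratios at the optimum
    reml_criterion: float  # -2 * restricted log-likelihood
    loglik: float
    method: str  # "reml" or "ml"
    converged: bool
    n_obs: int
    n_fixed: int
    random_levels: dict[str, int]
    _problem: "_LmmProblem" = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return self.n_fixed + len(self.theta) + 1


@dataclass
class VarianceProportions:
    proportions: dict[str, float]
    ci: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0
    n_failed: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class AnovaTable:
    rows: pd.DataFrame  # term, df, sum_sq, mean_sq, F
    residual_df: int
    residual_mean_sq: float


# ---------------------------------------------------------------------------
# design construction


def _term_labels(data: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    for p in parts:
        if p not in data.columns:
            raise KeyError(f"factor column {p!r} not found in data")
    lab = data[parts[0]].astype(str)
    for p in parts[1:]:
        lab = lab + ":" + data[p].astype(str)
    return lab


def _dummies(labels: pd.Series, drop_first: bool) -> tuple[np.ndarray, list[str]]:
    levels = sorted(labels.unique())
    use = levels[1:] if drop_first else levels
    cols = np.column_stack([(labels == lv).to_numpy(float) for lv in use]) if use else np.empty((len(labels), 0))
    return cols, list(use)


def build_fixed_design(data: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Intercept plus treatment-coded dummies per term, in the given order.

    Interaction columns are products of the constituent dropped-first
    dummies.  Columns linearly dependent on the columns before them (cells
    absent from an unbalanced design, or partial aliasing between an
    interaction and its margins) are dropped, as R's ``lm`` does via QR
    pivoting.  A term whose columns are *all* aliased with preceding terms
    raises :class:`SingularDesignError` naming it.
    """
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["(Intercept)"]
    term_cols: list[tuple[str, np.ndarray, list[str]]] = []
    for term in fixed:
        parts = term.split(":")
        if len(parts) == 1:
            cols, lvls = _dummies(_term_labels(data, term), drop_first=True)
            cnames = [f"{term}[{lv}]" for lv in lvls]
        else:
            sub_cols = []
            sub_names = []
            for p in parts:
                c, lv = _dummies(_term_labels(data, p), drop_first=True)
                sub_cols.append(c)
                sub_names.append([f"{p}[{x}]" for x in lv])
            cols_list, cnames = [], []
            # products of dropped-first dummies across the constituent factors
            def expand(i, cur, name):
                if i == len(sub_cols):
                    cols_list.append(cur)
                    cnames.append(":".join(name))
                    return
                for j in range(sub_cols[i].shape[1]):
                    expand(i + 1, cur * sub_cols[i][:, j], name + [sub_names[i][j]])
            expand(0, np.ones(n), [])
            cols = np.column_stack(cols_list) if cols_list else np.empty((n, 0))
        term_cols.append((term, cols, cnames))

    # greedy rank filter: keep a column only if it adds to the column space
    basis = np.ones((n, 1)) / math.sqrt(n)
    slices: dict[str, slice] = {}
    kept_blocks: list[np.ndarray] = []
    pos = 1
    for term, cols, cnames in term_cols:
        kept = []
        for j in range(cols.shape[1]):
            v = cols[:, j]
            r = v - basis @ (basis.T @ v)
            r = r - basis @ (basis.T @ r)  # second pass for numerical stability
            nv = np.linalg.norm(v)
            if nv > 0 and np.linalg.norm(r) > 1e-8 * nv:
                basis = np.column_stack([basis, r / np.linalg.norm(r)])
                kept.append(j)
        if cols.shape[1] > 0 and not kept:
            raise SingularDesignError(
                f"fixed-effect design is singular: term {term!r} is entirely "
                f"aliased with preceding terms"
            )
        kept_blocks.append(cols[:, kept])
        names.extend([cnames[j] for j in kept])
        slices[term] = slice(pos, pos + len(kept))
        pos += len(kept)
    X = np.column_stack(blocks + kept_blocks)
    return X, names, slices


def build_random_design(data: pd.DataFrame, random: Sequence[str]) -> tuple[np.ndarray, list[int], dict[str, list[str]]]:
    """Full indicator matrix per random grouping factor (all levels)."""
    blocks, sizes, levels = [], [], {}
    for term in random:
        cols, lvls = _dummies(_term_labels(data, term), drop_first=False)
        if len(lvls) < 2:
            raise ValueError(f"random grouping factor {term!r} has < 2 levels")
        blocks.append(cols)
        sizes.append(cols.shape[1])
        levels[term] = lvls
    Z = np.column_stack(blocks) if blocks else np.empty((len(data), 0))
    return Z, sizes, levels


# ---------------------------------------------------------------------------
# the REML/ML problem on cross-products


class _LmmProblem:
    """Holds the design and the cross-product matrices; evaluates the
    profiled deviance for a vector of variance ratios.

    The REML criterion is evaluated on the problem projected onto the
    orthogonal complement of the fixed-effect column space (REML is the
    marginal likelihood of error contrasts), which shrinks the per-
    evaluation Cholesky from (q+p) to q and is exactly equivalent: with
    G = Z'(I - QQ')Z and r = Z'(I - QQ')y,

        -2 l_R = log|L G L + I| + log|X'X|
                 + (n-p)(1 + log(2 pi pwrss / (n-p))).
    """

    def __init__(self, X: np.ndarray, Z: np.ndarray, q_sizes: Sequence[int], y: np.ndarray):
        self.X = X
        self.Z = Z
        self.q_sizes = list(q_sizes)
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.M = np.column_stack([Z, X]) if self.q else X
        self.CtC = self.M.T @ self.M
        self.Q, _ = np.linalg.qr(X)  # orthonormal basis of the fixed space
        self.ZtQ = Z.T @ self.Q if self.q else np.empty((0, self.p))
        self.G = Z.T @ Z - self.ZtQ @ self.ZtQ.T if self.q else np.empty((0, 0))
        sign, self.logdet_xtx = np.linalg.slogdet(X.T @ X)
        if sign <= 0:
            raise SingularDesignError("fixed-effect design is singular")
        self._eye_q = np.eye(self.q)
        # per-column index of the owning random term, for scaling
        self._expand = np.concatenate(
            [np.full(qk, i) for i, qk in enumerate(self.q_sizes)]
        ) if self.q_sizes else np.empty(0, int)
        self.set_y(y)

    def set_y(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, float)
        self.Mty = self.M.T @ self.y
        self.yty = float(self.y @ self.y)
        qty = self.Q.T @ self.y
        self.r_proj = self.Mty[: self.q] - self.ZtQ @ qty
        self.yty_proj = self.yty - float(qty @ qty)

    def _scale(self, theta: np.ndarray) -> np.ndarray:
        s = np.ones(self.q + self.p)
        if self.q:
            s[: self.q] = np.sqrt(theta[self._expand])
        return s

    def deviance(self, theta: np.ndarray, reml: bool = True) -> float:
        """-2 profiled (restricted) log-likelihood at variance ratios theta."""
        n, p, q = self.n, self.p, self.q
        if reml and q:
            s = np.sqrt(theta[self._expand])
            A = self.G * s[:, None] * s[None, :]
            A.flat[:: q + 1] += 1.0
            L, info = _dpotrf(A, 1, 0, 1)  # lower, no clean, overwrite
            if info != 0:
                return np.inf
            c, info = _dtrtrs(L, s * self.r_proj, 1)  # lower
            if info != 0:
                return np.inf
            pwrss = max(self.yty_proj - c @ c, 1e-300)
            dof = n - p
            return (
                2.0 * np.log(L.diagonal()).sum()
                + self.logdet_xtx
                + dof * (1.0 + np.log(2.0 * np.pi * pwrss / dof))
            )
        s = self._scale(theta)
        A = self.CtC * s[:, None] * s[None, :]
        if q:
            A[np.arange(q), np.arange(q)] += 1.0
        rhs = self.Mty * s
        try:
            L = linalg.cholesky(A, lower=True, check_finite=False, overwrite_a=True)
        except linalg.LinAlgError:
            return np.inf
        c = linalg.solve_triangular(L, rhs, lower=True, check_finite=False,
                                    overwrite_b=True)
        pwrss = max(self.yty - c @ c, 1e-300)
        d = np.log(np.diag(L))
        ld_u = 2.0 * d[:q].sum()
        ld_x = 2.0 * d[q:].sum()
        if reml:
            dof = n - p
            return ld_u + ld_x + dof * (1.0 + np.log(2.0 * np.pi * pwrss / dof))
        return ld_u + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))

    def solve(self, theta: np.ndarray, reml: bool = True):
        """Estimates at theta: (beta, blups, sigma2_e, deviance)."""
        n, p, q = self.n, self.p, self.q
        s = self._scale(theta)
        A = self.CtC * s[:, None] * s[None, :]
        if q:
            A[np.arange(q), np.arange(q)] += 1.0
        rhs = self.Mty * s
        L = linalg.cholesky(A, lower=True)
        c = linalg.solve_triangular(L, rhs, lower=True)
        x = linalg.solve_triangular(L.T, c, lower=False)
        pwrss = max(self.yty - c @ c, 0.0)
        beta = x[q:]
        blups = s[:q] * x[:q] if q else np.empty(0)
        dof = (n - p) if reml else n
        sigma2_e = pwrss / dof
        return beta, blups, sigma2_e, self.deviance(theta, reml=reml)


_DEFAULT_GRID = (0.01, 1.0, 100.0)


def _optimize_theta(
    problem: _LmmProblem,
    reml: bool,
    starts: Sequence[np.ndarray] | None = None,
    xatol: float = 1e-10,
    fatol: float = 1e-12,
    maxiter: int = 2000,
    polish: bool = True,
) -> tuple[np.ndarray, float, bool]:
    """Deterministic multi-start Nelder-Mead on log variance ratios,
    optionally polished by cyclic Brent line searches."""
    k = len(problem.q_sizes)
    if k == 0:
        return np.empty(0), problem.deviance(np.empty(0), reml=reml), True
    if starts is None:
        import itertools

        starts = [np.log(np.array(c)) for c in itertools.product(_DEFAULT_GRID, repeat=k)]
    obj = lambda phi: problem.deviance(np.exp(np.clip(phi, np.log(_VAR_FLOOR), 30.0)), reml=reml)
    best_phi, best_val = None, np.inf
    ok = False
    coarse = len(starts) > 1
    for phi0 in starts:
        res = optimize.minimize(
            obj,
            np.asarray(phi0, float),
            method="Nelder-Mead",
            options=(
                {"xatol": 1e-2, "fatol": 1e-6, "maxiter": min(maxiter, 200)}
                if coarse
                else {"xatol": xatol, "fatol": fatol, "maxiter": maxiter}
            ),
        )
        if np.isfinite(res.fun) and res.fun < best_val - 1e-12:
            best_phi, best_val, ok = res.x, res.fun, bool(res.success)
    if best_phi is None:
        raise ConvergenceError("all optimizer starts produced non-finite criteria")
    if coarse:
        # refine the multi-start winner at the requested tolerance
        res = optimize.minimize(
            obj, best_phi, method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        if np.isfinite(res.fun) and res.fun <= best_val:
            best_phi, best_val, ok = res.x, res.fun, bool(res.success) or ok
    # coordinate-wise Brent line searches give ~1e-11 precision per log-ratio
    if polish:
        phi = np.array(best_phi, float)
        for _ in range(3):
            for i in range(k):
                def line(t, i=i):
                    p = phi.copy()
                    p[i] = t
                    return obj(p)
                r = optimize.minimize_scalar(
                    line, bounds=(phi[i] - 2.0, phi[i] + 2.0),
                    method="bounded", options={"xatol": 1e-12},
                )
                if np.isfinite(r.fun) and r.fun <= best_val:
                    phi[i], best_val = r.x, r.fun
        best_phi = phi
    theta = np.exp(np.clip(best_phi, np.log(_VAR_FLOOR), 30.0))
    theta[theta <= _VAR_FLOOR * 1.001] = 0.0
    return theta, best_val, ok


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    method: str = "reml",
    starts: Sequence[np.ndarray] | None = None,
    xatol: float = 1e-10,
    fatol: float = 1e-12,
    maxiter: int = 2000,
) -> LmmFit:
    """Fit the mixed model by REML (default) or ML.

    The optimizer is a deterministic multi-start Nelder-Mead over log
    variance ratios (no RNG involved); variance estimates are constrained
    non-negative with ratios floored at 1e-10 and snapped to zero at the
    floor.

    Raises
    ------
    SingularDesignError
        if the fixed-effect design is rank deficient (the error names the
        aliased term).
    ConvergenceError
        if no optimizer start yields a finite criterion.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    y = data[spec.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X, xnames, _ = build_fixed_design(data, spec.fixed)
    Z, q_sizes, rlevels = build_random_design(data, spec.random)
    if len(data) - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom")
    problem = _LmmProblem(X, Z, q_sizes, y)
    reml = method == "reml"
    theta, crit, ok = _optimize_theta(problem, reml, starts, xatol, fatol, maxiter)
    beta, blups, sigma2_e, _ = problem.solve(theta, reml=reml)
    variances = {term: float(t * sigma2_e) for term, t in zip(spec.random, theta)}
    variances["residual"] = float(sigma2_e)
    return LmmFit(
        spec=spec,
        fixed_estimates=dict(zip(xnames, map(float, beta))),
        variance_estimates=variances,
        theta=theta,
        reml_criterion=float(crit),
        loglik=float(-0.5 * crit),
        method=method,
        converged=ok,
        n_obs=problem.n,
        n_fixed=problem.p,
        random_levels={t: len(v) for t, v in rlevels.items()},
        _problem=problem,
    )


# ---------------------------------------------------------------------------
# derived quantities


def variance_proportions(fit: LmmFit) -> VarianceProportions:
    """Share of total variance per component (residual included)."""
    total = sum(fit.variance_estimates.values())
    if total <= 0:
        raise ValueError("total variance is zero; proportions undefined")
    return VarianceProportions(
        proportions={k: v / total for k, v in fit.variance_estimates.items()}
    )


def _simulate_response(problem: _LmmProblem, beta, theta, sigma2_e, rng) -> np.ndarray:
    q = problem.q
    mu = problem.X @ beta
    if q:
        sd = np.sqrt(np.maximum(theta[problem._expand] * sigma2_e, 0.0))
        u = rng.standard_normal(q) * sd
        mu = mu + problem.Z @ u
    return mu + rng.standard_normal(problem.n) * np.sqrt(sigma2_e)


def bootstrap_ci(
    fit: LmmFit,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> VarianceProportions:
    """Parametric-bootstrap percentile CIs for the variance proportions.

    Simulates ``n_boot`` datasets from the fitted model (fixed effects plus
    Gaussian random effects at the estimated variances), refits each by the
    fitted criterion, and takes percentile intervals of each component's
    proportion of total variance.  Refits that fail are dropped and counted.
    A seed is mandatory: the CIs are part of the reported results and must
    be reproducible.
    """
    if seed is None:
        raise ValueError("bootstrap_ci requires an explicit seed")
    warn: list[str] = []
    if n_boot < 100:
        warn.append(f"n_boot={n_boot} is small; percentile CIs will be noisy")
    problem = fit._problem
    if problem is None:
        raise ValueError("fit does not carry its design; refit with fit_lmm")
    rng = np.random.default_rng(seed)
    beta = np.array(list(fit.fixed_estimates.values()))
    sigma2_e = fit.variance_estimates["residual"]
    comps = list(fit.spec.random) + ["residual"]
    reml = fit.method == "reml"
    y0 = problem.y.copy()
    warm = np.log(np.maximum(fit.theta, _VAR_FLOOR))
    draws = np.full((n_boot, len(comps)), np.nan)
    n_failed = 0
    try:
        for b in range(n_boot):
            problem.set_y(_simulate_response(problem, beta, fit.theta, sigma2_e, rng))
            try:
                # loose tolerances: percentile-CI precision is dominated by
                # Monte Carlo noise, not by the refit optimum
                theta_b, _, _ = _optimize_theta(
                    problem, reml, starts=[warm], xatol=1e-4, fatol=1e-9,
                    maxiter=200, polish=False,
                )
                _, _, s2e_b, _ = problem.solve(theta_b, reml=reml)
                var_b = np.append(theta_b * s2e_b, s2e_b)
                tot = var_b.sum()
                if tot <= 0 or not np.all(np.isfinite(var_b)):
                    n_failed += 1
                    continue
                draws[b] = var_b / tot
            except (ConvergenceError, linalg.LinAlgError):
                n_failed += 1
    finally:
        problem.set_y(y0)
    good = draws[np.all(np.isfinite(draws), axis=1)]
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(good, 100 * alpha, axis=0)
    hi = np.percentile(good, 100 * (1 - alpha), axis=0)
    point = variance_proportions(fit).proportions
    return VarianceProportions(
        proportions=point,
        ci={c: (float(l), float(h)) for c, l, h in zip(comps, lo, hi)},
        n_boot=n_boot - n_failed,
        n_failed=n_failed,
        warnings=warn,
    )


def anova_table(fit: LmmFit, data: pd.DataFrame) -> AnovaTable:
    """Sequential (Type I) fixed-effect ANOVA on the response after
    subtracting the predicted random effects (BLUPs).

    Sums of squares accumulate in the order the fixed terms were specified;
    F uses the residual mean square of the full fixed model on the
    random-effect-adjusted response.
    """
    if not fit.spec.fixed:
        raise ValueError("model has no fixed terms to tabulate")
    problem = fit._problem
    y = data[fit.spec.response].to_numpy(float)
    X, _, slices = build_fixed_design(data, fit.spec.fixed)
    _, blups, _, _ = problem.solve(fit.theta, reml=(fit.method == "reml"))
    y_adj = y - (problem.Z @ blups if problem.q else 0.0)
    Q, R = np.linalg.qr(X)
    coefs = Q.T @ y_adj
    rss = float(y_adj @ y_adj - coefs @ coefs)
    df_resid = len(y) - X.shape[1]
    ms_resid = rss / df_resid
    rows = []
    for term in fit.spec.fixed:
        sl = slices[term]
        ss = float(np.sum(coefs[sl] ** 2))
        df = sl.stop - sl.start
        ms = ss / df
        if ms_resid > 0:
            f_stat = ms / ms_resid
        else:  # deterministic response: F undefined (infinite for signal terms)
            f_stat = np.inf if ms > 0 else np.nan
        rows.append((term, df, ss, ms, f_stat))
    return AnovaTable(
        rows=pd.DataFrame(rows, columns=["term", "df", "sum_sq", "mean_sq", "F"]),
        residual_df=df_resid,
        residual_mean_sq=ms_resid,
    )


def _is_nested(a: ModelSpec, b: ModelSpec) -> bool:
    return set(a.fixed) <= set(b.fixed) and set(a.random) <= set(b.random)


def compare_models(fit_a: LmmFit, fit_b: LmmFit, data_a: pd.DataFrame | None = None,
                   data_b: pd.DataFrame | None = None) -> dict[str, float]:
    """Likelihood-ratio comparison of nested fits (a nested in b).

    When the fixed effects differ, both models are refitted internally by
    maximum likelihood (REML criteria are not comparable across fixed
    structures).  Returns LRT chi-square, its df and p-value, the
    log-likelihood difference and delta AIC (b minus a).
    """
    if not _is_nested(fit_a.spec, fit_b.spec):
        raise ValueError("models are not nested (a must nest within b)")
    if fit_a.spec.fixed != fit_b.spec.fixed:
        if fit_a.method != "ml":
            if data_a is None:
                raise ValueError("data_a required to refit model a by ML")
            fit_a = fit_lmm(data_a, fit_a.spec, method="ml")
        if fit_b.method != "ml":
            if data_b is None:
                raise ValueError("data_b required to refit model b by ML")
            fit_b = fit_lmm(data_b, fit_b.spec, method="ml")
    ll_a, ll_b = fit_a.loglik, fit_b.loglik
    chi2 = max(2.0 * (ll_b - ll_a), 0.0)
    df = fit_b.n_params - fit_a.n_params
    aic_a = 2.0 * fit_a.n_params - 2.0 * ll_a
    aic_b = 2.0 * fit_b.n_params - 2.0 * ll_b
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 == 0 else 0.0)
    return {
        "lrt_chi2": float(chi2),
        "df": int(df),
        "p": p,
        "delta_loglik": float(ll_b - ll_a),
        "delta_aic": float(aic_b - aic_a),
    }
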