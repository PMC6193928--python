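"""Linear mixed models with Satterthwaite df, Nakagawa R² and stepwise AIC.

The two study models are Gaussian LMMs with a single grouping factor:

* hourly egg availability ~ period of day + day of year + predator presence
  + temperature, random intercept by year;
* per-individual hourly predator presence ~ period + day of year + eggs,
  random intercept and date slope by individual.

The fit is a profiled REML/ML optimization over the relative random-effect
Cholesky factor Λ (Ψ = ΛΛ' = G/σ²), exactly the parameterization lme4 uses:
β and σ² are profiled out analytically, and all per-group quantities reduce
to cross-products, so one likelihood evaluation is O(Σᵢ q³ + pq²). A short
Newton polish on the profiled deviance pins the optimum to ~1e-11 so that
refits of numerically perturbed but equivalent data agree to high precision.

Satterthwaite denominator degrees of freedom follow the standard recipe:
for a fixed effect with sampling variance v(φ) = [C(φ)]ⱼⱼ, where
C(φ) = (X'V(φ)⁻¹X)⁻¹ and φ = (vech G, σ²),

    df = 2·v² / (∇v' A ∇v),   A = inverse observed information of φ̂

with gradient and information obtained by central differences of the
unprofiled REML log-likelihood. Nakagawa–Schielzeth R² uses
σ²_f = var(Xβ̂), σ²_r = mean over rows of zᵢ'Ĝzᵢ (exact for random
intercepts, the standard generalization for random slopes):
R²m = σ²_f/(σ²_f+σ²_r+σ²_e), R²c = (σ²_f+σ²_r)/(σ²_f+σ²_r+σ²_e).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from driftwatch.errors import (
    DriftwatchError,
    InsufficientDataError,
    InvalidParameterError,
)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# design construction and scaling
# ---------------------------------------------------------------------------

def build_design(
    egg_series: pd.Series,
    bleak_matrix: pd.DataFrame,
    temperature: pd.DataFrame,
    day_frac: pd.Series,
    model: str,
    temp_tolerance: pd.Timedelta = pd.Timedelta(minutes=90),
) -> tuple[pd.DataFrame, int]:
    """Assemble the hourly design table for the egg or the predator model.

    Temperature is joined by nearest logger reading within ``temp_tolerance``;
    bins without a reading that close are flagged and dropped (their count is
    returned). The egg model has one row per bin with predator presence
    aggregated to the per-bin sum of individual presence fractions; the
    predator model has one row per individual × bin.
    """
    if model not in ("eggs", "bleak"):
        raise InvalidParameterError(f"model must be 'eggs' or 'bleak', got {model!r}")
    bins = egg_series.index
    if len(bins) == 0 or len(bins.intersection(bleak_matrix.index)) == 0:
        raise DriftwatchError("empty intersection of the hourly grids")
    base = pd.DataFrame(
        {
            "eggs": egg_series,
            "bleak_presence": bleak_matrix.reindex(bins).fillna(0.0).sum(axis=1),
            "day_frac": day_frac.reindex(bins),
        }
    )
    base["period_night"] = (base["day_frac"] < 0.5).astype(float)
    base["date"] = bins.dayofyear.astype(float)
    base["year"] = bins.year.astype(str)

    temp = temperature.sort_values("timestamp")
    joined = pd.merge_asof(
        base.reset_index(names="bin_start").sort_values("bin_start"),
        temp.rename(columns={"timestamp": "temp_time"}),
        left_on="bin_start",
        right_on="temp_time",
        direction="nearest",
        tolerance=temp_tolerance,
    )
    n_flagged = int(joined["temp_c"].isna().sum())
    joined = joined.dropna(subset=["temp_c"]).drop(columns=["temp_time"])
    joined = joined.set_index("bin_start")

    if model == "eggs":
        return joined, n_flagged

    long = []
    for ind in bleak_matrix.columns:
        block = joined.copy()
        block["presence"] = bleak_matrix[ind].reindex(block.index).fillna(0.0)
        block["bleak_id"] = ind
        long.append(block)
    out = pd.concat(long).reset_index()
    return out, n_flagged


def centre_scale(
    table: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score the named columns; returns the scaled table plus (mean, sd) per column.

    All model variables — including the binary period indicator — are scaled
    the same way so effect sizes are comparable across covariates with very
    different native ranges. A constant column is an error (its z-score is
    undefined), named explicitly.
    """
    out = table.copy()
    meta: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise InvalidParameterError(f"column {col!r} is constant; cannot scale")
        out[col] = (x - mu) / sd
        meta[col] = (mu, sd)
    return out, meta


# ---------------------------------------------------------------------------
# the mixed-model core
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomSpec:
    """Random-effect structure: grouping column and columns with random slopes.

    An intercept is always included; ``slopes`` adds correlated random
    slopes for the named (already scaled) covariates.
    """

    group: str
    slopes: tuple[str, ...] = ()


@dataclass(frozen=True)
class TermStat:
    estimate: float
    se: float
    df: float
    t: float
    p: float


@dataclass
class LmmFit:
    """Fixed-effect table plus variance components and fit diagnostics."""

    terms: dict[str, TermStat]
    cov_re: np.ndarray          # G, the random-effect covariance (q×q)
    sigma2_e: float             # residual variance
    sigma2_f: float             # variance of the fixed-effect predictor
    sigma2_r: float             # mean random-effect variance per observation
    r2_marginal: float
    r2_conditional: float
    loglik: float
    aic: float
    reml: bool
    n_obs: int
    n_groups: int
    fixed: tuple[str, ...]
    random: RandomSpec
    singular: bool = False
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))


class _GroupData:
    """Per-group cross-products; everything a likelihood evaluation needs."""

    __slots__ = ("ZtZ", "ZtX", "Zty", "XtX", "Xty", "yty", "n", "Z", "X", "y")

    def __init__(self, X: np.ndarray, Z: np.ndarray, y: np.ndarray):
        self.X, self.Z, self.y = X, Z, y
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n = len(y)


def _theta_to_lambda(theta: np.ndarray, q: int) -> np.ndarray:
    lam = np.zeros((q, q))
    lam[np.tril_indices(q)] = theta
    return lam


def _profiled(theta: np.ndarray, groups: list[_GroupData], p: int, reml: bool):
    """Profiled deviance pieces for relative covariance factor ``theta``.

    Returns (deviance, beta, sigma2, XtVinvX_scaled) where XtVinvX_scaled is
    Σ X'V₀⁻¹X with V₀ = I + ZΨZ' (so cov(β̂) = σ²·inv of it).
    """
    q = groups[0].Z.shape[1]
    lam = _theta_to_lambda(theta, q)
    n = sum(g.n for g in groups)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    for g in groups:
        A = lam.T @ g.ZtZ @ lam + np.eye(q)
        sign, ld = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None, None, None
        logdet += ld
        LZtX = lam.T @ g.ZtX
        LZty = lam.T @ g.Zty
        Ainv_LZtX = np.linalg.solve(A, LZtX)
        Ainv_LZty = np.linalg.solve(A, LZty)
        XtVX += g.XtX - LZtX.T @ Ainv_LZtX
        XtVy += g.Xty - LZtX.T @ Ainv_LZty
        yVy += g.yty - LZty @ Ainv_LZty
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None, None
    rss = max(yVy - beta @ XtVy, 1e-300)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, ldx = np.linalg.slogdet(XtVX)
        dev = dof * (1 + _LOG2PI + np.log(sigma2)) + logdet + ldx
    else:
        sigma2 = rss / n
        dev = n * (1 + _LOG2PI + np.log(sigma2)) + logdet
    return dev, beta, sigma2, XtVX, logdet


def _newton_polish(fun, x0: np.ndarray, bounds_lo: np.ndarray) -> np.ndarray:
    """A few damped Newton steps with numeric derivatives, for a tight optimum."""
    x = x0.copy()
    d = len(x)
    for _ in range(12):
        h = np.maximum(1e-6, 1e-6 * np.abs(x))
        g = np.zeros(d)
        H = np.zeros((d, d))
        f0 = fun(x)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h[i]
            fp, fm = fun(x + ei), fun(x - ei)
            g[i] = (fp - fm) / (2 * h[i])
            H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
        for i, j in itertools.combinations(range(d), 2):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(d), -g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # damped line search respecting the lower bounds on diagonal entries
        t = 1.0
        for _ in range(30):
            xn = np.maximum(x + t * step, bounds_lo)
            if fun(xn) <= f0 + 1e-14 * abs(f0):
                break
            t *= 0.5
        else:
            break
        if np.max(np.abs(xn - x)) < 1e-11:
            x = xn
            break
        x = xn
    return x


def _unprofiled_reml(phi: np.ndarray, groups: list[_GroupData], p: int):
    """REML log-likelihood and C(φ)=cov(β̂) at unprofiled φ = (vech G, σ²).

    Uses V⁻¹ = σ⁻²[I − ZG(σ²I + Z'ZG)⁻¹Z'], valid for any (even singular) G.
    """
    q = groups[0].Z.shape[1]
    G = np.zeros((q, q))
    iu = np.tril_indices(q)
    G[iu] = phi[:-1]
    G = G + np.tril(G, -1).T
    sigma2 = phi[-1]
    if sigma2 <= 0:
        return -np.inf, None
    n = sum(g.n for g in groups)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yVy = 0.0
    logdet = 0.0
    for g in groups:
        K = sigma2 * np.eye(q) + g.ZtZ @ G
        sign, ldK = np.linalg.slogdet(K)
        if sign <= 0:
            return -np.inf, None
        logdet += g.n * np.log(sigma2) + ldK - q * np.log(sigma2)
        Kinv_ZtX = np.linalg.solve(K, g.ZtX)
        Kinv_Zty = np.linalg.solve(K, g.Zty)
        XtVX += (g.XtX - g.ZtX.T @ G @ Kinv_ZtX) / sigma2
        XtVy += (g.Xty - g.ZtX.T @ G @ Kinv_Zty) / sigma2
        yVy += (g.yty - g.Zty @ G @ Kinv_Zty) / sigma2
    try:
        C = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        return -np.inf, None
    beta = C @ XtVy
    quad = yVy - beta @ XtVy
    sign, ldx = np.linalg.slogdet(XtVX)
    ll = -0.5 * (logdet + quad + ldx + (n - p) * _LOG2PI)
    return ll, C


def _satterthwaite_dfs(
    phi_hat: np.ndarray, groups: list[_GroupData], p: int, n: int
) -> np.ndarray:
    """Per-coefficient Satterthwaite df via numeric differentiation of C(φ)."""
    d = len(phi_hat)
    h = np.maximum(1e-7, 1e-4 * np.abs(phi_hat))

    def loglik(phi):
        return _unprofiled_reml(phi, groups, p)[0]

    def covdiag(phi):
        C = _unprofiled_reml(phi, groups, p)[1]
        return None if C is None else np.diag(C).copy()

    # observed information of the variance parameters
    H = np.zeros((d, d))
    f0 = loglik(phi_hat)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (loglik(phi_hat + ei) - 2 * f0 + loglik(phi_hat - ei)) / h[i] ** 2
    for i, j in itertools.combinations(range(d), 2):
        ei = np.zeros(d)
        ej = np.zeros(d)
        ei[i] = h[i]
        ej[j] = h[j]
        H[i, j] = H[j, i] = (
            loglik(phi_hat + ei + ej)
            - loglik(phi_hat + ei - ej)
            - loglik(phi_hat - ei + ej)
            + loglik(phi_hat - ei - ej)
        ) / (4 * h[i] * h[j])
    A = np.linalg.pinv(-H)

    v0 = covdiag(phi_hat)
    grads = np.zeros((p, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        vp, vm = covdiag(phi_hat + ei), covdiag(phi_hat - ei)
        if vp is None or vm is None:
            continue
        grads[:, i] = (vp - vm) / (2 * h[i])
    dfs = np.empty(p)
    for j in range(p):
        denom = grads[j] @ A @ grads[j]
        if not np.isfinite(denom) or denom <= 0:
            dfs[j] = n - p
        else:
            dfs[j] = 2.0 * v0[j] ** 2 / denom
    return np.clip(dfs, 1.0, n - p)


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    random: RandomSpec,
    reml: bool = True,
    satterthwaite: bool = True,
) -> LmmFit:
    """Fit a Gaussian LMM with one grouping factor by profiled REML (or ML).

    ``fixed`` lists covariate columns (an intercept is always prepended).
    Raises :class:`InsufficientDataError` if the grouping factor has fewer
    than two levels. A fit whose random-effect covariance collapses to the
    boundary is flagged ``singular`` with a warning rather than hidden.
    """
    fixed = tuple(fixed)
    labels = ("intercept",) + fixed
    levels = table[random.group].unique()
    if len(levels) < 2:
        raise InsufficientDataError(
            f"grouping factor {random.group!r} needs >= 2 levels, got {len(levels)}"
        )
    y_all = table[response].to_numpy(dtype=float)
    X_all = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in fixed]
    )
    Z_all = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in random.slopes]
    )
    q = Z_all.shape[1]
    p = X_all.shape[1]
    codes = pd.Categorical(table[random.group]).codes
    groups = [
        _GroupData(X_all[codes == g], Z_all[codes == g], y_all[codes == g])
        for g in range(codes.max() + 1)
    ]
    n = len(y_all)

    ntheta = q * (q + 1) // 2
    # theta layout follows np.tril_indices order; diagonal entries bounded >= 0
    tril = list(zip(*np.tril_indices(q)))
    lo = np.array([0.0 if i == j else -np.inf for i, j in tril])
    x0 = np.array([1.0 if i == j else 0.0 for i, j in tril])

    def objective(theta):
        return _profiled(theta, groups, p, reml)[0]

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(l if np.isfinite(l) else None, None) for l in lo],
    )
    theta = _newton_polish(objective, res.x, lo)
    dev, beta, sigma2, XtVX, _ = _profiled(theta, groups, p, reml)
    if not np.isfinite(dev):
        raise DriftwatchError("mixed-model fit failed to converge")
    lam = _theta_to_lambda(theta, q)
    psi = lam @ lam.T
    G = sigma2 * psi
    singular = bool(np.any(np.abs(np.diag(lam)) < 1e-6))
    if singular:
        warnings.warn(
            f"singular fit: random-effect covariance for {random.group!r} is on "
            "the boundary"
        )

    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    loglik = -0.5 * dev

    phi_hat = np.concatenate([G[np.tril_indices(q)], [sigma2]])
    if satterthwaite:
        dfs = _satterthwaite_dfs(phi_hat, groups, p, n)
    else:
        dfs = np.full(p, n - p, dtype=float)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)

    # Nakagawa-Schielzeth variance decomposition
    fitted_fixed = X_all @ beta
    sigma2_f = float(np.var(fitted_fixed))
    sigma2_r = float(np.mean(np.einsum("ij,jk,ik->i", Z_all, G, Z_all)))
    denom = sigma2_f + sigma2_r + sigma2
    r2m = sigma2_f / denom
    r2c = (sigma2_f + sigma2_r) / denom

    k = p + ntheta + 1
    aic = float(dev + 2 * k)

    terms = {
        lab: TermStat(float(b), float(s), float(df), float(t), float(pv))
        for lab, b, s, df, t, pv in zip(labels, beta, se, dfs, tvals, pvals)
    }
    return LmmFit(
        terms=terms,
        cov_re=G,
        sigma2_e=float(sigma2),
        sigma2_f=sigma2_f,
        sigma2_r=sigma2_r,
        r2_marginal=float(r2m),
        r2_conditional=float(r2c),
        loglik=float(loglik),
        aic=aic,
        reml=reml,
        n_obs=n,
        n_groups=len(groups),
        fixed=fixed,
        random=random,
        singular=singular,
        beta=beta,
    )


def nakagawa_r2(sigma2_f: float, sigma2_r: float, sigma2_e: float) -> tuple[float, float]:
    """Closed-form marginal/conditional R² from the three variance components."""
    denom = sigma2_f + sigma2_r + sigma2_e
    return sigma2_f / denom, (sigma2_f + sigma2_r) / denom


def stepwise_aic(
    table: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    random: RandomSpec,
) -> tuple[tuple[str, ...], LmmFit, list[dict]]:
    """Backward elimination of fixed effects by ML-based AIC.

    The random structure is held fixed. Candidate models at each step are ML
    refits (REML likelihoods are not comparable across fixed structures); the
    returned final fit is refit by REML. The trace logs every candidate AIC.
    """
    current = list(fixed)
    trace: list[dict] = []
    cur_fit = fit_lmm(table, response, current, random, reml=False, satterthwaite=False)
    while current:
        candidates = []
        for term in current:
            reduced = [t for t in current if t != term]
            f = fit_lmm(table, response, reduced, random, reml=False, satterthwaite=False)
            candidates.append((f.aic, term, f))
        trace.append(
            {
                "model": tuple(current),
                "aic": cur_fit.aic,
                "candidates": {t: a for a, t, _ in candidates},
            }
        )
        best_aic, best_term, best_fit = min(candidates, key=lambda c: c[0])
        if best_aic < cur_fit.aic:
            current.remove(best_term)
            cur_fit = best_fit
        else:
            break
    final = fit_lmm(table, response, current, random, reml=True)
    return tuple(current), final, trace


def kendall_tau(x, y, seed: int = 0, n_perm: int = 9999) -> tuple[float, float]:
    """Kendall's tau-b with tie correction, plus a two-sided p-value.

    The statistic is the tie-corrected tau-b. For n ≤ 8 the p-value is exact
    by full enumeration of permutations; for 8 < n ≤ 30 it is a seeded
    Monte-Carlo permutation p-value (add-one estimator); above 30 the normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 2:
        raise InsufficientDataError("kendall_tau needs at least two observations")
    tau = float(stats.kendalltau(x, y, variant="b").statistic)

    def batch_numerators(perm_mat: np.ndarray) -> np.ndarray:
        # concordant-minus-discordant counts for many permutations at once;
        # the tie corrections are permutation-invariant so only this varies
        sx = np.sign(x[:, None] - x[None, :])
        sy = np.sign(perm_mat[:, :, None] - perm_mat[:, None, :])
        return np.einsum("ij,kij->k", sx, sy) / 2.0

    def tau_denom() -> float:
        n0 = n * (n - 1) / 2.0
        _, cx = np.unique(x, return_counts=True)
        _, cy = np.unique(y, return_counts=True)
        n1 = np.sum(cx * (cx - 1) / 2.0)
        n2 = np.sum(cy * (cy - 1) / 2.0)
        return float(np.sqrt((n0 - n1) * (n0 - n2)))

    if n <= 8:
        perms = np.array(list(itertools.permutations(y)))
        taus = batch_numerators(perms) / tau_denom()
        p = float(np.mean(np.abs(taus) >= abs(tau) - 1e-12))
    elif n <= 30:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        taus = batch_numerators(perms) / tau_denom()
        p = float((np.sum(np.abs(taus) >= abs(tau) - 1e-12) + 1) / (n_perm + 1))
    else:
        p = float(stats.kendalltau(x, y, variant="b", method="asymptotic").pvalue)
    return tau, float(p)
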