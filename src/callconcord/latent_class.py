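"""Latent class models for per-caller error rates without a gold standard.

K mutation callers evaluate N genomic positions for somatic status.  The
true status D_i of position i is unobserved; it is somatic with prevalence
eta = P(D_i = 1).  The observed K-bit detection pattern Y_i then follows a
two-component mixture

    P(Y_i) = (1 - eta) P(Y_i | D_i = 0) + eta P(Y_i | D_i = 1).

Two dependence structures are implemented:

* **Conditional independence (CI)** — given D_i the callers act
  independently, so each class-conditional factorizes over callers and the
  model has 1 + 2K free parameters: eta plus each caller's false-positive
  rate fp_k = P(Y_k=1 | D=0) and false-negative rate fn_k = P(Y_k=0 | D=1).
  Fitted by EM on the 2^K pattern-count table.

* **Random-effects probit (RE)** — a shared per-site standard-normal random
  effect b_i induces dependence among callers within a class:
  P(Y_k=1 | D=d, b) = Phi(a_{d,k} + sigma * b), with a single loading sigma
  shared between the somatic and non-somatic classes (one extra parameter
  over CI).  Marginalizing b uses Gauss-Hermite quadrature; the marginal
  per-caller rates have the closed form Phi(a_{d,k} / sqrt(1 + sigma^2)).
  Fitted by direct maximization of the multinomial log-likelihood.

Goodness of fit is assessed by the Pearson chi-square between observed and
fitted cell counts, with df = (2^K - 1) - (number of free parameters).
Both classes of a latent class model fit the data identically under label
swapping; the returned solution is always oriented so that mean
sensitivity exceeds mean false-positive rate (class 1 = somatic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .callset_io import PatternCounts, Pattern, all_patterns

__all__ = [
    "LcmCIParams",
    "LcmREParams",
    "LcmFit",
    "ci_pattern_prob",
    "ci_cell_probs",
    "ci_loglik",
    "fit_ci",
    "pearson_gof",
    "lcm_df",
    "re_pattern_prob",
    "re_cell_probs",
    "re_loglik",
    "fit_re",
    "marginal_rates",
    "ci_covariance",
    "re_covariance",
]

_PROB_FLOOR = 1e-12


def _phi(x):
    return special.ndtr(x)


@dataclass
class LcmCIParams:
    """Conditional-independence parameters: prevalence and per-caller rates."""

    eta: float
    fp: np.ndarray  # P(Y_k = 1 | D = 0)
    fn: np.ndarray  # P(Y_k = 0 | D = 1)

    def __post_init__(self) -> None:
        self.fp = np.asarray(self.fp, dtype=float)
        self.fn = np.asarray(self.fn, dtype=float)
        if self.fp.shape != self.fn.shape:
            raise ValueError("fp and fn must have equal length K")

    @property
    def K(self) -> int:
        return len(self.fp)

    @property
    def sens(self) -> np.ndarray:
        return 1.0 - self.fn

    def n_free(self) -> int:
        return 1 + 2 * self.K


@dataclass
class LcmREParams:
    """Random-effects probit parameters with shared loading sigma."""

    eta: float
    a0: np.ndarray  # probit intercepts, non-somatic class
    a1: np.ndarray  # probit intercepts, somatic class
    sigma: float

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=float)
        self.a1 = np.asarray(self.a1, dtype=float)
        if self.a0.shape != self.a1.shape:
            raise ValueError("a0 and a1 must have equal length K")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def K(self) -> int:
        return len(self.a0)

    def n_free(self) -> int:
        return 2 + 2 * self.K


@dataclass
class LcmFit:
    """A fitted latent class model with goodness-of-fit diagnostics."""

    params: LcmCIParams | LcmREParams
    loglik: float
    fitted_counts: dict[Pattern, float]
    pearson_chi2: float
    df: int
    converged: bool
    n_restarts_used: int
    pearson_chi2_pooled: float | None = None
    df_pooled: int | None = None
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# Conditional independence model


def ci_cell_probs(params: LcmCIParams, patterns: np.ndarray) -> np.ndarray:
    """Mixture cell probabilities for a [n_cells, K] 0/1 pattern matrix."""
    y = np.asarray(patterns, dtype=float)
    fp, sens = params.fp, params.sens
    p0 = np.prod(np.where(y == 1, fp, 1.0 - fp), axis=1)
    p1 = np.prod(np.where(y == 1, sens, 1.0 - sens), axis=1)
    return (1.0 - params.eta) * p0 + params.eta * p1


def ci_pattern_prob(params: LcmCIParams, pattern: Sequence[int]) -> float:
    """P(Y = pattern) under conditional independence."""
    return float(ci_cell_probs(params, np.asarray(pattern)[None, :])[0])


def ci_loglik(params: LcmCIParams, counts: PatternCounts) -> float:
    """Multinomial log-likelihood of a pattern-count table (kernel only)."""
    pats, n = counts.as_arrays()
    p = np.maximum(ci_cell_probs(params, pats), _PROB_FLOOR)
    return float(np.sum(n * np.log(p)))


def _orient_ci(params: LcmCIParams) -> LcmCIParams:
    """Resolve label switching: class 1 must be the better-detected class."""
    if params.sens.mean() < params.fp.mean():
        return LcmCIParams(eta=1.0 - params.eta, fp=params.sens, fn=1.0 - params.fp)
    return params


def _em_ci(
    counts: PatternCounts,
    start: LcmCIParams,
    tol: float,
    max_iter: int,
) -> tuple[LcmCIParams, float, bool, int, list[float]]:
    pats, n = counts.as_arrays()
    N = n.sum()
    eta, fp, sens = start.eta, start.fp.copy(), start.sens.copy()
    eps = 1e-10
    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p0 = np.prod(np.where(pats == 1, fp, 1.0 - fp), axis=1)
        p1 = np.prod(np.where(pats == 1, sens, 1.0 - sens), axis=1)
        p = np.maximum((1 - eta) * p0 + eta * p1, _PROB_FLOOR)
        ll = float(np.sum(n * np.log(p)))
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        # E-step: posterior P(D=1 | Y=y)
        w = eta * p1 / p
        # M-step: closed-form multinomial updates
        m1 = float(np.sum(n * w))
        m0 = N - m1
        eta = min(max(m1 / N, eps), 1 - eps)
        sens = np.clip((n * w) @ pats / max(m1, eps), eps, 1 - eps)
        fp = np.clip((n * (1 - w)) @ pats / max(m0, eps), eps, 1 - eps)
    return LcmCIParams(eta=eta, fp=fp, fn=1 - sens), trace[-1], converged, it, trace


def _ci_starts(counts: PatternCounts, n_restarts: int, rng: np.random.Generator):
    """Stratified random starts plus one data-driven start."""
    K = counts.K
    pats, n = counts.as_arrays()
    N = max(counts.N, 1)
    # data-driven: prevalence from the all-true cell share, rates from margins
    eta0 = min(max(counts.counts[(1,) * K] / N, 0.005), 0.5)
    marg = np.clip((n @ pats) / N, 0.01, 0.95)
    yield LcmCIParams(eta=eta0, fp=np.minimum(marg / 4, 0.2), fn=1 - np.clip(marg / max(eta0, 1e-3), 0.3, 0.99))
    for r in range(n_restarts - 1):
        lo, hi = ((0.002, 0.1) if r % 2 == 0 else (0.1, 0.6))
        eta = rng.uniform(lo, hi)
        fp = rng.uniform(0.0005, 0.15, K)
        sens = rng.uniform(0.5, 0.995, K)
        yield LcmCIParams(eta=eta, fp=fp, fn=1 - sens)


def fit_ci(
    counts: PatternCounts,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int | np.random.Generator | None = 0,
) -> LcmFit:
    """Maximum-likelihood CI fit by EM with multiple restarts.

    Requires K >= 3 (with K = 3 the model is saturated, df = 0).  The best
    of ``n_restarts`` EM runs is returned, oriented so class 1 is the
    high-detection (somatic) class.
    """
    if counts.K < 3:
        raise ValueError(f"CI latent class model needs K >= 3 callers, got K={counts.K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for start in _ci_starts(counts, n_restarts, rng):
        res = _em_ci(counts, start, tol, max_iter)
        if best is None or res[1] > best[1]:
            best = res
    params, ll, converged, n_iter, trace = best
    params = _orient_ci(params)
    return _finish_fit(
        params, ll, counts, model="ci", converged=converged,
        n_restarts=n_restarts, n_iter=n_iter, trace=trace,
    )


# ---------------------------------------------------------------------------
# Goodness of fit


def pearson_gof(
    observed: PatternCounts,
    fitted_counts: dict[Pattern, float] | np.ndarray,
    pool_floor: float = 0.0,
) -> tuple[float, int]:
    """Pearson chi-square between observed and fitted cell counts.

    Returns ``(chi2, n_cells_used)``.  With ``pool_floor > 0``, cells whose
    expected count falls below the floor are pooled into one remainder cell
    (``n_cells_used`` then counts the pooled cell once); with the default
    floor of 0 every cell enters individually.
    """
    pats = all_patterns(observed.K)
    obs = np.array([observed.counts[p] for p in pats], dtype=float)
    if isinstance(fitted_counts, dict):
        exp = np.array([fitted_counts[p] for p in pats], dtype=float)
    else:
        exp = np.asarray(fitted_counts, dtype=float)
    if not np.isclose(obs.sum(), exp.sum(), rtol=1e-6):
        raise ValueError(
            f"observed total {obs.sum()} != fitted total {exp.sum():.4f}"
        )
    keep = exp >= pool_floor if pool_floor > 0 else np.ones_like(exp, dtype=bool)
    if pool_floor > 0 and not keep.all():
        if not keep.any():
            raise ValueError("all cells below pooling floor; statistic undefined")
        o = np.append(obs[keep], obs[~keep].sum())
        e = np.append(exp[keep], exp[~keep].sum())
        if e[-1] <= 0:  # nothing expected in the remainder: drop it
            o, e = o[:-1], e[:-1]
    else:
        o, e = obs[exp > 0], exp[exp > 0]
    chi2 = float(np.sum((o - e) ** 2 / e))
    return chi2, len(o)


def lcm_df(K: int, model: str) -> int:
    """Residual degrees of freedom: cells - 1 - free parameters."""
    if K < 2:
        raise ValueError("need at least K = 2 callers")
    n_params = {"ci": 2 * K + 1, "re": 2 * K + 2}[model]
    df = 2**K - 1 - n_params
    if df < 0:
        raise ValueError(f"model '{model}' not identifiable at K={K} (df={df})")
    return df


def _finish_fit(params, ll, counts, model, converged, n_restarts, n_iter, trace) -> LcmFit:
    pats_list = all_patterns(counts.K)
    pats, n = counts.as_arrays()
    if model == "ci":
        p = ci_cell_probs(params, pats)
    else:
        p = re_cell_probs(params, pats)
    fitted = dict(zip(pats_list, counts.N * p))
    chi2, _ = pearson_gof(counts, fitted, pool_floor=0.0)
    chi2_pooled, used = pearson_gof(counts, fitted, pool_floor=0.5)
    df = lcm_df(counts.K, model)
    df_pooled = df - (2**counts.K - used)
    return LcmFit(
        params=params,
        loglik=ll,
        fitted_counts=fitted,
        pearson_chi2=chi2,
        df=df,
        converged=converged,
        n_restarts_used=n_restarts,
        pearson_chi2_pooled=chi2_pooled,
        df_pooled=df_pooled,
        n_iter=n_iter,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# Standard errors by observed information


def _num_hessian(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian of scalar f at x."""
    p = len(x)
    H = np.empty((p, p))
    h = step * np.maximum(np.abs(x), 1.0)
    for i in range(p):
        for j in range(i, p):
            xi, xj = h[i], h[j]
            if i == j:
                H[i, i] = (
                    f(x + 2 * _e(p, i) * xi) - 2 * f(x) + f(x - 2 * _e(p, i) * xi)
                ) / (4 * xi * xi)
            else:
                H[i, j] = H[j, i] = (
                    f(x + _e(p, i) * xi + _e(p, j) * xj)
                    - f(x + _e(p, i) * xi - _e(p, j) * xj)
                    - f(x - _e(p, i) * xi + _e(p, j) * xj)
                    + f(x - _e(p, i) * xi - _e(p, j) * xj)
                ) / (4 * xi * xj)
    return H


def _e(p: int, i: int) -> np.ndarray:
    v = np.zeros(p)
    v[i] = 1.0
    return v


def ci_covariance(params: LcmCIParams, counts: PatternCounts) -> np.ndarray:
    """Asymptotic covariance of (eta, fp_1..K, fn_1..K) at the CI MLE.

    Inverse of the observed information (negative Hessian of the
    multinomial log-likelihood), by central finite differences;
    pseudo-inverted for robustness near the parameter-space boundary.
    """
    K = params.K

    def negll(x: np.ndarray) -> float:
        p = LcmCIParams(
            eta=float(np.clip(x[0], 1e-9, 1 - 1e-9)),
            fp=np.clip(x[1 : 1 + K], 1e-9, 1 - 1e-9),
            fn=np.clip(x[1 + K :], 1e-9, 1 - 1e-9),
        )
        return -ci_loglik(p, counts)

    x0 = np.concatenate([[params.eta], params.fp, params.fn])
    return np.linalg.pinv(_num_hessian(negll, x0))


def re_covariance(
    params: LcmREParams, counts: PatternCounts, n_quad: int = 40
) -> np.ndarray:
    """Asymptotic covariance of (eta, a0_1..K, a1_1..K, sigma) at the RE MLE."""
    K = params.K

    def negll(x: np.ndarray) -> float:
        p = LcmREParams(
            eta=float(np.clip(x[0], 1e-9, 1 - 1e-9)),
            a0=x[1 : 1 + K],
            a1=x[1 + K : 1 + 2 * K],
            sigma=float(max(x[-1], 0.0)),
        )
        return -re_loglik(p, counts, n_quad)

    x0 = _re_pack(params).copy()
    x0[0] = params.eta  # untransformed prevalence
    return np.linalg.pinv(_num_hessian(negll, x0))


# ---------------------------------------------------------------------------
# Random-effects probit model


def _gh_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(b)], b ~ N(0,1), via Gauss-Hermite."""
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def re_cell_probs(
    params: LcmREParams, patterns: np.ndarray, n_quad: int = 40
) -> np.ndarray:
    """Marginal cell probabilities under the random-effects probit model."""
    y = np.asarray(patterns, dtype=float)  # [n_cells, K]
    nodes, weights = _gh_nodes(n_quad)  # [Q]
    out = np.zeros(len(y))
    for d, (a, wclass) in enumerate(
        [(params.a0, 1.0 - params.eta), (params.a1, params.eta)]
    ):
        # prob[k, q] = Phi(a_k + sigma * b_q)
        prob = _phi(a[:, None] + params.sigma * nodes[None, :])
        prob = np.clip(prob, _PROB_FLOOR, 1 - _PROB_FLOOR)
        # cell[c, q] = prod_k prob^y (1-prob)^(1-y)
        logp = y @ np.log(prob) + (1 - y) @ np.log1p(-prob)
        out += wclass * np.exp(logp) @ weights
    return out


def re_pattern_prob(
    params: LcmREParams, pattern: Sequence[int], n_quad: int = 40
) -> float:
    """P(Y = pattern) under the random-effects model (Gauss-Hermite)."""
    if n_quad < 10:
        raise ValueError("n_quad must be at least 10")
    return float(re_cell_probs(params, np.asarray(pattern)[None, :], n_quad)[0])


def re_loglik(params: LcmREParams, counts: PatternCounts, n_quad: int = 40) -> float:
    """Multinomial log-likelihood under the random-effects model."""
    pats, n = counts.as_arrays()
    p = np.maximum(re_cell_probs(params, pats, n_quad), _PROB_FLOOR)
    return float(np.sum(n * np.log(p)))


def marginal_rates(params: LcmREParams) -> tuple[np.ndarray, np.ndarray]:
    """Marginal (fp, fn) implied by the RE model.

    Integrating the probit over the standard-normal random effect gives
    P(Y_k=1 | D=d) = Phi(a_{d,k} / sqrt(1 + sigma^2)).
    """
    scale = np.sqrt(1.0 + params.sigma**2)
    fp = _phi(params.a0 / scale)
    fn = 1.0 - _phi(params.a1 / scale)
    return fp, fn


def _orient_re(params: LcmREParams) -> LcmREParams:
    fp, fn = marginal_rates(params)
    if (1 - fn).mean() < fp.mean():
        return LcmREParams(
            eta=1.0 - params.eta, a0=params.a1, a1=params.a0, sigma=params.sigma
        )
    return params


def _re_pack(params: LcmREParams) -> np.ndarray:
    return np.concatenate(
        [[special.logit(params.eta)], params.a0, params.a1, [params.sigma]]
    )


def _re_unpack(x: np.ndarray, K: int) -> LcmREParams:
    return LcmREParams(
        eta=float(special.expit(x[0])),
        a0=x[1 : 1 + K],
        a1=x[1 + K : 1 + 2 * K],
        sigma=float(x[-1]),
    )


def fit_re(
    counts: PatternCounts,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 5000,
    n_quad: int = 40,
    seed: int | np.random.Generator | None = 0,
) -> LcmFit:
    """Maximum-likelihood RE-probit fit by quasi-Newton on transformed params.

    The CI fit provides the primary start (sigma near 0 plus small
    perturbations); the likelihood is maximized with L-BFGS-B, sigma bounded
    below by 0, so the CI model is nested at the boundary and
    ``loglik(fit_re) >= loglik(fit_ci)`` up to optimizer tolerance.
    """
    if counts.K < 4:
        raise ValueError(f"RE model needs K >= 4 callers for df >= 1, got K={counts.K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = counts.K
    pats, n = counts.as_arrays()

    def nll(x: np.ndarray) -> float:
        p = np.maximum(re_cell_probs(_re_unpack(x, K), pats, n_quad), _PROB_FLOOR)
        return -float(np.sum(n * np.log(p)))

    ci = fit_ci(counts, n_restarts=max(n_restarts, 5), tol=tol, max_iter=max_iter, seed=rng)
    cip: LcmCIParams = ci.params  # type: ignore[assignment]
    a0 = special.ndtri(np.clip(cip.fp, 1e-6, 1 - 1e-6))
    a1 = special.ndtri(np.clip(cip.sens, 1e-6, 1 - 1e-6))
    starts = [LcmREParams(eta=cip.eta, a0=a0, a1=a1, sigma=0.1)]
    for _ in range(n_restarts - 1):
        starts.append(
            LcmREParams(
                eta=float(np.clip(cip.eta * rng.uniform(0.5, 2.0), 1e-4, 0.6)),
                a0=a0 + rng.normal(0, 0.5, K),
                a1=a1 + rng.normal(0, 0.5, K),
                sigma=float(rng.uniform(0.0, 2.5)),
            )
        )
    bounds = [(-12, 12)] + [(-8, 8)] * (2 * K) + [(0.0, 10.0)]
    best_x, best_ll, ok, n_iter = None, -np.inf, False, 0
    for s in starts:
        res = optimize.minimize(
            nll, _re_pack(s), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol},
        )
        if -res.fun > best_ll:
            best_x, best_ll, ok, n_iter = res.x, -res.fun, bool(res.success), res.nit
    params = _orient_re(_re_unpack(best_x, K))
    return _finish_fit(
        params, best_ll, counts, model="re", converged=ok,
        n_restarts=len(starts), n_iter=n_iter, trace=[best_ll],
    )
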