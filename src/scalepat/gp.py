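"""Bayesian optimization of reaction-diffusion parameters.

A Matérn-5/2 Gaussian process with automatic relevance determination (one
length scale per parameter) surrogates the expensive pattern objective; the
expected-improvement acquisition proposes the next parameter vector.  The
module also provides the greedy iterative parameter-addition procedure used
to narrow the optimization subset, and the sensitivity scan that perturbs
the optimum within +/-10% of the fitted length scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

__all__ = [
    "GPModel",
    "OptSpec",
    "matern52",
    "fit_gp",
    "gp_posterior",
    "expected_improvement",
    "bayes_opt",
    "iterative_param_addition",
    "sensitivity_scan",
]


def matern52(x, xp, sigma_f: float, length_scales) -> np.ndarray:
    """Matérn-5/2 ARD covariance.

    k(x, x') = sigma_f^2 (1 + sqrt(5) h + 5/3 h^2) exp(-sqrt(5) h) with
    h^2 = (x - x') diag(ls)^-2 (x - x')^T.  ``x`` and ``xp`` may be single
    vectors or row-stacked matrices.
    """
    if sigma_f <= 0 or np.any(np.asarray(length_scales) <= 0):
        raise ValueError("hyper-parameters must be positive")
    X = np.atleast_2d(np.asarray(x, float))
    Xp = np.atleast_2d(np.asarray(xp, float))
    ls = np.asarray(length_scales, float)
    d = (X[:, None, :] - Xp[None, :, :]) / ls
    h = np.sqrt(np.maximum((d * d).sum(-1), 0.0))
    r5 = np.sqrt(5.0) * h
    K = sigma_f**2 * (1.0 + r5 + (5.0 / 3.0) * h * h) * np.exp(-r5)
    if np.ndim(x) == 1 and np.ndim(xp) == 1:
        return float(K[0, 0])
    return K


@dataclass
class GPModel:
    """Noise-free GP with zero prior mean and cached Cholesky factor."""

    X: np.ndarray
    f: np.ndarray
    sigma_f: float
    length_scales: np.ndarray
    jitter: float = 1e-10
    _cho: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.f = np.asarray(self.f, float).ravel()
        self.length_scales = np.asarray(self.length_scales, float)
        self._factorize()

    def _factorize(self) -> None:
        K = matern52(self.X, self.X, self.sigma_f, self.length_scales)
        jit = self.jitter
        while True:
            try:
                self._cho = cho_factor(K + jit * np.eye(len(K)), lower=True)
                break
            except np.linalg.LinAlgError:
                jit *= 10.0
                if jit > 1e-6:
                    raise
        if jit != self.jitter:
            self.jitter = jit
        self._alpha = cho_solve(self._cho, self.f)


def _neg_log_marginal(theta: np.ndarray, X: np.ndarray, f: np.ndarray, jitter: float) -> float:
    sigma_f, ls = np.exp(theta[0]), np.exp(theta[1:])
    K = matern52(X, X, sigma_f, ls) + jitter * np.eye(len(X))
    try:
        L = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, f))
    return float(0.5 * f @ alpha + np.log(np.diag(L)).sum() + 0.5 * len(f) * np.log(2 * np.pi))


def fit_gp(X: np.ndarray, f: np.ndarray, rng=None, n_restarts: int = 3,
           jitter: float = 1e-10) -> GPModel:
    """Fit GP hyper-parameters by log-marginal-likelihood ascent with restarts."""
    X = np.atleast_2d(np.asarray(X, float))
    f = np.asarray(f, float).ravel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = X.shape[1]
    span = np.maximum(X.max(0) - X.min(0), 1e-3)
    sf0 = max(np.std(f), 1e-3)
    best, best_val = None, np.inf
    starts = [np.concatenate([[np.log(sf0)], np.log(span)])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.concatenate(
                [[np.log(sf0) + rng.normal(0, 0.5)], np.log(span) + rng.normal(0, 1.0, d)]
            )
        )
    for x0 in starts:
        res = minimize(
            _neg_log_marginal, x0, args=(X, f, jitter), method="L-BFGS-B",
            bounds=[(-10, 10)] * (d + 1),
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    return GPModel(X, f, float(np.exp(best[0])), np.exp(best[1:]), jitter)


def gp_posterior(model: GPModel, xstar) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at ``xstar`` (prior mean m(x) = 0).

    m_post = k*^T K^-1 f ; k_post = k(x*, x*) - k*^T K^-1 k*.
    """
    Xs = np.atleast_2d(np.asarray(xstar, float))
    ks = matern52(model.X, Xs, model.sigma_f, model.length_scales)
    mean = ks.T @ model._alpha
    v = cho_solve(model._cho, ks)
    var = np.maximum(model.sigma_f**2 - np.einsum("ij,ij->j", ks, v), 0.0)
    if np.ndim(xstar) == 1:
        return float(mean[0]), float(var[0])
    return mean, var


def expected_improvement(mean, var, f_min: float):
    """Closed-form expected improvement below the incumbent f_min.

    EI = (f_min - m) Phi(z) + s phi(z), z = (f_min - m)/s, s = sqrt(var);
    at s = 0 the EI is max(f_min - m, 0).
    """
    mean = np.asarray(mean, float)
    s = np.sqrt(np.asarray(var, float))
    out = np.maximum(f_min - mean, 0.0)
    pos = s > 0
    z = np.where(pos, (f_min - mean) / np.where(pos, s, 1.0), 0.0)
    out = np.where(pos, (f_min - mean) * norm.cdf(z) + s * norm.pdf(z), out)
    return float(out) if out.ndim == 0 else out


@dataclass
class OptSpec:
    """Search specification: active parameter names, box bounds, budgets."""

    names: list
    bounds: dict          # name -> (lo, hi), finite
    budget: int = 60
    n_init: int = 8
    stop_after: int = 50  # non-improving iterations before stopping
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in self.names:
            lo, hi = self.bounds[nm]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {nm} must be finite with lo < hi")

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.bounds[nm][0] for nm in self.names])

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.bounds[nm][1] for nm in self.names])


def _maximize_ei(model: GPModel, f_min: float, lo, hi, rng, n_starts: int = 6):
    d = lo.size
    cand = rng.uniform(lo, hi, size=(128, d))
    m, v = gp_posterior(model, cand)
    ei = expected_improvement(m, v, f_min)
    order = np.argsort(ei)[::-1][:n_starts]

    def neg_ei(x):
        mm, vv = gp_posterior(model, x)
        return -expected_improvement(mm, vv, f_min)

    best_x, best_val = cand[order[0]], -ei[order[0]]
    for i in order:
        res = minimize(neg_ei, cand[i], method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if res.fun < best_val:
            best_x, best_val = np.clip(res.x, lo, hi), res.fun
    return best_x


def bayes_opt(objective, spec: OptSpec, x0: np.ndarray | None = None):
    """Expected-improvement Bayesian optimization over a box.

    Loop: refit hypers by marginal-likelihood ascent, maximize EI by
    multi-start local search, evaluate, append.  Evaluations are cached by
    parameter-vector hash; non-finite objective values are recorded as a
    large penalty.  Stops at ``budget`` evaluations or after ``stop_after``
    consecutive non-improving ones.  Returns ``(best_x, best_f, trace)``
    with trace rows (iteration, x..., f, best_so_far).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.lo, spec.hi
    d = lo.size
    cache: dict = {}

    def ev(x):
        key = tuple(np.round(x, 12))
        if key not in cache:
            val = objective(np.asarray(x, float))
            if not np.isfinite(val):
                warnings.warn("non-finite objective; recording penalty")
                val = 1e6
            cache[key] = float(val)
        return cache[key]

    X, f = [], []
    n_init = min(spec.n_init, spec.budget)
    init_pts = rng.uniform(lo, hi, size=(n_init, d))
    if x0 is not None:
        init_pts[0] = np.clip(np.asarray(x0, float), lo, hi)
    for x in init_pts:
        X.append(x)
        f.append(ev(x))
    best_i = int(np.argmin(f))
    since_improve = 0
    while len(f) < spec.budget and since_improve < spec.stop_after:
        model = fit_gp(np.array(X), np.array(f), rng=rng)
        xn = _maximize_ei(model, min(f), lo, hi, rng)
        if any(np.allclose(xn, xi, atol=1e-12) for xi in X):
            xn = rng.uniform(lo, hi, d)  # duplicate proposal: explore
        X.append(xn)
        f.append(ev(xn))
        if f[-1] < f[best_i] - 1e-12:
            best_i = len(f) - 1
            since_improve = 0
        else:
            since_improve += 1
    best = np.fmin.accumulate(f)
    trace = np.column_stack([np.arange(len(f)), np.array(X), np.array(f), best])
    return np.array(X[best_i]), float(f[best_i]), trace


def iterative_param_addition(
    objective,
    base_values: dict,
    candidates: list,
    bounds: dict,
    start: tuple = ("q", "r"),
    budget: int = 40,
    seed: int = 0,
):
    """Greedy forward selection of the RD parameters worth optimizing.

    ``objective(params_dict)`` is evaluated with the active subset replaced
    by proposed values and all others at ``base_values``.  Starting from the
    ``start`` subset, each round optimizes every one-parameter augmentation
    and permanently adds the parameter giving the lowest objective; stops
    when no augmentation reduces the best objective.  Returns the ordered
    subset and a table of (subset, objective) per accepted round.
    """
    if not candidates:
        raise ValueError("need at least one candidate parameter")

    def run(names, sd):
        spec = OptSpec(
            names=list(names), bounds={n: bounds[n] for n in names},
            budget=budget, n_init=min(6, budget), stop_after=budget, seed=sd,
        )
        x0 = np.array([base_values[n] for n in names])

        def obj_vec(x):
            p = dict(base_values)
            p.update({n: v for n, v in zip(names, x)})
            return objective(p)

        bx, bf, _ = bayes_opt(obj_vec, spec, x0=x0)
        return bx, bf

    subset = [n for n in start if n in bounds]
    _, best_f = run(subset, seed)
    table = [(tuple(subset), best_f)]
    remaining = [c for c in candidates if c not in subset]
    sd = seed
    while remaining:
        scores = []
        for c in remaining:
            sd += 1
            _, fc = run(subset + [c], sd)
            scores.append((fc, c))
        scores.sort()
        if scores[0][0] >= best_f - 1e-12:
            break
        best_f, chosen = scores[0]
        subset.append(chosen)
        remaining.remove(chosen)
        table.append((tuple(subset), best_f))
    return subset, table


def sensitivity_scan(
    simulate,
    params_opt: dict,
    hyper_sigma: dict,
    n_samples: int,
    esbs_fn,
    seed: int = 0,
):
    """Esbs distribution under joint uniform parameter perturbations.

    Each run jointly perturbs every parameter by U(-0.1 sigma_i, +0.1
    sigma_i) with sigma_i the fitted GP length scale of that parameter, then
    compares the perturbed simulation against the unperturbed one with
    ``esbs_fn(sim, ref)``.  Failed simulations are excluded and counted.
    Returns ``(esbs_values, gamma_fit, n_failed)`` where ``gamma_fit`` holds
    the MLE (shape, loc=0, scale) and the implied mean and SD.
    """
    rng = np.random.default_rng(seed)
    names = list(params_opt)
    ref = simulate(dict(params_opt))
    vals, failed = [], 0
    for _ in range(n_samples):
        p = dict(params_opt)
        for nm in names:
            p[nm] = p[nm] + rng.uniform(-0.1, 0.1) * hyper_sigma[nm]
        try:
            sim = simulate(p)
            e = float(esbs_fn(sim, ref))
            if not np.isfinite(e):
                raise FloatingPointError
            vals.append(e)
        except (FloatingPointError, np.linalg.LinAlgError):
            failed += 1
    vals = np.asarray(vals)
    fit = None
    if vals.size and vals.std() > 0:
        a, locg, scale = gamma_dist.fit(np.maximum(vals, 1e-12), floc=0.0)
        fit = {
            "shape": a, "loc": locg, "scale": scale,
            "mean": a * scale, "sd": np.sqrt(a) * scale,
        }
    return vals, fit, failed
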