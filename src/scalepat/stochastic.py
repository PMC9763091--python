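"""Stochastic models of scale-by-scale color change.

Two discrete-state models run on the same scale lattice:

* a 16-parameter stochastic cellular automaton (sCA) whose per-scale flip
  probability depends only on the scale's own state and its number of
  isochromatic neighbors (0-7); the probabilities are inferred from observed
  flip counts with a Binomial likelihood and flat prior, E[p] = (k+1)/(n+2);
* a 2-parameter Lenz-Ising model (dimensionless coupling betaJ and field
  betaB) sampled with single-site Metropolis dynamics, treating green/black
  scales as +1/-1 dipoles.  Antiferromagnetic coupling (betaJ < 0) favors
  labyrinthine patterns; with green = +1, a preference for black scales
  shows up as a fitted betaB < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit

from .lattice import GREEN, PatternState, ScaleLattice

__all__ = [
    "SCARules",
    "IsingParams",
    "infer_sca_rules",
    "simulate_sca",
    "ising_energy",
    "simulate_ising",
    "sample_ising",
    "fit_ising_params",
]


@dataclass
class SCARules:
    """Flip-probability table per configuration (state, isochromatic count).

    ``n[s, i]`` and ``k[s, i]`` are trial and success counts; the posterior
    mean flip probability is E[p] = (k+1)/(n+2) (flat prior), and the
    posterior mode p_MAP = k/n where n > 0 (NaN otherwise).
    """

    n: np.ndarray  # (2, 8) int
    k: np.ndarray  # (2, 8) int

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if self.n.shape != (2, 8) or self.k.shape != (2, 8):
            raise ValueError("rule tables must be (2, 8)")
        if (self.k > self.n).any() or (self.k < 0).any():
            raise ValueError("successes must satisfy 0 <= k <= n")

    @property
    def expected_p(self) -> np.ndarray:
        return (self.k + 1.0) / (self.n + 2.0)

    @property
    def p_map(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.k / self.n, np.nan)

    @classmethod
    def from_probabilities(cls, p: np.ndarray, n: int = 10**6) -> "SCARules":
        """Rules whose E[p] approximates a given probability table (for tests
        and hand-set configurations)."""
        p = np.asarray(p, dtype=float)
        k = np.clip(np.round(p * (n + 2) - 1), 0, n).astype(np.int64)
        return cls(np.full((2, 8), n), k.reshape(2, 8))


def _configs(lattice: ScaleLattice, states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-scale (state, isochromatic-count) pair, count capped at 7."""
    i, j, _ = lattice.laplacian_weights()
    iso = np.zeros(lattice.n_scales, dtype=np.int64)
    np.add.at(iso, i, (states[i] == states[j]).astype(np.int64))
    return states.astype(np.int64), np.minimum(iso, 7)


def infer_sca_rules(lattice: ScaleLattice, patterns) -> SCARules:
    """Bayesian inference of sCA flip probabilities from a pattern time series.

    For every non-final time point, each scale contributes one trial to its
    configuration bin; a success is a flip by the next time point.  Trials
    and successes are summed across time points; empty bins get E[p] = 1/2.
    """
    patterns = list(patterns)
    if len(patterns) < 2:
        raise ValueError("need at least 2 time points")
    n = np.zeros((2, 8), dtype=np.int64)
    k = np.zeros((2, 8), dtype=np.int64)
    for a, b in zip(patterns[:-1], patterns[1:]):
        s, iso = _configs(lattice, a.states)
        flipped = a.states != b.states
        np.add.at(n, (s, iso), 1)
        np.add.at(k, (s, iso), flipped.astype(np.int64))
    return SCARules(n, k)


def simulate_sca(
    lattice: ScaleLattice,
    p0: PatternState,
    rules: SCARules,
    target_flips: int,
    seed: int = 0,
    max_iter: int = 10_000,
) -> tuple[PatternState, list[PatternState]]:
    """Synchronous sCA iterations until cumulative flips reach ``target_flips``.

    Every scale flips independently with the E[p] of its current
    configuration; one iteration typically flips several scales, so the
    cumulative count overshoots the target slightly.  Returns the final
    pattern and the trajectory (including the initial pattern).  If the
    target is unreachable within ``max_iter`` iterations a warning is issued.
    """
    rng = np.random.default_rng(seed)
    ep = rules.expected_p
    s = p0.states.copy()
    traj = [PatternState(s.copy(), 0.0)]
    cum = 0
    for it in range(1, max_iter + 1):
        st, iso = _configs(lattice, s)
        p = ep[st, iso]
        flips = rng.random(s.size) < p
        cum += int(flips.sum())
        s = np.where(flips, 1 - s, s).astype(np.int8)
        traj.append(PatternState(s.copy(), float(it)))
        if cum >= target_flips:
            break
    else:
        warnings.warn(f"flip target {target_flips} not reached in {max_iter} iterations")
    return traj[-1], traj


@dataclass
class IsingParams:
    """Dimensionless Lenz-Ising coupling and field (already scaled by beta)."""

    betaJ: float
    betaB: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.betaJ) and np.isfinite(self.betaB)):
            raise ValueError("parameters must be finite")


def _spins(states: np.ndarray) -> np.ndarray:
    """Green scales are +1 dipoles, black scales -1."""
    return np.where(states == GREEN, 1, -1).astype(np.int8)


def ising_energy(lattice: ScaleLattice, pattern: PatternState, params: IsingParams) -> float:
    """Dimensionless energy betaH = -betaJ sum_<ij> s_i s_j - betaB sum_i s_i."""
    s = _spins(pattern.states)
    pair = int(np.sum(s[lattice.edges[:, 0]] * s[lattice.edges[:, 1]]))
    return float(-params.betaJ * pair - params.betaB * int(s.sum()))


def _csr_adjacency(lattice: ScaleLattice) -> tuple[np.ndarray, np.ndarray]:
    nbrs = lattice.neighbors
    indptr = np.zeros(lattice.n_scales + 1, dtype=np.int64)
    for i, nb in enumerate(nbrs):
        indptr[i + 1] = indptr[i] + len(nb)
    indices = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in nbrs]) if indptr[
        -1
    ] else np.empty(0, dtype=np.int64)
    return indptr, indices


@njit(cache=True)
def _metropolis_kernel(s, indptr, indices, betaJ, betaB, n_updates, target_flips, seeds, record_every, codes):  # pragma: no cover - jitted
    ns = s.size
    np.random.seed(seeds)
    flips = 0
    rec = 0
    for step in range(n_updates):
        i = np.random.randint(0, ns)
        m = 0
        for a in range(indptr[i], indptr[i + 1]):
            m += s[indices[a]]
        dE = 2.0 * betaJ * s[i] * m + 2.0 * betaB * s[i]
        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            s[i] = -s[i]
            flips += 1
            if target_flips > 0 and flips >= target_flips:
                return flips
        if record_every > 0 and (step + 1) % record_every == 0 and rec < codes.size:
            code = 0
            for j in range(ns):
                if s[j] > 0:
                    code |= 1 << j
            codes[rec] = code
            rec += 1
    return flips


def simulate_ising(
    lattice: ScaleLattice,
    p0: PatternState,
    params: IsingParams,
    n_sweeps: int,
    target_flips: int | None = None,
    seed: int = 0,
) -> PatternState:
    """Single-site Metropolis dynamics sampling exp(-betaH).

    One sweep is ``n_scales`` random single-site proposals.  Stops after
    ``n_sweeps`` sweeps, or earlier once the cumulative number of accepted
    flip events reaches ``target_flips`` (the same stopping semantics as the
    sCA's cumulative flip count, for comparability).
    """
    s = _spins(p0.states).astype(np.int8)
    indptr, indices = _csr_adjacency(lattice)
    codes = np.empty(0, dtype=np.int64)
    _metropolis_kernel(
        s, indptr, indices, params.betaJ, params.betaB,
        n_sweeps * lattice.n_scales, -1 if target_flips is None else int(target_flips),
        int(seed) % (2**31 - 1), 0, codes,
    )
    return PatternState((s > 0).astype(np.int8), time=float(n_sweeps))


def sample_ising(
    lattice: ScaleLattice,
    params: IsingParams,
    n_sweeps: int,
    seed: int = 0,
    p0: PatternState | None = None,
    burn_in: int = 0,
) -> np.ndarray:
    """Record the chain state (as a spin bitmask) once per sweep.

    Only usable for lattices with <= 63 scales; intended for validating the
    sampler against exact Boltzmann enumeration on tiny lattices.
    """
    if lattice.n_scales > 63:
        raise ValueError("state codes only defined for <= 63 scales")
    rng = np.random.default_rng(seed)
    if p0 is None:
        p0 = PatternState(rng.integers(0, 2, lattice.n_scales).astype(np.int8))
    s = _spins(p0.states).astype(np.int8)
    indptr, indices = _csr_adjacency(lattice)
    total = (n_sweeps + burn_in) * lattice.n_scales
    codes = np.full(n_sweeps + burn_in, -1, dtype=np.int64)
    _metropolis_kernel(
        s, indptr, indices, params.betaJ, params.betaB, total, -1,
        int(seed) % (2**31 - 1), lattice.n_scales, codes,
    )
    return codes[burn_in:]


def fit_ising_params(
    lattice: ScaleLattice, pattern: PatternState, bound: float = 10.0
) -> tuple[IsingParams, bool]:
    """Maximum pseudo-likelihood estimate of (betaJ, betaB).

    Each site's conditional law P(s_i = +1 | neighbors) = logistic(2 (betaJ
    m_i + betaB)) with m_i the neighbor spin sum; the product of conditionals
    is maximized over the box [-bound, bound]^2.  Returns the estimate and a
    flag that is True when the optimum sits on the box boundary (degenerate
    patterns, e.g. uniform ones, push betaB to infinity).
    """
    s = _spins(pattern.states).astype(float)
    m = np.zeros(lattice.n_scales)
    i, j, _ = lattice.laplacian_weights()
    np.add.at(m, i, s[j])
    y = (s + 1) / 2

    def nll(theta):
        z = 2.0 * (theta[0] * m + theta[1])
        # -log L = -sum y*z - log(1+e^z)
        return float(np.sum(np.logaddexp(0.0, z) - y * z))

    def grad(theta):
        p = expit(2.0 * (theta[0] * m + theta[1]))
        r = p - y
        return np.array([2.0 * np.sum(r * m), 2.0 * np.sum(r)])

    res = minimize(
        nll, x0=np.zeros(2), jac=grad, method="L-BFGS-B",
        bounds=[(-bound, bound)] * 2,
    )
    at_bound = bool(np.any(np.isclose(np.abs(res.x), bound, atol=1e-6)))
    if at_bound:
        warnings.warn("pseudo-likelihood optimum at parameter bound (degenerate pattern)")
    return IsingParams(float(res.x[0]), float(res.x[1])), at_bound
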