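"""Pattern-comparison metrics: the 16-bin neighborhood error E16D, the
scale-by-scale error Esbs, the optimization objective, and PCA of
error-vector populations.
"""

from __future__ import annotations

import numpy as np

from .colormap import ColorClusters, nearest_center_states
from .lattice import ColorState, PatternState, ScaleLattice, neighbor_stats

__all__ = ["e16d", "esbs", "pattern_objective", "error_pca", "as_pattern"]


def as_pattern(state, clusters: ColorClusters | None = None) -> PatternState:
    """Coerce a ColorState to a binary pattern by nearest cluster center."""
    if isinstance(state, PatternState):
        return state
    if clusters is None:
        raise ValueError("clusters required to threshold continuous colors")
    return PatternState(nearest_center_states(state, clusters), time=state.time)


def e16d(
    lattice: ScaleLattice, sim: PatternState, obs: PatternState
) -> tuple[float, np.ndarray]:
    """Normalized L2 neighborhood-statistics error and its 16-vector.

    E16D = (1/ns) sqrt( sum_i (n_sim(G,i) - n_obs(G,i))^2
                              + (n_sim(B,i) - n_obs(B,i))^2 )

    The returned error vector holds the 16 signed count differences divided
    by ns (order: black i=0..7 then green i=0..7); its L2 norm is E16D.
    """
    if sim.n_scales != obs.n_scales:
        raise ValueError("patterns live on different lattices")
    ns = lattice.n_scales
    d = (neighbor_stats(lattice, sim) - neighbor_stats(lattice, obs)).astype(float)
    vec = d.ravel() / ns
    return float(np.linalg.norm(vec)), vec


def esbs(sim, obs, clusters: ColorClusters | None = None) -> float:
    """Scale-by-scale error between a simulated and an observed pattern.

    Color mode (ColorState inputs): mean per-scale CIELAB distance normalized
    by the green-black cluster separation ||Cb - Cg||.  Binary mode
    (PatternState inputs): the fraction of mismatched scales, which is the
    color formula evaluated with scales sitting exactly on the two centers.
    """
    if isinstance(sim, PatternState) and isinstance(obs, PatternState):
        if sim.n_scales != obs.n_scales:
            raise ValueError("patterns live on different lattices")
        return float(np.mean(sim.states != obs.states))
    if not (isinstance(sim, ColorState) and isinstance(obs, ColorState)):
        raise TypeError("sim and obs must both be PatternState or both ColorState")
    if clusters is None:
        raise ValueError("clusters required for color-mode Esbs")
    sep = clusters.separation
    if sep == 0:
        raise ValueError("Cg equals Cb; normalization undefined")
    d = np.linalg.norm(sim.colors - obs.colors, axis=1)
    return float(d.mean() / sep)


def pattern_objective(
    lattice: ScaleLattice,
    sim_series,
    obs_series,
    clusters: ColorClusters | None = None,
) -> float:
    """Mean-over-time L1 neighborhood-count mismatch (optimization objective).

    f = (1/n_k) sum_k (1/ns) sum_i |dGreen_i| + |dBlack_i| at time k, with
    simulated continuous colors thresholded to the nearest cluster center.
    """
    if len(sim_series) != len(obs_series):
        raise ValueError("misaligned time grids")
    ns = lattice.n_scales
    total = 0.0
    for sim, obs in zip(sim_series, obs_series):
        ps, po = as_pattern(sim, clusters), as_pattern(obs, clusters)
        if not np.isclose(ps.time, po.time):
            raise ValueError("misaligned time grids")
        d = neighbor_stats(lattice, ps) - neighbor_stats(lattice, po)
        total += np.abs(d).sum() / ns
    return float(total / len(sim_series))


def error_pca(vectors: np.ndarray, n_components: int = 3):
    """Centered PCA of a population of 16-bin error vectors.

    Returns ``(components, explained_variance_ratio, projections)`` where
    components are rows (descending eigenvalue order) and projections are the
    centered vectors expressed in the first ``n_components`` axes.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    if n_components > min(X.shape):
        raise ValueError("fewer vectors/dimensions than requested components")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / X.shape[0]
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = np.maximum(w[order], 0.0), V[:, order]
    ratios = w / w.sum() if w.sum() > 0 else np.zeros_like(w)
    comps = V[:, :n_components].T
    return comps, ratios, Xc @ comps.T
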