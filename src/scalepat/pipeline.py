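"""End-to-end glue: the RD optimization objective and color-space models.

The Bayesian-optimization loop evaluates a candidate RD parameter vector by
(i) converting the observed juvenile colors to RD concentrations with the
candidate's linear-stability transform and contraction r, (ii) integrating
the discrete RD equations across the observation times, (iii) converting
each simulated state back to CIELAB with the per-time-point ellipsoid
transform Te, and (iv) scoring the thresholded patterns against the
observations with the L1 neighborhood objective.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .colormap import ColorClusters, colors_to_rd, fit_color_transform, rd_to_colors
from .lattice import ColorState, ScaleLattice
from .metrics import pattern_objective
from .rd import RDParams, linear_stability, simulate_drd

__all__ = ["make_drd_objective", "make_drd_color_model"]

PENALTY = 1e6


def make_drd_objective(
    lattice: ScaleLattice,
    obs_series: list[ColorState],
    clusters: ColorClusters,
    base: RDParams,
    names: list[str],
    dt: float = 2.0,
    refit_te: bool = True,
):
    """Objective f(x) over the parameter subset ``names``.

    ``obs_series`` are observed per-scale colors at the comparison times
    (first entry = juvenile initial condition).  Candidates whose HSS leaves
    the central reaction branch, or whose simulation blows up, score a large
    penalty.  With ``refit_te=False`` the Te fitted at the final time point
    is reused everywhere.
    """
    taus = np.array([c.time for c in obs_series])

    def from_dict(d: dict) -> float:
        params = replace(base, **d)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stab = linear_stability(params, lattice.S, params.eps_ref)
                if not stab.hss_valid or stab.lambda1 <= 0:
                    return PENALTY
                ic = colors_to_rd(obs_series[0], clusters, stab, params.r)
                states = simulate_drd(lattice, params, ic, taus, dt=dt)
                te_final = None
                if not refit_te:
                    te_final = fit_color_transform(states[-1], obs_series[-1])
                sim_colors = []
                for st, obs in zip(states, obs_series):
                    te = te_final if te_final is not None else fit_color_transform(st, obs)
                    sim_colors.append(rd_to_colors(st, te))
                return pattern_objective(lattice, sim_colors, obs_series, clusters)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return PENALTY

    def objective(x) -> float:
        return from_dict({nm: float(v) for nm, v in zip(names, np.atleast_1d(x))})

    objective.from_dict = from_dict
    return objective


def make_drd_color_model(
    lattice: ScaleLattice,
    params: RDParams,
    clusters: ColorClusters,
    tau_grid,
    dt: float = 2.0,
):
    """Closure colors -> (RD trajectory, final colors) for divergence runs.

    The juvenile colors are mapped to RD space with the stability transform
    and the final state back to color space with the fixed line map along
    the dominating eigenvector (the same map for every run, so that final
    colors of different runs are comparable).
    """
    from .synth import _forward_colors

    stab = linear_stability(params, lattice.S, params.eps_ref)

    def model(colors: ColorState):
        ic = colors_to_rd(colors, clusters, stab, params.r)
        states = simulate_drd(lattice, params, ic, tau_grid, dt=dt)
        final = ColorState(
            _forward_colors(states[-1].u, stab, clusters), time=states[-1].time
        )
        return states, final

    return model
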