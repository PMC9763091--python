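"""Sensitivity to initial conditions: trajectory divergence and the
Lyapunov exponent of the reaction-diffusion patterning dynamics.

Perturbed juvenile color states are propagated alongside the reference
trajectory; the divergence delta(tau) = ||S_tau - S_tau_ref|| (Euclidean
distance in the full 3 x n_scales RD state) grows exponentially while the
dynamics are in the linear regime, and the Lyapunov exponent is the
least-squares slope of log(delta/delta0) over the pre-saturation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .lattice import ColorState
from .synth import perturb_colors

__all__ = [
    "DivergenceTrace",
    "divergence_trajectories",
    "lyapunov_exponent",
    "ic_to_final_error",
]


@dataclass
class DivergenceTrace:
    """Distance between a perturbed and the reference trajectory over time."""

    times: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.delta = np.asarray(self.delta, float)
        if (self.delta < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def delta0(self) -> float:
        return float(self.delta[0])


def _state_matrix(states) -> np.ndarray:
    """(T, 3 ns) trajectory matrix from a list of RDState."""
    return np.stack([st.u.ravel() for st in states])


def divergence_trajectories(
    ref_colors: ColorState,
    model,
    n_perturbations: int,
    esbs_fn,
    seed: int = 0,
) -> tuple[list[DivergenceTrace], np.ndarray]:
    """Propagate noisy initial conditions and record their divergence.

    ``model(colors)`` must return ``(rd_states, final_colors)`` — the RD
    trajectory started from the given juvenile colors and the colors of its
    final state.  Each of the ``n_perturbations`` runs perturbs the
    reference colors (uniform amplitude times correlated Gaussian noise,
    :func:`~scalepat.synth.perturb_colors`), simulates, and records the
    per-time Euclidean distance to the reference trajectory together with
    the initial and final scale-by-scale errors (``esbs_fn(a, b)``).
    Zero-distance perturbations are discarded.  Returns the traces and an
    (n, 2) array of (Esbs0, Esbsf).
    """
    ref_states, ref_final_colors = model(ref_colors)
    R = _state_matrix(ref_states)
    times = np.array([st.time for st in ref_states])
    rng = np.random.default_rng(seed)
    traces, errs = [], []
    for _ in range(n_perturbations):
        pert, s = perturb_colors(ref_colors, seed=int(rng.integers(0, 2**31 - 1)))
        if s == 0 or np.allclose(pert.colors, ref_colors.colors):
            continue
        states, final_colors = model(pert)
        P = _state_matrix(states)
        delta = np.linalg.norm(P - R, axis=1)
        if delta[0] == 0:
            continue
        traces.append(DivergenceTrace(times, delta))
        errs.append(
            (float(esbs_fn(pert, ref_colors)), float(esbs_fn(final_colors, ref_final_colors)))
        )
    return traces, np.asarray(errs)


def lyapunov_exponent(
    trace: DivergenceTrace,
    saturation_frac: float = 0.5,
    horizon_frac: float = 0.5,
    min_samples: int = 5,
) -> float:
    """Least-squares slope of log(delta/delta0) before saturation.

    The pre-saturation window keeps samples with delta below
    ``saturation_frac`` of the trace maximum and times within the first
    ``horizon_frac`` of the horizon (both window rules are package
    defaults; the underlying definition is the early-time slope).
    """
    if (trace.delta <= 0).any():
        raise ValueError("non-positive distances in trace")
    t0 = trace.times[0]
    tmax = trace.times[-1]
    sel = (trace.delta < saturation_frac * trace.delta.max()) & (
        trace.times <= t0 + horizon_frac * (tmax - t0)
    )
    sel[0] = True
    if sel.sum() < min_samples:
        raise ValueError(f"fewer than {min_samples} pre-saturation samples")
    x = trace.times[sel] - t0
    y = np.log(trace.delta[sel] / trace.delta0)
    return float(np.polyfit(x, y, 1)[0])


def ic_to_final_error(
    runs: np.ndarray, probe_points, min_runs: int = 50, window_frac: float = 0.1
):
    """Monotone map from initial to final scale-by-scale error.

    Fits an isotonic (non-decreasing) regression of Esbsf on Esbs0 across
    the runs and evaluates it at each probe, together with the empirical
    mean and SD of Esbsf among the runs whose Esbs0 falls within a
    ``window_frac`` band around the probe.  Probes outside the observed
    range are flagged as extrapolations.
    """
    runs = np.asarray(runs, float)
    if runs.shape[0] < min_runs:
        raise ValueError(f"need at least {min_runs} runs")
    e0, ef = runs[:, 0], runs[:, 1]
    iso = IsotonicRegression(out_of_bounds="clip").fit(e0, ef)
    span = e0.max() - e0.min()
    out = []
    for p in np.atleast_1d(np.asarray(probe_points, float)):
        extrapolated = bool(p < e0.min() or p > e0.max())
        near = np.abs(e0 - p) <= window_frac * span
        local_mean = float(ef[near].mean()) if near.any() else np.nan
        local_sd = float(ef[near].std()) if near.any() else np.nan
        out.append(
            {
                "probe": float(p),
                "fitted": float(iso.predict([p])[0]),
                "local_mean": local_mean,
                "local_sd": local_sd,
                "n_local": int(near.sum()),
                "extrapolated": extrapolated,
            }
        )
    return out
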