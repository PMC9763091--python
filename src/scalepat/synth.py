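"""Synthetic inputs with the statistical structure the pipeline assumes.

No public scan data accompanies the study system this package models, so
every input the analysis needs is generated here: scale lattices with binary
or continuous color series, random patterns spanning all length scales,
logistic growth curves, bump-array normal maps, matched lattice pairs, and
color perturbations for the sensitivity analyses.  All generators are pure
functions of their configuration and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .colormap import ColorClusters
from .lattice import ColorState, PatternState, ScaleLattice
from .rd import RDParams, RDState, StabilityReport, logistic_growth, simulate_drd

__all__ = [
    "SynthConfig",
    "gen_random_patterns",
    "gen_growth_series",
    "gen_truth_series",
    "gen_normal_map",
    "gen_matched_pair",
    "perturb_colors",
    "perturbed_hss_ic",
    "BumpGridSpec",
]

#: default CIELAB cluster centers: a desaturated green and a near-black,
#: loosely matching juvenile dorsal scale colors (Lg* > Lb* by construction)
DEFAULT_CG = np.array([55.0, -30.0, 25.0])
DEFAULT_CB = np.array([18.0, 2.0, 4.0])


@dataclass
class SynthConfig:
    """Shared configuration for the synthetic-data generators."""

    nx: int = 10
    ny: int = 10
    S: float = 2.0
    jitter: float = 0.0          # lattice center jitter amplitude (units of S)
    Cg: np.ndarray = field(default_factory=lambda: DEFAULT_CG.copy())
    Cb: np.ndarray = field(default_factory=lambda: DEFAULT_CB.copy())
    noise_sd: float = 1.0        # measurement noise SD, CIELAB units
    times: tuple = (0.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Cg[0] <= self.Cb[0]:
            raise ValueError("Cg must be lighter than Cb (Lg* > Lb*)")

    @property
    def clusters(self) -> ColorClusters:
        return ColorClusters(np.asarray(self.Cg, float), np.asarray(self.Cb, float), None)


def gen_random_patterns(
    lattice: ScaleLattice,
    n: int,
    length_scale_range: tuple[float, float],
    green_fraction: float = 0.5,
    seed: int = 0,
) -> list[PatternState]:
    """Random binary patterns spanning all length scales.

    Each pattern thresholds a Gaussian random field on the scale centers
    (squared-exponential kernel) at the ``green_fraction`` quantile; the
    correlation length is drawn log-uniformly from ``length_scale_range``
    (in units of the mean edge length S), so an ensemble spans everything
    from independent speckle to patch sizes of a quarter domain.
    """
    lo, hi = length_scale_range
    if not (0 < lo <= hi):
        raise ValueError("empty or invalid length-scale range")
    rng = np.random.default_rng(seed)
    D2 = cdist(lattice.centers, lattice.centers, "sqeuclidean")
    S = lattice.S
    out = []
    for _ in range(n):
        ell = np.exp(rng.uniform(np.log(lo), np.log(hi))) * S
        K = np.exp(-D2 / (2.0 * ell * ell)) + 1e-8 * np.eye(lattice.n_scales)
        z = np.linalg.cholesky(K) @ rng.standard_normal(lattice.n_scales)
        if green_fraction >= 1.0:
            states = np.ones(lattice.n_scales, dtype=np.int8)
        elif green_fraction <= 0.0:
            states = np.zeros(lattice.n_scales, dtype=np.int8)
        else:
            thr = np.quantile(z, 1.0 - green_fraction)
            states = (z >= thr).astype(np.int8)
        out.append(PatternState(states))
    return out


def gen_growth_series(k1: float, k2: float, k3: float, times) -> np.ndarray:
    """Logistic mean-edge-length series S(tau) = k1/(exp(-k2 tau + k3) + 1)."""
    return logistic_growth(np.asarray(times, dtype=float), k1, k2, k3)


def _line_coordinate(u: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine coordinate along the segment [a, b] (0 at a, 1 at b)."""
    d = b - a
    return (u - a) @ d / float(d @ d)


def _forward_colors(u: np.ndarray, stability: StabilityReport, clusters: ColorClusters):
    """Generator-side RD -> color map: position along [ub, ug] mapped onto
    the [Cb, Cg] color segment (affine, rank-1)."""
    t = _line_coordinate(u, stability.ub, stability.ug)
    return clusters.Cb + np.outer(t, clusters.Cg - clusters.Cb)


def gen_truth_series(
    lattice: ScaleLattice,
    rd_params: RDParams,
    ic: RDState,
    times,
    noise_sd: float,
    seed: int = 0,
    stability: StabilityReport | None = None,
    clusters: ColorClusters | None = None,
    dt: float = 1.0,
) -> tuple[list[ColorState], list[RDState]]:
    """Forward-model color time series from a known RD parameter set.

    Integrates the discrete RD system from ``ic``, maps each sampled state to
    CIELAB (position along the dominating line mapped affinely onto the
    [Cb, Cg] color segment) and adds i.i.d. isotropic CIELAB noise.  Returns
    the noisy color series and the underlying ground-truth RD states.
    """
    from .rd import linear_stability

    if stability is None:
        stability = linear_stability(rd_params, lattice.S, rd_params.eps_ref)
    if clusters is None:
        clusters = ColorClusters(DEFAULT_CG.copy(), DEFAULT_CB.copy(), None)
    rng = np.random.default_rng(seed)
    states = simulate_drd(lattice, rd_params, ic, times, dt=dt)
    colors = []
    for st in states:
        if not np.isfinite(st.u).all():
            raise FloatingPointError(f"non-finite RD state at tau={st.time}")
        C = _forward_colors(st.u, stability, clusters)
        C = C + rng.normal(0.0, noise_sd, C.shape) if noise_sd > 0 else C
        colors.append(ColorState(C, time=st.time))
    return colors, states


def perturbed_hss_ic(
    lattice: ScaleLattice, params: RDParams, amplitude: float = 0.02, seed: int = 0
) -> RDState:
    """Homogeneous steady state plus small i.i.d. fluctuations (Turing seed)."""
    from .rd import solve_hss

    rng = np.random.default_rng(seed)
    hss = solve_hss(params)
    return RDState(hss.ustar + rng.normal(0.0, amplitude, (lattice.n_scales, 3)))


@dataclass
class BumpGridSpec:
    """Hexagonal array of super-Gaussian bumps for synthetic normal maps.

    ``S`` is the bump spacing in physical units, ``sigma``/``p`` the
    super-Gaussian width and exponent, ``height`` the bump amplitude.
    """

    nx: int = 8
    ny: int = 8
    S: float = 1.0
    sigma: float = 0.28
    p: float = 1.0
    height: float = 0.3
    arrangement: str = "hex"  # "hex" (offset rows) or "square" (frame-aligned)


def gen_normal_map(
    spec: BumpGridSpec,
    resolution: int,
    seed: int = 0,
    height_jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Synthetic 16-bit normal map of a bump array with its height field.

    ``resolution`` is the pixel count across one bump spacing S and must give
    at least 400 px per scale (>= 20 px across).  Normals are computed
    analytically from the height-field gradient and encoded channel-wise from
    (-1, 1) to (0, 65535).  Returns ``(encoded_uint16, normals, heights,
    pitch)``.
    """
    from .imaging import encode_normal_map

    if resolution < 20:
        raise ValueError("resolution too coarse: need >= 400 px per scale")
    rng = np.random.default_rng(seed)
    if spec.arrangement == "square":
        w, row_h, x_off, y_off = spec.S, spec.S, 0.5 * spec.S, 0.5 * spec.S
        cx = np.array([w * i for j in range(spec.ny) for i in range(spec.nx)])
        cy = np.array([row_h * j for j in range(spec.ny) for i in range(spec.nx)])
    else:  # hexagonal rows, offset by half a spacing
        w, row_h = np.sqrt(3.0) * spec.S, 1.5 * spec.S
        x_off, y_off = 0.5 * w, 0.5 * row_h
        cx = np.array([w * (i + 0.5 * (j % 2)) for j in range(spec.ny) for i in range(spec.nx)])
        cy = np.array([row_h * j for j in range(spec.ny) for i in range(spec.nx)])
    hts = spec.height * (1.0 + height_jitter * rng.standard_normal(cx.size))
    # the image spans exactly the nx x ny cells, and the height field is made
    # periodic with ghost bumps so edge cells look interior
    Wx, Wy = spec.nx * w, row_h * spec.ny
    pitch = spec.S / resolution
    nxp, nyp = int(round(Wx / pitch)), int(round(Wy / pitch))
    X, Y = np.meshgrid((np.arange(nxp) + 0.5) * pitch - x_off,
                       (np.arange(nyp) + 0.5) * pitch - y_off)
    Z = np.zeros_like(X)
    s2 = 2.0 * (spec.sigma * spec.S) ** 2
    for dx in (-Wx, 0.0, Wx):
        for dy in (-Wy, 0.0, Wy):
            for x0, y0, h in zip(cx + dx, cy + dy, hts):
                if x0 < X.min() - 2 * spec.S or x0 > X.max() + 2 * spec.S:
                    continue
                if y0 < Y.min() - 2 * spec.S or y0 > Y.max() + 2 * spec.S:
                    continue
                r2 = (X - x0) ** 2 + (Y - y0) ** 2
                np.maximum(Z, h * np.exp(-((r2 / s2) ** spec.p)), out=Z)
    zy, zx = np.gradient(Z, pitch)
    n = np.stack([-zx, -zy, np.ones_like(Z)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return encode_normal_map(n), n, Z, pitch


def gen_matched_pair(
    centers: np.ndarray | ScaleLattice,
    similarity: tuple[float, float, np.ndarray],
    jitter_sd: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second center set related to the first by a similarity transform.

    ``similarity`` = (theta, s, t): rotation angle, isotropic scale > 0 and
    translation.  Gaussian jitter of SD ``jitter_sd`` is added and each scale
    is dropped independently with probability ``dropout``.  Returns
    ``(A, B, truth)`` where ``truth[i]`` is the index in B matching scale i
    of A, or -1 for dropped scales.
    """
    A = centers.centers if isinstance(centers, ScaleLattice) else np.asarray(centers, float)
    theta, s, t = similarity
    if s <= 0:
        raise ValueError("scale factor must be positive")
    rng = np.random.default_rng(seed)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    B_full = (s * (A @ R.T)) + np.asarray(t, float)
    if jitter_sd > 0:
        B_full = B_full + rng.normal(0.0, jitter_sd, B_full.shape)
    keep = rng.random(A.shape[0]) >= dropout
    truth = np.full(A.shape[0], -1, dtype=int)
    truth[keep] = np.arange(int(keep.sum()))
    return A, B_full[keep], truth


def perturb_colors(
    Cref: ColorState, seed: int = 0, s: float | None = None
) -> tuple[ColorState, float]:
    """Noisy copy C = Cref + s C' with s ~ U(0,1) and rows C' ~ N(0, Cov(Cref)).

    This is the perturbation model of the sensitivity analyses: noise drawn
    from the empirical covariance of the reference colors, scaled by a
    uniform amplitude.  A singular covariance falls back to its diagonal
    (with a warning).  Returns the perturbed colors and the drawn s.
    """
    X = Cref.colors
    if X.shape[0] < 2:
        raise ValueError("need at least 2 scales to define a covariance")
    rng = np.random.default_rng(seed)
    cov = np.cov(X, rowvar=False)
    try:
        L = np.linalg.cholesky(cov + 0.0)
    except np.linalg.LinAlgError:
        warnings.warn("singular color covariance; using diagonal fallback")
        L = np.diag(np.sqrt(np.maximum(np.diag(cov), 0.0)))
    if s is None:
        s = float(rng.random())
    Cp = rng.standard_normal(X.shape) @ L.T
    return ColorState(X + s * Cp, time=Cref.time), s
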