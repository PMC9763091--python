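"""Three-component reaction-diffusion core: reactions, steady state, linear
stability, and the 2D discrete (polygonal) and 2D continuous solvers.

The model tracks densities (u, v, w) of melanophore-, xanthophore- and
long-range-factor-like components.  Reaction terms are clamped linear forms
(the clamping is the only non-linearity and is what permits Turing
instabilities); decay is linear; diffusion has Du = Dv << Dw.  Skin thinning
at scale borders is modeled by multiplying the diffusivities by a factor
P in (0, 1] across interscale edges.  Isotropic lattice growth S(tau), a
logistic in the growth time tau, enters the equations only through the
(S_ref / S(tau))^2 rescaling of the diffusion exchange term; the reference
geometry is the last observed time point with eps_ref = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .lattice import ScaleLattice

__all__ = [
    "RDParams",
    "RDState",
    "StabilityReport",
    "reaction_terms",
    "solve_hss",
    "linear_stability",
    "analytic_linear_solution",
    "simulate_drd",
    "simulate_crd2d",
    "logistic_growth",
]

#: reaction/decay/diffusion values of the reference three-component model
#: (caps Fmax/Gmax/Hmax are placeholders documented in docs/methods.md)
DEFAULTS = dict(
    c1=-0.04, c2=-0.056, c3=0.382,
    c4=-0.05, c5=0.0, c6=0.25,
    c7=0.016, c8=-0.03, c9=0.24,
    cu=0.020, cv=0.025, cw=0.06,
    Du=1.125, Dw=12.5, P=0.00889,
    Fmax=0.5, Gmax=0.5, Hmax=0.5,
)


@dataclass
class RDParams:
    """Reaction-diffusion parameters (Dv = Du is implied throughout)."""

    c1: float = DEFAULTS["c1"]
    c2: float = DEFAULTS["c2"]
    c3: float = DEFAULTS["c3"]
    c4: float = DEFAULTS["c4"]
    c5: float = DEFAULTS["c5"]
    c6: float = DEFAULTS["c6"]
    c7: float = DEFAULTS["c7"]
    c8: float = DEFAULTS["c8"]
    c9: float = DEFAULTS["c9"]
    cu: float = DEFAULTS["cu"]
    cv: float = DEFAULTS["cv"]
    cw: float = DEFAULTS["cw"]
    Du: float = DEFAULTS["Du"]
    Dw: float = DEFAULTS["Dw"]
    P: float = DEFAULTS["P"]
    Fmax: float = DEFAULTS["Fmax"]
    Gmax: float = DEFAULTS["Gmax"]
    Hmax: float = DEFAULTS["Hmax"]
    q: float = 1.0          # rate factor dt/dtau between RD and growth clocks
    r: float = 1.0          # initial-condition contraction toward the HSS
    growth: tuple | None = None  # (k1, k2, k3) logistic constants, or None
    S_ref: float = 1.0      # reference mean edge length (last time point)
    eps_ref: float = 1.0    # reference interscale width

    def __post_init__(self) -> None:
        if self.Dw <= self.Du:
            warnings.warn("expected Dw > Du for the long-range component")
        if not 0.0 < self.P <= 1.0:
            raise ValueError("P must lie in (0, 1]")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")

    @property
    def Dv(self) -> float:
        return self.Du

    @property
    def reaction_jacobian(self) -> np.ndarray:
        """Jacobian of F(u) - c u on the central (unclamped) branch."""
        return np.array(
            [
                [-self.cu, self.c1, self.c2],
                [self.c4, -self.cv, self.c5],
                [self.c7, self.c8, -self.cw],
            ]
        )

    @property
    def c_vec(self) -> np.ndarray:
        return np.array([self.cu, self.cv, self.cw])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([self.c3, self.c6, self.c9])

    @property
    def D_vec(self) -> np.ndarray:
        return np.array([self.Du, self.Du, self.Dw])

    @property
    def caps(self) -> np.ndarray:
        return np.array([self.Fmax, self.Gmax, self.Hmax])

    def with_(self, **kwargs) -> "RDParams":
        return replace(self, **kwargs)


@dataclass
class RDState:
    """Per-node (u, v, w) concentrations at one time."""

    u: np.ndarray  # (n, 3)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.u.shape[1] != 3:
            raise ValueError("state must be (n, 3)")

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]


def logistic_growth(tau, k1: float, k2: float, k3: float):
    """Logistic mean edge length S(tau) = k1 / (exp(-k2 tau + k3) + 1)."""
    if k1 <= 0:
        raise ValueError("k1 (asymptotic size) must be positive")
    tau = np.asarray(tau, dtype=float)
    return k1 / (np.exp(-k2 * tau + k3) + 1.0)


def reaction_terms(u, v, w, params: RDParams):
    """Clamped linear reaction terms (F, G, H).

    Each term is the linear form in the other two components clamped to
    [0, max]; inside the central region the terms are exactly linear.
    """
    p = params
    F = np.clip(p.c1 * np.asarray(v) + p.c2 * np.asarray(w) + p.c3, 0.0, p.Fmax)
    G = np.clip(p.c4 * np.asarray(u) + p.c5 * np.asarray(w) + p.c6, 0.0, p.Gmax)
    H = np.clip(p.c7 * np.asarray(u) + p.c8 * np.asarray(v) + p.c9, 0.0, p.Hmax)
    return F, G, H


@dataclass
class HSSResult:
    ustar: np.ndarray
    valid: bool
    branch_values: np.ndarray  # the three linear forms evaluated at u*


def solve_hss(params: RDParams) -> HSSResult:
    """Homogeneous steady state on the central branch: solve F(u*) = c u*.

    Also checks the middle-branch validity conditions (each linear form in
    (0, max] at u*); ``valid=False`` flags parameter sets whose nominal HSS
    leaves the central region.
    """
    J = params.reaction_jacobian
    if abs(np.linalg.det(J)) < 1e-14:
        raise np.linalg.LinAlgError("singular reaction matrix; HSS undefined")
    ustar = np.linalg.solve(-J, params.offsets)
    forms = np.array(
        [
            params.c1 * ustar[1] + params.c2 * ustar[2] + params.c3,
            params.c4 * ustar[0] + params.c5 * ustar[2] + params.c6,
            params.c7 * ustar[0] + params.c8 * ustar[1] + params.c9,
        ]
    )
    valid = bool(np.all(forms > 0) and np.all(forms <= params.caps))
    return HSSResult(ustar, valid, forms)


@dataclass
class StabilityReport:
    """Linearization of the discrete RD dynamics about the HSS.

    M and b define du/dt = M u + b for a single scale whose neighbors sit at
    the HSS; eigenvalues are sorted by descending real part.  The dominating
    line u* + t' v1 intersects the clamping planes at the extremities ug and
    ub (labeled so that the v-component of ug exceeds that of ub).
    """

    ustar: np.ndarray
    M: np.ndarray
    b: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, same order as eigenvalues
    ug: np.ndarray
    ub: np.ndarray
    hss_valid: bool = True
    defective: bool = False

    @property
    def lambda1(self) -> float:
        return float(np.real(self.eigenvalues[0]))

    @property
    def v1(self) -> np.ndarray:
        return np.real(self.eigenvectors[:, 0])


def hex_exchange_coefficient(params: RDParams, S: float, eps: float) -> float:
    """Per-neighbor diffusion exchange coefficient 2P/(3 sqrt(3) S eps) on a
    regular hexagonal lattice (multiplies D (u_j - u_i) for each neighbor)."""
    return 2.0 * params.P / (3.0 * np.sqrt(3.0) * S * eps)


def linear_stability(params: RDParams, S: float, eps: float) -> StabilityReport:
    """Linearize the hexagonal discrete RD system about the HSS.

    With neighbors approximated at the HSS, du/dt = M u + b where
    M = J - 6 kappa D, b = (c3, c6, c9) + 6 kappa D u*, kappa the
    per-neighbor exchange coefficient.  Note -M^{-1} b = u* exactly.
    """
    hss = solve_hss(params)
    kappa6 = 6.0 * hex_exchange_coefficient(params, S, eps)
    M = params.reaction_jacobian - kappa6 * np.diag(params.D_vec)
    b = params.offsets + kappa6 * params.D_vec * hss.ustar

    w, V = np.linalg.eig(M)
    order = np.argsort(-w.real)
    w, V = w[order], V[:, order]
    defective = False
    if np.linalg.matrix_rank(V, tol=1e-10) < 3:
        warnings.warn("defective M; falling back to Schur vectors")
        from scipy.linalg import schur

        T, Z = schur(M, output="real")
        V = Z.astype(complex)
        defective = True

    v1 = np.real(V[:, 0])
    v1 = v1 / np.linalg.norm(v1)
    ug, ub = _line_extremities(hss.ustar, v1, params)
    return StabilityReport(hss.ustar, M, b, w, V, ug, ub, hss.valid, defective)


def _line_extremities(ustar: np.ndarray, v1: np.ndarray, params: RDParams):
    """Intersections of the dominating line with the six clamping planes.

    Walking from u* along +/- v1, each of the three linear reaction forms
    hits 0 or its cap at some parameter t; the nearest crossing on each side
    defines the two extremities.  They are labeled (ug, ub) with vg > vb.
    """
    rows = np.array(
        [[0.0, params.c1, params.c2], [params.c4, 0.0, params.c5], [params.c7, params.c8, 0.0]]
    )
    consts = params.offsets + rows @ ustar  # form value at u* (a0 + rows·(u-u*))
    slopes = rows @ v1
    t_pos, t_neg = np.inf, -np.inf
    for a0, sl, cap in zip(consts, slopes, params.caps):
        if abs(sl) < 1e-15:
            continue
        for bound in (0.0, cap):
            t = (bound - a0) / sl
            if t > 1e-12:
                t_pos = min(t_pos, t)
            elif t < -1e-12:
                t_neg = max(t_neg, t)
    if not np.isfinite(t_pos) or not np.isfinite(t_neg):
        raise ValueError("dominating line does not intersect the clamping planes")
    e1, e2 = ustar + t_pos * v1, ustar + t_neg * v1
    return (e1, e2) if e1[1] > e2[1] else (e2, e1)


def analytic_linear_solution(u0: np.ndarray, M: np.ndarray, b: np.ndarray, t) -> np.ndarray:
    """Closed-form solution u(t) = e^{Mt} (u0 + M^{-1} b) - M^{-1} b.

    Uses the spectral decomposition of M; falls back to a dense matrix
    exponential when M is defective.  ``t`` may be scalar or an array (the
    result then has shape (len(t), 3)).
    """
    M = np.asarray(M, float)
    if abs(np.linalg.det(M)) < 1e-300:
        raise np.linalg.LinAlgError("singular M")
    Minvb = np.linalg.solve(M, np.asarray(b, float))
    x0 = np.asarray(u0, float) + Minvb
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    w, V = np.linalg.eig(M)
    if np.linalg.cond(V) < 1e12:
        a = np.linalg.solve(V, x0.astype(complex))
        out = np.real(np.einsum("ij,tj->ti", V, a[None, :] * np.exp(np.outer(ts, w)))) - Minvb
    else:
        from scipy.linalg import expm

        out = np.stack([expm(M * tk) @ x0 - Minvb for tk in ts])
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# 2D discrete RD on polygonal lattices


def _growth_factor(params: RDParams, tau: float) -> float:
    """(S_ref / S(tau))^2 rescaling of the diffusion term; 1 without growth."""
    if params.growth is None:
        return 1.0
    k1, k2, k3 = params.growth
    S_tau = logistic_growth(tau, k1, k2, k3)
    return float((params.S_ref / S_tau) ** 2)


def drd_rhs(lattice: ScaleLattice, params: RDParams, u: np.ndarray, tau: float) -> np.ndarray:
    """Right-hand side of the polygonal discrete RD system (per growth time).

    (1/q) du_i/dtau = F(u_i) - c u_i
                      + (S_ref/S(tau))^2 (P D / (A_i eps_ref)) sum_j (u_j - u_i) L_ij

    Geometry (A_i, L_ij) is the reference (last time point) geometry; absent
    neighbors contribute nothing (zero-flux boundary).
    """
    F, G, H = reaction_terms(u[:, 0], u[:, 1], u[:, 2], params)
    react = np.stack([F, G, H], axis=1) - u * params.c_vec
    i, j, w = lattice.laplacian_weights()
    flux = np.zeros_like(u)
    np.add.at(flux, i, w[:, None] * (u[j] - u[i]))
    g = _growth_factor(params, tau)
    diff = g * params.P / (lattice.areas[:, None] * params.eps_ref) * flux * params.D_vec
    return params.q * (react + diff)


def simulate_drd(
    lattice: ScaleLattice,
    params: RDParams,
    ic: RDState,
    tau_grid,
    dt: float = 0.2,
) -> list[RDState]:
    """Integrate the polygonal discrete RD system, sampling at ``tau_grid``.

    Classical RK4 with fixed step ``dt`` (sub-stepping exactly onto each grid
    point).  Raises if the state blows up beyond the bound implied by the
    reaction caps (diagnostic includes the offending step size).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    u = np.array(ic.u, dtype=float)
    if u.shape[0] != lattice.n_scales:
        raise ValueError("initial condition does not match lattice size")
    bound = float(np.max(params.caps) / max(min(params.c_vec), 1e-12)) + float(
        np.abs(u).max()
    ) + 1.0
    out = []
    tau = float(tau_grid[0])
    out.append(RDState(u.copy(), tau))
    for tk in tau_grid[1:]:
        while tau < tk - 1e-12:
            h = min(dt, tk - tau)
            k1 = drd_rhs(lattice, params, u, tau)
            k2 = drd_rhs(lattice, params, u + 0.5 * h * k1, tau + 0.5 * h)
            k3 = drd_rhs(lattice, params, u + 0.5 * h * k2, tau + 0.5 * h)
            k4 = drd_rhs(lattice, params, u + h * k3, tau + h)
            u = u + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            tau += h
            if not np.isfinite(u).all() or np.abs(u).max() > 10 * bound:
                raise FloatingPointError(
                    f"discrete RD integration unstable at tau={tau:.4g} with dt={h:.4g}"
                )
        out.append(RDState(u.copy(), float(tk)))
    return out


# ---------------------------------------------------------------------------
# 2D continuous RD on a pixel grid with interscale-edge diffusivity P*D


def _crd2d_operator(boundary_mask: np.ndarray, eps: float, P: float) -> sp.csr_matrix:
    """Sparse divergence-form diffusion operator (unit D) on a square grid.

    Face diffusivity is evaluated at cell-pair midpoints: a face bordering a
    marked interscale pixel carries diffusivity P, all others 1.  Zero-flux
    outer boundary.  Multiply by the component's D to get its operator.
    """
    ny, nx = boundary_mask.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    mask = boundary_mask.astype(bool)
    rows, cols, vals = [], [], []

    def add_faces(ia, ib, ma, mb):
        d = np.where(ma | mb, P, 1.0) / eps**2
        for s, t in ((ia, ib), (ib, ia)):
            rows.append(s)
            cols.append(t)
            vals.append(d)
            rows.append(s)
            cols.append(s)
            vals.append(-d)

    add_faces(idx[:, :-1].ravel(), idx[:, 1:].ravel(), mask[:, :-1].ravel(), mask[:, 1:].ravel())
    add_faces(idx[:-1, :].ravel(), idx[1:, :].ravel(), mask[:-1, :].ravel(), mask[1:, :].ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def simulate_crd2d(
    boundary_mask: np.ndarray,
    params: RDParams,
    ic: RDState,
    tau_grid,
    eps: float = 1.0,
    dt: float = 0.5,
) -> list[RDState]:
    """Semi-implicit 2D continuous RD on a square grid with spacing ``eps``.

    ``boundary_mask`` marks interscale pixels where diffusivity is scaled by
    P.  Diffusion is treated implicitly (sparse LU, factors cached while the
    growth factor is unchanged), the clamped reactions explicitly.  States
    are (ny*nx, 3) row-major rasters.
    """
    mask = np.asarray(boundary_mask, dtype=bool)
    n = mask.size
    u = np.array(ic.u, dtype=float)
    if u.shape[0] != n:
        raise ValueError("initial condition does not match grid size")
    L = _crd2d_operator(mask, eps, params.P)
    tau_grid = np.asarray(tau_grid, dtype=float)
    out = [RDState(u.copy(), float(tau_grid[0]))]
    tau = float(tau_grid[0])
    solvers, g_cached = None, None
    for tk in tau_grid[1:]:
        while tau < tk - 1e-12:
            h = min(dt, tk - tau)
            g = _growth_factor(params, tau)
            key = (round(g, 12), round(h, 12))
            if key != g_cached:
                solvers = [
                    spla.splu((sp.identity(n) - params.q * h * g * D * L).tocsc())
                    for D in params.D_vec
                ]
                g_cached = key
            F, G, H = reaction_terms(u[:, 0], u[:, 1], u[:, 2], params)
            react = np.stack([F, G, H], axis=1) - u * params.c_vec
            rhs = u + params.q * h * react
            u = np.stack([solvers[c].solve(rhs[:, c]) for c in range(3)], axis=1)
            tau += h
            if not np.isfinite(u).all():
                raise FloatingPointError(f"2D-cRD unstable at tau={tau:.4g}")
        out.append(RDState(u.copy(), float(tk)))
    return out
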