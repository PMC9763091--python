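"""CIELAB color handling and the color <-> reaction-diffusion transforms.

Juvenile scale colors are near-binary: a two-cluster K-means in CIELAB gives
the "green" and "black" cluster centers Cg, Cb (relabeled so Lg* > Lb*).
Colors are mapped into the (u, v, w) reaction-diffusion space by composing
three affine maps: T1 projects each color onto the Cg-Cb line, T2 carries
that line onto the segment [ug, ub] between the two extremities of the
dominating eigenvector line of the linearized RD system, and T3 contracts
the result toward the homogeneous steady state u* by a factor r in [0, 1].
The inverse direction (RD state -> color, used at post-juvenile time points)
is the affine map Te that carries the PCA ellipsoid of the RD point cloud
onto the PCA ellipsoid of the color cloud.

RGB <-> CIELAB conversions use the D65 illuminant / 2 degree observer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab
from sklearn.cluster import KMeans

from .lattice import ColorState

__all__ = [
    "ColorClusters",
    "AffineMap3",
    "rgb_to_lab",
    "lab_to_rgb",
    "kmeans2",
    "t1_projection",
    "t2_line_map",
    "t3_contraction",
    "colors_to_rd",
    "fit_color_transform",
    "rd_to_colors",
    "nearest_center_states",
]


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """RGB in [0, 1] (any leading shape, last axis 3) to CIELAB, D65/2deg."""
    return rgb2lab(np.asarray(rgb, dtype=float))


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    return lab2rgb(np.asarray(lab, dtype=float))


@dataclass
class ColorClusters:
    """Two CIELAB cluster centers with Lg* > Lb* and per-scale assignments."""

    Cg: np.ndarray
    Cb: np.ndarray
    labels: np.ndarray  # 1 where assigned to Cg ("green"), 0 for Cb

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.Cg - self.Cb))


def kmeans2(colors: ColorState | np.ndarray, seed: int = 0) -> ColorClusters:
    """Two-means clustering in CIELAB; centers relabeled so Lg* > Lb*."""
    X = colors.colors if isinstance(colors, ColorState) else np.atleast_2d(colors)
    if np.allclose(X, X[0]):
        raise ValueError("all colors identical; two clusters undefined")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    c0, c1 = km.cluster_centers_
    if c0[0] >= c1[0]:  # L* of cluster 0 larger -> it is the green one
        Cg, Cb, labels = c0, c1, (km.labels_ == 0).astype(np.int8)
    else:
        Cg, Cb, labels = c1, c0, (km.labels_ == 1).astype(np.int8)
    return ColorClusters(Cg, Cb, labels)


class AffineMap3:
    """Affine map on 3-vectors stored as a 4x4 homogeneous matrix."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4) or not np.allclose(matrix[3], [0, 0, 0, 1]):
            raise ValueError("expected a 4x4 homogeneous matrix with last row (0,0,0,1)")
        self.matrix = matrix

    @classmethod
    def from_linear(cls, Q: np.ndarray, offset: np.ndarray) -> "AffineMap3":
        m = np.eye(4)
        m[:3, :3] = Q
        m[:3, 3] = offset
        return cls(m)

    @classmethod
    def identity(cls) -> "AffineMap3":
        return cls(np.eye(4))

    def __matmul__(self, other: "AffineMap3") -> "AffineMap3":
        return AffineMap3(self.matrix @ other.matrix)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out


def _unit(x: np.ndarray, xp: np.ndarray) -> np.ndarray:
    d = np.asarray(x, float) - np.asarray(xp, float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate line: identical endpoints")
    return d / n


def t1_projection(x: np.ndarray, xp: np.ndarray) -> AffineMap3:
    """Orthogonal projection of 3-space onto the line through x and x'."""
    e = _unit(x, xp)
    P = np.outer(e, e)
    return AffineMap3.from_linear(P, (np.eye(3) - P) @ np.asarray(x, float))


def t2_line_map(x, xp, y, yp) -> AffineMap3:
    """Affine map taking the line through (x, x') to the line through (y, y').

    Maps x to y and x' to y', scaling distances along the line by
    ||y - y'|| / ||x - x'||.
    """
    ex, ey = _unit(x, xp), _unit(y, yp)
    s = np.linalg.norm(np.asarray(y, float) - np.asarray(yp, float)) / np.linalg.norm(
        np.asarray(x, float) - np.asarray(xp, float)
    )
    Q = s * np.outer(ey, ex)
    return AffineMap3.from_linear(Q, np.asarray(y, float) - Q @ np.asarray(x, float))


def t3_contraction(r: float, ustar: np.ndarray) -> AffineMap3:
    """Contraction toward the HSS: u -> r u + (1 - r) u*, r in [0, 1]."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    return AffineMap3.from_linear(r * np.eye(3), (1.0 - r) * np.asarray(ustar, float))


def colors_to_rd(colors: ColorState, clusters: ColorClusters, stability, r: float):
    """Map juvenile CIELAB colors to RD concentrations: u1 = T3 T2 T1 C.

    ``stability`` is a :class:`~scalepat.rd.StabilityReport` providing the
    HSS u* and the extremities (ug, ub) of the dominating eigenvector line.
    """
    from .rd import RDState

    if np.allclose(stability.ug, stability.ub):
        raise ValueError("degenerate dominating line: ug == ub")
    T = (
        t3_contraction(r, stability.ustar)
        @ t2_line_map(clusters.Cg, clusters.Cb, stability.ug, stability.ub)
        @ t1_projection(clusters.Cg, clusters.Cb)
    )
    return RDState(T(colors.colors), time=colors.time)


def _pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, eigenvalues (descending) and eigenvectors of Cov = X'X/n."""
    mu = X.mean(axis=0)
    C = (X - mu).T @ (X - mu) / X.shape[0]
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return mu, w[order], V[:, order]


def fit_color_transform(rd_states, color_cloud: ColorState, jitter: float = 1e-12) -> AffineMap3:
    """Fit the ellipsoid-to-ellipsoid affine map Te from RD space to color space.

    Te maps the RD centroid to the color centroid with linear part
    Q = V_C D_C^(1/2) (V_u D_u^(1/2))^(-1) built from the PCA of each cloud.
    The intrinsic eigenvector sign ambiguity is fixed by orienting each RD
    axis so that the per-scale PCA scores of the two (paired) clouds
    correlate positively.  Rank-deficient covariances are regularized with a
    small jitter (with a warning).
    """
    U = rd_states.u if hasattr(rd_states, "u") else np.atleast_2d(np.asarray(rd_states, float))
    C = color_cloud.colors
    if U.shape[0] != C.shape[0]:
        raise ValueError("RD and color clouds must be paired per scale")
    muU, wU, VU = _pca(U)
    muC, wC, VC = _pca(C)
    tolU, tolC = 1e-12 * max(wU[0], 1.0), 1e-12 * max(wC[0], 1.0)
    if (wU < tolU).any() or (wC < tolC).any():
        warnings.warn("rank-deficient covariance; regularizing with jitter")
        wU = np.maximum(wU, jitter)
        wC = np.maximum(wC, jitter)
    # sign fix: paired scores must correlate positively axis by axis
    for k in range(3):
        if float(((U - muU) @ VU[:, k]) @ ((C - muC) @ VC[:, k])) < 0:
            VU[:, k] = -VU[:, k]
    Q = (VC * np.sqrt(wC)) @ np.linalg.inv(VU * np.sqrt(wU))
    return AffineMap3.from_linear(Q, muC - Q @ muU)


def rd_to_colors(state, Te: AffineMap3) -> ColorState:
    """Per-scale affine application of Te: C = Te u."""
    return ColorState(Te(state.u), time=state.time)


def nearest_center_states(colors: ColorState, clusters: ColorClusters) -> np.ndarray:
    """Threshold continuous colors by assigning each scale to the nearest of (Cg, Cb).

    Returns int8 labels (1 = green).  This is the simulation-side analogue of
    the K-means thresholding applied to observed colors.
    """
    dg = np.linalg.norm(colors.colors - clusters.Cg, axis=1)
    db = np.linalg.norm(colors.colors - clusters.Cb, axis=1)
    return (dg <= db).astype(np.int8)
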