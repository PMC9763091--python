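"""Scale detection from normal maps and cross-time scale matching.

The imaging stage turns a photometric-stereo normal map into a scale
lattice: mean curvature is computed from the per-pixel normals, smoothed
with Gaussian and median filters, segmented by watershed (scale centers are
curvature minima), and the Voronoi diagram of the segment centroids defines
scale boundaries and connectivity.  Scales are then traced across scan time
points by growing local affine matches from a few seed correspondences, and
the pairwise matches are unified into a space-time network whose topology is
invariant over time.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.ndimage import distance_transform_edt, median_filter
from scipy.spatial import cKDTree
from skimage.filters import gaussian
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .lattice import ColorState, ScaleLattice, build_voronoi_lattice

__all__ = [
    "NormalField",
    "SpaceTimeNetwork",
    "encode_normal_map",
    "decode_normal_map",
    "read_normal_map",
    "write_normal_map",
    "mean_curvature",
    "detect_scales",
    "extract_scale_colors",
    "match_pair",
    "similarity_transform",
    "unify_network",
]


class NormalField:
    """Per-pixel unit surface normals (y-down image convention) plus pixel pitch."""

    def __init__(self, normals: np.ndarray, pitch: float = 1.0):
        normals = np.asarray(normals, dtype=float)
        if normals.ndim != 3 or normals.shape[2] != 3:
            raise ValueError("normals must be (H, W, 3)")
        norms = np.linalg.norm(normals, axis=-1)
        if (norms <= 0).any():
            raise ValueError("zero-length normals")
        self.normals = normals / norms[..., None]
        self.pitch = float(pitch)

    @property
    def shape(self) -> tuple[int, int]:
        return self.normals.shape[:2]


def encode_normal_map(normals: np.ndarray) -> np.ndarray:
    """Encode unit normals channel-wise from (-1, 1) to uint16 (0, 65535)."""
    v = np.clip((np.asarray(normals, float) + 1.0) / 2.0, 0.0, 1.0)
    return np.round(v * 65535.0).astype(np.uint16)


def decode_normal_map(image: np.ndarray, pitch: float = 1.0) -> NormalField:
    """Decode a 16-bit 3-channel normal image: v -> 2 v / 65535 - 1.

    The decoded components are renormalized to unit length (quantization
    leaves them within 1/65535 per channel of the encoded values).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel image")
    if image.dtype != np.uint16:
        raise ValueError("expected 16-bit channels")
    n = 2.0 * image.astype(float) / 65535.0 - 1.0
    return NormalField(n, pitch)


def write_normal_map(path: str, encoded: np.ndarray) -> None:
    """Write an encoded normal map as 16-bit RGB TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(encoded, dtype=np.uint16))


def read_normal_map(path: str, pitch: float = 1.0) -> NormalField:
    import tifffile

    return decode_normal_map(tifffile.imread(path), pitch)


def mean_curvature(nf: NormalField) -> np.ndarray:
    """Mean curvature field H from the normal map.

    With the surface parametrized as a height field and zu = -n1/n3,
    zv = -n2/n3, the fundamental forms give

        E = 1 + (n1/n3)^2,  F = n1 n2 / n3^2,  G = 1 + (n2/n3)^2,
        L = -du(n1/n3) n3,  M = -dv(n1/n3) n3,  N = -dv(n2/n3) n3,
        H = (E N - 2 F M + G L) / (2 (E G - F^2)).

    Derivatives are central differences; the one-pixel border and pixels
    with n3 near zero are masked to NaN.
    """
    n = nf.normals
    n3 = n[..., 2]
    bad = np.abs(n3) < 1e-6
    n3s = np.where(bad, 1.0, n3)
    a = n[..., 0] / n3s  # n1/n3
    b = n[..., 1] / n3s  # n2/n3
    # u is the x (column) direction, v the y (row) direction
    da_du = np.gradient(a, nf.pitch, axis=1)
    da_dv = np.gradient(a, nf.pitch, axis=0)
    db_dv = np.gradient(b, nf.pitch, axis=0)
    E = 1.0 + a * a
    F = a * b
    G = 1.0 + b * b
    L = -da_du * n3s
    M = -da_dv * n3s
    N = -db_dv * n3s
    H = (E * N - 2.0 * F * M + G * L) / (2.0 * (E * G - F * F))
    H[bad] = np.nan
    H[0, :] = H[-1, :] = np.nan
    H[:, 0] = H[:, -1] = np.nan
    return H


def detect_scales(
    H: np.ndarray, s: float, h_frac: float = 0.05
) -> tuple[np.ndarray, ScaleLattice, np.ndarray]:
    """Detect scale centers on a curvature field and build their lattice.

    Pipeline: Gaussian filter (sigma = s/10), median filter (window (s, s)),
    watershed of the filtered field with markers at its local minima
    (h-minima suppression at ``h_frac`` of the dynamic range, so shallow
    noise minima do not over-segment).  The lattice is the Voronoi diagram
    of the watershed-segment centroids clipped to the image rectangle.
    Returns ``(centers, lattice, labels)`` with centers in (x, y) pixels.
    """
    if s < 10:
        raise ValueError("expected scale size s >= 10 px")
    Hf = np.array(H, dtype=float)
    nanmask = ~np.isfinite(Hf)
    if nanmask.any():
        Hf[nanmask] = np.nanmax(Hf)
    ny, nx = Hf.shape
    # reflect-pad so frame-clipped basins complete themselves in the pad;
    # only minima whose markers fall in the core window become scales
    pad = int(round(s))
    Hp = np.pad(Hf, pad, mode="reflect")
    Hp = gaussian(Hp, sigma=s / 10.0, preserve_range=True)
    Hp = median_filter(Hp, size=int(round(s)))
    rng_dyn = Hp.max() - Hp.min()
    if rng_dyn <= 0:
        raise ValueError("flat curvature field: no minima found")
    minima = h_minima(Hp, h_frac * rng_dyn)
    markers = cc_label(minima)
    core_ids = set()
    m = max(2.0, s / 10.0)  # frame-line minima (mirror artifacts) sit within ~1 px
    for p in regionprops(markers):
        cy, cx = p.centroid
        if pad + m <= cy < pad + ny - m and pad + m <= cx < pad + nx - m:
            core_ids.add(p.label)
    if not core_ids:
        raise ValueError("no curvature minima found")
    labels_p = watershed(Hp, markers)
    centers = np.array(
        [
            [p.centroid[1] - pad, p.centroid[0] - pad]
            for p in regionprops(labels_p)
            if p.label in core_ids
        ]
    )  # (x, y) in core coordinates
    labels = np.where(np.isin(labels_p, sorted(core_ids)), labels_p, 0)[
        pad:-pad, pad:-pad
    ]
    from shapely.geometry import Polygon

    region = Polygon([(0, 0), (nx, 0), (nx, ny), (0, ny)])
    lattice = build_voronoi_lattice(centers, region) if len(centers) >= 3 else None
    return centers, lattice, labels


def _pixel_assignment(shape: tuple[int, int], centers: np.ndarray) -> np.ndarray:
    ny, nx = shape
    X, Y = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    _, idx = cKDTree(centers).query(pts)
    return idx.reshape(ny, nx)


def extract_scale_colors(
    albedo: np.ndarray,
    lattice: ScaleLattice,
    s: float,
    return_distributions: bool = False,
):
    """Per-scale CIELAB color summaries from an albedo image.

    Pixels are assigned to the nearest scale center; pixels closer than s/10
    to a scale boundary are excluded (their shading is dominated by border
    curvature).  Returns the mean-color :class:`ColorState` and a dict with
    ``median`` and ``mode`` (n, 3) arrays (the alternative summaries used by
    the measurement-uncertainty analyses); with ``return_distributions`` the
    per-scale retained CIELAB pixel lists are included as well.
    """
    from .colormap import rgb_to_lab

    albedo = np.asarray(albedo, dtype=float)
    if albedo.dtype.kind in "ui":
        albedo = albedo / np.iinfo(albedo.dtype).max
    if albedo.max() > 1.0 + 1e-9:
        albedo = albedo / (65535.0 if albedo.max() > 255.5 else 255.0)
    lab = rgb_to_lab(albedo)
    assign = _pixel_assignment(albedo.shape[:2], lattice.centers)
    border = np.zeros(assign.shape, dtype=bool)
    border[:, 1:] |= assign[:, 1:] != assign[:, :-1]
    border[:, :-1] |= assign[:, 1:] != assign[:, :-1]
    border[1:, :] |= assign[1:, :] != assign[:-1, :]
    border[:-1, :] |= assign[1:, :] != assign[:-1, :]
    dist = distance_transform_edt(~border)
    keep = dist >= s / 10.0

    n = lattice.n_scales
    mean = np.full((n, 3), np.nan)
    median = np.full((n, 3), np.nan)
    mode = np.full((n, 3), np.nan)
    flagged = np.zeros(n, dtype=bool)
    dists = {} if return_distributions else None
    for i in range(n):
        sel = (assign == i) & keep
        if not sel.any():
            flagged[i] = True
            continue
        px = lab[sel]
        mean[i] = px.mean(axis=0)
        median[i] = np.median(px, axis=0)
        for c in range(3):  # per-channel KDE mode
            v = px[:, c]
            if v.max() - v.min() < 1e-9 or v.size < 5:
                mode[i, c] = v.mean()
                continue
            from scipy.stats import gaussian_kde

            grid = np.linspace(v.min(), v.max(), 128)
            mode[i, c] = grid[int(np.argmax(gaussian_kde(v)(grid)))]
        if return_distributions:
            dists[i] = px
    extras = {"median": median, "mode": mode, "flagged": flagged}
    if return_distributions:
        extras["pixels"] = dists
    return ColorState(mean), extras


def _affine_lsq(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 2D affine (3x3 homogeneous) mapping src -> dst."""
    A = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    M = np.eye(3)
    M[:2, :] = coef.T
    return M


def match_pair(
    centersA: np.ndarray,
    centersB: np.ndarray,
    seed_matches,
    epsilon: float | None = None,
    min_nbrs: int = 3,
    max_nbrs: int = 10,
) -> dict[int, int]:
    """Grow a partial correspondence A -> B from seed matches.

    Frontier growth: for each unmatched A-scale adjacent (by proximity) to
    the matched patch, a local affine is fit from its ``min_nbrs``..
    ``max_nbrs`` nearest already-matched scales and used to transfer its
    center; the transfer is accepted when the nearest unmatched B center
    lies within ``epsilon`` (default 0.05 x the mean neighbor-center
    distance of A).  Iterates to a fixpoint.  Ties (two A-scales claiming
    one B-scale in the same round) go to the smaller distance, then the
    smaller scale id.
    """
    A = np.asarray(centersA, float)
    B = np.asarray(centersB, float)
    seeds = dict(seed_matches if not isinstance(seed_matches, dict) else seed_matches.items())
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed matches")
    if epsilon is None:
        d, _ = cKDTree(A).query(A, k=2)
        epsilon = 0.05 * float(np.mean(d[:, 1])) * 1.0
        # mean neighbor distance approximated by nearest-neighbor spacing
    matched = dict(seeds)
    used_b = set(matched.values())
    treeB = cKDTree(B)
    while True:
        cand_ids = [i for i in range(len(A)) if i not in matched]
        if not cand_ids:
            break
        matched_ids = np.fromiter(matched.keys(), dtype=int)
        matched_A = A[matched_ids]
        treeM = cKDTree(matched_A)
        proposals = []  # (dist, a, b)
        for a in cand_ids:
            k = min(max_nbrs, len(matched_ids))
            if k < min_nbrs:
                continue
            dd, ii = treeM.query(A[a], k=k)
            ii = np.atleast_1d(ii)
            src = matched_A[ii]
            # collinear neighbor sets give a rank-deficient affine: widen,
            # and if the whole matched patch is collinear fall back to the
            # closed-form similarity transform
            while (
                np.linalg.matrix_rank(np.column_stack([src, np.ones(len(src))])) < 3
                and len(ii) < len(matched_ids)
            ):
                k2 = min(len(ii) * 2, len(matched_ids))
                _, ii = treeM.query(A[a], k=k2)
                ii = np.atleast_1d(ii)
                src = matched_A[ii]
            dst = B[[matched[int(matched_ids[t])] for t in ii]]
            if np.linalg.matrix_rank(np.column_stack([src, np.ones(len(src))])) < 3:
                theta, s_, t_ = similarity_transform(dst, src)
                p = apply_similarity(A[a], theta, s_, t_, dst.mean(0), src.mean(0))
            else:
                M = _affine_lsq(src, dst)
                p = M[:2, :2] @ A[a] + M[:2, 2]
            db, jb = treeB.query(p)
            if db < epsilon and int(jb) not in used_b:
                proposals.append((float(db), a, int(jb)))
        if not proposals:
            break
        new = False
        for db, a, jb in sorted(proposals):
            if a in matched or jb in used_b:
                continue
            matched[a] = jb
            used_b.add(jb)
            new = True
        if not new:
            break
    return matched


def similarity_transform(ref: np.ndarray, target: np.ndarray):
    """Closed-form least-squares similarity (theta, s, t) mapping target -> ref.

    Shear and anisotropic scaling are excluded (they would distort the
    Voronoi topology toward the reference time point): after translating the
    target by the centroid difference t, theta and s minimize the summed
    squared distance, with the printed closed forms

        theta = arctan( <yr xt' - xr yt'> / <xr xt' + yr yt'> ),
        s = [cos(theta) <xr xt' + yr yt'> + sin(theta) <yr xt' - xr yt'>]
            / <xt'^2 + yt'^2>,

    angle brackets denoting means over matched scales and primes the
    centroid-centered target coordinates.
    """
    ref = np.asarray(ref, float)
    target = np.asarray(target, float)
    t = ref.mean(0) - target.mean(0)
    rp = ref - ref.mean(0)
    tp = target - target.mean(0)
    num = float(np.mean(rp[:, 1] * tp[:, 0] - rp[:, 0] * tp[:, 1]))
    den = float(np.mean(rp[:, 0] * tp[:, 0] + rp[:, 1] * tp[:, 1]))
    theta = np.arctan2(num, den)
    s = (np.cos(theta) * den + np.sin(theta) * num) / float(np.mean(tp[:, 0] ** 2 + tp[:, 1] ** 2))
    return float(theta), float(s), t


def apply_similarity(points: np.ndarray, theta: float, s: float, t: np.ndarray,
                     ref_centroid: np.ndarray, tgt_centroid: np.ndarray) -> np.ndarray:
    """Apply (theta, s) about the target centroid, then move onto the reference."""
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return (np.asarray(points, float) - tgt_centroid) @ (s * R).T + ref_centroid


class SpaceTimeNetwork:
    """Scales traced across all time points with a single shared topology.

    ``lattice`` is rebuilt by Voronoi tessellation of the across-time
    averaged centers; ``colors`` maps each time point to a per-scale color
    array aligned with the lattice; ``node_ids`` records, per kept scale,
    its original index at each time point.
    """

    def __init__(self, lattice: ScaleLattice, times, colors, node_ids, transforms):
        self.lattice = lattice
        self.times = list(times)
        self.colors = colors          # list of ColorState or None
        self.node_ids = node_ids      # (n_scales, n_times) int
        self.transforms = transforms  # per time: (theta, s, t)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def patterns(self, clusters):
        from .metrics import as_pattern

        return [as_pattern(c, clusters) for c in self.colors]


def unify_network(
    center_sets: list[np.ndarray],
    pair_matches: dict[tuple[int, int], dict[int, int]],
    color_sets: list[np.ndarray] | None = None,
    times=None,
) -> SpaceTimeNetwork:
    """Combine pairwise matches into a unified space-time network.

    Nodes (t, i) are joined by match edges; connected components with
    exactly one node per time point are kept.  Each time point is registered
    onto the first by its closed-form similarity transform; the final
    lattice is the Voronoi diagram of the across-time averaged centers.
    """
    T = len(center_sets)
    if times is None:
        times = list(range(T))
    G = nx.Graph()
    for t, centers in enumerate(center_sets):
        G.add_nodes_from((t, i) for i in range(len(centers)))
    for (ta, tb), m in pair_matches.items():
        G.add_edges_from(((ta, a), (tb, b)) for a, b in m.items())
    kept = []
    for comp in nx.connected_components(G):
        ts = sorted(n[0] for n in comp)
        if ts == list(range(T)):
            ids = {t: i for t, i in comp}
            kept.append([ids[t] for t in range(T)])
    if not kept:
        raise ValueError("no connected component spans all time points")
    node_ids = np.array(kept, dtype=int)

    ref = center_sets[0][node_ids[:, 0]]
    transforms, registered = [], [ref]
    for t in range(1, T):
        tgt = center_sets[t][node_ids[:, t]]
        theta, s, tr = similarity_transform(ref, tgt)
        transforms.append((theta, s, tr))
        registered.append(apply_similarity(tgt, theta, s, tr, ref.mean(0), tgt.mean(0)))
    transforms.insert(0, (0.0, 1.0, np.zeros(2)))
    avg = np.mean(registered, axis=0)
    lattice = build_voronoi_lattice(avg)
    colors = None
    if color_sets is not None:
        colors = [
            ColorState(np.asarray(color_sets[t])[node_ids[:, t]], time=times[t])
            for t in range(T)
        ]
    return SpaceTimeNetwork(lattice, times, colors, node_ids, transforms)
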