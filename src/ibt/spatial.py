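"""Spatial statistics on reconstructed ion tomograms.

Covers the downstream quantification used on deconvolved / localized
cubes: fuzzy C-means chromatin-state segmentation (compacted, decondensed,
very-low density), spatially resolved 3D K-means over multiple mass
channels with per-cluster z-score profiles, block-wise peak counting,
pairwise peak distances, Euclidean-distance hierarchical clustering of
voxel coordinates, channel Pearson correlation / association matrices, and
Delaunay triangle/tetrahedron neighborhood graphs over block centroids.

All physical distances respect anisotropic voxel scaling (dx, dy lateral,
z_step axial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .stack import AcquisitionGeometry

__all__ = [
    "StateMap", "ClusterResult", "PeakSet", "NeighborhoodGraph",
    "STATE_NAMES", "fcm_states", "kmeans3d",
    "block_peaks", "peak_rate", "peak_pairwise_distances",
    "euclid_hierarchical", "channel_correlation_matrix",
    "delaunay_neighborhoods",
]

STATE_NAMES = ("very-low", "decondensed", "compacted")


@dataclass
class StateMap:
    """Voxel-wise chromatin-state segmentation from fuzzy C-means."""
    labels: np.ndarray            # int state index, ascending mean intensity
    memberships: np.ndarray       # (n_voxels, C), rows sum to 1
    centroids: np.ndarray         # per-state mean intensity, ascending
    state_names: tuple[str, ...]
    n_iter: int
    converged: bool

    def state_label(self, index: int) -> str:
        return self.state_names[index]


@dataclass
class ClusterResult:
    """3D K-means assignment with per-cluster channel z-score profiles."""
    labels: np.ndarray            # per-voxel cluster id in [0, C)
    zscore_means: np.ndarray      # (C, M) mean standardized value
    inertia: float
    n_iter: int
    seed: int


@dataclass
class PeakSet:
    """Detected local peaks with block bookkeeping."""
    positions: np.ndarray         # (n, 3) columns (x_px, y_px, z_slice)
    intensities: np.ndarray
    block_ids: np.ndarray
    n_blocks: int
    n_dropped_blocks: int


@dataclass
class NeighborhoodGraph:
    """Delaunay simplices over intensity-weighted block centroids."""
    centroids: np.ndarray         # (n_blocks, 2 or 3), pixel/slice units
    block_signals: np.ndarray     # (n_blocks, n_channels) summed signal
    simplices: np.ndarray         # (n_simplices, 3 or 4) centroid indices
    simplex_mean_signals: np.ndarray  # (n_simplices, n_channels)
    n_dropped_blocks: int
    jittered: bool = False


def fcm_states(volume: np.ndarray, C: int = 3, m: float = 2.0,
               tol: float = 1e-5, max_iter: int = 300,
               state_names: tuple[str, ...] | None = None) -> StateMap:
    """Fuzzy C-means segmentation of voxel intensities into C states.

    Full FCM iteration on the scalar intensity distribution: memberships
    u_ik proportional to distance ratios with fuzzifier ``m``, centroids
    the membership-weighted means; converged when the max membership
    change drops below ``tol``.  Centroids initialize at evenly spaced
    data quantiles, which makes the hard labels invariant to positive
    affine rescaling of the input (the whole iteration is equivariant).
    States are named by ascending centroid intensity: very-low <
    decondensed < compacted.
    """
    x = np.asarray(volume, dtype=float).ravel()
    if np.unique(x).size < C:
        raise ValueError(f"need >= {C} distinct voxel values for C={C} states")
    if state_names is None:
        state_names = STATE_NAMES if C == 3 else tuple(f"state-{i}" for i in range(C))
    if len(state_names) != C:
        raise ValueError("state_names length must equal C")
    centroids = np.quantile(x, (np.arange(C) + 0.5) / C)
    exponent = 2.0 / (m - 1.0)
    u_prev = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = np.abs(x[:, None] - centroids[None, :])
        d = np.maximum(d, 1e-12)
        inv = d ** (-exponent)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        if u_prev is not None and np.abs(u - u_prev).max() < tol:
            converged = True
            break
        u_prev = u
    if not converged:
        warnings.warn(f"FCM did not converge in {max_iter} iterations")
    order = np.argsort(centroids)
    centroids = centroids[order]
    u = u[:, order]
    labels = np.argmax(u, axis=1).reshape(np.asarray(volume).shape)
    return StateMap(labels=labels, memberships=u, centroids=centroids,
                    state_names=tuple(state_names), n_iter=n_iter,
                    converged=converged)


def kmeans3d(channel_cubes: np.ndarray, C: int = 6, seed: int = 0,
             scale: bool = True, normalize: bool = True) -> ClusterResult:
    """Spatially resolved K-means over per-voxel multi-channel vectors.

    ``channel_cubes`` is (M, z, y, x).  Features are standardized per
    channel (zero mean, unit variance) and then min-max normalized to
    [0, 1] - both steps, in that order, each optional by flag - before
    k-means++ Lloyd iterations at a fixed seed.  The returned z-score
    means are computed on the standardized features for heatmap export.
    """
    cubes = np.asarray(channel_cubes, dtype=float)
    if cubes.ndim != 4:
        raise ValueError("channel_cubes must be (M, z, y, x)")
    M = cubes.shape[0]
    X = cubes.reshape(M, -1).T  # (n_voxels, M)
    if X.shape[0] < C:
        raise ValueError("voxel count must be >= C")
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - X.mean(axis=0)) / std  # z-scores, kept for the heatmap
    feats = Z if scale else X.copy()
    if normalize:
        lo, hi = feats.min(axis=0), feats.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        feats = (feats - lo) / rng
    km = KMeans(n_clusters=C, init="k-means++", n_init=10,
                random_state=seed).fit(feats)
    labels = km.labels_
    zmeans = np.vstack([Z[labels == c].mean(axis=0) if np.any(labels == c)
                        else np.full(M, np.nan) for c in range(C)])
    return ClusterResult(labels=labels.reshape(cubes.shape[1:]),
                         zscore_means=zmeans, inertia=float(km.inertia_),
                         n_iter=int(km.n_iter_), seed=seed)


def _local_maxima(img: np.ndarray, threshold: float) -> np.ndarray:
    peak = (ndimage.maximum_filter(img, size=3, mode="constant", cval=-np.inf)
            == img) & (img > threshold)
    return np.argwhere(peak)


def block_peaks(image: np.ndarray, block: int = 20, k_mad: float = 4.0,
                z_slice: int = 0) -> PeakSet:
    """Local peaks detected block by block with per-block thresholds.

    The image is divided into ``block`` x ``block`` pixel blocks; each
    block is thresholded at its own median + k * MAD and local maxima
    above it are kept.  Incomplete edge blocks are dropped and counted.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    nby, nbx = ny // block, nx // block
    if nby < 1 or nbx < 1:
        raise ValueError("image smaller than one block")
    total_blocks = -(-ny // block) * (-(-nx // block))
    dropped = total_blocks - nby * nbx
    positions, intensities, block_ids = [], [], []
    for by in range(nby):
        for bx in range(nbx):
            sub = img[by * block:(by + 1) * block, bx * block:(bx + 1) * block]
            med = np.median(sub)
            mad = np.median(np.abs(sub - med))
            thr = med + k_mad * 1.4826 * mad
            for (iy, ix) in _local_maxima(sub, thr):
                positions.append((bx * block + ix, by * block + iy, z_slice))
                intensities.append(sub[iy, ix])
                block_ids.append(by * nbx + bx)
    return PeakSet(positions=np.asarray(positions, dtype=float).reshape(-1, 3),
                   intensities=np.asarray(intensities, dtype=float),
                   block_ids=np.asarray(block_ids, dtype=int),
                   n_blocks=nby * nbx, n_dropped_blocks=dropped)


def peak_rate(*images: np.ndarray, block: int = 20,
              k_mad: float = 4.0) -> dict:
    """Mean peaks per block averaged over one or more images, with the
    per-image counts kept for step-plot export."""
    if not images:
        raise ValueError("need at least one image")
    per_image = []
    for img in images:
        ps = block_peaks(img, block=block, k_mad=k_mad)
        per_image.append(len(ps.intensities) / ps.n_blocks)
    return {"mean_peaks_per_block": float(np.mean(per_image)),
            "per_image": per_image}


def peak_pairwise_distances(peaks: PeakSet,
                            geom: AcquisitionGeometry) -> dict:
    """All unordered pairwise peak distances in nm, anisotropically scaled
    by (dx, dy, z_step).  Fewer than 2 peaks gives an empty result."""
    pts = peaks.positions
    if len(pts) < 2:
        return {"distances_nm": np.empty(0), "mean_nm": float("nan"),
                "n_pairs": 0, "n_zero": 0, "note": "fewer than 2 peaks"}
    scaled = pts * np.array([geom.dx_nm, geom.dy_nm, geom.z_step_nm])
    d = pdist(scaled)
    n_zero = int(np.sum(d == 0))
    if n_zero:
        warnings.warn(f"{n_zero} duplicate peak pair(s) at zero distance")
    return {"distances_nm": d, "mean_nm": float(d.mean()),
            "n_pairs": int(d.size), "n_zero": n_zero, "note": ""}


def euclid_hierarchical(voxels_a: np.ndarray, voxels_b: np.ndarray,
                        max_voxels: int = 2000, seed: int = 0,
                        method: str = "average", n_clusters: int = 2) -> dict:
    """Euclidean-distance matrix over two voxel coordinate sets with
    average-linkage hierarchical clustering.

    Coordinates from both sets are pooled (with origin labels kept); sets
    larger than ``max_voxels`` are subsampled with the given seed.  The
    cut at ``n_clusters`` is exported alongside the dendrogram leaf order.
    """
    A = np.asarray(voxels_a, dtype=float)
    B = np.asarray(voxels_b, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("voxel coordinate lists must be non-empty")
    rng = np.random.default_rng(seed)

    def cap(P: np.ndarray) -> np.ndarray:
        if len(P) > max_voxels:
            return P[rng.choice(len(P), max_voxels, replace=False)]
        return P

    A, B = cap(A), cap(B)
    pts = np.vstack([A, B])
    origin = np.r_[np.zeros(len(A), dtype=int), np.ones(len(B), dtype=int)]
    dmat = squareform(pdist(pts))
    Z = linkage(pdist(pts), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    from scipy.cluster.hierarchy import leaves_list
    return {"distance_matrix": dmat, "origin": origin, "linkage": Z,
            "cut_labels": labels, "leaf_order": leaves_list(Z)}


def channel_correlation_matrix(channel_cubes: np.ndarray) -> dict:
    """Pairwise Pearson correlation of channel voxel values, plus the
    clipped non-negative association matrix used for chord export.

    Constant channels get NaN rows/columns and are flagged.
    """
    cubes = np.asarray(channel_cubes, dtype=float)
    if cubes.ndim < 2 or cubes.shape[0] < 2:
        raise ValueError("need >= 2 channels")
    M = cubes.shape[0]
    X = cubes.reshape(M, -1)
    constant = X.std(axis=1) == 0
    corr = np.full((M, M), np.nan)
    with np.errstate(invalid="ignore"):
        valid = ~constant
        if valid.sum() >= 2:
            corr_valid = np.corrcoef(X[valid])
            ix = np.flatnonzero(valid)
            corr[np.ix_(ix, ix)] = corr_valid
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    association = np.clip(np.nan_to_num(corr, nan=0.0), 0.0, None)
    return {"correlation": corr, "association": association,
            "constant_channels": np.flatnonzero(constant).tolist()}


def delaunay_neighborhoods(channel_cubes: np.ndarray, block: int = 2,
                           three_d: bool = False, jitter_seed: int = 0,
                           intensity_channel: int = 0) -> NeighborhoodGraph:
    """Delaunay triangulation (2D) / tetrahedralization (3D) of
    intensity-weighted block centroids.

    ``channel_cubes`` is (M, y, x) for 2D or (M, z, y, x) for 3D; the
    field is divided into ``block``-sized subregions (2, 4 or 8 px), each
    summarized by its center of mass (weighted by ``intensity_channel``)
    and per-channel signal sums.  Zero-signal blocks are dropped.  Per-
    simplex mean signals are exported for heatmap tables.  Degenerate
    (collinear/cospherical) centroid sets get a deterministic seeded
    1e-6 px jitter and one retry.
    """
    cubes = np.asarray(channel_cubes, dtype=float)
    expect = 4 if three_d else 3
    if cubes.ndim != expect:
        raise ValueError(f"channel_cubes must be {expect}D for "
                         f"{'3D' if three_d else '2D'} analysis")
    M = cubes.shape[0]
    spatial_shape = cubes.shape[1:]
    nb = [s // block for s in spatial_shape]
    if min(nb) < 1:
        raise ValueError("field smaller than one block")
    centroids, signals = [], []
    dropped = 0
    for idx in np.ndindex(*nb):
        slicer = tuple(slice(i * block, (i + 1) * block) for i in idx)
        blocks = cubes[(slice(None),) + slicer]
        sig = blocks.reshape(M, -1).sum(axis=1)
        w = blocks[intensity_channel]
        total = w.sum()
        if total <= 0:
            dropped += 1
            continue
        grids = np.meshgrid(*[np.arange(i * block, (i + 1) * block)
                              for i in idx], indexing="ij")
        com = [float((w * g).sum() / total) for g in grids]
        # reorder axis convention to (x, y[, z->first axis last])
        centroids.append(com[::-1])
        signals.append(sig)
    centroids = np.asarray(centroids)
    signals = np.asarray(signals)
    need = 4 if three_d else 3
    if len(centroids) < need:
        raise ValueError(f"need >= {need} non-empty blocks")
    jittered = False
    try:
        tri = Delaunay(centroids)
    except QhullError:
        jittered = True
        rng = np.random.default_rng(jitter_seed)
        tri = Delaunay(centroids + rng.normal(0.0, 1e-6, centroids.shape))
    simplex_means = signals[tri.simplices].mean(axis=1)
    return NeighborhoodGraph(centroids=centroids, block_signals=signals,
                             simplices=tri.simplices,
                             simplex_mean_signals=simplex_means,
                             n_dropped_blocks=dropped, jittered=jittered)
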