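"""Stimulus similarity metrics.

Three quantities used to characterize and select stimuli:

* ``skeletal_distance`` — symmetrized mean nearest-neighbour distance between
  two 3-D skeletal point sets after maximal rigid alignment (multi-start
  iterative closest point, no scaling).
* ``select_distinct_exemplars`` — k-means over a classical-MDS embedding of a
  pairwise distance matrix, returning one representative per cluster (used to
  pick maximally distinct skeletons from a generated pool).
* Gabor-jet features — magnitudes and phases of a bank of 40 complex Gabor
  filters (5 scales x 8 orientations) sampled on a 12 x 12 grid, an
  image-level similarity representation; two videos are compared by paired
  t-tests between corresponding frames' feature vectors, averaged over frames.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal, stats
from scipy.spatial import cKDTree
from skimage.filters import gabor_kernel
from sklearn.cluster import KMeans

__all__ = [
    "GaborJetConfig",
    "skeletal_distance",
    "select_distinct_exemplars",
    "gabor_jet_features",
    "gabor_video_difference",
]


# ---------------------------------------------------------------------------
# Skeletal point-set distance


def _sym_nn_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Average of both directed mean nearest-neighbour distances."""
    da = cKDTree(b).query(a)[0].mean()
    db = cKDTree(a).query(b)[0].mean()
    return 0.5 * (da + db)


@lru_cache(maxsize=1)
def _octahedral_rotations() -> tuple:
    """The 24 proper rotations of the cube, as orientation restarts for ICP."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            R = np.zeros((3, 3))
            for i, (p, s) in enumerate(zip(perm, signs)):
                R[i, p] = s
            if np.linalg.det(R) > 0:
                mats.append(R)
    return tuple(mats)


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||q - (R p + t)||^2."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def skeletal_distance(a: np.ndarray, b: np.ndarray, align: bool = True,
                      n_icp_iterations: int = 30, tol: float = 1e-10) -> float:
    """Symmetrized mean nearest-neighbour distance between 3-D point sets.

    With ``align`` set, b is first brought into maximal alignment with a by
    rigid ICP (rotation + translation, no scaling) restarted from the 24
    octahedral orientations; the minimum symmetrized distance over restarts
    is returned.  Deterministic.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be nonempty")
    if not align:
        return _sym_nn_distance(a, b)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    best = np.inf
    tree_a = cKDTree(a)
    for R0 in _octahedral_rotations():
        bt = (b - cb) @ R0.T + ca
        prev = np.inf
        for _ in range(n_icp_iterations):
            idx = tree_a.query(bt)[1]
            R, t = _kabsch(bt, a[idx])
            bt = bt @ R.T + t
            cur = _sym_nn_distance(a, bt)
            if prev - cur < tol:
                break
            prev = cur
        best = min(best, _sym_nn_distance(a, bt))
    return float(best)


# ---------------------------------------------------------------------------
# Exemplar selection


def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) MDS: double-centered squared distances,
    coordinates from the positive eigenvalues."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > max(w.max(), 0) * 1e-9
    if not keep.any():
        return np.zeros((n, 1))
    return V[:, keep] * np.sqrt(w[keep])


def select_distinct_exemplars(dist_matrix: np.ndarray, k: int,
                              n_restarts: int = 50, seed: int = 0) -> list[int]:
    """One maximally distinct exemplar per k-means cluster of a distance matrix.

    Items are embedded by classical MDS of the (symmetric, zero-diagonal)
    distance matrix, clustered by k-means with ``n_restarts`` restarts at a
    fixed seed, and the item nearest each cluster centroid is returned.
    """
    D = np.asarray(dist_matrix, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dist_matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("dist_matrix must be symmetric with zero diagonal")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items ({n})")
    if k == n:
        return list(range(n))
    X = _classical_mds(D)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    exemplars: list[int] = []
    for c in range(k):
        members = np.nonzero(km.labels_ == c)[0]
        members = np.setdiff1d(members, exemplars)
        if members.size == 0:
            # degenerate (e.g. identical items): fall back to any unused item
            members = np.setdiff1d(np.arange(n), exemplars)
        d2 = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        exemplars.append(int(members[np.argmin(d2)]))
    return sorted(exemplars)


# ---------------------------------------------------------------------------
# Gabor jets


@dataclass(frozen=True)
class GaborJetConfig:
    """Filter-bank layout: a grid of sample points x scales x orientations.

    Wavelengths default to 5 octave-spaced values spanning 4-64 px (natural
    for 256 x 256 inputs; rescale for smaller images).
    """

    grid_rows: int = 12
    grid_cols: int = 12
    n_scales: int = 5
    n_orientations: int = 8
    wavelengths: tuple = (4.0, 8.0, 16.0, 32.0, 64.0)
    bandwidth: float = 1.0

    def __post_init__(self):
        if len(self.wavelengths) != self.n_scales:
            raise ValueError("need one wavelength per scale")

    @property
    def n_filters(self) -> int:
        return self.n_scales * self.n_orientations

    @property
    def vector_length(self) -> int:
        return self.grid_rows * self.grid_cols * self.n_filters * 2


@lru_cache(maxsize=8)
def _kernels(cfg: GaborJetConfig) -> tuple:
    ks = []
    for lam in cfg.wavelengths:
        for j in range(cfg.n_orientations):
            theta = np.pi * j / cfg.n_orientations
            k = gabor_kernel(frequency=1.0 / lam, theta=theta, bandwidth=cfg.bandwidth)
            k = k - k.mean()        # enforce zero DC response exactly
            ks.append(k)
    return tuple(ks)


def _grid_points(shape: tuple[int, int], cfg: GaborJetConfig) -> tuple[np.ndarray, np.ndarray]:
    H, W = shape
    rows = np.floor((np.arange(cfg.grid_rows) + 0.5) * H / cfg.grid_rows).astype(int)
    cols = np.floor((np.arange(cfg.grid_cols) + 0.5) * W / cfg.grid_cols).astype(int)
    return rows, cols


def gabor_jet_features(image: np.ndarray, cfg: GaborJetConfig = GaborJetConfig()) -> np.ndarray:
    """Gabor-jet feature vector of one grayscale image.

    The image is convolved with each complex filter and the response's
    magnitude and phase are sampled at the grid points.  Layout: for each
    grid point (row-major), for each filter (scales outer, orientations
    inner): magnitude then phase.  Default length 12*12*40*2 = 11520.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < max(cfg.grid_rows, cfg.grid_cols):
        raise ValueError(f"image must be 2-D and at least {cfg.grid_rows}x{cfg.grid_cols}")
    img = img - img.mean()      # DC removal: constant images respond exactly 0
    rows, cols = _grid_points(img.shape, cfg)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    n_pts = cfg.grid_rows * cfg.grid_cols
    out = np.empty((n_pts, cfg.n_filters, 2))
    for f, k in enumerate(_kernels(cfg)):
        resp = signal.fftconvolve(img, k, mode="same")
        sampled = resp[rr, cc].ravel()
        out[:, f, 0] = np.abs(sampled)
        out[:, f, 1] = np.angle(sampled)
    return out.reshape(-1)


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired t-test p-value across vector elements; a zero-variance
    zero-mean difference (identical vectors) is defined as p = 1."""
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return 1.0 if np.allclose(diff, 0) else 0.0
    t = diff.mean() / (sd / np.sqrt(len(diff)))
    return float(2 * stats.t.sf(abs(t), len(diff) - 1))


def gabor_video_difference(a, b, cfg: GaborJetConfig = GaborJetConfig()) -> float:
    """Mean over frames of the paired-t p-value between corresponding frames'
    Gabor-jet vectors.  Low values indicate a systematic image-level
    difference between the two videos."""
    fa = a.frames if hasattr(a, "frames") else np.asarray(a)
    fb = b.frames if hasattr(b, "frames") else np.asarray(b)
    if fa.shape[0] != fb.shape[0]:
        raise ValueError(f"frame counts differ: {fa.shape[0]} vs {fb.shape[0]}")
    ps = [_paired_p(gabor_jet_features(x, cfg), gabor_jet_features(y, cfg))
          for x, y in zip(fa, fb)]
    return float(np.mean(ps))
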