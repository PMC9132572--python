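"""Flux-based medial-axis skeleton extraction from 2-D shapes.

The medial axis of a shape is the locus of centers of maximal inscribed
disks.  It can be located robustly via the *average outward flux* of the
gradient of the Euclidean distance transform: away from the medial axis the
distance gradient is a unit vector field with zero divergence, so its mean
outward flux through a small circle is ~0, while medial points are sinks of
the field and carry strongly negative flux.  A homotopy-preserving thinning
that removes simple pixels in flux order (least medial first) and anchors
endpoints of strongly negative flux yields a thin, pruned skeleton that is
tolerant to local contour perturbations.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "BinaryShapeImage",
    "FluxMap",
    "SkeletonImage",
    "EmptyShapeError",
    "binarize",
    "distance_transform",
    "average_outward_flux",
    "extract_skeleton",
    "blur_skeleton",
]


class EmptyShapeError(ValueError):
    """Frame contains no foreground after thresholding."""


@dataclass
class BinaryShapeImage:
    """Single connected foreground region on a pixel grid (origin top-left)."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise EmptyShapeError("mask must be a nonempty 2-D binary image")


@dataclass
class FluxMap:
    """Average outward flux per foreground pixel; values in [-1, 1]."""

    values: np.ndarray
    foreground: np.ndarray


@dataclass
class SkeletonImage:
    mask: np.ndarray
    blur_sigma: float = 0.0
    degenerate: bool = False  # shape too thin to skeletonize; mask is the shape itself


def binarize(frame: np.ndarray, threshold: float = 0.1) -> BinaryShapeImage:
    """Threshold a grayscale frame and keep the largest connected component."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = np.asarray(frame, dtype=float) > threshold
    if not mask.any():
        raise EmptyShapeError("no foreground above threshold")
    lab = measure.label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return BinaryShapeImage(mask=lab == counts.argmax())


def distance_transform(shape: BinaryShapeImage) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel (pixels).

    The image border counts as background, so shapes touching the border
    still get a finite field.
    """
    padded = np.pad(shape.mask, 1)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


def average_outward_flux(distance_field: np.ndarray, neighborhood_radius: float = 1.5,
                         n_circle_samples: int = 8) -> FluxMap:
    """Mean outward flux of the distance gradient through a small circle.

    At each foreground pixel p the distance gradient (central differences,
    bilinearly interpolated) is sampled at ``n_circle_samples`` points on the
    circle of ``neighborhood_radius`` around p and dotted with the outward
    unit normal.  Medial pixels are sinks of the gradient field and carry
    strongly negative flux; generic interior pixels have flux near 0.
    """
    D = np.asarray(distance_field, dtype=float)
    fg = D > 0
    gy, gx = np.gradient(D)
    rows, cols = np.nonzero(fg)
    flux = np.zeros(len(rows))
    thetas = 2 * np.pi * np.arange(n_circle_samples) / n_circle_samples
    for th in thetas:
        ny, nx = np.sin(th), np.cos(th)
        qy = rows + neighborhood_radius * ny
        qx = cols + neighborhood_radius * nx
        coords = np.vstack([qy, qx])
        gys = ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
        gxs = ndimage.map_coordinates(gx, coords, order=1, mode="nearest")
        flux += gys * ny + gxs * nx
    flux /= n_circle_samples
    values = np.zeros_like(D)
    values[rows, cols] = np.clip(flux, -1.0, 1.0)
    return FluxMap(values=values, foreground=fg)


# ---------------------------------------------------------------------------
# Simple-point lookup table (8-connected foreground / 4-connected background).
# Neighbor bit order: (dy,dx) in row-major order around the center:
#   0 1 2
#   3 . 4
#   5 6 7

_NB_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _build_simple_lut() -> np.ndarray:
    """simple[mask] is True iff removing the center keeps one 8-connected
    foreground component among the neighbors and exactly one 4-connected
    background component touching the center."""
    pos = {off: i for i, off in enumerate(_NB_OFFSETS)}
    lut = np.zeros(256, dtype=bool)
    coords = _NB_OFFSETS
    for m in range(256):
        fg = [coords[i] for i in range(8) if m >> i & 1]
        bg = [coords[i] for i in range(8) if not (m >> i & 1)]
        if not fg:
            continue
        # 8-connectivity components of foreground neighbors
        parent = {c: c for c in fg}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for a in fg:
            for b in fg:
                if a < b and max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1:
                    parent[find(a)] = find(b)
        n_fg = len({find(c) for c in fg})
        # 4-connectivity components of background neighbors that are 4-adjacent
        # to the center (the edge-neighbors), linked through any bg neighbor
        bgset = set(bg)
        parent2 = {c: c for c in bg}

        def find2(c):
            while parent2[c] != c:
                parent2[c] = parent2[parent2[c]]
                c = parent2[c]
            return c

        for a in bg:
            for b in bg:
                if a < b and abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1:
                    parent2[find2(a)] = find2(b)
        edge_bg = [c for c in bg if abs(c[0]) + abs(c[1]) == 1]
        n_bg = len({find2(c) for c in edge_bg})
        lut[m] = n_fg == 1 and n_bg == 1
    return lut


_SIMPLE_LUT = _build_simple_lut()


def _neighbor_mask(mask: np.ndarray, y: int, x: int) -> int:
    m = 0
    H, W = mask.shape
    for i, (dy, dx) in enumerate(_NB_OFFSETS):
        yy, xx = y + dy, x + dx
        if 0 <= yy < H and 0 <= xx < W and mask[yy, xx]:
            m |= 1 << i
    return m


def _is_simple(mask: np.ndarray, y: int, x: int) -> bool:
    return bool(_SIMPLE_LUT[_neighbor_mask(mask, y, x)])


def _n_neighbors(mask: np.ndarray, y: int, x: int) -> int:
    return bin(_neighbor_mask(mask, y, x)).count("1")


def _prune_short_branches(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Delete terminal branches shorter than ``min_len`` pixels (walking from
    each endpoint to the first junction).  Tree branches, so homotopy-safe."""
    mask = mask.copy()
    changed = True
    while changed:
        changed = False
        ys, xs = np.nonzero(mask)
        endpoints = [(y, x) for y, x in zip(ys, xs) if _n_neighbors(mask, y, x) <= 1]
        for y0, x0 in endpoints:
            if not mask[y0, x0]:
                continue
            branch = [(y0, x0)]
            prev = None
            cur = (y0, x0)
            while len(branch) < min_len:
                nbs = [(cur[0] + dy, cur[1] + dx) for dy, dx in _NB_OFFSETS
                       if 0 <= cur[0] + dy < mask.shape[0] and 0 <= cur[1] + dx < mask.shape[1]
                       and mask[cur[0] + dy, cur[1] + dx] and (cur[0] + dy, cur[1] + dx) != prev]
                if len(nbs) != 1:
                    break                      # junction or isolated: branch ends
                prev, cur = cur, nbs[0]
                if _n_neighbors(mask, *cur) > 2:
                    break                      # reached a junction pixel
                branch.append(cur)
            else:
                continue                       # branch at least min_len: keep
            if len(branch) < min_len and len(branch) < mask.sum():
                for y, x in branch:
                    mask[y, x] = False
                changed = True
    return mask


def extract_skeleton(shape: BinaryShapeImage, flux_threshold: float = -0.4,
                     min_branch_length: int = 5,
                     neighborhood_radius: float = 1.5) -> SkeletonImage:
    """Homotopy-preserving thinning ordered by average outward flux.

    Simple (removable) pixels are deleted starting from the least medial
    (highest flux).  A curve endpoint whose flux is below ``flux_threshold``
    is anchored as a skeleton endpoint; branches shorter than
    ``min_branch_length`` are pruned afterwards.  The result is a thin subset
    of the foreground with the same homotopy type as the input shape.
    """
    mask = shape.mask.copy()
    D = distance_transform(shape)
    if D.max() < 1.5:
        warnings.warn("shape thinner than 2 px everywhere; returning it unchanged")
        return SkeletonImage(mask=mask, degenerate=True)
    flux = average_outward_flux(D, neighborhood_radius).values

    heap: list = []
    in_heap = np.zeros_like(mask)
    ys, xs = np.nonzero(mask & ~ndimage.binary_erosion(mask))
    for y, x in zip(ys, xs):
        heapq.heappush(heap, (-flux[y, x], y, x))   # max flux popped first
        in_heap[y, x] = True
    anchored = np.zeros_like(mask)
    while heap:
        _, y, x = heapq.heappop(heap)
        in_heap[y, x] = False
        if not mask[y, x] or anchored[y, x]:
            continue
        if not _is_simple(mask, y, x):
            continue
        if _n_neighbors(mask, y, x) <= 1 and flux[y, x] <= flux_threshold:
            anchored[y, x] = True               # medial endpoint: keep
            continue
        mask[y, x] = False                      # remove; neighbors become candidates
        for dy, dx in _NB_OFFSETS:
            yy, xx = y + dy, x + dx
            if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                    and mask[yy, xx] and not in_heap[yy, xx] and not anchored[yy, xx]):
                heapq.heappush(heap, (-flux[yy, xx], yy, xx))
                in_heap[yy, xx] = True
    if min_branch_length > 1:
        mask = _prune_short_branches(mask, min_branch_length)
    return SkeletonImage(mask=mask)


def blur_skeleton(skel: SkeletonImage, sigma: float = 3.0) -> np.ndarray:
    """Gaussian-blur the binary skeleton, renormalized to max 1.

    sigma = 0 returns the mask as floats.  The blur gives the decoder a
    spatially extended reconstruction target instead of a 1-px curve.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = skel.mask.astype(float)
    if sigma == 0:
        return img
    out = ndimage.gaussian_filter(img, sigma)
    m = out.max()
    return out / m if m > 0 else out
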