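"""Feature backbones feeding the habituation autoencoder.

A backbone maps each video frame (or adjacent frame pair, for optic flow) to
a fixed-shape feature grid.  Backbones themselves are frozen functions of
the input; only the adapter/decoder layers of the autoencoder train during
habituation.

Registry names: "pixel" (identity), "skeleton" (binarize -> flux skeleton ->
Gaussian blur), "flow" (classical variational optic flow on adjacent frame
pairs), "conv" (a small fixed random convolutional feature extractor, the
mount point for external pretrained feature producers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from . import skeleton as sk
from ._nn import Conv2D, DualPool2, GlobalDualPool, ReLU, Sequential

__all__ = [
    "FlowField",
    "Backbone",
    "pixel_backbone",
    "skeleton_backbone",
    "flow_backbone",
    "ConvFeaturesExtractor",
    "make_backbone",
    "BACKBONE_NAMES",
]


# ---------------------------------------------------------------------------
# Frame-level operations


def pixel_backbone(frame: np.ndarray) -> np.ndarray:
    """Identity: classification rests on raw image structure alone."""
    return np.asarray(frame, dtype=float)


def skeleton_backbone(frame: np.ndarray, threshold: float = 0.1,
                      flux_threshold: float = -0.4, min_branch_length: int = 5,
                      blur_sigma: float = 3.0) -> np.ndarray:
    """Binarize the frame, extract the pruned flux skeleton, blur it.

    The blurred skeleton image is the feature grid the decoder reconstructs
    the frame from.
    """
    shape = sk.binarize(frame, threshold)
    skel = sk.extract_skeleton(shape, flux_threshold=flux_threshold,
                               min_branch_length=min_branch_length)
    return sk.blur_skeleton(skel, blur_sigma)


@dataclass
class FlowField:
    """Per-pixel displacement between two frames (pixels/frame)."""

    u: np.ndarray  # horizontal (x) displacement
    v: np.ndarray  # vertical (y) displacement

    def as_image(self) -> np.ndarray:
        """Single-channel rendering: signed horizontal flow dominates the
        rotation stimuli; mapped to [0,1] with 0 flow at 0.5."""
        mag = np.hypot(self.u, self.v)
        m = mag.max()
        return 0.5 + 0.5 * (self.u / m if m > 0 else self.u)


def flow_backbone(frame_a: np.ndarray, frame_b: np.ndarray,
                  smoothness_weight: float = 0.001, n_iterations: int = 100,
                  n_warps: int = 5) -> FlowField:
    """Classical variational optic flow (brightness constancy + smoothness).

    Horn–Schunck fixed-point iteration at a single resolution, with a few
    warping refinements so integer-pixel displacements of ~2 px are
    recovered despite the linearized brightness-constancy term.
    Deterministic.
    """
    a = ndimage.gaussian_filter(np.asarray(frame_a, dtype=float), 1.0)
    b = ndimage.gaussian_filter(np.asarray(frame_b, dtype=float), 1.0)
    if a.shape != b.shape:
        raise ValueError("frames must share dimensions")
    H, W = a.shape
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    avg_k = np.array([[1, 2, 1], [2, 0, 2], [1, 2, 1]], dtype=float) / 12.0
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    alpha2 = smoothness_weight
    for _ in range(n_warps):
        bw = ndimage.map_coordinates(b, [yy + v, xx + u], order=1, mode="nearest")
        Ix = ndimage.sobel(0.5 * (a + bw), axis=1, mode="nearest") / 8.0
        Iy = ndimage.sobel(0.5 * (a + bw), axis=0, mode="nearest") / 8.0
        It = bw - a
        du = np.zeros_like(u)
        dv = np.zeros_like(v)
        denom = alpha2 + Ix ** 2 + Iy ** 2
        for _ in range(n_iterations):
            du_bar = ndimage.convolve(du, avg_k, mode="nearest")
            dv_bar = ndimage.convolve(dv, avg_k, mode="nearest")
            common = (Ix * du_bar + Iy * dv_bar + It) / denom
            du = du_bar - Ix * common
            dv = dv_bar - Iy * common
        u = u + du
        v = v + dv
    return FlowField(u=u, v=v)


class ConvFeaturesExtractor:
    """One fixed random convolution + ReLU + max/avg pooling.

    ``pool="global"`` (default) collapses to a feature vector, matching the
    global average-pooled outputs of pretrained recognition networks; integer
    pools keep a spatial grid.  Stands in for external pretrained feature
    producers behind the same interface (any callable frame -> (C, H', W')
    grid plugs into the engine).
    """

    def __init__(self, n_channels: int = 16, kernel_size: int = 3,
                 pool="global", seed: int = 0, in_channels: int = 1):
        if pool not in (1, 2, "global"):
            raise ValueError("pool must be 1, 2 or 'global'")
        rng = np.random.default_rng(seed)
        layers = [Conv2D(in_channels, n_channels, kernel_size, rng), ReLU()]
        if pool == 2:
            layers.append(DualPool2())
        elif pool == "global":
            layers.append(GlobalDualPool())
        self.net = Sequential(*layers)
        self.pool = pool
        self.out_channels = n_channels * (2 if pool in (2, "global") else 1)

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        x = np.asarray(frame, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return self.net.forward(x[None])[0]


# ---------------------------------------------------------------------------
# Backbone objects consumed by the habituation engine


@dataclass
class Backbone:
    """Named frozen feature producer over a whole video.

    ``features(frames)`` returns (n_items, C, H', W') representation images
    (one per frame, or per adjacent-frame pair for flow).  ``targets(frames)``
    is what the autoencoder's decoder must reconstruct: the backbone's own
    representation image for pixel/skeleton/flow (the autoencoder recreates
    the stimulus as the model represents it, through the lower-dimensional
    pooled features), and the raw frame for conv-feature backbones, whose
    decoder inverts the feature maps back to the image.
    """

    name: str
    per_frame: Optional[Callable] = None
    per_pair: Optional[Callable] = None
    n_channels: int = 1
    frozen: bool = True
    reconstructs: str = "representation"      # or "frame"
    params: dict = field(default_factory=dict)

    def features(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=float)
        if self.per_pair is not None:
            out = [self.per_pair(frames[i], frames[i + 1])
                   for i in range(len(frames) - 1)]
        else:
            out = [self.per_frame(f) for f in frames]
        out = np.stack([o if o.ndim == 3 else o[None] for o in out])
        return out

    def targets(self, frames: np.ndarray) -> np.ndarray:
        frames = np.asarray(frames, dtype=float)
        if self.reconstructs == "representation":
            feats = self.features(frames)
            if feats.shape[1] == 1:
                return feats
            # multi-channel representation: reconstruct its channel mean image
            return feats.mean(axis=1, keepdims=True)
        if self.per_pair is not None:
            return frames[1:][:, None]
        return frames[:, None]


BACKBONE_NAMES = ("pixel", "skeleton", "flow", "conv")


def make_backbone(name: str, **params) -> Backbone:
    """Construct a registered backbone; extra kwargs configure it."""
    if name == "pixel":
        return Backbone(name="pixel", per_frame=pixel_backbone, n_channels=1)
    if name == "skeleton":
        return Backbone(name="skeleton",
                        per_frame=lambda f: skeleton_backbone(f, **params),
                        n_channels=1, params=params)
    if name == "flow":
        def pair(a, b):
            return flow_backbone(a, b, **params).as_image()
        return Backbone(name="flow", per_pair=pair, n_channels=1, params=params)
    if name == "conv":
        ext = ConvFeaturesExtractor(**params)
        return Backbone(name="conv", per_frame=ext, n_channels=ext.out_channels,
                        reconstructs="frame", params=params)
    raise KeyError(f"unknown backbone {name!r}; known: {BACKBONE_NAMES}")
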