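"""Autoencoder habituation/dishabituation engine.

Any backbone is converted into an autoencoder by passing its feature grid
through a trainable convolutional adapter (one conv + ReLU + concatenated
max/avg pooling) and a single transposed-convolution decoding layer that
reconstructs the input frame.  "Habituation" is training on one video with
Adam under a mean-squared-error loss until the infant stopping rule is met:
the mean error over the last four epochs falls below 50% of the mean over
the first four.  Test-phase reconstruction error on other videos, normalized
to the end of habituation, is the computational analog of looking time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._nn import (Adam, Conv2D, FullFrameDeconv, GlobalDualPool, ReLU,
                  Sequential, mse_loss)
from .backbones import Backbone, make_backbone

__all__ = [
    "InsufficientDataError",
    "DivergenceError",
    "HabituationTrace",
    "AutoencoderState",
    "DissimilarityMatrix",
    "habituation_met",
    "first_habituation_epoch",
    "habituate",
    "test_error",
    "dissimilarity_matrix",
]


class InsufficientDataError(ValueError):
    """Fewer observations than the criterion's two four-trial windows."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def habituation_met(errors: Sequence[float]) -> bool:
    """The habituation stopping rule shared by models and infants.

    True iff the mean of the last four values is strictly below 50% of the
    mean of the first four.  Requires at least 8 values.
    """
    e = np.asarray(list(errors), dtype=float)
    if len(e) < 8:
        raise InsufficientDataError(f"need >= 8 values, got {len(e)}")
    return bool(e[-4:].mean() < 0.5 * e[:4].mean())


def first_habituation_epoch(errors: Sequence[float]) -> Optional[int]:
    """1-based index of the first epoch at which the criterion holds
    (sliding last-four window over a fixed first-four window), or None."""
    e = list(errors)
    for k in range(8, len(e) + 1):
        if habituation_met(e[:k]):
            return k
    return None


@dataclass
class HabituationTrace:
    """Per-epoch mean reconstruction error with criterion metadata."""

    per_epoch_error: list
    criterion_met_at: Optional[int]
    cap: int

    @property
    def end_level(self) -> float:
        """Mean error over the last four habituation epochs (the
        normalization reference for test-phase responses)."""
        return float(np.mean(self.per_epoch_error[-4:]))


class AutoencoderState:
    """A backbone plus trainable adapter/decoder layers and optimizer state.

    Backbones producing frame-resolution representation images ("pixel",
    "skeleton", "flow") pass through a trainable feature-extraction layer
    (conv k3 -> ReLU -> concatenated global max/avg pooling), yielding a
    low-dimensional code vector that matches the global-pooled outputs of
    pretrained recognition networks; vector-producing backbones ("conv" with
    global pooling, external feature producers) skip the adapter.  The
    decoder is a single transposed convolution whose kernel spans the whole
    frame, mapping the code back to a frame-sized reconstruction.

    The network is built lazily at the first forward pass (the frame size
    fixes the decoder's kernel).
    """

    def __init__(self, backbone: Backbone, adapter_channels: int = 16,
                 learning_rate: float = 1e-2, batch_size: int = 4, seed: int = 0):
        self.backbone = backbone
        self.seed = seed
        self.batch_size = batch_size
        self.adapter_channels = adapter_channels
        self.learning_rate = learning_rate
        self.uses_adapter = backbone.per_pair is not None or backbone.name in ("pixel", "skeleton")
        self.net: Optional[Sequential] = None
        self.optimizer: Optional[Adam] = None
        self.habituated = False
        self.trace: Optional[HabituationTrace] = None
        self._train_shape: Optional[tuple] = None

    def _build(self, feat_shape: tuple, out_hw: tuple):
        rng = np.random.default_rng(self.seed)
        if self.uses_adapter:
            self.net = Sequential(
                Conv2D(self.backbone.n_channels, self.adapter_channels, 3, rng),
                ReLU(),
                GlobalDualPool(),
                FullFrameDeconv(2 * self.adapter_channels, out_hw, rng),
            )
        else:
            c = int(np.prod(feat_shape[:-2])) if len(feat_shape) > 2 else feat_shape[0]
            self.net = Sequential(FullFrameDeconv(c, out_hw, rng))
        self.optimizer = Adam(self.net.params, self.net.grads, lr=self.learning_rate)

    def reconstruct(self, features: np.ndarray) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("network not built yet; run habituate() first")
        x = features
        if not self.uses_adapter and x.ndim == 4 and x.shape[-1] != 1:
            x = x.reshape(x.shape[0], -1, 1, 1)   # vector code from any grid
        return self.net.forward(x)


def precompute_features(backbone: Backbone, video) -> tuple[np.ndarray, np.ndarray]:
    """Feature grids and reconstruction targets for one video.

    Backbones are frozen, so features can be computed once per video and
    shared across autoencoder states (habituation rows).
    """
    frames = video.frames if hasattr(video, "frames") else np.asarray(video)
    feats = backbone.features(frames)
    if backbone.reconstructs == "representation":
        targets = feats if feats.shape[1] == 1 else feats.mean(axis=1, keepdims=True)
    else:
        targets = backbone.targets(frames)
    return feats, targets


def habituate(state: AutoencoderState, video, cap: int = 100,
              precomputed: Optional[tuple] = None) -> HabituationTrace:
    """Train the autoencoder on one video until the criterion or the cap.

    One epoch is a full pass over the video's frames in fixed batches; the
    recorded epoch error is the mean reconstruction error evaluated after
    that epoch's updates, so the end-of-habituation level matches what a
    frozen-weights test on the same video returns.  Stops at the first epoch
    (>= 8) where ``habituation_met`` holds.  Reproducible given the state's
    seed.
    """
    if cap < 8:
        raise ValueError("cap must be >= 8 (criterion needs two 4-epoch windows)")
    feats, targets = precomputed if precomputed is not None else \
        precompute_features(state.backbone, video)
    state._train_shape = feats.shape[1:]
    if not state.uses_adapter and feats.ndim == 4 and feats.shape[-1] != 1:
        feats = feats.reshape(feats.shape[0], -1, 1, 1)
    if state.net is None:
        state._build(feats.shape[1:], targets.shape[-2:])
    n = feats.shape[0]
    bs = state.batch_size
    errors: list[float] = []
    met_at = None
    for epoch in range(1, cap + 1):
        for i in range(0, n, bs):
            xb, yb = feats[i:i + bs], targets[i:i + bs]
            pred = state.net.forward(xb)
            loss, dpred = mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, lr={state.optimizer.lr}")
            state.net.backward(dpred)
            state.optimizer.step()
        # post-update evaluation: the epoch's recorded error signal
        total, count = 0.0, 0
        for i in range(0, n, bs):
            pred = state.net.forward(feats[i:i + bs])
            total += float(((pred - targets[i:i + bs]) ** 2).sum())
            count += pred.size
        errors.append(total / count)
        if epoch >= 8 and habituation_met(errors):
            met_at = epoch
            break
    state.habituated = True
    state.trace = HabituationTrace(per_epoch_error=errors, criterion_met_at=met_at, cap=cap)
    return state.trace


def test_error(state: AutoencoderState, video, precomputed: Optional[tuple] = None) -> float:
    """Frozen-weights mean squared reconstruction error on a test video."""
    if not state.habituated:
        raise RuntimeError("habituate() must run before test_error()")
    feats, targets = precomputed if precomputed is not None else \
        precompute_features(state.backbone, video)
    if feats.shape[1:] != state._train_shape:
        raise ValueError(
            f"test feature shape {feats.shape[1:]} != training shape {state._train_shape}")
    if not state.uses_adapter and feats.ndim == 4 and feats.shape[-1] != 1:
        feats = feats.reshape(feats.shape[0], -1, 1, 1)
    total, count = 0.0, 0
    bs = state.batch_size
    for i in range(0, feats.shape[0], bs):
        pred = state.net.forward(feats[i:i + bs])
        total += float(((pred - targets[i:i + bs]) ** 2).sum())
        count += pred.size
    return total / count


@dataclass
class DissimilarityMatrix:
    """Rows: habituation object; columns: test object; values: test error
    minus end-of-habituation error.  Asymmetric by construction."""

    values: np.ndarray
    labels: list
    backbone: str
    traces: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        names = [str(l) for l in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)


def dissimilarity_matrix(backbone_config: dict, catalog, cap: int = 100,
                         seed: int = 0, engine_params: Optional[dict] = None) -> DissimilarityMatrix:
    """Habituate a fresh autoencoder on every catalog video and score all
    videos (including the habituated one) with frozen weights.

    ``backbone_config`` is ``{"name": ..., **backbone_params}``.  Each entry
    is the test error normalized by subtracting the habituation end level, so
    diagonal entries sit near 0.
    """
    keys = catalog.keys()
    if len(keys) < 2:
        raise ValueError("need at least 2 videos")
    cfg = dict(backbone_config)
    name = cfg.pop("name")
    engine_params = engine_params or {}
    n = len(keys)
    values = np.zeros((n, n))
    traces = []
    backbone = make_backbone(name, **cfg)
    cache = {k: precompute_features(backbone, catalog.videos[k]) for k in keys}
    for i, ki in enumerate(keys):
        state = AutoencoderState(backbone, seed=seed + i, **engine_params)
        try:
            trace = habituate(state, catalog.videos[ki], cap=cap, precomputed=cache[ki])
        except (DivergenceError, ValueError) as err:
            raise RuntimeError(f"habituation failed for row {ki}: {err}") from err
        traces.append(trace)
        for j, kj in enumerate(keys):
            try:
                values[i, j] = test_error(state, catalog.videos[kj],
                                          precomputed=cache[kj]) - trace.end_level
            except ValueError as err:
                raise RuntimeError(f"test failed for row {ki}, column {kj}: {err}") from err
    return DissimilarityMatrix(values=values, labels=keys, backbone=name, traces=traces)
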