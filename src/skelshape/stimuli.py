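"""Synthetic skeleton-defined objects and rotation videos.

Objects are defined by a small tree of axial segments (the shape skeleton)
inflated with a "surface form": a radius profile realizing the four
non-accidental properties (taper, positive curvature / bulge, negative
curvature / concavity, convergence to a vertex).  Each object is rendered
as a grayscale video of the object rigidly rotating back-and-forth about
the vertical axis under orthographic projection, as a union of filled
disks (one per surface sample) whose intensity encodes local thickness.

Crossing ``n_skeletons`` skeletal structures with ``n_forms`` surface forms
yields a factorial stimulus catalog: videos sharing a skeleton differ only
in surface form, which is the property every downstream analysis consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v2 as imageio
import numpy as np

__all__ = [
    "Segment",
    "SkeletonSpec",
    "SurfaceFormSpec",
    "RenderConfig",
    "FrameStack",
    "StimulusCatalog",
    "StructuralValidationError",
    "ParameterError",
    "RenderingError",
    "build_skeleton_points",
    "inflate",
    "render_rotation_video",
    "perturb_skeleton",
    "generate_stimulus_set",
    "default_render_config",
    "save_frame_stack",
    "load_frame_stack",
]


class StructuralValidationError(ValueError):
    """Skeleton tree is cyclic, disconnected, or otherwise malformed."""


class ParameterError(ValueError):
    """A numeric parameter is outside its valid range."""


class RenderingError(RuntimeError):
    """Object does not fit in the frame; message carries margin diagnostics."""


@dataclass(frozen=True)
class Segment:
    """One axial segment of a skeletal tree.

    ``parent`` is the index of the parent segment (``None`` for the root),
    ``attach_t`` the fractional position along the parent's axis where this
    segment attaches, ``direction`` a 3-vector (normalized on construction)
    and ``length`` the segment length in object units.
    """

    parent: Optional[int]
    attach_t: float
    direction: tuple[float, float, float]
    length: float

    def __post_init__(self):
        if self.length <= 0:
            raise StructuralValidationError(f"segment length must be > 0, got {self.length}")
        d = np.asarray(self.direction, dtype=float)
        nrm = float(np.linalg.norm(d))
        if nrm == 0 or not np.isfinite(nrm):
            raise StructuralValidationError("segment direction must be a nonzero finite vector")
        if abs(nrm - 1.0) > 1e-9:       # normalize once; keep already-unit vectors bitwise
            d = d / nrm
        object.__setattr__(self, "direction", tuple(d.tolist()))
        if self.parent is not None and not 0.0 <= self.attach_t <= 1.0:
            raise StructuralValidationError(f"attach_t must lie in [0,1], got {self.attach_t}")


@dataclass(frozen=True)
class SkeletonSpec:
    """Parametric tree of axial segments defining an object's skeleton."""

    segments: tuple[Segment, ...]

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        segs = self.segments
        roots = [i for i, s in enumerate(segs) if s.parent is None]
        if len(roots) != 1:
            raise StructuralValidationError(f"expected exactly one root segment, found {len(roots)}")
        # Walk each segment to the root; a repeat or out-of-range parent is a cycle/corruption.
        for i, s in enumerate(segs):
            seen = {i}
            j = s.parent
            while j is not None:
                if j < 0 or j >= len(segs) or j in seen:
                    raise StructuralValidationError(f"segment {i} has a cyclic or invalid parent chain")
                seen.add(j)
                j = segs[j].parent

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def children_of(self, index: int) -> list[int]:
        return [i for i, s in enumerate(self.segments) if s.parent == index]

    def segment_start(self, index: int) -> np.ndarray:
        """3-D start point of a segment (root starts at the origin)."""
        s = self.segments[index]
        if s.parent is None:
            return np.zeros(3)
        p = self.segments[s.parent]
        return self.segment_start(s.parent) + np.asarray(p.direction) * p.length * s.attach_t

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"parent": s.parent, "attach_t": s.attach_t,
                 "direction": list(s.direction), "length": s.length}
                for s in self.segments
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonSpec":
        return cls(tuple(
            Segment(parent=e["parent"], attach_t=e["attach_t"],
                    direction=tuple(e["direction"]), length=e["length"])
            for e in d["segments"]
        ))


@dataclass(frozen=True)
class SurfaceFormSpec:
    """Radius profile along each segment, realizing the non-accidental properties.

    r(t) = base_radius * (1 - taper * t) + (bulge - concavity) * sin(pi t),
    clipped below at ``min_radius``; ``end_vertex`` forces r(1) = 0 on terminal
    segments (the part converges to a point).
    """

    base_radius: float
    taper: float = 0.0
    bulge: float = 0.0
    concavity: float = 0.0
    end_vertex: bool = False
    min_radius: float = 1e-3

    def __post_init__(self):
        if self.base_radius <= 0:
            raise ParameterError("base_radius must be > 0")
        if not 0.0 <= self.taper <= 1.0:
            raise ParameterError("taper must lie in [0,1]")
        if self.bulge < 0 or self.concavity < 0:
            raise ParameterError("bulge and concavity must be >= 0")

    def radius(self, t: np.ndarray, terminal: bool) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = self.base_radius * (1.0 - self.taper * t) + (self.bulge - self.concavity) * np.sin(np.pi * t)
        interior = (t > 0) & (t < 1)
        if np.any(r[interior] <= 0):
            raise ParameterError("radius profile nonpositive on segment interior")
        r = np.clip(r, self.min_radius, None)
        if terminal and self.end_vertex:
            r = np.where(t >= 1.0, 0.0, r)
        return r

    def to_dict(self) -> dict:
        return {"base_radius": self.base_radius, "taper": self.taper, "bulge": self.bulge,
                "concavity": self.concavity, "end_vertex": self.end_vertex,
                "min_radius": self.min_radius}

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceFormSpec":
        return cls(**d)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry for one rotation video.

    The rotation is palindromic: the object sweeps from -amplitude/2 to
    +amplitude/2 and back, so frame ``i`` shows the same pose as frame
    ``n_frames - 1 - i``.  ``n_frames`` must equal duration x fps with
    duration = 2 * amplitude / speed (one full back-and-forth).
    """

    image_size: int = 256
    n_frames: int = 300
    rotation_amplitude: float = 60.0
    angular_speed: float = 12.0
    fps: float = 30.0
    axis: str = "y"
    scale: Optional[float] = None      # pixels per object unit; None = auto-fit
    fill_fraction: float = 0.6         # auto-fit: object height as fraction of frame
    silhouette: bool = False           # flat intensity 1 instead of thickness shading
    samples_per_segment: int = 40
    min_disk_radius_px: float = 1.5    # keeps the disk union connected

    def __post_init__(self):
        if self.axis not in ("y", "x"):
            raise ParameterError("axis must be 'y' or 'x'")
        if self.n_frames < 1 or self.image_size < 8:
            raise ParameterError("n_frames >= 1 and image_size >= 8 required")
        if self.rotation_amplitude > 0:
            duration = 2.0 * self.rotation_amplitude / self.angular_speed
            expected = duration * self.fps
            if abs(self.n_frames - expected) > 0.5:
                raise ParameterError(
                    f"n_frames ({self.n_frames}) must equal duration*fps "
                    f"({expected:.1f}) for one back-and-forth sweep")

    def angles(self) -> np.ndarray:
        """Palindromic angle schedule in degrees, angle[i] == angle[n-1-i]."""
        n, a = self.n_frames, self.rotation_amplitude
        if n == 1 or a == 0:
            return np.zeros(n)
        u = np.arange(n) / (n - 1)
        return -a / 2.0 + a * (1.0 - np.abs(2.0 * u - 1.0))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "image_size", "n_frames", "rotation_amplitude", "angular_speed", "fps",
            "axis", "scale", "fill_fraction", "silhouette", "samples_per_segment",
            "min_disk_radius_px")}

    @classmethod
    def from_dict(cls, d: dict) -> "RenderConfig":
        return cls(**d)


def default_render_config(image_size: int = 64, n_frames: int = 60) -> RenderConfig:
    """Desk-scale rendering defaults: 60-degree sweep at 12 deg/s, fps chosen
    so n_frames covers exactly one back-and-forth cycle."""
    duration = 2 * 60.0 / 12.0
    return RenderConfig(image_size=image_size, n_frames=n_frames,
                        rotation_amplitude=60.0, angular_speed=12.0,
                        fps=n_frames / duration)


@dataclass
class FrameStack:
    """Ordered grayscale frame sequence for one rotating-object video."""

    frames: np.ndarray                 # (n, H, W) float in [0, 1]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ParameterError("frames must be a nonempty (n, H, W) array")
        if f.min() < -1e-9 or f.max() > 1 + 1e-9:
            raise ParameterError("frame intensities must lie in [0, 1]")
        self.frames = np.clip(f, 0.0, 1.0)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# Geometry


def build_skeleton_points(spec: SkeletonSpec, samples_per_segment: int = 40):
    """Sample points uniformly along every segment axis.

    Returns ``(points, labels, ts)``: an (N, 3) array of 3-D points, the
    segment index of each point, and its fractional position t along its
    segment.  N = n_segments * samples_per_segment.
    """
    if samples_per_segment < 2:
        raise ParameterError("samples_per_segment must be >= 2")
    pts, labels, ts = [], [], []
    t = np.linspace(0.0, 1.0, samples_per_segment)
    for i, seg in enumerate(spec.segments):
        start = spec.segment_start(i)
        d = np.asarray(seg.direction)
        pts.append(start[None, :] + t[:, None] * (d * seg.length)[None, :])
        labels.append(np.full(samples_per_segment, i))
        ts.append(t)
    return np.concatenate(pts), np.concatenate(labels), np.concatenate(ts)


@dataclass
class InflatedObject:
    """Surface point cloud: axial samples with a per-point radius."""

    points: np.ndarray   # (N, 3)
    radii: np.ndarray    # (N,)
    labels: np.ndarray   # (N,) segment index


def inflate(spec: SkeletonSpec, form: SurfaceFormSpec,
            samples_per_segment: int = 40) -> InflatedObject:
    """Attach the surface-form radius profile to skeleton axis samples."""
    points, labels, ts = build_skeleton_points(spec, samples_per_segment)
    terminal = {i for i in range(spec.n_segments) if not spec.children_of(i)}
    radii = np.empty(len(points))
    for i in range(spec.n_segments):
        m = labels == i
        radii[m] = form.radius(ts[m], terminal=i in terminal)
    return InflatedObject(points=points, radii=radii, labels=labels)


def _rotation_matrix(angle_deg: float, axis: str) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "y":      # vertical image axis: x-z plane rotates
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _auto_scale(obj: InflatedObject, cfg: RenderConfig) -> float:
    """Pixels per object unit such that the rotated object spans
    ``fill_fraction`` of the frame height (and fits horizontally)."""
    p, r = obj.points, obj.radii
    if cfg.axis == "y":
        h_extent = (p[:, 1] + r).max() - (p[:, 1] - r).min()
        radial = np.hypot(p[:, 0], p[:, 2]) + r
    else:
        h_extent = 2 * (np.hypot(p[:, 1], p[:, 2]) + r).max()
        radial = np.abs(p[:, 0]) + r
    w_extent = 2 * radial.max()
    s_h = cfg.fill_fraction * cfg.image_size / max(h_extent, 1e-9)
    s_w = 0.94 * cfg.image_size / max(w_extent, 1e-9)
    return min(s_h, s_w)


def _rasterize_disks(centers_px: np.ndarray, radii_px: np.ndarray,
                     intensities: np.ndarray, size: int) -> np.ndarray:
    """Union (max) of filled disks on a black background."""
    img = np.zeros((size, size))
    for (cx, cy), r, v in zip(centers_px, radii_px, intensities):
        if r <= 0:
            continue
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        if x1 <= 0 or y1 <= 0 or x0 >= size or y0 >= size:
            raise RenderingError(
                f"disk at ({cx:.1f},{cy:.1f}) r={r:.1f}px entirely outside {size}x{size} frame")
        x0c, x1c, y0c, y1c = max(x0, 0), min(x1, size), max(y0, 0), min(y1, size)
        if (x0 < 0 or y0 < 0 or x1 > size or y1 > size):
            raise RenderingError(
                f"object projects outside the frame: disk at ({cx:.1f},{cy:.1f}) "
                f"r={r:.1f}px, margins L={x0} R={size - x1} T={y0} B={size - y1}")
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        sub = img[y0c:y1c, x0c:x1c]
        np.maximum(sub, np.where(inside, v, 0.0), out=sub)
    return img


def render_rotation_video(spec: SkeletonSpec, form: SurfaceFormSpec,
                          cfg: RenderConfig) -> FrameStack:
    """Render one object as a back-and-forth rotation video.

    Each frame rigidly rotates the inflated object to the palindromic angle
    schedule, projects orthographically along z, and rasterizes the union of
    per-sample disks.  Intensity encodes local thickness (larger radius ->
    brighter) unless ``cfg.silhouette`` is set.  Deterministic.
    """
    obj = inflate(spec, form, cfg.samples_per_segment)
    pts = obj.points - obj.points.mean(axis=0)   # rotate about the centroid
    scale = cfg.scale if cfg.scale is not None else _auto_scale(
        InflatedObject(pts, obj.radii, obj.labels), cfg)
    r_px = np.maximum(obj.radii * scale, np.where(obj.radii > 0, cfg.min_disk_radius_px, 0.0))
    rmax = max(obj.radii.max(), 1e-9)
    if cfg.silhouette:
        intens = np.ones(len(pts))
    else:
        intens = 0.25 + 0.75 * (obj.radii / rmax)
    c = (cfg.image_size - 1) / 2.0
    frames = np.empty((cfg.n_frames, cfg.image_size, cfg.image_size))
    for k, ang in enumerate(cfg.angles()):
        q = pts @ _rotation_matrix(ang, cfg.axis).T
        centers = np.column_stack([c + scale * q[:, 0], c - scale * q[:, 1]])
        frames[k] = _rasterize_disks(centers, r_px, intens, cfg.image_size)
    return FrameStack(frames=frames, metadata={
        "spec": spec.to_dict(), "form": form.to_dict(), "cfg": cfg.to_dict()})


def perturb_skeleton(spec: SkeletonSpec, segment_index: int,
                     new_attach_t: float) -> SkeletonSpec:
    """Move one segment's attachment point along its parent's axis.

    Changes the quantitative skeleton while keeping coarse part adjacency
    (which part attaches to which) fixed.  The root cannot be perturbed.
    """
    if spec.segments[segment_index].parent is None:
        raise ParameterError("cannot perturb the root segment")
    if not 0.0 <= new_attach_t <= 1.0:
        raise ParameterError(f"new_attach_t must lie in [0,1], got {new_attach_t}")
    segs = list(spec.segments)
    segs[segment_index] = replace(segs[segment_index], attach_t=new_attach_t)
    return SkeletonSpec(tuple(segs))


# ---------------------------------------------------------------------------
# Catalog generation


#: Surface-form palette: each preset leads with a different non-accidental
#: property (taper + vertex, bulge, concavity, mixed), so any two presets
#: differ in at least one NAP field.
FORM_PALETTE = (
    SurfaceFormSpec(base_radius=0.13, taper=0.8, end_vertex=True),
    SurfaceFormSpec(base_radius=0.13, bulge=0.07),
    SurfaceFormSpec(base_radius=0.15, concavity=0.06),
    SurfaceFormSpec(base_radius=0.12, taper=0.45, bulge=0.04),
)


def _random_skeleton(rng: np.random.Generator, n_parts: int = 3) -> SkeletonSpec:
    """A random 3-part tree: vertical root with side branches."""
    segs = [Segment(parent=None, attach_t=0.0, direction=(0.0, 1.0, 0.0), length=1.0)]
    for _ in range(n_parts - 1):
        t = rng.uniform(0.15, 0.95)
        az = rng.uniform(0, 2 * np.pi)
        el = rng.uniform(-0.35, 0.6)       # mostly sideways, slight up/down
        d = (np.cos(el) * np.cos(az), np.sin(el), np.cos(el) * np.sin(az))
        segs.append(Segment(parent=0, attach_t=float(t), direction=d,
                            length=float(rng.uniform(0.45, 0.75))))
    return SkeletonSpec(tuple(segs))


@dataclass
class StimulusCatalog:
    """Factorial catalog of rendered videos: skeleton id x surface-form id."""

    videos: dict                       # (skel_id, form_id) -> FrameStack
    skeletons: list                    # SkeletonSpec per skeleton id
    forms: list                        # SurfaceFormSpec per form id
    cfg: RenderConfig
    seed: int

    @property
    def n_skeletons(self) -> int:
        return len(self.skeletons)

    @property
    def n_forms(self) -> int:
        return len(self.forms)

    def keys(self):
        return list(self.videos.keys())


def generate_stimulus_set(n_skeletons: int = 3, n_forms: int = 2, seed: int = 0,
                          cfg: Optional[RenderConfig] = None,
                          candidate_pool: int = 12) -> StimulusCatalog:
    """Generate the factorial stimulus catalog.

    Skeletons are drawn as random 3-part trees from a candidate pool and the
    ``n_skeletons`` most mutually distinct ones are selected by k-means over
    their pairwise skeletal distances (mirroring exemplar selection from a
    larger generated set); each selected skeleton is rendered with each
    surface form from the palette.  Deterministic for a fixed seed.
    """
    from .metrics import skeletal_distance, select_distinct_exemplars

    if n_skeletons < 1 or n_forms < 1:
        raise ParameterError("counts must be >= 1")
    if n_forms > len(FORM_PALETTE):
        raise ParameterError(f"at most {len(FORM_PALETTE)} surface-form presets available")
    cfg = cfg or default_render_config()
    rng = np.random.default_rng(seed)
    pool = max(candidate_pool, n_skeletons)
    candidates = [_random_skeleton(rng) for _ in range(pool)]
    if n_skeletons < pool:
        pts = [build_skeleton_points(s, 12)[0] for s in candidates]
        dmat = np.zeros((pool, pool))
        for i in range(pool):
            for j in range(i + 1, pool):
                d = skeletal_distance(pts[i], pts[j], align=False)
                dmat[i, j] = dmat[j, i] = d
        chosen = select_distinct_exemplars(dmat, n_skeletons)
    else:
        chosen = list(range(pool))
    skeletons = [candidates[i] for i in sorted(chosen)]
    forms = list(FORM_PALETTE[:n_forms])
    videos = {}
    for si, spec in enumerate(skeletons):
        for fi, form in enumerate(forms):
            videos[(si, fi)] = render_rotation_video(spec, form, cfg)
    return StimulusCatalog(videos=videos, skeletons=skeletons, forms=forms,
                           cfg=cfg, seed=seed)


# ---------------------------------------------------------------------------
# Disk I/O: one directory per video with numbered PNGs + JSON sidecar


def save_frame_stack(stack: FrameStack, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n = stack.n_frames
    width = max(4, len(str(n - 1)))
    for i in range(n):
        img = (stack.frames[i] * 255).round().astype(np.uint8)
        imageio.imwrite(d / f"frame_{i:0{width}d}.png", img)
    (d / "metadata.json").write_text(json.dumps(stack.metadata, indent=1))


def load_frame_stack(directory) -> FrameStack:
    d = Path(directory)
    files = sorted(d.glob("frame_*.png"))
    if not files:
        raise FileNotFoundError(f"no frame_*.png files in {d}")
    frames = np.stack([np.asarray(imageio.imread(f), dtype=float) / 255.0 for f in files])
    if frames.ndim == 4:       # collapse RGB(A) to grayscale
        frames = frames[..., :3].mean(axis=-1)
    meta_path = d / "metadata.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FrameStack(frames=frames, metadata=meta)
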