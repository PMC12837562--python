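"""Synthetic Micro-TESE-like microscope video with exact ground truth.

Testicular-tissue fields of view are emulated as bright-field-like scenes:
a light background with dark objects, Gaussian sensor noise and a mild
optical blur.  Three object families are rendered:

* **sperm phantoms** — an elliptical head (defaults 5 x 3 um) attached to a
  thin sinusoidally-curved tail (default 45 um, total length ~50 um),
  moving by one of three closed-form motion models (stationary, straight,
  sinusoidal progressive swimming);
* **cell clusters** — large irregular aggregates of overlapping blobs,
  mimicking the aggregating tissue-cell clutter of provisional samples;
* **head-like debris** — small ellipses with an axis ratio near the sperm
  head's, which is the classical false-positive challenge for any
  shape-based detector.

Optionally a cluster is deliberately drawn across a sperm tail
(``occlusion_probability``) to reproduce partial-tail occlusion, the
canonical missed-detection mode.

Because head motion is closed-form, the exported ground truth carries exact
per-frame bounding boxes (from the rendered pixel masks), head coordinates,
and analytic head trajectories in micrometres — so detector, tracker and
kinematics outputs can all be scored against known truth.

Everything is a pure function of :class:`SceneConfig` (including its seed):
the same config renders bit-identical videos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy import ndimage

from .core import (
    AnnotatedBox,
    BoundingBox,
    CalibrationProfile,
    FrameAnnotation,
    VideoSequence,
)
from .kinematics import Trajectory

__all__ = [
    "Stationary",
    "Straight",
    "Sinusoidal",
    "SpermPhantom",
    "SceneConfig",
    "GroundTruth",
    "head_path",
    "render_frame",
    "simulate_scene",
    "GroundTruthDetector",
]


# ---------------------------------------------------------------------------
# Motion models (closed form, micrometre units)


@dataclass(frozen=True)
class Stationary:
    heading_deg: float = 0.0


@dataclass(frozen=True)
class Straight:
    speed: float  # um/s
    heading_deg: float = 0.0


@dataclass(frozen=True)
class Sinusoidal:
    """Straight progression plus a lateral sinusoidal beat."""

    speed: float  # progressive speed, um/s
    amplitude: float  # lateral beat amplitude, um
    frequency: float  # beat frequency, Hz
    heading_deg: float = 0.0


Motion = Union[Stationary, Straight, Sinusoidal]


def _heading_vectors(heading_deg: float) -> tuple[np.ndarray, np.ndarray]:
    th = math.radians(heading_deg)
    u = np.array([math.cos(th), math.sin(th)])  # along heading (y down)
    n = np.array([-math.sin(th), math.cos(th)])  # left-perpendicular
    return u, n


def head_path(motion: Motion, t: float | np.ndarray,
              origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Closed-form head position (um) at time(s) ``t`` (s).

    Stationary phantoms stay at the origin; straight swimmers advance at
    constant speed along their heading; sinusoidal swimmers add a lateral
    offset ``A * sin(2 pi f t)`` perpendicular to the heading.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    p0 = np.asarray(origin, dtype=float)
    u, n = _heading_vectors(motion.heading_deg)
    if isinstance(motion, Stationary):
        out = np.broadcast_to(p0, t.shape + (2,)).copy()
    elif isinstance(motion, Straight):
        out = p0 + np.multiply.outer(motion.speed * t, u)
    elif isinstance(motion, Sinusoidal):
        out = (
            p0
            + np.multiply.outer(motion.speed * t, u)
            + np.multiply.outer(motion.amplitude * np.sin(2 * np.pi * motion.frequency * t), n)
        )
    else:  # pragma: no cover
        raise TypeError(f"unknown motion {motion!r}")
    return out


# ---------------------------------------------------------------------------
# Scene configuration


@dataclass(frozen=True)
class SpermPhantom:
    """Geometry, optics and motion of one rendered spermatozoon (um)."""

    position_um: tuple[float, float]  # initial head position
    motion: Motion = Stationary()
    head_major: float = 5.0
    head_minor: float = 3.0
    tail_length: float = 45.0  # head + tail total ~50 um
    tail_width: float = 0.3
    tail_wave_amplitude: float = 2.0  # lateral amplitude of the rendered flagellum arc
    contrast: float = 0.45  # darkness below background, on a [0, 1] scale

    def __post_init__(self) -> None:
        if min(self.head_major, self.head_minor, self.tail_length, self.tail_width) <= 0:
            raise ValueError("all phantom lengths must be positive")
        speed = getattr(self.motion, "speed", 0.0)
        if speed < 0:
            raise ValueError("speed must be non-negative")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic video; the seed fixes everything."""

    width_px: int = 384
    height_px: int = 384
    duration_s: float = 2.0
    calibration: CalibrationProfile = field(
        default_factory=lambda: CalibrationProfile(microns_per_pixel=0.28, frames_per_second=10.0)
    )
    sperm: tuple[SpermPhantom, ...] = ()
    n_cell_clusters: int = 0
    n_debris: int = 0
    occlusion_probability: float = 0.0
    noise_sigma: float = 0.02  # on the [0, 1] intensity scale
    seed: int = 0
    background_level: float = 0.82
    blur_sigma_px: float = 0.7
    invert: bool = False  # dark-field style: bright objects on dark background

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("duration * fps must give at least 2 frames")
        if not 0.0 <= self.occlusion_probability <= 1.0:
            raise ValueError("occlusion_probability must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.calibration.frames_per_second))


@dataclass
class GroundTruth:
    """Exact per-frame annotations and analytic head trajectories (um)."""

    annotations: list[FrameAnnotation]
    trajectories: dict[int, Trajectory]
    heads_px: dict[int, np.ndarray]  # track id -> (n_frames, 2) head pixel coords


# ---------------------------------------------------------------------------
# Static clutter layout (drawn once per scene)


@dataclass
class _Blob:
    cx: float
    cy: float
    rx: float
    ry: float
    theta: float
    depth: float


@dataclass
class _Layout:
    clusters: list[list[_Blob]]
    debris: list[_Blob]
    occluders: list[tuple[int, list[_Blob]]]  # (sperm index, cluster blobs)


def _sample_cluster(rng: np.random.Generator, cx: float, cy: float, mpp: float) -> list[_Blob]:
    n = int(rng.integers(4, 25))
    blobs = []
    for _ in range(n):
        r = rng.uniform(2.0, 6.0) / mpp  # 2-6 um blobs
        off = rng.normal(0.0, 8.0 / mpp, size=2)
        blobs.append(
            _Blob(cx + off[0], cy + off[1], r, r * rng.uniform(0.7, 1.0),
                  rng.uniform(0, np.pi), rng.uniform(0.25, 0.45))
        )
    return blobs


def _build_layout(config: SceneConfig, rng: np.random.Generator) -> _Layout:
    mpp = config.calibration.microns_per_pixel
    W, H = config.width_px, config.height_px
    clusters = []
    for _ in range(config.n_cell_clusters):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        clusters.append(_sample_cluster(rng, cx, cy, mpp))
    debris = []
    for _ in range(config.n_debris):
        # axis ratio deliberately near the head's ~5:3
        scale = rng.uniform(0.8, 1.3)
        debris.append(
            _Blob(
                rng.uniform(0, W),
                rng.uniform(0, H),
                2.5 * scale / mpp,
                1.5 * scale * rng.uniform(0.9, 1.1) / mpp,
                rng.uniform(0, np.pi),
                rng.uniform(0.35, 0.5),
            )
        )
    occluders = []
    for i, ph in enumerate(config.sperm):
        if rng.random() < config.occlusion_probability:
            # park a cluster on the tail midpoint (position at t = 0)
            head0 = np.asarray(ph.position_um) / mpp
            u, _ = _heading_vectors(ph.motion.heading_deg)
            mid = head0 - u * (ph.head_major / 2 + ph.tail_length / 2) / mpp
            occluders.append((i, _sample_cluster(rng, mid[0], mid[1], mpp)))
    return _Layout(clusters=clusters, debris=debris, occluders=occluders)


# ---------------------------------------------------------------------------
# Rasterization helpers


def _paint_ellipse(mask: np.ndarray, b: _Blob) -> None:
    H, W = mask.shape
    rmax = max(b.rx, b.ry) + 2
    y0, y1 = int(max(0, b.cy - rmax)), int(min(H, b.cy + rmax + 1))
    x0, x1 = int(max(0, b.cx - rmax)), int(min(W, b.cx + rmax + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - b.cx, yy - b.cy
    xr = dx * math.cos(b.theta) + dy * math.sin(b.theta)
    yr = -dx * math.sin(b.theta) + dy * math.cos(b.theta)
    mask[y0:y1, x0:x1] |= (xr / b.rx) ** 2 + (yr / b.ry) ** 2 <= 1.0


def _paint_polyline(mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Stamp disks of ``radius`` px at each point of a dense polyline."""
    H, W = mask.shape
    r = int(math.ceil(radius))
    stencil = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dx * dx + dy * dy <= radius * radius + 0.25
    ]
    xs = np.rint(pts[:, 0]).astype(int)
    ys = np.rint(pts[:, 1]).astype(int)
    for dy, dx in stencil:
        x, y = xs + dx, ys + dy
        ok = (x >= 0) & (x < W) & (y >= 0) & (y < H)
        mask[y[ok], x[ok]] = True


def _sperm_mask(
    config: SceneConfig, ph: SpermPhantom, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one phantom at time t; returns (mask, head_center_px)."""
    mpp = config.calibration.microns_per_pixel
    H, W = config.height_px, config.width_px
    mask = np.zeros((H, W), dtype=bool)

    head_um = head_path(ph.motion, t, ph.position_um)
    head_px = head_um / mpp
    u, n = _heading_vectors(ph.motion.heading_deg)

    _paint_ellipse(
        mask,
        _Blob(head_px[0], head_px[1], ph.head_major / 2 / mpp, ph.head_minor / 2 / mpp,
              math.radians(ph.motion.heading_deg), ph.contrast),
    )

    # flagellum: a sine arc trailing the head; its phase advances with the
    # beat frequency for sinusoidal swimmers so the beat is visible on film
    freq = getattr(ph.motion, "frequency", 0.0)
    phase = 2 * np.pi * freq * t
    base = head_px - u * (ph.head_major / 2) / mpp
    s = np.arange(0.0, ph.tail_length, mpp / 2)  # um along the tail
    wavelength = ph.tail_length / 1.5
    lateral = ph.tail_wave_amplitude * np.sin(2 * np.pi * s / wavelength + phase)
    taper = 1.0 - 0.6 * s / ph.tail_length  # beat amplitude tapers toward the tip
    pts = base + np.multiply.outer(-s / mpp, u) + np.multiply.outer(lateral * taper / mpp, n)
    _paint_polyline(mask, pts, max(ph.tail_width / 2 / mpp, 0.8))
    return mask, head_px


def _mask_box(mask: np.ndarray) -> BoundingBox | None:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    return BoundingBox(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def render_frame(
    config: SceneConfig,
    t: float,
    layout: _Layout | None = None,
    rng: np.random.Generator | None = None,
    frame_index: int | None = None,
) -> tuple[np.ndarray, FrameAnnotation]:
    """Render one frame at time ``t`` plus its exact annotation.

    Standalone calls rebuild the static clutter layout from the scene seed
    and draw the noise field from a per-frame child stream, so the same
    (config, t) pair always renders the same image.
    """
    if t < 0 or t > config.duration_s:
        raise ValueError("t outside scene duration")
    if frame_index is None:
        frame_index = int(round(t * config.calibration.frames_per_second))
    if layout is None:
        layout = _build_layout(config, np.random.default_rng(config.seed))
    if rng is None:
        rng = np.random.default_rng([config.seed, frame_index])

    H, W = config.height_px, config.width_px
    img = np.full((H, W), config.background_level, dtype=float)

    for blobs in layout.clusters:
        m = np.zeros((H, W), dtype=bool)
        for b in blobs:
            _paint_ellipse(m, b)
        img[m] = config.background_level - np.mean([b.depth for b in blobs])
    for b in layout.debris:
        m = np.zeros((H, W), dtype=bool)
        _paint_ellipse(m, b)
        img[m] = config.background_level - b.depth

    boxes: list[AnnotatedBox] = []
    for i, ph in enumerate(config.sperm):
        mask, head_px = _sperm_mask(config, ph, t)
        img[mask] = config.background_level - ph.contrast
        box = _mask_box(mask)
        full_mask_box = None
        if box is None:
            # fully outside the field: annotate the analytic extent, flagged
            mpp = config.calibration.microns_per_pixel
            half = (ph.head_major / 2 + ph.tail_length) / mpp
            cx, cy = head_path(ph.motion, t, ph.position_um) / mpp
            box = BoundingBox(cx - half, cy - half, cx + half, cy + half)
            out = True
        else:
            # partially out of frame when the mask touches the image border
            ys, xs = np.nonzero(mask)
            out = bool(xs.min() == 0 or ys.min() == 0 or xs.max() == W - 1 or ys.max() == H - 1)
        boxes.append(AnnotatedBox(box=box, track_id=i + 1, partially_out_of_frame=out))

    # occluding clusters are painted after the sperm, on top of their tails
    for _, blobs in layout.occluders:
        m = np.zeros((H, W), dtype=bool)
        for b in blobs:
            _paint_ellipse(m, b)
        img[m] = config.background_level - np.mean([b.depth for b in blobs])

    if config.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma_px)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    if config.invert:
        img = 1.0 - img
    frame = (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
    return frame, FrameAnnotation(frame_index=frame_index, boxes=boxes)


def simulate_scene(config: SceneConfig) -> tuple[VideoSequence, GroundTruth]:
    """Render the whole scene and its exact ground truth.

    The returned trajectories are the closed forms of :func:`head_path`
    sampled at the frame times (in um), not re-measured from pixels.
    """
    rng = np.random.default_rng(config.seed)
    layout = _build_layout(config, rng)
    fps = config.calibration.frames_per_second
    mpp = config.calibration.microns_per_pixel

    frames, annotations = [], []
    heads_px: dict[int, list[np.ndarray]] = {i + 1: [] for i in range(len(config.sperm))}
    for k in range(config.n_frames):
        t = k / fps
        frame, ann = render_frame(
            config, t, layout=layout, rng=np.random.default_rng([config.seed, k]), frame_index=k
        )
        frames.append(frame)
        annotations.append(ann)
        for i, ph in enumerate(config.sperm):
            heads_px[i + 1].append(head_path(ph.motion, t, ph.position_um) / mpp)

    times = np.arange(config.n_frames) / fps
    trajectories = {
        i + 1: Trajectory(
            track_id=i + 1,
            times=times,
            positions=head_path(ph.motion, times, ph.position_um),
            fps=fps,
        )
        for i, ph in enumerate(config.sperm)
    }
    video = VideoSequence(frames=frames, calibration=config.calibration)
    gt = GroundTruth(
        annotations=annotations,
        trajectories=trajectories,
        heads_px={k: np.asarray(v) for k, v in heads_px.items()},
    )
    return video, gt


class GroundTruthDetector:
    """Perfect detector backed by simulator ground truth.

    Satisfies the detector contract (frame -> detections) by keeping an
    internal frame counter; call :meth:`reset` before re-running a video.
    Useful for isolating tracker and kinematics behaviour from detection
    errors.
    """

    def __init__(self, gt: GroundTruth, confidence: float = 1.0):
        self._gt = gt
        self._confidence = confidence
        self._cursor = 0

    def reset(self) -> None:
        self._cursor = 0

    def __call__(self, frame: np.ndarray, frame_index: int | None = None):
        from .core import Detection  # local import to avoid cycle at module load

        k = self._cursor if frame_index is None else frame_index
        self._cursor = k + 1
        ann = self._gt.annotations[k]
        dets = []
        for ab in ann.boxes:
            head = None
            if ab.track_id is not None and ab.track_id in self._gt.heads_px:
                hx, hy = self._gt.heads_px[ab.track_id][k]
                head = (float(hx), float(hy))
                b, m = ab.box, Detection.HEAD_MARGIN
                # a head that left the visible extent cannot be reported
                if not (b.x_min - m <= hx <= b.x_max + m and b.y_min - m <= hy <= b.y_max + m):
                    head = None
            dets.append(Detection(box=ab.box, confidence=self._confidence, head=head))
        return dets
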