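"""End-to-end orchestration: detect -> track -> kinematics, with an
annotated overlay and per-stage latency accounting.

The overlay mirrors what a search-assist display shows the operator: each
confirmed track's bounding box, its id, a circle on the head point, and the
current 1-second windowed straight-line speed (VSL) — the one kinematic
index robust enough to show live, since detection cannot be guaranteed in
every frame.  Tracks without a complete window yet show an em dash.

Latency is wall-clock per stage (read, detection, tracking, kinematics,
render) and is *logged only*: a budget overrun warns but never fails, as
throughput is a property of the host, not of the algorithms.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from . import kinematics as kin
from .core import (
    CalibrationProfile,
    TrackRow,
    VideoSequence,
    write_track_table,
)
from .detect import ClassicalDetector, DetectorParams
from .track import Tracker, TrackerConfig, _call_detector
from .kinematics import SmoothingSpec, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "OverlayOptions",
    "PipelineConfig",
    "LatencyReport",
    "RunResult",
    "render_overlay",
    "run",
]

STAGES = ("read", "detect", "track", "kinematics", "render")


@dataclass(frozen=True)
class OverlayOptions:
    box_color: tuple[int, int, int] = (255, 64, 64)
    head_color: tuple[int, int, int] = (64, 64, 255)
    text_color: tuple[int, int, int] = (255, 255, 0)
    show_id: bool = True
    show_velocity: bool = True
    velocity_units: str = "µm/s"
    head_radius_px: int = 4


@dataclass(frozen=True)
class PipelineConfig:
    detector_params: DetectorParams = field(default_factory=DetectorParams)
    tracker_config: TrackerConfig = field(default_factory=TrackerConfig)
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    calibration: CalibrationProfile = field(default_factory=CalibrationProfile)
    overlay: OverlayOptions = field(default_factory=OverlayOptions)
    vsl_window_s: float = 1.0
    latency_budget_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.latency_budget_ms <= 0:
            raise ValueError("latency budget must be positive")


@dataclass
class LatencyReport:
    """Per-frame, per-stage wall-clock durations in milliseconds."""

    stages: dict[str, list[float]] = field(
        default_factory=lambda: {s: [] for s in STAGES}
    )

    def add(self, stage: str, ms: float) -> None:
        self.stages[stage].append(ms)

    def stage_totals(self) -> dict[str, float]:
        return {s: float(np.sum(v)) for s, v in self.stages.items()}

    @property
    def total_ms(self) -> float:
        return float(sum(self.stage_totals().values()))

    def per_frame_totals(self) -> list[float]:
        n = max((len(v) for v in self.stages.values()), default=0)
        out = []
        for i in range(n):
            out.append(sum(v[i] for v in self.stages.values() if i < len(v)))
        return out

    def check_budget(self, budget_ms: float) -> bool:
        """Warn (never raise) when any frame exceeded the latency budget."""
        worst = max(self.per_frame_totals(), default=0.0)
        if worst > budget_ms:
            warnings.warn(
                f"frame latency {worst:.1f} ms exceeded the {budget_ms:.0f} ms budget",
                RuntimeWarning,
                stacklevel=2,
            )
            return False
        return True

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "totals": self.stage_totals(), "total_ms": self.total_ms}
        )

    @classmethod
    def from_json(cls, text: str) -> "LatencyReport":
        data = json.loads(text)
        return cls(stages={s: list(v) for s, v in data["stages"].items()})


def _format_velocity(v: float | None, units: str) -> str:
    return f"{v:.1f} {units}" if v is not None and np.isfinite(v) else "—"


def render_overlay(
    frame: np.ndarray,
    tracks: list[tuple[int, "object", tuple[float, float] | None, float | None]],
    options: OverlayOptions | None = None,
) -> np.ndarray:
    """Draw boxes, ids, head markers and live VSL onto a copy of the frame.

    ``tracks`` rows are (track_id, box, head point or None, windowed VSL or
    None).  The input frame is never modified; with no tracks the output
    equals the input (expanded to RGB).
    """
    options = options or OverlayOptions()
    img = Image.fromarray(np.asarray(frame)).convert("RGB")
    draw = ImageDraw.Draw(img)
    for track_id, box, head, vsl_value in tracks:
        draw.rectangle(
            [box.x_min, box.y_min, box.x_max, box.y_max], outline=options.box_color, width=1
        )
        label_parts = []
        if options.show_id:
            label_parts.append(f"#{track_id}")
        if options.show_velocity:
            label_parts.append(_format_velocity(vsl_value, options.velocity_units))
        if label_parts:
            draw.text(
                (box.x_min, max(box.y_min - 12, 0)),
                " ".join(label_parts),
                fill=options.text_color,
            )
        if head is not None:
            r = options.head_radius_px
            draw.ellipse(
                [head[0] - r, head[1] - r, head[0] + r, head[1] + r],
                outline=options.head_color,
                width=1,
            )
    return np.asarray(img)


@dataclass
class RunResult:
    trajectories: dict[int, Trajectory]
    track_rows: list[TrackRow]
    kinematics: "object"  # pandas DataFrame
    overlays: list[np.ndarray]
    latency: LatencyReport
    tracks_path: Path | None = None
    kinematics_path: Path | None = None
    overlay_dir: Path | None = None


def _live_vsl(samples_px: list[tuple[float, tuple[float, float]]],
              cal: CalibrationProfile, window: float) -> float | None:
    """Windowed VSL from the most recent complete window, um/s."""
    if not samples_px:
        return None
    t_last, p_last = samples_px[-1]
    target = t_last - window
    tol = 0.5 / cal.frames_per_second
    for t, p in samples_px:
        if abs(t - target) <= tol:
            d = np.hypot(p_last[0] - p[0], p_last[1] - p[1]) * cal.microns_per_pixel
            return float(d / window)
    return None


def run(
    sequence: VideoSequence,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    detector=None,
) -> RunResult:
    """Run detect -> track -> kinematics over a video.

    Writes ``tracks.csv``, ``kinematics.csv``, ``latency.json`` and the
    overlay frames under ``out_dir`` when given.  A custom detector
    callable overrides the classical one.
    """
    config = config or PipelineConfig()
    cal = sequence.calibration
    if detector is None:
        detector = ClassicalDetector(params=config.detector_params, cal=cal)
    tracker = Tracker(config=config.tracker_config)
    latency = LatencyReport()

    rows: list[TrackRow] = []
    overlays: list[np.ndarray] = []
    history: dict[int, list[tuple[float, tuple[float, float]]]] = {}
    samples: dict[int, list[tuple[int, tuple[float, float], bool]]] = {}

    for k, frame in enumerate(sequence.frames):
        t0 = time.perf_counter()
        frame = np.asarray(frame)
        t1 = time.perf_counter()
        detections = _call_detector(detector, frame, k)
        t2 = time.perf_counter()
        confirmed = tracker.step(detections, frame)
        t3 = time.perf_counter()

        overlay_rows = []
        t_s = k / cal.frames_per_second
        for t in confirmed:
            if t.last_detection is not None:
                d = t.last_detection
                head = d.head if d.head is not None else d.box.center
                box, conf, observed = d.box, d.confidence, True
            else:
                box = t.kalman.box()
                head, conf, observed = box.center, 0.0, False
            rows.append(
                TrackRow(frame=k, track_id=t.track_id, box=box, confidence=conf,
                         head=head, observed=observed)
            )
            samples.setdefault(t.track_id, []).append((k, head, observed))
            if observed:
                history.setdefault(t.track_id, []).append((t_s, head))
            vsl_live = _live_vsl(history.get(t.track_id, []), cal, config.vsl_window_s)
            overlay_rows.append((t.track_id, box, head, vsl_live))
        t4 = time.perf_counter()
        overlays.append(render_overlay(frame, overlay_rows, config.overlay))
        t5 = time.perf_counter()

        latency.add("read", (t1 - t0) * 1e3)
        latency.add("detect", (t2 - t1) * 1e3)
        latency.add("track", (t3 - t2) * 1e3)
        latency.add("kinematics", (t4 - t3) * 1e3)
        latency.add("render", (t5 - t4) * 1e3)

    fps = cal.frames_per_second
    trajectories = {}
    for tid, entries in samples.items():
        frames_idx = np.array([e[0] for e in entries])
        pos_px = np.array([list(e[1]) for e in entries], dtype=float)
        observed = np.array([e[2] for e in entries], dtype=bool)
        trajectories[tid] = Trajectory(
            track_id=tid,
            times=frames_idx / fps,
            positions=pos_px * cal.microns_per_pixel,
            observed=observed,
            fps=fps,
        )
    report = kin.analyze(
        trajectories.values(), spec=config.smoothing, vsl_window=config.vsl_window_s
    )

    latency.check_budget(config.latency_budget_ms)
    logger.info("pipeline latency totals (ms): %s", latency.stage_totals())

    result = RunResult(
        trajectories=trajectories,
        track_rows=rows,
        kinematics=report,
        overlays=overlays,
        latency=latency,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.tracks_path = out_dir / "tracks.csv"
        write_track_table(rows, result.tracks_path)
        result.kinematics_path = out_dir / "kinematics.csv"
        report.to_csv(result.kinematics_path, index=False)
        (out_dir / "latency.json").write_text(latency.to_json())
        result.overlay_dir = out_dir / "overlay"
        result.overlay_dir.mkdir(exist_ok=True)
        from .core import write_image_sequence

        write_image_sequence(result.overlays, result.overlay_dir, prefix="overlay_")
    return result
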