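"""Classical single-frame sperm detector.

Micro-TESE sperm are often nearly stationary, so motion cues are useless
and each frame must be searched on shape alone.  The detector here follows
the classical morphology route: gradient (Sobel) filtering, binarization,
connected-component labeling, and PCA shape statistics on each component,
followed by an explicit head/tail assembly step:

1. Sobel gradient magnitude of the (optionally pre-smoothed) frame.
2. Binarize the gradient (Otsu by default, fixed threshold optional) and
   fill enclosed holes so object outlines become solid blobs.
3. Split the foreground morphologically: an opening with a small disk keeps
   only "thick" structures (head-sized blobs and larger); the thin
   remainder holds tail-like filaments.
4. Label each sub-mask into components and compute PCA statistics
   (eigenvalues of the pixel-coordinate covariance, orientation,
   elongation, extents).
5. Keep head candidates by physical area and elongation, tail segments by
   length and thickness, then pair each head with a nearby, angularly
   consistent tail.  One detection is emitted per head-tail pair, with the
   box spanning the union head-to-tail extent.

The pairing step is what rejects head-like debris (an ellipse with no
adjacent filament never forms a pair) and large cell clusters (wrong area /
thickness at every stage) — the same candidate-reduction idea that makes a
shape-based detector viable in cluttered tissue.

Confidence is a bounded product of per-criterion margin scores: it orders
detections by how comfortably they satisfy the shape criteria, and carries
no probabilistic meaning.

Any callable ``frame -> list[Detection]`` may replace this detector in the
pipeline (:data:`DetectorInterface`), e.g. an adapter around a learned
one-stage detector; training such a model is outside this package's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .core import BoundingBox, CalibrationProfile, Detection

__all__ = [
    "Component",
    "DetectorParams",
    "DetectorInterface",
    "gradient_magnitude",
    "binarize",
    "label_components",
    "component_orientation",
    "find_head_candidates",
    "find_tail_segments",
    "assemble_detections",
    "detect",
    "ClassicalDetector",
]

DetectorInterface = Callable[[np.ndarray], "list[Detection]"]


@dataclass
class Component:
    """One connected foreground region with PCA shape statistics.

    ``eigenvalues`` are the (descending) eigenvalues of the covariance of
    the member pixel coordinates; ``orientation`` is the principal-axis
    angle in degrees within [0, 180), measured from +x toward +y (image
    convention, y down); ``elongation`` is the eigenvalue ratio
    lambda1/lambda2 (infinite for perfectly 1-D components).
    """

    coords: np.ndarray  # (N, 2) as (row, col)
    centroid: tuple[float, float]  # (x, y) pixels
    eigenvalues: tuple[float, float]  # lambda1 >= lambda2 >= 0
    orientation: float  # degrees, [0, 180)
    area: int
    major_extent: float  # peak-to-peak extent along the principal axis, px
    minor_extent: float  # along the secondary axis, px

    @property
    def elongation(self) -> float:
        l1, l2 = self.eigenvalues
        return l1 / l2 if l2 > 1e-12 else float("inf")

    @property
    def box(self) -> BoundingBox:
        ys, xs = self.coords[:, 0], self.coords[:, 1]
        return BoundingBox(float(xs.min()), float(ys.min()),
                           float(xs.max() + 1), float(ys.max() + 1))

    def thickness(self) -> float:
        """Local width (px) as twice the maximum Euclidean distance
        transform inside the component — robust to curvature, unlike the
        minor-axis extent of a bent filament."""
        ys, xs = self.coords[:, 0], self.coords[:, 1]
        h = ys.max() - ys.min() + 3
        w = xs.max() - xs.min() + 3
        m = np.zeros((h, w), dtype=bool)
        m[ys - ys.min() + 1, xs - xs.min() + 1] = True
        return float(2.0 * ndimage.distance_transform_edt(m).max())

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Extreme member pixels along the principal axis, as (x, y)."""
        xy = self.coords[:, ::-1].astype(float)
        th = math.radians(self.orientation)
        axis = np.array([math.cos(th), math.sin(th)])
        proj = (xy - xy.mean(axis=0)) @ axis
        return xy[int(np.argmin(proj))], xy[int(np.argmax(proj))]


@dataclass(frozen=True)
class DetectorParams:
    """Shape criteria in physical units, so one parameter set transfers
    across magnifications.

    Defaults derive from typical human sperm dimensions (head ~5 x 3 um,
    total length ~50 um, tail diameter 0.2-0.3 um): head area spans an
    ellipse of those axes with margin; the tail thickness bound is wider
    than the physical tail because gradient filtering and finite pixel
    size thicken a sub-resolution filament to a few pixels.
    """

    threshold: str | float = "otsu"  # "otsu" or a fixed gradient threshold
    connectivity: int = 8
    smooth_sigma_px: float = 0.0  # pre-smoothing; optics usually blur enough already
    head_area_um2: tuple[float, float] = (6.0, 20.0)
    head_elongation: tuple[float, float] = (1.3, 4.0)
    tail_min_length_um: float = 15.0
    tail_max_width_um: float = 1.6
    junction_max_um: float = 3.0
    angle_tolerance_deg: float = 45.0
    separation_radius_um: float = 0.8  # opening radius splitting heads from tails
    emit_unpaired_heads: bool = False
    unpaired_confidence_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for lo, hi in (self.head_area_um2, self.head_elongation):
            if not 0 < lo < hi:
                raise ValueError("ranges must be positive and non-empty")


def gradient_magnitude(frame: np.ndarray) -> np.ndarray:
    """Per-pixel magnitude of the horizontal/vertical 3x3 Sobel responses."""
    f = np.asarray(frame, dtype=float)
    if f.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def binarize(gradient: np.ndarray, threshold: str | float = "otsu") -> np.ndarray:
    """Threshold a gradient image; a featureless image yields an empty mask."""
    if isinstance(threshold, (int, float)):
        return gradient > float(threshold)
    if threshold != "otsu":
        raise ValueError(f"unknown threshold method {threshold!r}")
    if gradient.max() - gradient.min() < 1e-9:
        return np.zeros_like(gradient, dtype=bool)
    return gradient > filters.threshold_otsu(gradient)


def _component_from_coords(coords: np.ndarray) -> Component:
    xy = coords[:, ::-1].astype(float)  # (x, y)
    mean = xy.mean(axis=0)
    if len(xy) >= 2:
        cov = np.cov((xy - mean).T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        v = evecs[:, order[0]]
        orient = math.degrees(math.atan2(v[1], v[0])) % 180.0
        th = math.radians(orient)
        axis = np.array([math.cos(th), math.sin(th)])
        perp = np.array([-axis[1], axis[0]])
        centered = xy - mean
        major = float(np.ptp(centered @ axis)) + 1.0
        minor = float(np.ptp(centered @ perp)) + 1.0
    else:
        evals = np.array([0.0, 0.0])
        orient, major, minor = 0.0, 1.0, 1.0
    return Component(
        coords=coords,
        centroid=(float(mean[0]), float(mean[1])),
        eigenvalues=(float(evals[0]), float(evals[1])),
        orientation=orient,
        area=len(coords),
        major_extent=major,
        minor_extent=minor,
    )


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Maximal connected foreground regions with PCA statistics."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    return [_component_from_coords(r.coords) for r in measure.regionprops(labeled)]


def component_orientation(c: Component) -> float:
    """Principal-axis angle in degrees, [0, 180)."""
    if c.area < 2:
        raise ValueError("orientation needs at least 2 pixels")
    return c.orientation


def find_head_candidates(
    components: Sequence[Component], params: DetectorParams, cal: CalibrationProfile
) -> list[Component]:
    """Keep components whose physical area and elongation match a sperm head."""
    um2 = cal.microns_per_pixel**2
    lo_a, hi_a = params.head_area_um2
    lo_e, hi_e = params.head_elongation
    return [
        c
        for c in components
        if lo_a <= c.area * um2 <= hi_a and lo_e <= c.elongation <= hi_e
    ]


def find_tail_segments(
    components: Sequence[Component], params: DetectorParams, cal: CalibrationProfile
) -> list[Component]:
    """Keep long, thin components: principal extent at least the minimum
    tail length and local thickness at most the tail width bound."""
    mpp = cal.microns_per_pixel
    out = []
    for c in components:
        if c.major_extent * mpp < params.tail_min_length_um:
            continue
        if c.thickness() * mpp > params.tail_max_width_um:
            continue
        out.append(c)
    return out


def _axial_diff(a_deg: float, b_deg: float) -> float:
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


def _range_score(value: float, lo: float, hi: float) -> float:
    """1 at the range midpoint, 0.5 at the edges; used as a margin score."""
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return max(0.0, 1.0 - 0.5 * abs(value - mid) / half)


def assemble_detections(
    heads: Sequence[Component],
    tails: Sequence[Component],
    params: DetectorParams,
    cal: CalibrationProfile,
) -> list[Detection]:
    """Pair heads with tails into sperm detections.

    A tail is eligible for a head when its proximal endpoint lies within
    the junction distance of the head's pixels and the head-to-junction
    direction agrees with the head's principal axis within the angular
    tolerance.  Eligible (head, tail) pairs are resolved greedily by
    junction distance, so a tail claimed by two heads goes to the nearer
    one and the loser is treated as unpaired.
    """
    mpp = cal.microns_per_pixel
    um2 = mpp * mpp
    pairs = []  # (distance_px, head_idx, tail_idx, proximal_xy)
    for hi_idx, head in enumerate(heads):
        head_xy = head.coords[:, ::-1].astype(float)
        hc = np.asarray(head.centroid)
        for ti_idx, tail in enumerate(tails):
            e1, e2 = tail.endpoints()
            prox = e1 if np.linalg.norm(e1 - hc) <= np.linalg.norm(e2 - hc) else e2
            dist = float(np.min(np.linalg.norm(head_xy - prox, axis=1)))
            if dist * mpp > params.junction_max_um:
                continue
            neck = prox - hc
            if np.linalg.norm(neck) > 1e-9:
                neck_angle = math.degrees(math.atan2(neck[1], neck[0])) % 180.0
                if _axial_diff(neck_angle, head.orientation) > params.angle_tolerance_deg:
                    continue
            pairs.append((dist, hi_idx, ti_idx, prox))

    pairs.sort(key=lambda p: p[0])
    used_heads: set[int] = set()
    used_tails: set[int] = set()
    detections = []
    for dist, hi_idx, ti_idx, prox in pairs:
        if hi_idx in used_heads or ti_idx in used_tails:
            continue
        used_heads.add(hi_idx)
        used_tails.add(ti_idx)
        head, tail = heads[hi_idx], tails[ti_idx]
        box = head.box.union_extent(tail.box)
        hc = np.asarray(head.centroid)
        neck = prox - hc
        orientation = (
            math.degrees(math.atan2(neck[1], neck[0])) % 180.0
            if np.linalg.norm(neck) > 1e-9
            else head.orientation
        )
        conf = (
            _range_score(head.area * um2, *params.head_area_um2)
            * _range_score(min(head.elongation, 10.0), *params.head_elongation)
            * min(1.0, tail.major_extent * mpp / (2.0 * params.tail_min_length_um) + 0.5)
        )
        detections.append(
            Detection(
                box=box,
                confidence=float(np.clip(conf, 0.0, 1.0)),
                head=head.centroid,
                orientation=orientation,
            )
        )

    if params.emit_unpaired_heads:
        for hi_idx, head in enumerate(heads):
            if hi_idx in used_heads:
                continue
            conf = (
                _range_score(head.area * um2, *params.head_area_um2)
                * _range_score(min(head.elongation, 10.0), *params.head_elongation)
                * params.unpaired_confidence_scale
            )
            detections.append(
                Detection(
                    box=head.box,
                    confidence=float(np.clip(conf, 0.0, 1.0)),
                    head=head.centroid,
                    orientation=head.orientation,
                )
            )
    detections.sort(key=lambda d: -d.confidence)
    return detections


def split_masks(
    mask: np.ndarray, params: DetectorParams, cal: CalibrationProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Split a filled foreground mask into thick (head-scale) and thin
    (tail-scale) sub-masks by morphological opening."""
    r = max(1, int(round(params.separation_radius_um / cal.microns_per_pixel)))
    thick = morphology.opening(mask, morphology.disk(r))
    thin = mask & ~morphology.dilation(thick, morphology.disk(1))
    return thick, thin


def detect(
    frame: np.ndarray, params: DetectorParams | None = None,
    cal: CalibrationProfile | None = None,
) -> list[Detection]:
    """Run the full classical detector on one frame.

    Returns detections sorted by descending confidence; a featureless frame
    yields an empty list.
    """
    params = params or DetectorParams()
    cal = cal or CalibrationProfile()
    f = np.asarray(frame, dtype=float)
    if params.smooth_sigma_px > 0:
        f = ndimage.gaussian_filter(f, params.smooth_sigma_px)
    grad = gradient_magnitude(f)
    mask = binarize(grad, params.threshold)
    if not mask.any():
        return []
    filled = ndimage.binary_fill_holes(mask)
    thick, thin = split_masks(filled, params, cal)
    heads = find_head_candidates(label_components(thick, params.connectivity), params, cal)
    tails = find_tail_segments(label_components(thin, params.connectivity), params, cal)
    return assemble_detections(heads, tails, params, cal)


def write_detections_csv(detections_by_frame: dict[int, Sequence[Detection]], path) -> None:
    """Flat CSV of per-frame detections (frame, box, conf, head, orientation)."""
    import pandas as pd

    records = []
    for k in sorted(detections_by_frame):
        for d in detections_by_frame[k]:
            hx, hy = d.head if d.head is not None else (float("nan"), float("nan"))
            records.append(
                {
                    "frame": k,
                    "x_min": d.box.x_min,
                    "y_min": d.box.y_min,
                    "x_max": d.box.x_max,
                    "y_max": d.box.y_max,
                    "conf": d.confidence,
                    "head_x": hx,
                    "head_y": hy,
                    "orientation": d.orientation if d.orientation is not None else float("nan"),
                }
            )
    pd.DataFrame.from_records(
        records,
        columns=["frame", "x_min", "y_min", "x_max", "y_max", "conf",
                 "head_x", "head_y", "orientation"],
    ).to_csv(path, index=False)


def read_detections_csv(path) -> dict[int, list[Detection]]:
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[int, list[Detection]] = {}
    for _, row in df.iterrows():
        head = None
        if np.isfinite(row["head_x"]) and np.isfinite(row["head_y"]):
            head = (float(row["head_x"]), float(row["head_y"]))
        orient = float(row["orientation"]) if np.isfinite(row["orientation"]) else None
        out.setdefault(int(row["frame"]), []).append(
            Detection(
                box=BoundingBox(row["x_min"], row["y_min"], row["x_max"], row["y_max"]),
                confidence=float(row["conf"]),
                head=head,
                orientation=orient,
            )
        )
    return out


@dataclass
class ClassicalDetector:
    """The classical detector bound to fixed parameters, satisfying the
    plain ``frame -> detections`` detector contract."""

    params: DetectorParams = field(default_factory=DetectorParams)
    cal: CalibrationProfile = field(default_factory=CalibrationProfile)

    def __call__(self, frame: np.ndarray, frame_index: int | None = None) -> list[Detection]:
        return detect(frame, self.params, self.cal)
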