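"""Per-tooth radiographic bone loss (RBL) geometry.

For each tooth polygon, a central axis is defined as the principal (major)
axis of the filled polygon's second central moments, passing through its
centroid. The axis, oriented crown -> root apex by jaw, is intersected with
the CEJ and bone-level contours; the distance from the CEJ to the alveolar
crest (Distance 1) over the distance from the CEJ to the root apex
(Distance 2) gives RBL(%) = D1 / D2 x 100. Being a ratio of collinear
distances, RBL is invariant to rigid motion and uniform scaling of the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations_io import (
    FDI_CODES,
    AnnotationScene,
    PolygonContour,
    jaw_of_fdi,
)
from .errors import AmbiguousAxisError, MeasurementError, SceneValidationError, SchemaError

#: Eigenvalue-ratio threshold below which the principal axis is ambiguous.
AXIS_EIGENVALUE_RATIO_MIN = 1.05
#: Tolerance used when comparing axis parameters t.
_T_TOL = 1e-9


def polygon_moments(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact area, centroid and second-central-moment (covariance) matrix of a
    filled simple polygon, via Green's-theorem shoelace sums.

    Returns ``(area, centroid(2,), cov(2,2))`` with ``area > 0`` regardless
    of vertex winding. ``cov`` is the covariance of the uniform distribution
    over the polygon interior.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)  # signed area
    if a == 0:
        raise SceneValidationError("degenerate polygon with zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    # second moments about the origin (integrals of x^2, y^2, xy)
    ixx = np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0
    iyy = np.sum(cross * (y * y + y * y1 + y1 * y1)) / 12.0
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    cov = np.array(
        [
            [ixx / a - cx * cx, ixy / a - cx * cy],
            [ixy / a - cx * cy, iyy / a - cy * cy],
        ]
    )
    return abs(a), np.array([cx, cy]), cov


@dataclass
class ToothAxis:
    """The central crown->apex axis of one tooth.

    ``crown_point`` and ``apex_point`` are the two intersections of the
    principal-moment axis with the tooth polygon boundary; which endpoint is
    the apex is decided by jaw (maxillary apex points up / smaller y,
    mandibular apex down / larger y). ``direction`` is the unit vector from
    crown toward apex.
    """

    fdi_code: int
    crown_point: np.ndarray
    apex_point: np.ndarray
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fdi_code not in FDI_CODES:
            raise SchemaError(f"invalid FDI code {self.fdi_code!r}")
        self.crown_point = np.asarray(self.crown_point, dtype=float)
        self.apex_point = np.asarray(self.apex_point, dtype=float)
        delta = self.apex_point - self.crown_point
        length = float(np.linalg.norm(delta))
        if length == 0:
            raise SceneValidationError("axis endpoints coincide")
        if self.direction is None:
            self.direction = delta / length
        else:
            self.direction = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
                raise SceneValidationError("axis direction must be a unit vector")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.apex_point - self.crown_point))

    def point_at(self, t: float) -> np.ndarray:
        return self.crown_point + t * (self.apex_point - self.crown_point)


@dataclass
class RBLMeasurement:
    """One tooth's axis landmarks, Distance 1, Distance 2 and RBL%."""

    fdi_code: int
    cej_point: tuple[float, float] | None = None
    bone_point: tuple[float, float] | None = None
    apex_point: tuple[float, float] | None = None
    distance1: float = float("nan")
    distance2: float = float("nan")
    rbl_percent: float = float("nan")
    measurable: bool = False
    notes: list[str] = field(default_factory=list)


def compute_tooth_axis(tooth: PolygonContour, fdi_code: int) -> ToothAxis:
    """Principal-moment central axis of a tooth polygon.

    The axis line is the major eigenvector of the filled polygon's second
    central moments through the centroid; the endpoints are its two extreme
    intersections with the polygon boundary. Raises
    :class:`AmbiguousAxisError` when the moment eigenvalue ratio is below
    ``AXIS_EIGENVALUE_RATIO_MIN`` (near-isotropic shape).
    """
    if fdi_code not in FDI_CODES:
        raise SchemaError(f"invalid FDI code {fdi_code!r}")
    _, centroid, cov = polygon_moments(tooth.points)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    lo, hi = float(eigvals[0]), float(eigvals[1])
    if lo <= 0 or hi / lo < AXIS_EIGENVALUE_RATIO_MIN:
        raise AmbiguousAxisError(
            f"tooth {fdi_code}: eigenvalue ratio "
            f"{hi / lo if lo > 0 else float('inf'):.4f} below "
            f"{AXIS_EIGENVALUE_RATIO_MIN} (shape too isotropic)"
        )
    direction = eigvecs[:, 1]

    hits = _line_polygon_intersections(centroid, direction, tooth.points)
    if len(hits) < 2:
        raise SceneValidationError(
            f"tooth {fdi_code}: principal axis does not cross the boundary twice"
        )
    s_values = np.array([s for s, _ in hits])
    p_min = hits[int(np.argmin(s_values))][1]
    p_max = hits[int(np.argmax(s_values))][1]

    if jaw_of_fdi(fdi_code) == "maxillary":
        apex, crown = (p_min, p_max) if p_min[1] < p_max[1] else (p_max, p_min)
    else:
        apex, crown = (p_min, p_max) if p_min[1] > p_max[1] else (p_max, p_min)
    return ToothAxis(fdi_code=fdi_code, crown_point=crown, apex_point=apex)


def _line_polygon_intersections(
    origin: np.ndarray, direction: np.ndarray, points: np.ndarray
) -> list[tuple[float, np.ndarray]]:
    """Intersections of an infinite line with every polygon edge.

    Returns ``(s, point)`` pairs with s the signed arc length along
    ``direction`` from ``origin``. Vertex / tangential touches are reported
    once (deduplicated by s). Edges parallel to the line are skipped.
    """
    pts = np.asarray(points, dtype=float)
    a = pts
    b = np.roll(pts, -1, axis=0)
    e = b - a
    d = np.asarray(direction, dtype=float)
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    ao = a - origin
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]) / denom
        u = (ao[:, 0] * d[1] - ao[:, 1] * d[0]) / denom
    ok = (np.abs(denom) > 1e-12) & (u >= -1e-9) & (u < 1.0 - 1e-9)
    raw = sorted(float(sv) for sv in s[ok])
    hits: list[tuple[float, np.ndarray]] = []
    for sv in raw:
        if hits and abs(sv - hits[-1][0]) <= 1e-9 * (1.0 + abs(sv)):
            continue
        hits.append((sv, origin + sv * d))
    return hits


def axis_intersections(
    axis: ToothAxis, contour: PolygonContour
) -> list[tuple[float, np.ndarray]]:
    """Intersections of the infinite axis line with a polygon contour.

    Each hit is reported as ``(t, point)`` with t = 0 at the crown point and
    t = 1 at the apex point (t increasing toward the apex), sorted ascending.
    An empty list is a legal result.
    """
    hits = _line_polygon_intersections(
        axis.crown_point, axis.direction, contour.points
    )
    length = axis.length
    return [(s / length, p) for s, p in hits]


def measure_rbl(
    axis: ToothAxis,
    cej_contour: PolygonContour,
    bone_contour: PolygonContour,
) -> RBLMeasurement:
    """Measure Distance 1, Distance 2 and RBL% along one tooth axis.

    The CEJ point is the most coronal (smallest-t) intersection with the CEJ
    contour; the alveolar-crest point is the most coronal bone intersection
    at or apical to the CEJ. Pathological geometry is clamped with a note:
    bone coronal to the CEJ -> Distance 1 = 0; bone apical to the apex ->
    RBL = 100%. Missing intersections yield ``measurable=False`` with a
    ``missing-landmark`` note.
    """
    m = RBLMeasurement(fdi_code=axis.fdi_code)
    cej_hits = axis_intersections(axis, cej_contour)
    if not cej_hits:
        m.notes.append("missing-landmark:cej")
        return m
    t_cej, cej_p = cej_hits[0]

    bone_hits = axis_intersections(axis, bone_contour)
    if not bone_hits:
        m.notes.append("missing-landmark:bone")
        return m
    apical = [(t, p) for t, p in bone_hits if t >= t_cej - _T_TOL]
    clamped_d1 = False
    if apical:
        t_bone, bone_p = apical[0]
    else:
        # every bone crossing is coronal to the CEJ: clamp Distance 1 to 0
        t_bone, bone_p = bone_hits[-1]
        clamped_d1 = True

    apex_p = axis.apex_point
    d2 = float(np.linalg.norm(apex_p - cej_p))
    if d2 <= _T_TOL:
        m.notes.append("degenerate-axis")
        return m
    d1 = float(np.linalg.norm(bone_p - cej_p))
    if clamped_d1:
        d1 = 0.0
        m.notes.append("bone-coronal-to-cej:distance1-clamped-to-0")

    rbl = 100.0 * d1 / d2
    if t_bone > 1.0 + _T_TOL:
        rbl = 100.0
        m.notes.append("bone-beyond-apex:rbl-clamped-to-100")
    rbl = float(np.clip(rbl, 0.0, 100.0))

    m.cej_point = (float(cej_p[0]), float(cej_p[1]))
    m.bone_point = (float(bone_p[0]), float(bone_p[1]))
    m.apex_point = (float(apex_p[0]), float(apex_p[1]))
    m.distance1 = d1
    m.distance2 = d2
    m.rbl_percent = rbl
    m.measurable = True
    return m


def measure_scene(scene: AnnotationScene) -> list[RBLMeasurement]:
    """Measure RBL for every tooth in a scene.

    Maxillary teeth are intersected with the maxillary CEJ contour and
    mandibular teeth with the mandibular one; all teeth share the single bone
    contour. Teeth whose jaw lacks a CEJ contour, or whose axis is ambiguous,
    are retained with ``measurable=False`` rather than aborting the scene.
    """
    if scene.bone is None:
        raise MeasurementError("scene has no bone contour")
    if not scene.cej:
        raise MeasurementError("scene has no CEJ contour")
    if not scene.teeth:
        raise MeasurementError("scene has no teeth")

    results: list[RBLMeasurement] = []
    for code in sorted(scene.teeth):
        jaw = jaw_of_fdi(code)
        cej_contour = scene.cej.get(jaw)
        if cej_contour is None:
            results.append(
                RBLMeasurement(fdi_code=code, notes=[f"missing-landmark:cej-{jaw}"])
            )
            continue
        try:
            axis = compute_tooth_axis(scene.teeth[code], code)
        except AmbiguousAxisError:
            results.append(RBLMeasurement(fdi_code=code, notes=["ambiguous-axis"]))
            continue
        results.append(measure_rbl(axis, cej_contour, scene.bone))
    return results


def measurements_to_table(measurements: list[RBLMeasurement]) -> pd.DataFrame:
    """Per-tooth measurement table (one row per tooth, CSV-ready)."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "fdi": m.fdi_code,
                "cej_x": m.cej_point[0] if m.cej_point else np.nan,
                "cej_y": m.cej_point[1] if m.cej_point else np.nan,
                "bone_x": m.bone_point[0] if m.bone_point else np.nan,
                "bone_y": m.bone_point[1] if m.bone_point else np.nan,
                "apex_x": m.apex_point[0] if m.apex_point else np.nan,
                "apex_y": m.apex_point[1] if m.apex_point else np.nan,
                "d1_px": m.distance1,
                "d2_px": m.distance2,
                "rbl_percent": m.rbl_percent,
                "measurable": m.measurable,
                "notes": ";".join(m.notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fdi", "cej_x", "cej_y", "bone_x", "bone_y", "apex_x", "apex_y",
            "d1_px", "d2_px", "rbl_percent", "measurable", "notes",
        ],
    )


def draw_overlay(image: np.ndarray | None, scene: AnnotationScene,
                 measurements: list[RBLMeasurement]):
    """Render axis lines and CEJ / crest / apex landmarks on the radiograph.

    ``image`` is a grayscale array (or None for a blank canvas). Returns a
    PIL RGB image for clinician review.
    """
    from PIL import Image, ImageDraw

    if image is None:
        base = Image.new("L", (scene.image_width, scene.image_height), 0)
    else:
        base = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L")
    canvas = base.convert("RGB")
    draw = ImageDraw.Draw(canvas)
    for m in measurements:
        if not m.measurable:
            continue
        draw.line([m.cej_point, m.apex_point], fill=(80, 160, 255), width=1)
        for pt, color in (
            (m.cej_point, (255, 220, 0)),
            (m.bone_point, (255, 60, 60)),
            (m.apex_point, (60, 255, 120)),
        ):
            x, y = pt
            draw.ellipse([x - 2, y - 2, x + 2, y + 2], fill=color)
    return canvas
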