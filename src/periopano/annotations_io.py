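"""LabelMe-style polygon annotations: parsing, writing, YOLO export,
rasterization, and the 75:15:10 dataset split.

One JSON document describes one radiograph. Three label roles exist: a single
``bone`` outline, up to two CEJ curves (maxillary / mandibular), and up to 32
teeth keyed by their two-digit FDI code. Coordinates are continuous 0-based
pixels, origin top-left, y increasing downward.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import (
    AnnotationParseError,
    DuplicateAnnotationError,
    SceneValidationError,
    SchemaError,
    SplitError,
    UnsupportedShapeError,
)

#: All valid FDI tooth codes: quadrant (1-4) * 10 + position (1-8).
FDI_CODES: tuple[int, ...] = tuple(
    q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 9)
)

MAXILLARY_QUADRANTS = (1, 2)
MANDIBULAR_QUADRANTS = (3, 4)

#: Canonical label texts. The study never names its labels, so these are the
#: package defaults; any mapping ``label text -> canonical token`` may be
#: passed to :func:`read_labelme` to override them.
BONE_LABEL = "bone"
CEJ_UPPER_LABEL = "cej_upper"
CEJ_LOWER_LABEL = "cej_lower"

DEFAULT_LABEL_SCHEMA: dict[str, str] = {
    BONE_LABEL: BONE_LABEL,
    CEJ_UPPER_LABEL: CEJ_UPPER_LABEL,
    CEJ_LOWER_LABEL: CEJ_LOWER_LABEL,
    **{str(code): str(code) for code in FDI_CODES},
}

_CEJ_ROLE_BY_TOKEN = {CEJ_UPPER_LABEL: "maxillary", CEJ_LOWER_LABEL: "mandibular"}
_CEJ_TOKEN_BY_ROLE = {v: k for k, v in _CEJ_ROLE_BY_TOKEN.items()}


def jaw_of_fdi(fdi_code: int) -> str:
    """Return ``"maxillary"`` or ``"mandibular"`` for a valid FDI code."""
    quadrant = fdi_code // 10
    if quadrant in MAXILLARY_QUADRANTS:
        return "maxillary"
    if quadrant in MANDIBULAR_QUADRANTS:
        return "mandibular"
    raise SchemaError(f"invalid FDI code {fdi_code!r}")


@dataclass(eq=False)
class PolygonContour:
    """A labeled closed polygon in pixel coordinates.

    The polygon is implicitly closed: the last vertex need not repeat the
    first. At least 3 vertices are required; all coordinates must be finite
    and non-negative.
    """

    label: str
    points: np.ndarray
    shape_type: str = "polygon"

    def __post_init__(self) -> None:
        if self.shape_type != "polygon":
            raise UnsupportedShapeError(
                f"shape_type {self.shape_type!r} is not supported (only 'polygon')"
            )
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise SceneValidationError(
                f"contour {self.label!r}: points must be an (N, 2) array"
            )
        if pts.shape[0] < 3:
            raise SceneValidationError(
                f"contour {self.label!r}: a polygon needs at least 3 points"
            )
        if not np.all(np.isfinite(pts)):
            raise SceneValidationError(f"contour {self.label!r}: non-finite coordinate")
        if np.any(pts < 0):
            raise SceneValidationError(f"contour {self.label!r}: negative coordinate")
        self.points = pts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PolygonContour):
            return NotImplemented
        return (
            self.label == other.label
            and self.shape_type == other.shape_type
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
        )

    def translated(self, dx: float, dy: float) -> "PolygonContour":
        return PolygonContour(self.label, self.points + np.array([dx, dy]))

    def as_shapely(self) -> ShapelyPolygon:
        poly = ShapelyPolygon(self.points)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly


@dataclass(eq=False)
class AnnotationScene:
    """All polygon annotations of one radiograph plus its dimensions.

    ``teeth`` maps FDI code -> contour, ``cej`` maps jaw role
    (``"maxillary"`` / ``"mandibular"``) -> contour, ``bone`` is the single
    optional bone outline. ``warnings`` collects labels that were present in
    the source document but not mapped by the schema; it does not take part
    in equality.
    """

    image_width: int
    image_height: int
    image_path: str = ""
    teeth: dict[int, PolygonContour] = field(default_factory=dict)
    cej: dict[str, PolygonContour] = field(default_factory=dict)
    bone: PolygonContour | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise SceneValidationError("image dimensions must be positive")
        for role in self.cej:
            if role not in ("maxillary", "mandibular"):
                raise SceneValidationError(f"unknown CEJ role {role!r}")
        for code in self.teeth:
            if code not in FDI_CODES:
                raise SchemaError(f"invalid FDI code {code!r} in teeth map")
        tol = 1e-6
        for role, key, contour in self.iter_contours():
            pts = contour.points
            if (
                np.any(pts[:, 0] < -tol)
                or np.any(pts[:, 0] > self.image_width + tol)
                or np.any(pts[:, 1] < -tol)
                or np.any(pts[:, 1] > self.image_height + tol)
            ):
                raise SceneValidationError(
                    f"{role} contour {key!r} has coordinates outside "
                    f"[0, {self.image_width}] x [0, {self.image_height}]"
                )

    def iter_contours(self) -> Iterator[tuple[str, object, PolygonContour]]:
        """Yield ``(role, key, contour)`` — teeth (FDI-sorted), CEJ, bone."""
        for code in sorted(self.teeth):
            yield "tooth", code, self.teeth[code]
        for role in ("maxillary", "mandibular"):
            if role in self.cej:
                yield "cej", role, self.cej[role]
        if self.bone is not None:
            yield "bone", "bone", self.bone

    @property
    def n_contours(self) -> int:
        return len(self.teeth) + len(self.cej) + (self.bone is not None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationScene):
            return NotImplemented
        return (
            self.image_width == other.image_width
            and self.image_height == other.image_height
            and self.image_path == other.image_path
            and self.teeth == other.teeth
            and self.cej == other.cej
            and self.bone == other.bone
        )


# ---------------------------------------------------------------------------
# LabelMe reading / writing
# ---------------------------------------------------------------------------

def read_labelme(
    raw_annotation_text: str,
    label_schema: Mapping[str, str] | None = None,
) -> AnnotationScene:
    """Parse a LabelMe JSON document into an :class:`AnnotationScene`.

    ``label_schema`` maps label text to a canonical token: ``"bone"``,
    ``"cej_upper"``, ``"cej_lower"``, or a two-digit FDI code string. Labels
    absent from the schema are collected into ``scene.warnings`` rather than
    silently dropped. Only ``imageWidth`` / ``imageHeight`` / ``imagePath`` /
    ``shapes`` are consumed; ``flags`` and ``group_id`` are ignored.
    """
    schema = dict(DEFAULT_LABEL_SCHEMA if label_schema is None else label_schema)
    try:
        doc = json.loads(raw_annotation_text)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"not valid JSON: {exc}") from exc
    for fld in ("imageWidth", "imageHeight", "shapes"):
        if fld not in doc:
            raise AnnotationParseError(f"missing field {fld!r}")

    teeth: dict[int, PolygonContour] = {}
    cej: dict[str, PolygonContour] = {}
    bone: PolygonContour | None = None
    unmapped: list[str] = []

    for i, shape in enumerate(doc["shapes"]):
        for fld in ("label", "points", "shape_type"):
            if fld not in shape:
                raise AnnotationParseError(f"shape #{i}: missing field {fld!r}")
        label = str(shape["label"])
        contour = PolygonContour(label, shape["points"], shape["shape_type"])
        token = schema.get(label)
        if token is None:
            unmapped.append(f"unmapped label {label!r} (shape #{i})")
            continue
        if token == BONE_LABEL:
            if bone is not None:
                raise DuplicateAnnotationError("duplicate bone annotation")
            bone = contour
        elif token in _CEJ_ROLE_BY_TOKEN:
            role = _CEJ_ROLE_BY_TOKEN[token]
            if role in cej:
                raise DuplicateAnnotationError(f"duplicate {role} CEJ annotation")
            cej[role] = contour
        else:
            try:
                code = int(token)
            except ValueError:
                raise SchemaError(f"schema token {token!r} is not a known role")
            if code not in FDI_CODES:
                raise SchemaError(f"schema token {token!r} is not a valid FDI code")
            if code in teeth:
                raise DuplicateAnnotationError(f"duplicate annotation for tooth {code}")
            teeth[code] = contour

    return AnnotationScene(
        image_width=int(doc["imageWidth"]),
        image_height=int(doc["imageHeight"]),
        image_path=str(doc.get("imagePath", "")),
        teeth=teeth,
        cej=cej,
        bone=bone,
        warnings=unmapped,
    )


def write_labelme(scene: AnnotationScene) -> str:
    """Serialize a scene back to a LabelMe JSON document (round-trip safe)."""
    shapes = []
    for _, _, contour in scene.iter_contours():
        shapes.append(
            {
                "label": contour.label,
                "points": [[float(x), float(y)] for x, y in contour.points],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
        )
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": scene.image_path,
        "imageHeight": scene.image_height,
        "imageWidth": scene.image_width,
    }
    return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# YOLO segmentation export
# ---------------------------------------------------------------------------

def teeth_class_map() -> dict[str, int]:
    """FDI codes sorted ascending -> classes 0..31."""
    return {str(code): i for i, code in enumerate(sorted(FDI_CODES))}


def bone_class_map() -> dict[str, int]:
    return {BONE_LABEL: 0}


def cej_class_map() -> dict[str, int]:
    return {CEJ_UPPER_LABEL: 0, CEJ_LOWER_LABEL: 1}


def to_yolo_segmentation(
    scene: AnnotationScene, class_map: Mapping[str, int]
) -> list[str]:
    """Convert a scene to YOLO segmentation label lines.

    One line per contour: class index followed by the polygon vertices
    normalized to [0, 1] (x / width, y / height), vertex order preserved.
    Every contour label must appear in ``class_map``.
    """
    lines: list[str] = []
    w, h = float(scene.image_width), float(scene.image_height)
    for _, _, contour in scene.iter_contours():
        if contour.label not in class_map:
            raise SchemaError(f"label {contour.label!r} missing from class map")
        cls = class_map[contour.label]
        coords: list[str] = []
        for x, y in contour.points:
            coords.append(str(float(x) / w))
            coords.append(str(float(y) / h))
        lines.append(f"{cls} " + " ".join(coords))
    return lines


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(contour: PolygonContour, width: int, height: int) -> np.ndarray:
    """Rasterize a polygon to a boolean mask of shape ``(height, width)``.

    A pixel with index (row, col) covers the unit square
    [col, col+1] x [row, row+1]; it is set iff its center
    (col + 0.5, row + 0.5) lies inside or on the boundary of the filled
    polygon. Degenerate (zero-area) or fully out-of-frame polygons yield an
    empty mask with a warning.
    """
    if width <= 0 or height <= 0:
        raise SceneValidationError("mask dimensions must be positive")
    mask = np.zeros((height, width), dtype=bool)
    poly = contour.as_shapely()
    if poly.is_empty or poly.area == 0:
        warnings.warn(
            f"contour {contour.label!r} has zero area; empty mask", stacklevel=2
        )
        return mask
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx - 1)), 0)
    c1 = min(int(np.ceil(maxx + 1)), width)
    r0 = max(int(np.floor(miny - 1)), 0)
    r1 = min(int(np.ceil(maxy + 1)), height)
    if c0 >= c1 or r0 >= r1:
        warnings.warn(
            f"contour {contour.label!r} lies outside the frame; empty mask",
            stacklevel=2,
        )
        return mask
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    shapely.prepare(poly)
    inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel())
    mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return mask


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    """A 75:15:10-style partition of item identifiers."""

    train: list
    validation: list
    test: list
    seed: int

    def as_dict(self) -> dict[str, list]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


def split_dataset(
    item_ids: Sequence,
    ratios: tuple[float, float, float] = (0.75, 0.15, 0.10),
    seed: int = 0,
) -> SplitResult:
    """Randomly partition items into train / validation / test.

    Items are shuffled with a seeded generator, then
    ``|test| = floor(test_ratio * N)`` and
    ``|validation| = floor(validation_ratio * N)``; the remainder goes to
    train. With 500 items and the default 75:15:10 ratios this reproduces
    exactly 375 / 75 / 50. Deterministic for a fixed seed.
    """
    items = list(item_ids)
    n = len(items)
    if n == 0:
        raise SplitError("cannot split an empty item list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError(f"ratios {ratios} do not sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [items[i] for i in order]
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_val - n_test
    return SplitResult(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
    )
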