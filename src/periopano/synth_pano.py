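"""Synthetic panoramic-like scenes with exact bone-loss ground truth.

Teeth are drawn as tapered hexagons (wide crown, narrowing root) along two
curved dental arches — maxillary crowns pointing down, mandibular crowns up,
matching panoramic orientation. Per tooth, the CEJ lies exactly at the
crown/root junction on the tooth axis; each jaw's CEJ contour is a thin band
whose coronal edge passes through every CEJ point. The bone contour is a
single polygon spanning the inter-arch region: its upper boundary is the
maxillary bone-level polyline and its lower boundary the mandibular one,
each passing each tooth's axis at exactly ``loss_fraction x root_length``
apical to the CEJ. Running the measurement geometry on an uncorrupted scene
therefore recovers the configured per-tooth RBL up to floating-point noise.

The generator does not attempt photorealism: no superimposed anatomy, no
restorations, and simple flat gray levels plus Gaussian noise. It exists to
give every downstream module a fully known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .aap_classifier import PatientRecord, stage_tooth
from .annotations_io import (
    BONE_LABEL,
    CEJ_LOWER_LABEL,
    CEJ_UPPER_LABEL,
    AnnotationScene,
    PolygonContour,
    write_labelme,
)
from .errors import GenerationError

#: Worst-tooth loss-fraction sampling bands per target stage, kept clear of
#: the 15% / 33% breakpoints so a target stage is unambiguous.
STAGE_FRACTION_BANDS = {
    "I": (0.04, 0.14),
    "II": (0.16, 0.32),
    "III_IV": (0.35, 0.75),
}

_GRAY_BACKGROUND = 170  # jaw bone
_GRAY_MOUTH = 70        # inter-arch space
_GRAY_TOOTH = 225
_FRAME_X = 20.0         # x where arch-wide polylines meet the frame side


@dataclass
class SyntheticSceneConfig:
    image_width: int = 800
    image_height: int = 440
    n_teeth_per_jaw: int = 8
    tooth_width: tuple[float, float] = (26.0, 34.0)
    crown_length: tuple[float, float] = (40.0, 55.0)
    root_length: tuple[float, float] = (90.0, 120.0)
    arch_curvature: float = 0.0003
    #: mapping FDI -> fraction in [0, 1], or a (low, high) sampling range
    per_tooth_loss_fraction: Mapping[int, float] | tuple[float, float] = (0.05, 0.6)
    tooth_tilt_range_deg: tuple[float, float] = (-6.0, 6.0)
    noise_sigma: float = 3.0
    cej_band_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_teeth_per_jaw <= 16:
            raise ValueError("n_teeth_per_jaw must be in 1..16")
        if isinstance(self.per_tooth_loss_fraction, Mapping):
            bad = [f for f in self.per_tooth_loss_fraction.values()
                   if not 0.0 <= f <= 1.0]
            if bad:
                raise ValueError(f"loss fractions outside [0, 1]: {bad}")
        for rng_ in (self.tooth_width, self.crown_length, self.root_length):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid geometry range {rng_}")


@dataclass
class SyntheticTruth:
    scene: AnnotationScene
    true_rbl_percent: dict[int, float]
    patient: PatientRecord
    image_id: str = ""


def fdi_codes_for_jaw(n: int, jaw: str) -> list[int]:
    """FDI codes for n teeth of one jaw, left-to-right in image order.

    Codes are assigned outward from the midline: e.g. 8 maxillary teeth ->
    [14, 13, 12, 11, 21, 22, 23, 24]. Quadrant 1 (upper right) and 4 (lower
    right) sit on the image left, matching panoramic convention.
    """
    quadrants = (1, 2) if jaw == "maxillary" else (4, 3)
    n_left = (n + 1) // 2
    n_right = n - n_left
    left = [quadrants[0] * 10 + p for p in range(n_left, 0, -1)]
    right = [quadrants[1] * 10 + p for p in range(1, n_right + 1)]
    return left + right


def _rotation(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def generate_scene(
    config: SyntheticSceneConfig | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Generate one panoramic-like image with its exact ground truth.

    Deterministic for a fixed ``config.seed``: identical image pixels,
    polygons, loss fractions and sampled patient record.
    """
    cfg = config or SyntheticSceneConfig()
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.image_width, cfg.image_height
    center_x = w / 2.0
    y_cej_base = {"maxillary": 0.36 * h, "mandibular": 0.64 * h}
    half_band = cfg.cej_band_px / 2.0

    def cej_y(jaw: str, x: float) -> float:
        # arches curve away from the occlusal plane toward the image edges
        bow = cfg.arch_curvature * (x - center_x) ** 2
        if jaw == "maxillary":
            return y_cej_base[jaw] - bow
        return y_cej_base[jaw] + bow

    margin = 60.0
    step = (w - 2 * margin) / cfg.n_teeth_per_jaw
    teeth: dict[int, PolygonContour] = {}
    cej_points: dict[str, list[np.ndarray]] = {"maxillary": [], "mandibular": []}
    bone_points: dict[str, list[np.ndarray]] = {"maxillary": [], "mandibular": []}
    true_rbl: dict[int, float] = {}
    placed: dict[str, list] = {"maxillary": [], "mandibular": []}

    for jaw in ("maxillary", "mandibular"):
        codes = fdi_codes_for_jaw(cfg.n_teeth_per_jaw, jaw)
        apical_sign = -1.0 if jaw == "maxillary" else 1.0
        for i, code in enumerate(codes):
            cx = margin + step * (i + 0.5)
            cej = np.array([cx, cej_y(jaw, cx)])
            width = rng.uniform(*cfg.tooth_width)
            crown_len = rng.uniform(*cfg.crown_length)
            root_len = rng.uniform(*cfg.root_length)
            tilt = rng.uniform(*cfg.tooth_tilt_range_deg)
            if isinstance(cfg.per_tooth_loss_fraction, Mapping):
                frac = float(cfg.per_tooth_loss_fraction.get(code, 0.0))
            else:
                frac = float(rng.uniform(*cfg.per_tooth_loss_fraction))

            rot = _rotation(tilt)
            u = rot @ np.array([0.0, apical_sign])   # unit apical direction
            v = rot @ np.array([1.0, 0.0])           # unit mesio-distal direction
            crown_base = cej - crown_len * u
            apex_base = cej + root_len * u
            poly = np.array([
                crown_base - (width / 2) * v,
                crown_base + (width / 2) * v,
                cej + (width / 2) * v,
                apex_base + (width / 8) * v,
                apex_base - (width / 8) * v,
                cej - (width / 2) * v,
            ])
            if np.any(poly[:, 0] < 0) or np.any(poly[:, 0] > w) or \
               np.any(poly[:, 1] < 0) or np.any(poly[:, 1] > h):
                raise GenerationError(
                    f"tooth {code} falls outside the frame; reduce crown/root "
                    "lengths, curvature or n_teeth_per_jaw"
                )
            teeth[code] = PolygonContour(str(code), poly)
            cej_points[jaw].append(cej)
            bone_points[jaw].append(cej + frac * root_len * u)
            true_rbl[code] = 100.0 * frac
            placed[jaw].append(poly)

    _check_overlap(placed)

    # CEJ bands: coronal edge exactly through the per-tooth CEJ points
    cej_contours: dict[str, PolygonContour] = {}
    for jaw, label in (("maxillary", CEJ_UPPER_LABEL), ("mandibular", CEJ_LOWER_LABEL)):
        pts = cej_points[jaw]
        coronal = [np.array([_FRAME_X, cej_y(jaw, _FRAME_X)])] + pts + [
            np.array([w - _FRAME_X, cej_y(jaw, w - _FRAME_X)])
        ]
        apical_sign = -1.0 if jaw == "maxillary" else 1.0
        offset = np.array([0.0, apical_sign * 2 * half_band])  # band thickness
        apical = [p + offset for p in reversed(coronal)]
        band = np.array(coronal + apical)
        band[:, 1] = np.clip(band[:, 1], 0.0, h)
        cej_contours[jaw] = PolygonContour(label, band)

    # single bone polygon: maxillary bone line (top) + mandibular (bottom)
    top = bone_points["maxillary"]
    bottom = bone_points["mandibular"]
    top_line = [np.array([_FRAME_X, top[0][1]])] + top + [
        np.array([w - _FRAME_X, top[-1][1]])
    ]
    bottom_line = [np.array([_FRAME_X, bottom[0][1]])] + bottom + [
        np.array([w - _FRAME_X, bottom[-1][1]])
    ]
    bone_poly = np.array(top_line + list(reversed(bottom_line)))
    bone_contour = PolygonContour(BONE_LABEL, bone_poly)

    scene = AnnotationScene(
        image_width=w, image_height=h,
        teeth=teeth, cej=cej_contours, bone=bone_contour,
    )

    patient = PatientRecord(
        age=int(rng.integers(25, 76)),
        cigarettes_per_day=int(rng.integers(1, 21)) if rng.random() < 0.3 else 0,
        has_diabetes=(diabetic := rng.random() < 0.15),
        hba1c_percent=round(float(rng.uniform(5.5, 9.5)), 1) if diabetic else None,
    )

    image = _render(scene, cfg, rng)
    return image, SyntheticTruth(
        scene=scene, true_rbl_percent=true_rbl, patient=patient
    )


def _check_overlap(placed: dict[str, list]) -> None:
    from shapely.geometry import Polygon as SPoly

    for jaw, polys in placed.items():
        for a, b in zip(polys, polys[1:]):
            if SPoly(a).intersection(SPoly(b)).area > 1e-6:
                raise GenerationError(
                    f"adjacent {jaw} teeth overlap; reduce tooth_width or "
                    "tooth_tilt_range_deg, or lower n_teeth_per_jaw"
                )


def _render(
    scene: AnnotationScene, cfg: SyntheticSceneConfig, rng: np.random.Generator
) -> np.ndarray:
    img = Image.new("L", (scene.image_width, scene.image_height), _GRAY_BACKGROUND)
    draw = ImageDraw.Draw(img)
    draw.polygon([tuple(p) for p in scene.bone.points], fill=_GRAY_MOUTH)
    for contour in scene.teeth.values():
        draw.polygon([tuple(p) for p in contour.points], fill=_GRAY_TOOTH)
    arr = np.asarray(img, dtype=float)
    if cfg.noise_sigma > 0:
        arr = arr + rng.normal(0.0, cfg.noise_sigma, arr.shape)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _target_stage_counts(n: int, stage_mix: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of n images to the three stages."""
    exact = [n * p for p in stage_mix]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    remainders = sorted(
        range(3), key=lambda i: exact[i] - base[i], reverse=True
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def generate_dataset(
    n_images: int,
    out_dir: str | Path,
    config: SyntheticSceneConfig | None = None,
    seed: int = 0,
    stage_mix: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Write ``n_images`` synthetic scenes (PNG + LabelMe JSON each) plus one
    ``truth.csv`` holding per-tooth true RBL, stage and the sampled patient
    record. Returns the truth table.

    ``stage_mix`` targets the worst-tooth stage composition (fractions for
    Stage I / II / III_IV), apportioned by largest remainder so the realized
    counts match the targets exactly. Regeneration with the same seed
    reproduces identical files.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cfg = config or SyntheticSceneConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)

    stage_targets: list[str | None] = [None] * n_images
    if stage_mix is not None:
        counts = _target_stage_counts(n_images, stage_mix)
        labels = (["I"] * counts[0] + ["II"] * counts[1] + ["III_IV"] * counts[2])
        order = rng.permutation(n_images)
        stage_targets = [labels[i] for i in order]

    rows = []
    for i in range(n_images):
        image_id = f"scene_{i:03d}"
        loss = cfg.per_tooth_loss_fraction
        if stage_targets[i] is not None:
            loss = _fractions_for_stage(
                stage_targets[i], cfg.n_teeth_per_jaw,
                np.random.default_rng(int(child_seeds[i]) ^ 0x5F5F),
            )
        child_cfg = dataclasses.replace(
            cfg, seed=int(child_seeds[i]), per_tooth_loss_fraction=loss
        )
        image, truth = generate_scene(child_cfg)
        truth.image_id = image_id
        truth.scene.image_path = f"{image_id}.png"

        Image.fromarray(image, mode="L").save(out / f"{image_id}.png")
        (out / f"{image_id}.json").write_text(write_labelme(truth.scene))
        for code in sorted(truth.true_rbl_percent):
            rbl = truth.true_rbl_percent[code]
            rows.append(
                {
                    "image_id": image_id,
                    "fdi": code,
                    "true_rbl_percent": rbl,
                    "stage": stage_tooth(rbl).token,
                    "age": truth.patient.age,
                    "cigarettes_per_day": truth.patient.cigarettes_per_day,
                    "has_diabetes": truth.patient.has_diabetes,
                    "hba1c_percent": truth.patient.hba1c_percent,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "truth.csv", index=False)
    return table


def _fractions_for_stage(
    stage: str, n_per_jaw: int, rng: np.random.Generator
) -> dict[int, float]:
    """Per-tooth loss fractions whose worst tooth lands in the target stage."""
    lo, hi = STAGE_FRACTION_BANDS[stage]
    worst = float(rng.uniform(lo, hi))
    codes = fdi_codes_for_jaw(n_per_jaw, "maxillary") + fdi_codes_for_jaw(
        n_per_jaw, "mandibular"
    )
    worst_code = codes[int(rng.integers(0, len(codes)))]
    fractions = {
        code: float(rng.uniform(0.02, worst)) for code in codes
    }
    fractions[worst_code] = worst
    return fractions


# ---------------------------------------------------------------------------
# Controlled corruption (fake "predicted" segmentations)
# ---------------------------------------------------------------------------

def corrupt_scene(
    truth: SyntheticTruth,
    mode: str,
    magnitude: float,
    seed: int = 0,
) -> AnnotationScene:
    """Degrade a ground-truth scene to emulate segmentation-model error.

    ``dilate_bone`` shifts the bone boundary coronally by ``magnitude``
    pixels on both jaws — lowering every measured RBL, the understaging
    failure mode. ``drop_cej`` removes the maxillary CEJ band (both bands if
    ``magnitude >= 2``), making the affected teeth unmeasurable.
    ``jitter_polygons`` adds uniform +-magnitude noise to every vertex of
    every contour.
    """
    scene = truth.scene
    w, h = scene.image_width, scene.image_height

    def copy_contour(ct: PolygonContour) -> PolygonContour:
        return PolygonContour(ct.label, ct.points.copy())

    teeth = {c: copy_contour(t) for c, t in scene.teeth.items()}
    cej = {r: copy_contour(t) for r, t in scene.cej.items()}
    bone = copy_contour(scene.bone) if scene.bone is not None else None

    if mode == "dilate_bone":
        if bone is not None:
            pts = bone.points
            upper = pts[:, 1] < h / 2.0  # maxillary boundary: move down (coronal)
            pts[upper, 1] += magnitude
            pts[~upper, 1] -= magnitude
            pts[:, 1] = np.clip(pts[:, 1], 0.0, h)
    elif mode == "drop_cej":
        cej.pop("maxillary", None)
        if magnitude >= 2:
            cej.pop("mandibular", None)
    elif mode == "jitter_polygons":
        rng = np.random.default_rng(seed)
        for contour in [*teeth.values(), *cej.values(),
                        *([bone] if bone is not None else [])]:
            contour.points += rng.uniform(
                -magnitude, magnitude, contour.points.shape
            )
            contour.points[:, 0] = np.clip(contour.points[:, 0], 0.0, w)
            contour.points[:, 1] = np.clip(contour.points[:, 1], 0.0, h)
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")

    return AnnotationScene(
        image_width=w, image_height=h, image_path=scene.image_path,
        teeth=teeth, cej=cej, bone=bone,
    )
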