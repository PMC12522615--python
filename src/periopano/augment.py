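"""Annotation-consistent training-time augmentation.

Each input image yields five variants. Per variant, additive Gaussian noise
(intensity drawn from 0-5% of the dynamic range) is applied first; then k
transforms (k uniform on {0..4}, drawn without replacement) from a pool of
six: checkerboard alpha blending, affine rotation (+-10 deg), gamma contrast
(0.5-1.75), brightness shift (+-30), salt-and-pepper noise (3% of pixels),
and motion blur (10x10 kernel, angle +-45 deg). Rotation is the only
geometric transform: it rotates every annotation polygon about the image
center with the exact closed-form map used to warp the image, clipping
coordinates to the frame; photometric transforms leave annotations
untouched.

Validation-set augmentation is the same pipeline at reduced intensity: each
parameter's deviation from its identity value (noise 0, angle 0, gamma 1,
shift 0, fraction 0, blend alpha 0) is multiplied by
``validation_intensity_scale``, so scale 1 reproduces the training
distribution and scale 0 yields exact identity variants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .annotations_io import AnnotationScene, PolygonContour

_DYNAMIC_RANGE = 255.0


@dataclass
class AugmentationConfig:
    gaussian_noise_intensity_range: tuple[float, float] = (0.0, 0.05)
    max_transforms: int = 4
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    gamma_range: tuple[float, float] = (0.5, 1.75)
    brightness_shift_range: tuple[float, float] = (-30.0, 30.0)
    salt_pepper_fraction: float = 0.03
    motion_blur_kernel: int = 10
    motion_blur_angle_range_deg: tuple[float, float] = (-45.0, 45.0)
    blend_cell_size_range: tuple[int, int] = (8, 32)
    blend_alpha_range: tuple[float, float] = (0.2, 0.8)
    blend_contrast_range: tuple[float, float] = (0.8, 1.3)
    blend_brightness_range: tuple[float, float] = (-20.0, 20.0)
    variants_per_image: int = 5
    seed: int = 0
    validation_intensity_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.variants_per_image < 1:
            raise ValueError("variants_per_image must be >= 1")
        if not 0.0 < self.validation_intensity_scale <= 1.0 and (
            self.validation_intensity_scale != 0.0
        ):
            raise ValueError("validation_intensity_scale must be in [0, 1]")


def _toward(value: float, identity: float, scale: float) -> float:
    """Scale a drawn parameter's deviation from its identity value."""
    return identity + (value - identity) * scale


def rotate_with_annotations(
    image: np.ndarray, scene: AnnotationScene, angle_deg: float
) -> tuple[np.ndarray, AnnotationScene]:
    """Rotate image and polygons consistently about the image center.

    The forward point map is p' = R(p - c) + c with c = (width/2, height/2)
    and R the rotation by ``angle_deg`` (positive = counter-clockwise in x,y
    coordinates; on a y-down image this appears clockwise). The image is
    warped with the exact inverse map (bilinear interpolation); polygon
    vertices use the closed-form forward map and are clipped to the frame.
    """
    h, w = image.shape[:2]
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    center_xy = np.array([w / 2.0, h / 2.0])

    # inverse map in (row, col) space for scipy.ndimage.affine_transform
    a_rc = np.array([[c, -s], [s, c]])
    center_rc = np.array([h / 2.0, w / 2.0])
    offset = center_rc - a_rc @ center_rc
    warped = ndimage.affine_transform(
        np.asarray(image, dtype=float), a_rc, offset=offset, order=1,
        mode="constant", cval=0.0,
    )

    rot_xy = np.array([[c, -s], [s, c]])

    def _transform(contour: PolygonContour) -> PolygonContour:
        pts = (contour.points - center_xy) @ rot_xy.T + center_xy
        pts[:, 0] = np.clip(pts[:, 0], 0.0, w)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, h)
        return PolygonContour(contour.label, pts)

    new_scene = AnnotationScene(
        image_width=scene.image_width,
        image_height=scene.image_height,
        image_path=scene.image_path,
        teeth={code: _transform(ct) for code, ct in scene.teeth.items()},
        cej={role: _transform(ct) for role, ct in scene.cej.items()},
        bone=_transform(scene.bone) if scene.bone is not None else None,
    )
    return warped, new_scene


def _motion_blur_kernel(size: int, angle_deg: float) -> np.ndarray:
    """A normalized line kernel of the given size and orientation."""
    kernel = np.zeros((size, size))
    center = (size - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    half = center
    for t in np.linspace(-half, half, 10 * size + 1):
        col = int(round(center + t * np.cos(theta)))
        row = int(round(center + t * np.sin(theta)))
        if 0 <= row < size and 0 <= col < size:
            kernel[row, col] = 1.0
    return kernel / kernel.sum()


def _checkerboard(shape: tuple[int, int], cell: int) -> np.ndarray:
    rows = (np.arange(shape[0]) // cell) % 2
    cols = (np.arange(shape[1]) // cell) % 2
    return (rows[:, None] + cols[None, :]) % 2 == 0


def _clip(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, _DYNAMIC_RANGE)


def _identity_scene_copy(scene: AnnotationScene) -> AnnotationScene:
    return AnnotationScene(
        image_width=scene.image_width,
        image_height=scene.image_height,
        image_path=scene.image_path,
        teeth={c: PolygonContour(t.label, t.points.copy())
               for c, t in scene.teeth.items()},
        cej={r: PolygonContour(t.label, t.points.copy())
             for r, t in scene.cej.items()},
        bone=(PolygonContour(scene.bone.label, scene.bone.points.copy())
              if scene.bone is not None else None),
    )


def _augment(
    image: np.ndarray,
    scene: AnnotationScene,
    config: AugmentationConfig,
    scale: float,
) -> list[tuple[np.ndarray, AnnotationScene]]:
    img_in = np.asarray(image)
    if img_in.size == 0:
        raise ValueError("empty image")
    if img_in.shape[:2] != (scene.image_height, scene.image_width):
        raise ValueError("image dimensions do not match the scene")
    rng = np.random.default_rng(config.seed)
    variants: list[tuple[np.ndarray, AnnotationScene]] = []

    for _ in range(config.variants_per_image):
        img = img_in.astype(float)
        out_scene = _identity_scene_copy(scene)

        intensity = rng.uniform(*config.gaussian_noise_intensity_range) * scale
        img = _clip(img + rng.normal(0.0, intensity * _DYNAMIC_RANGE, img.shape))

        k = int(rng.integers(0, config.max_transforms + 1))
        chosen = sorted(rng.choice(6, size=k, replace=False).tolist()) if k else []
        # fixed application order regardless of draw order, for reproducibility
        for idx in chosen:
            if idx == 0:  # blend-alpha regular grid
                cell = int(round(rng.uniform(*config.blend_cell_size_range)))
                alpha = rng.uniform(*config.blend_alpha_range) * scale
                contrast = _toward(rng.uniform(*config.blend_contrast_range), 1.0, scale)
                bright = rng.uniform(*config.blend_brightness_range) * scale
                perturbed = _clip(img * contrast + bright)
                mask = _checkerboard(img.shape[:2], max(cell, 1)).astype(float)
                img = _clip(img * (1 - alpha * mask) + perturbed * (alpha * mask))
            elif idx == 1:  # affine rotation (moves annotations)
                angle = rng.uniform(*config.rotation_range_deg) * scale
                img, out_scene = rotate_with_annotations(img, out_scene, angle)
                img = _clip(img)
            elif idx == 2:  # gamma contrast
                gamma = _toward(rng.uniform(*config.gamma_range), 1.0, scale)
                img = _DYNAMIC_RANGE * np.power(_clip(img) / _DYNAMIC_RANGE, gamma)
            elif idx == 3:  # brightness shift
                img = _clip(img + rng.uniform(*config.brightness_shift_range) * scale)
            elif idx == 4:  # salt and pepper
                frac = config.salt_pepper_fraction * scale
                n_px = int(round(frac * img.size))
                if n_px:
                    flat = img.reshape(-1)
                    pos = rng.choice(img.size, size=n_px, replace=False)
                    vals = rng.integers(0, 2, size=n_px) * _DYNAMIC_RANGE
                    flat[pos] = vals
            elif idx == 5:  # motion blur, blended in by the intensity scale
                angle = rng.uniform(*config.motion_blur_angle_range_deg)
                kernel = _motion_blur_kernel(config.motion_blur_kernel, angle)
                blurred = ndimage.convolve(img, kernel, mode="nearest")
                img = _clip((1.0 - scale) * img + scale * blurred)

        out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        variants.append((out, out_scene))
    return variants


def augment_image(
    image: np.ndarray, scene: AnnotationScene, config: AugmentationConfig | None = None
) -> list[tuple[np.ndarray, AnnotationScene]]:
    """Training-set augmentation: exactly ``variants_per_image`` variants.

    Fully reproducible for a fixed ``config.seed``.
    """
    return _augment(image, scene, config or AugmentationConfig(), scale=1.0)


def augment_validation(
    image: np.ndarray, scene: AnnotationScene, config: AugmentationConfig | None = None
) -> list[tuple[np.ndarray, AnnotationScene]]:
    """Validation-set augmentation at reduced intensity.

    Identical to :func:`augment_image` with every parameter's deviation from
    identity multiplied by ``config.validation_intensity_scale``.
    """
    config = config or AugmentationConfig()
    return _augment(image, scene, config, scale=config.validation_intensity_scale)
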