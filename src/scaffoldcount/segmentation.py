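"""Automated nucleus segmentation of projected optical-section columns.

The automated counting path mirrors a three-step workflow: (a) convert the
acquired stack to 8 bit and flatten it by maximum-intensity z-projection,
(b) classify pixels with a shallow, trainable classifier (a bagged-tree
learner over a small bank of linear filter responses, in the spirit of
trainable-segmentation plugins such as Labkit), and (c) label the resulting
binary mask into objects, discarding sub-nuclear specks and optionally
splitting touching nuclei with a distance-transform watershed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigError, FormatError, InvalidSpecError

DEFAULT_NUCLEUS_RADIUS_UM = 5.0

#: (filter family, scale in um) pairs: 4 families x 3 scales
#: (0.5, 1 and 2 x the nominal 5-um nucleus radius).
DEFAULT_FEATURE_CONFIG: tuple[tuple[str, float], ...] = tuple(
    (name, scale)
    for name in ("gaussian", "dog", "gradient", "laplacian")
    for scale in (2.5, 5.0, 10.0)
)

_FILTER_NAMES = ("gaussian", "dog", "gradient", "laplacian")


@dataclass
class ImageStack:
    """A calibrated 3D intensity grid, axis order (z, y, x)."""

    voxels: np.ndarray
    pixel_size: float  # um per pixel, XY
    z_spacing: float  # um between sections
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise InvalidSpecError("voxels must be a non-empty (z, y, x) grid")
        if self.bit_depth not in (8, 16):
            raise InvalidSpecError("bit_depth must be 8 or 16")
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise InvalidSpecError("pixel_size and z_spacing must be positive")

    @property
    def n_sections(self) -> int:
        return self.voxels.shape[0]


@dataclass
class LabeledMask:
    """Integer-labelled objects (0 = background), 2D or 3D.

    ``provenance`` records whether the mask came from a z-projection
    ("projection") or from a single optical section ("section").
    """

    labels: np.ndarray
    n_objects: int
    provenance: str = "projection"

    def __post_init__(self) -> None:
        if self.provenance not in ("projection", "section"):
            raise InvalidSpecError("provenance must be 'projection' or 'section'")


@dataclass
class SegmentationModel:
    """A trained shallow pixel classifier plus the feature bank it expects."""

    feature_config: tuple[tuple[str, float], ...]
    learner: RandomForestClassifier
    pixel_size: float  # um per pixel the features were computed at
    training_meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "SegmentationModel":
        model = joblib.load(path)
        if not isinstance(model, SegmentationModel):
            raise FormatError(f"{path} does not contain a SegmentationModel")
        return model


def to_8bit(stack: ImageStack) -> ImageStack:
    """Linearly rescale [global min, global max] to [0, 255].

    A constant stack (max == min) maps to all zeros: an empty field is dark.
    Idempotent on stacks that already span the full 8-bit range.
    """
    v = stack.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros(v.shape, dtype=np.uint8)
    elif v.dtype in (np.uint8, np.uint16):
        # integer input: rescale through a lookup table (exact and fast)
        ilo, ihi = int(lo), int(hi)
        lut = np.zeros(ihi + 1, dtype=np.uint8)
        lut[ilo:] = np.rint(
            (np.arange(ilo, ihi + 1, dtype=np.float64) - lo) * (255.0 / (hi - lo))
        ).astype(np.uint8)
        out = lut[v]
    else:
        out = np.rint(
            (v.astype(np.float64) - lo) * (255.0 / (hi - lo))
        ).astype(np.uint8)
    return ImageStack(out, stack.pixel_size, stack.z_spacing, bit_depth=8)


def max_project(stack: ImageStack) -> np.ndarray:
    """Pixelwise maximum over z; dominates every individual section."""
    return stack.voxels.max(axis=0)


def compute_features(
    image: np.ndarray,
    feature_config: Sequence[tuple[str, float]] = DEFAULT_FEATURE_CONFIG,
    pixel_size: float = 1.3,
) -> np.ndarray:
    """Per-pixel filter responses, shape (n_features, H, W).

    Scales are physical (um) and converted to pixel sigmas via ``pixel_size``.
    Families: "gaussian" (smoothing), "dog" (difference of Gaussians,
    sigma vs 1.6 sigma), "gradient" (Gaussian gradient magnitude) and
    "laplacian" (Gaussian Laplacian).
    """
    if not feature_config:
        raise ConfigError("feature_config must contain at least one entry")
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ConfigError("compute_features expects a single 2D image")
    planes = []
    for name, scale_um in feature_config:
        sigma = scale_um / pixel_size
        if name == "gaussian":
            planes.append(ndi.gaussian_filter(img, sigma))
        elif name == "dog":
            planes.append(
                ndi.gaussian_filter(img, sigma) - ndi.gaussian_filter(img, 1.6 * sigma)
            )
        elif name == "gradient":
            planes.append(ndi.gaussian_gradient_magnitude(img, sigma))
        elif name == "laplacian":
            planes.append(ndi.gaussian_laplace(img, sigma))
        else:
            raise ConfigError(
                f"unknown filter {name!r}; expected one of {_FILTER_NAMES}"
            )
    return np.stack(planes)


def train_pixel_classifier(
    images: Sequence[np.ndarray],
    label_masks: Sequence[np.ndarray],
    feature_config: Sequence[tuple[str, float]] = DEFAULT_FEATURE_CONFIG,
    pixel_size: float = 1.3,
    seed: int = 0,
    n_trees: int = 100,
) -> SegmentationModel:
    """Fit a bagged-tree pixel classifier on sparsely labelled images.

    ``label_masks`` use 0 = unlabelled, 1 = background, 2 = foreground
    (nucleus).  Only labelled pixels enter the fit.  Training is deterministic
    given ``seed``.
    """
    if len(images) != len(label_masks) or not images:
        raise ConfigError("need equally many images and label masks")
    X, y = [], []
    for img, lab in zip(images, label_masks):
        lab = np.asarray(lab)
        if lab.shape != np.asarray(img).shape:
            raise ConfigError("label mask shape must match image shape")
        feats = compute_features(img, feature_config, pixel_size)
        sel = lab > 0
        if sel.any():
            X.append(feats[:, sel].T)
            y.append(lab[sel])
    if not X:
        raise InvalidSpecError("no labelled pixels provided")
    X = np.concatenate(X)
    y = np.concatenate(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidSpecError(
            "training labels must contain both foreground and background pixels"
        )
    learner = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    learner.fit(X, y)
    return SegmentationModel(
        feature_config=tuple(feature_config),
        learner=learner,
        pixel_size=pixel_size,
        training_meta={
            "n_images": len(images),
            "n_labeled_pixels": int(y.size),
            "seed": seed,
            "n_trees": n_trees,
        },
    )


def sample_training_labels(
    truth_mask: np.ndarray,
    n_per_class: int = 500,
    seed: int = 0,
    near_fraction: float = 0.5,
    ring_px: int = 3,
) -> np.ndarray:
    """Turn a full ground-truth mask into sparse training scribbles.

    Emulates how an annotator labels: foreground strokes inside nuclei and
    background strokes both far away and immediately around nuclei (the
    ``near_fraction`` of background labels comes from a ``ring_px``-wide ring
    around objects -- without it a classifier never sees the bright halo just
    outside a nucleus and systematically over-segments).  Returns a label
    image: 0 unlabelled, 1 background, 2 foreground.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    lab = np.zeros(truth_mask.shape, dtype=np.uint8)
    outer_ring = ndi.binary_dilation(truth_mask, iterations=ring_px) & ~truth_mask
    inner_ring = truth_mask & ~ndi.binary_erosion(truth_mask, iterations=1)
    n_near = int(round(n_per_class * near_fraction))
    pools = (
        (np.argwhere(inner_ring), n_near, 2),
        (np.argwhere(truth_mask & ~inner_ring), n_per_class - n_near, 2),
        (np.argwhere(outer_ring), n_near, 1),
        (np.argwhere(~truth_mask & ~outer_ring), n_per_class - n_near, 1),
    )
    for pool, n, cls in pools:
        if len(pool) and n > 0:
            pick = pool[rng.choice(len(pool), min(n, len(pool)), replace=False)]
            lab[tuple(pick.T)] = cls
    return lab


def segment(
    image: np.ndarray,
    model: SegmentationModel | None = None,
    threshold_fallback: float | str | None = None,
) -> np.ndarray:
    """Per-pixel foreground decision; returns a boolean mask.

    With a trained ``model``, pixels classified as foreground (class 2) are
    kept.  Without one, a global threshold is applied: ``"otsu"`` or a fixed
    intensity; pixels >= threshold are foreground.
    """
    img = np.asarray(image)
    if model is not None:
        feats = compute_features(img, model.feature_config, model.pixel_size)
        flat = feats.reshape(feats.shape[0], -1).T
        pred = model.learner.predict(flat).reshape(img.shape)
        return pred == 2
    if threshold_fallback is None:
        raise ConfigError("segment needs a trained model or a threshold fallback")
    if isinstance(threshold_fallback, str):
        if threshold_fallback != "otsu":
            raise ConfigError(f"unknown threshold mode {threshold_fallback!r}")
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(img)
        return img > thr
    return img >= threshold_fallback


def default_min_area_px(
    pixel_size: float, nucleus_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM
) -> int:
    """Area (px) of a disc of half the nominal nucleus radius; speck filter."""
    r_px = (nucleus_radius_um / 2.0) / pixel_size
    return max(1, int(round(np.pi * r_px**2)))


def label_and_filter(
    mask: np.ndarray,
    min_area_px: int = 0,
    split_touching: bool = False,
    nucleus_radius_px: float | None = None,
) -> LabeledMask:
    """Label a binary mask into objects (8-connectivity) and filter specks.

    Components smaller than ``min_area_px`` are dropped.  With
    ``split_touching``, merged blobs are split by a watershed on the distance
    transform, seeded at distance maxima at least one nucleus radius apart
    (``nucleus_radius_px``, default 3 px).  Labels are renumbered 1..n.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise FormatError("label_and_filter expects a 2D binary mask")
    if split_touching and mask.any():
        dist = ndi.distance_transform_edt(mask)
        # floor of 3 px: pixelated boundaries create spurious distance maxima
        # within ~2 px of the genuine ones, which would over-split nuclei
        min_dist = max(3, int(round(nucleus_radius_px if nucleus_radius_px else 3)))
        peaks = peak_local_max(
            dist, min_distance=min_dist, labels=measure.label(mask, connectivity=2),
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers=markers, mask=mask, connectivity=2)
    else:
        labels = measure.label(mask, connectivity=2)
    if min_area_px > 0 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
    labels, n = relabel_consecutive(labels)
    return LabeledMask(labels=labels, n_objects=n, provenance="projection")


def relabel_consecutive(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber nonzero labels to 1..n (order-preserving)."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels], int(ids.size)
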