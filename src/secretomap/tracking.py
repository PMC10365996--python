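"""Cell segmentation and tracking inside a microwell.

A random-forest pixel classifier (100 trees by default) is trained from
sparse human (or simulator) labels on the multi-scale feature bank of
:mod:`secretomap.features`.  Its output is a per-pixel *background*
probability map (0 = certainly cell, 1 = certainly background) which is
mean-filtered, thresholded with Otsu's method, and accumulated over time
into a cumulative mask: every pixel the motile cell ever occupied, to be
excluded from the secretion maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .exceptions import CompatibilityError, TrainingError
from .features import DERIVATIVE_SCALES, GAUSSIAN_SCALES, FeatureStack, compute_pixel_features
from .io import AcquisitionMeta, object_pixel_size, pixel_area

__all__ = [
    "LABEL_CELL",
    "LABEL_BACKGROUND",
    "PixelClassifier",
    "train_pixel_classifier",
    "predict_probability_map",
    "binarize_probability_map",
    "segment_stack",
    "accumulate_masks",
    "CellTrack",
    "track_metrics",
]

# Sparse-label image convention: 0 = unlabelled.
LABEL_CELL = 1
LABEL_BACKGROUND = 2


@dataclass
class PixelClassifier:
    """A trained cell/background random forest with its feature-bank contract."""

    model: RandomForestClassifier
    channel_names: tuple[str, ...]
    n_trees: int
    seed: int
    training_summary: dict = field(default_factory=dict)
    holdout_accuracy: float | None = None
    gaussian_scales: tuple[float, ...] = GAUSSIAN_SCALES
    derivative_scales: tuple[float, ...] = DERIVATIVE_SCALES


def train_pixel_classifier(
    features: list[FeatureStack],
    labels: list[np.ndarray],
    n_trees: int = 100,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> PixelClassifier:
    """Train a random forest from sparsely labelled pixels.

    ``labels[i]`` matches ``features[i]`` spatially; pixel values are 0
    (unlabelled), 1 (cell) or 2 (background).  Both classes must be present
    across the collection.  A stratified hold-out split reports accuracy;
    training is reproducible given ``seed``.
    """
    if len(features) != len(labels):
        raise TrainingError("one label image per feature stack required")
    xs, ys = [], []
    for feat, lab in zip(features, labels):
        lab = np.asarray(lab)
        if lab.shape != feat.data.shape[:2]:
            raise TrainingError(
                f"label shape {lab.shape} does not match image {feat.data.shape[:2]}"
            )
        marked = lab > 0
        xs.append(feat.as_table()[marked.ravel()])
        ys.append(lab[marked])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError(f"need labels for both classes, got classes {classes.tolist()}")

    x_train, x_test, y_train, y_test = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(x_train, y_train)
    accuracy = float(model.score(x_test, y_test))

    return PixelClassifier(
        model=model,
        channel_names=features[0].channel_names,
        n_trees=n_trees,
        seed=seed,
        training_summary={
            "n_cell": int(np.sum(y == LABEL_CELL)),
            "n_background": int(np.sum(y == LABEL_BACKGROUND)),
        },
        holdout_accuracy=accuracy,
    )


def predict_probability_map(
    classifier: PixelClassifier, image: np.ndarray | FeatureStack
) -> np.ndarray:
    """Per-pixel *background* probability in [0, 1] (0 means cell).

    Accepts a raw image (features are computed with the classifier's scale
    ladders) or a precomputed :class:`FeatureStack`, whose channel names
    must match the training bank.
    """
    if isinstance(image, FeatureStack):
        feat = image
        if feat.channel_names != classifier.channel_names:
            raise CompatibilityError("feature bank does not match the trained classifier")
    else:
        feat = compute_pixel_features(
            np.asarray(image),
            gaussian_scales=classifier.gaussian_scales,
            derivative_scales=classifier.derivative_scales,
        )
    proba = classifier.model.predict_proba(feat.as_table())
    bg_col = list(classifier.model.classes_).index(LABEL_BACKGROUND)
    return proba[:, bg_col].reshape(feat.data.shape[:2])


def binarize_probability_map(probmap: np.ndarray, filter_radius: int = 1) -> np.ndarray:
    """Smooth with an arithmetic mean filter, then Otsu-threshold.

    Pixels whose smoothed background probability falls *below* the Otsu
    threshold are flagged cell.  A constant map has no threshold: an empty
    mask is returned with a warning.
    """
    probmap = np.asarray(probmap, dtype=float)
    size = 2 * int(filter_radius) + 1
    smoothed = ndimage.uniform_filter(probmap, size=size, mode="reflect")
    if np.ptp(smoothed) == 0:
        warnings.warn("constant probability map: no Otsu threshold, empty cell mask")
        return np.zeros(probmap.shape, dtype=bool)
    threshold = threshold_otsu(smoothed)
    return smoothed < threshold


def segment_stack(
    classifier: PixelClassifier, frames: np.ndarray, filter_radius: int = 1
) -> np.ndarray:
    """Per-frame binary cell masks for a ``(T, H, W)`` stack."""
    return np.stack(
        [
            binarize_probability_map(
                predict_probability_map(classifier, frame), filter_radius
            )
            for frame in frames
        ]
    )


def accumulate_masks(masks: np.ndarray) -> np.ndarray:
    """Cumulative union of per-frame cell masks.

    ``cumulative[t]`` flags every pixel occupied by the cell in any frame up
    to and including ``t``; the result is monotone non-decreasing in ``t``.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3:
        raise ValueError(f"masks must be (T, H, W), got shape {masks.shape}")
    return np.logical_or.accumulate(masks, axis=0)


@dataclass
class CellTrack:
    """Per-frame morphology/motility of the (largest) cell in a well.

    Centroids and areas are in physical units (um, um^2).  ``msd_um2`` is
    the mean over t >= 1 of the squared displacement from the first frame.
    Frames with an empty mask carry NaN centroids and zero area; an
    all-empty track is flagged via ``empty``.
    """

    centroids_um: np.ndarray  # (T, 2) row/col, NaN where empty
    areas_um2: np.ndarray  # (T,)
    boundaries: list[np.ndarray | None]
    msd_um2: float
    empty: bool = False


def _largest_component(mask: np.ndarray) -> np.ndarray | None:
    if not mask.any():
        return None
    labelled = label(mask)
    regions = regionprops(labelled)
    biggest = max(regions, key=lambda r: r.area)
    return labelled == biggest.label


def track_metrics(masks: np.ndarray, meta: AcquisitionMeta) -> CellTrack:
    """Centroid trajectory, area series, boundary polygons and MSD.

    When a frame contains several connected components (debris, mitosis)
    only the largest is measured; daughters are still covered by the
    cumulative mask used for exclusion.
    """
    masks = np.asarray(masks, dtype=bool)
    scale = object_pixel_size(meta)
    area_px = pixel_area(meta)

    centroids = np.full((len(masks), 2), np.nan)
    areas = np.zeros(len(masks))
    boundaries: list[np.ndarray | None] = []
    for t, mask in enumerate(masks):
        component = _largest_component(mask)
        if component is None:
            boundaries.append(None)
            continue
        rows, cols = np.nonzero(component)
        centroids[t] = (rows.mean() * scale, cols.mean() * scale)
        areas[t] = component.sum() * area_px
        contours = find_contours(component.astype(float), 0.5)
        boundaries.append(max(contours, key=len) * scale if contours else None)

    valid = ~np.isnan(centroids[:, 0])
    if not valid.any():
        return CellTrack(centroids, areas, boundaries, msd_um2=float("nan"), empty=True)
    origin = centroids[np.argmax(valid)]
    later = valid.copy()
    later[np.argmax(valid)] = False
    if later.any():
        disp = centroids[later] - origin
        msd = float(np.mean(np.sum(disp**2, axis=1)))
    else:
        msd = 0.0
    return CellTrack(centroids, areas, boundaries, msd_um2=msd)
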