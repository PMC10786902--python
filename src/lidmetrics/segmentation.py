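"""Segmentation backend contract, desk-scale backends, and mIoU scoring.

Measurement only ever consumes a :class:`SegmentationBundle` of binary
masks, so any mask producer — the ground-truth oracle, the color-rule
classifier, mask files on disk, or an external neural-network stage —
is interchangeable behind :meth:`SegmentationBackend.segment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import MaskError, ParameterError, SegmentationBackendError
from .synthetic_scene import MASK_CLASSES, SCENE_COLORS

ALL_CLASSES = frozenset(MASK_CLASSES)


@dataclass
class SegmentationBundle:
    """Binary masks per class, all sharing one image frame.

    ``frame`` tags the coordinate frame the masks live in (``"original"``
    or ``"resized"``); downstream morphometry requires ``"original"``.
    """

    masks: dict[str, np.ndarray]
    frame: str = "original"

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise MaskError(f"masks must share dimensions, got {shapes}")
        for name, m in self.masks.items():
            if m.dtype != bool:
                self.masks[name] = m.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def classes(self) -> set[str]:
        return set(self.masks)


@dataclass(frozen=True)
class SegmentationScore:
    per_class_iou: dict[str, float]
    mean_iou: float


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Measurement assumes a single object per class; stray pixels from noisy
    backends are dropped here.  Empty masks pass through unchanged.
    """
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask.astype(bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def despeckle(mask: np.ndarray, min_px: int = 20, min_frac: float = 0.005) -> np.ndarray:
    """Drop noise specks but keep every substantial component.

    Unlike :func:`largest_component` this preserves classes that are
    legitimately multi-part — the sclera shows as two lobes whenever the
    cornea touches both lid margins.  Components smaller than
    ``max(min_px, min_frac * foreground)`` are removed.
    """
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask.astype(bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    thresh = max(min_px, min_frac * sizes.sum())
    keep = np.flatnonzero(sizes >= thresh)
    return np.isin(labels, keep)


def _check_targets(targets) -> set[str]:
    targets = set(targets)
    unknown = targets - ALL_CLASSES
    if unknown:
        raise ParameterError(f"unknown segmentation classes: {sorted(unknown)}")
    return targets


class SegmentationBackend:
    """Contract: one binary mask per requested class, image-sized."""

    name = "abstract"

    #: whether the pipeline should feed this backend the padded 512x512
    #: resize (fixed-input models) or the native-resolution sub-image
    wants_resized = False

    def segment(self, image: np.ndarray, targets) -> SegmentationBundle:
        raise NotImplementedError


class OracleBackend(SegmentationBackend):
    """Returns pre-known ground-truth masks (the generator's rasters).

    Constructed with full-frame or cropped truth masks matching the images
    it will be asked to segment; used to validate the measurement stages in
    isolation from any real segmentation model.
    """

    name = "oracle"

    def __init__(self, masks: dict[str, np.ndarray]):
        self._masks = {k: v.astype(bool) for k, v in masks.items()}

    def segment(self, image: np.ndarray, targets) -> SegmentationBundle:
        targets = _check_targets(targets)
        out = {}
        for t in targets:
            if t not in self._masks:
                raise SegmentationBackendError(self.name, f"no oracle mask for class {t!r}")
            m = self._masks[t]
            if m.shape != image.shape[:2]:
                raise SegmentationBackendError(
                    self.name, f"oracle mask shape {m.shape} != image {image.shape[:2]}"
                )
            out[t] = m.copy()
        return SegmentationBundle(out, frame="original")


class ColorRuleBackend(SegmentationBackend):
    """Nearest-reference-color pixel classifier for rendered scenes.

    Each pixel is assigned to the closest scene color (skin, sclera, cornea,
    light reflex, marker) in RGB space; the cornea class absorbs the reflex
    (the reflex sits on the cornea), then each mask is despeckled and its
    holes filled.
    """

    name = "color"

    def __init__(self):
        self._names = list(SCENE_COLORS)
        self._refs = np.array([SCENE_COLORS[n] for n in self._names], dtype=float)

    def segment(self, image: np.ndarray, targets) -> SegmentationBundle:
        targets = _check_targets(targets)
        if image.ndim != 3 or image.shape[2] != 3:
            raise SegmentationBackendError(self.name, "expected an RGB image")
        px = image.reshape(-1, 3).astype(float)
        d2 = ((px[:, None, :] - self._refs[None, :, :]) ** 2).sum(axis=2)
        label = d2.argmin(axis=1).reshape(image.shape[:2])
        idx = {n: i for i, n in enumerate(self._names)}
        out = {}
        for t in targets:
            if t == "cornea":
                m = (label == idx["cornea"]) | (label == idx["light_reflex"])
            else:
                m = label == idx[t]
            m = despeckle(m)
            if t != "sclera":  # single-object classes
                m = largest_component(m)
            out[t] = ndimage.binary_fill_holes(m)
        return SegmentationBundle(out, frame="original")


class ExternalBackend(SegmentationBackend):
    """Reads pre-computed mask PNGs (``mask_<class>.png``) from a directory.

    Adapter slot for an external semantic-segmentation stage run out of
    band (e.g. an encoder–decoder network with atrous convolutions trained
    per class on batches of 32 for 30 epochs with AdamW at lr 1e-3 on 724
    images split 0.6/0.2/0.2 — inference itself is out of scope here).
    """

    name = "external"

    def __init__(self, directory):
        self.directory = Path(directory)

    def segment(self, image: np.ndarray, targets) -> SegmentationBundle:
        targets = _check_targets(targets)
        out = {}
        for t in targets:
            path = self.directory / f"mask_{t}.png"
            if not path.exists():
                raise SegmentationBackendError(self.name, f"missing mask file {path}")
            m = iio.imread(path) > 127
            if m.shape != image.shape[:2]:
                raise SegmentationBackendError(
                    self.name, f"mask {path.name} shape {m.shape} != image {image.shape[:2]}"
                )
            out[t] = m
        return SegmentationBundle(out, frame="original")


def get_backend(name: str, **kwargs) -> SegmentationBackend:
    if name == "oracle":
        return OracleBackend(kwargs["masks"])
    if name == "color":
        return ColorRuleBackend()
    if name == "external":
        return ExternalBackend(kwargs["directory"])
    raise ParameterError(f"unknown backend {name!r}")


def mean_iou(pred: SegmentationBundle, truth: SegmentationBundle) -> SegmentationScore:
    """Per-class intersection-over-union and its arithmetic mean.

    A class whose union is empty in both bundles scores 1 (vacuous
    agreement).
    """
    if pred.classes != truth.classes:
        raise ParameterError(
            f"bundles must share classes: {sorted(pred.classes)} vs {sorted(truth.classes)}"
        )
    per = {}
    for name in sorted(pred.classes):
        a, b = pred[name], truth[name]
        if a.shape != b.shape:
            raise ParameterError(f"mask dimensions differ for class {name!r}")
        union = int(np.logical_or(a, b).sum())
        inter = int(np.logical_and(a, b).sum())
        per[name] = 1.0 if union == 0 else inter / union
    return SegmentationScore(per_class_iou=per, mean_iou=float(np.mean(list(per.values()))))
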