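"""Photograph splitting and square resizing with zero padding.

The acquisition protocol frames the face so that the two eyes occupy the
left and right halves of the photograph and the forehead marker sits in the
middle half.  Segmentation backends with a fixed square input receive the
sub-images resized to ``side x side`` with the aspect ratio preserved and
the remainder zero-padded (content anchored top-left, padding on the
right/bottom); :class:`ResizeTransform` records everything needed to map
masks back to original coordinates, where all measurement takes place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ParameterError


@dataclass(frozen=True)
class ResizeTransform:
    """Invertible record of a pad-to-square resize.

    ``scale`` is output pixels per input pixel along the scaled (longer)
    dimension; content occupies the top-left ``(side - pad_bottom_px) x
    (side - pad_right_px)`` region of the output.
    """

    scale: float
    pad_right_px: int
    pad_bottom_px: int
    input_size: tuple[int, int]  # (width, height)
    output_size: tuple[int, int]  # (side, side)


def split_image(image: np.ndarray):
    """Split a photograph into left-half, right-half, and middle-half crops.

    Halves are column ranges ``[0, W//2)`` and ``[W//2, W)``; the marker crop
    covers columns ``[W//4, 3W//4)`` at full height.
    """
    if image.ndim < 2 or image.shape[1] < 4:
        raise ParameterError("image width must be at least 4 pixels")
    w = image.shape[1]
    left = image[:, : w // 2].copy()
    right = image[:, w // 2:].copy()
    marker = image[:, w // 4: 3 * w // 4].copy()
    return left, right, marker


def resize_with_padding(image: np.ndarray, side: int = 512):
    """Resize so the longer dimension equals ``side``; zero-pad the shorter.

    Images are resampled bilinearly with anti-aliasing; use
    :func:`mask_to_original` (nearest-neighbour) to bring masks back.
    """
    if side < 2:
        raise ParameterError("side must be >= 2")
    if image.size == 0:
        raise ParameterError("cannot resize an empty image")
    h, w = image.shape[:2]
    scale = side / max(w, h)
    out_w = side if w >= h else int(round(w * scale))
    out_h = side if h >= w else int(round(h * scale))
    content = _sk_resize(
        image, (out_h, out_w) + image.shape[2:], order=1,
        preserve_range=True, anti_aliasing=True,
    ).astype(image.dtype)
    out = np.zeros((side, side) + image.shape[2:], dtype=image.dtype)
    out[:out_h, :out_w] = content
    t = ResizeTransform(
        scale=scale,
        pad_right_px=side - out_w,
        pad_bottom_px=side - out_h,
        input_size=(w, h),
        output_size=(side, side),
    )
    return out, t


def mask_to_original(mask: np.ndarray, t: ResizeTransform) -> np.ndarray:
    """Map a binary mask from the padded square frame back to input coordinates.

    Strips the zero padding and rescales nearest-neighbour so the result
    stays binary.
    """
    side = t.output_size[0]
    if mask.shape[:2] != (side, side):
        raise ParameterError(
            f"mask shape {mask.shape[:2]} does not match transform output {t.output_size}"
        )
    content = mask[: side - t.pad_bottom_px, : side - t.pad_right_px]
    w, h = t.input_size
    out = _sk_resize(content.astype(float), (h, w), order=0, preserve_range=True,
                     anti_aliasing=False)
    return out > 0.5
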