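"""Calibrated eyelid measurements from binary masks.

Pipeline (all in original-image coordinates): the forehead marker's
equivalent-circle diameter fixes the mm-per-pixel scale; the palpebral
fissure is the filled union of the sclera and cornea masks; its crack
boundary, cut at the two canthi (the horizontal endpoints of the sclera),
yields the upper and lower eyelid margins whose quadrant-corrected lengths
are the eyelid lengths; MRD1/MRD2 are the vertical distances from the
light-reflex centroid to the margins; and the visible cornea's
quadrant-corrected boundary is the corneal perimeter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .chain import BoundaryChain, corrected_length, trace_boundary
from .errors import MaskError, MeasurementError, ParameterError
from .segmentation import SegmentationBundle, largest_component

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale derived from the circular forehead marker."""

    marker_diameter_px: float
    marker_diameter_mm: float
    mm_per_px: float


@dataclass(frozen=True)
class EyelidMeasurements:
    """Complete calibrated measurement record for one eye."""

    mrd1_mm: float
    mrd2_mm: float
    upper_len_mm: float
    lower_len_mm: float
    cornea_perimeter_mm: float
    reflex_center_px: tuple[float, float]  # (row, col)
    canthi_px: tuple[tuple[float, float], tuple[float, float]]  # (medial, lateral)


def estimate_marker_diameter(marker_mask: np.ndarray) -> float:
    """Equivalent-circle diameter ``2*sqrt(area/pi)`` of the marker, in px.

    Uses the largest connected component; robust to one-pixel boundary
    noise, unlike a Feret (caliper) diameter.
    """
    marker_mask = np.asarray(marker_mask).astype(bool)
    if not marker_mask.any():
        raise MaskError("marker not found (empty mask)")
    area = int(largest_component(marker_mask).sum())
    return float(2.0 * np.sqrt(area / np.pi))


def calibrate(marker_diameter_px: float, marker_diameter_mm: float = 9.0) -> Calibration:
    """Build the mm/px scale from the marker's known physical diameter."""
    if marker_diameter_px <= 0 or marker_diameter_mm <= 0:
        raise ParameterError("marker diameters must be positive")
    return Calibration(
        marker_diameter_px=float(marker_diameter_px),
        marker_diameter_mm=float(marker_diameter_mm),
        mm_per_px=marker_diameter_mm / marker_diameter_px,
    )


def quadrant_perimeter(mask: np.ndarray) -> float:
    """Quadrant-corrected outer perimeter of the foreground, in px.

    See :func:`lidmetrics.chain.corrected_length` for the correction; the
    raw crack perimeter of a digitized curved object overestimates its true
    perimeter, which this rule repairs (a single pixel measures pi).  If
    several components are present the largest is used and a warning logged.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MaskError("cannot measure the perimeter of an empty mask")
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        log.warning("quadrant_perimeter: %d components, using the largest", n)
        mask = largest_component(mask)
    return corrected_length(trace_boundary(mask))


def find_canthi(mask: np.ndarray, eye_side: str = "left"):
    """Horizontal endpoints of the (sclera or fissure) mask as canthus pixels.

    Returns ``(medial, lateral)`` as integer ``(row, col)`` pixels.  In each
    extreme column the vertically median foreground pixel is taken.  On an
    unmirrored photograph the subject's left eye has its lateral canthus at
    the image-left extreme (``eye_side="left"``, the default); pass
    ``eye_side="right"`` for the other eye.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MaskError("cannot locate canthi in an empty mask")
    cols = np.flatnonzero(mask.any(axis=0))
    points = []
    for c in (cols[0], cols[-1]):
        rows = np.flatnonzero(mask[:, c])
        points.append((int(rows[(len(rows) - 1) // 2]), int(c)))
    leftmost, rightmost = points
    if eye_side == "left":
        return rightmost, leftmost
    if eye_side == "right":
        return leftmost, rightmost
    raise ParameterError(f"eye_side must be 'left' or 'right', got {eye_side!r}")


def fissure_mask(sclera: np.ndarray, cornea: np.ndarray) -> np.ndarray:
    """Palpebral fissure region: filled union of sclera and cornea masks."""
    m = ndimage.binary_fill_holes(np.asarray(sclera).astype(bool)
                                  | np.asarray(cornea).astype(bool))
    return largest_component(m)


def split_margins(fissure: np.ndarray, canthi) -> tuple[BoundaryChain, BoundaryChain]:
    """Cut the fissure boundary at the canthi into upper and lower margins.

    Each canthus pixel is snapped to the nearest boundary vertex (within
    2 px); the sub-chain containing the topmost boundary vertex is the
    upper margin.  Both open chains share exactly the two canthus vertices.
    """
    fissure = np.asarray(fissure).astype(bool)
    rows = np.flatnonzero(fissure.any(axis=1))
    if rows.size == 0:
        raise MaskError("empty fissure mask")
    if rows[-1] - rows[0] < 1:
        raise MeasurementError("fissure is a single pixel row; margins are ambiguous")
    closed = trace_boundary(fissure)
    v = closed.vertices
    cut = []
    for (r, c) in canthi:
        target = np.array([r + 0.5, c + 0.5])
        d = np.linalg.norm(v - target, axis=1)
        if d.min() > 2.0:
            raise MeasurementError(
                f"canthus {(r, c)} is {d.min():.2f} px from the fissure boundary (> 2 px)"
            )
        cut.append(int(d.argmin()))
    i, j = sorted(cut)
    if i == j:
        raise MeasurementError("canthi snap to the same boundary vertex")
    chain_a = v[i: j + 1]
    chain_b = np.vstack([v[j:], v[: i + 1]])
    top_row = v[:, 0].min()
    a_is_upper = chain_a[:, 0].min() <= chain_b[:, 0].min()
    upper, lower = (chain_a, chain_b) if a_is_upper else (chain_b, chain_a)
    if upper[:, 0].min() > top_row:
        raise MeasurementError("canthus cut does not separate the upper margin")
    return BoundaryChain(upper, closed=False), BoundaryChain(lower, closed=False)


def margin_length(chain: BoundaryChain, cal: Calibration) -> float:
    """Quadrant-corrected curvilinear length of an open margin chain, in mm."""
    if chain.closed:
        raise ParameterError("margin_length expects an open chain; use quadrant_perimeter")
    return corrected_length(chain) * cal.mm_per_px


def reflex_center(light_reflex_mask: np.ndarray) -> tuple[float, float]:
    """Centroid of the light-reflex mask, sub-pixel ``(row, col)``.

    The reflex is the measurement reference point; photographs without a
    visible reflex are outside the method's domain.
    """
    m = np.asarray(light_reflex_mask).astype(bool)
    if not m.any():
        raise MaskError("light reflex not detected (empty mask)")
    rr, cc = np.nonzero(m)
    return (float(rr.mean() + 0.5), float(cc.mean() + 0.5))


def _column_crossings(chain: BoundaryChain, col: float) -> np.ndarray:
    """Rows where the chain polyline crosses the vertical line ``x = col``."""
    v = chain.vertices
    if abs(col - round(col)) < 1e-9:  # avoid grazing vertical lattice edges
        col = round(col) + 1e-6
    c0, c1 = v[:-1, 1], v[1:, 1]
    hit = (np.minimum(c0, c1) < col) & (col < np.maximum(c0, c1))
    idx = np.flatnonzero(hit)
    t = (col - c0[idx]) / (c1[idx] - c0[idx])
    return v[idx, 0] + t * (v[idx + 1, 0] - v[idx, 0])


def compute_mrds(upper: BoundaryChain, lower: BoundaryChain,
                 center: tuple[float, float], cal: Calibration) -> tuple[float, float]:
    """MRD1 and MRD2: vertical distances (mm) from the reflex to the margins.

    The margin rows are interpolated where each chain crosses the reflex
    column; a reflex covered by the upper lid (negative MRD1) is outside
    the method's measurement range and raises :class:`MeasurementError`.
    """
    r0, c0 = center
    up = _column_crossings(upper, c0)
    lo = _column_crossings(lower, c0)
    if up.size == 0 or lo.size == 0:
        raise MeasurementError("reflex column does not intersect both eyelid margins")
    # nearest crossing on each side of the reflex row
    mrd1 = (r0 - up[np.abs(up - r0).argmin()]) * cal.mm_per_px
    mrd2 = (lo[np.abs(lo - r0).argmin()] - r0) * cal.mm_per_px
    if mrd1 < 0:
        raise MeasurementError(
            "negative MRD1: light reflex above the upper margin crossing "
            "(out of measurement range)"
        )
    if mrd2 < 0:
        raise MeasurementError("negative MRD2: light reflex below the lower margin crossing")
    return float(mrd1), float(mrd2)


def measure_eye(bundle: SegmentationBundle, cal: Calibration,
                eye_side: str = "left") -> EyelidMeasurements:
    """Run the full measurement sequence on one eye's segmentation bundle.

    Requires the ``sclera``, ``cornea``, and ``light_reflex`` classes in
    original-image coordinates.  Stage failures propagate with a stage label.
    """
    for name in ("sclera", "cornea", "light_reflex"):
        if name not in bundle:
            raise MaskError(f"segmentation bundle is missing the {name.replace('_', ' ')!r} mask")
    if bundle.frame != "original":
        raise ParameterError("measurement requires masks in original-image coordinates")

    def _stage(label, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise MeasurementError(f"stage {label!r}: {exc}") from exc

    cornea_perim = _stage("cornea perimeter", quadrant_perimeter, bundle["cornea"])
    log.debug("cornea perimeter: %.2f px", cornea_perim)
    fissure = _stage("fissure", fissure_mask, bundle["sclera"], bundle["cornea"])
    canthi = _stage("canthi", find_canthi, bundle["sclera"], eye_side)
    log.debug("canthi (medial, lateral): %s", canthi)
    upper, lower = _stage("margins", split_margins, fissure, canthi)
    upper_len = margin_length(upper, cal)
    lower_len = margin_length(lower, cal)
    log.debug("margin lengths: upper %.2f mm, lower %.2f mm", upper_len, lower_len)
    center = _stage("light reflex", reflex_center, bundle["light_reflex"])
    mrd1, mrd2 = _stage("MRD", compute_mrds, upper, lower, center, cal)
    log.debug("MRD1 %.2f mm, MRD2 %.2f mm", mrd1, mrd2)
    return EyelidMeasurements(
        mrd1_mm=mrd1,
        mrd2_mm=mrd2,
        upper_len_mm=upper_len,
        lower_len_mm=lower_len,
        cornea_perimeter_mm=cornea_perim * cal.mm_per_px,
        reflex_center_px=center,
        canthi_px=(tuple(map(float, canthi[0])), tuple(map(float, canthi[1]))),
    )
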