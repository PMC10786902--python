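"""Radial eyelid-contour profiling and normative abnormality detection.

The eyelid margin is resampled as 360 radial distances (1-degree steps)
about a reference origin on the intercanthal line — by default the point
where the perpendicular (the "orthogonal line") dropped from the light
reflex meets it.  Because the lateral canthus usually sits higher than the
medial one, the intercanthal line is inclined; the frame is rotated so it
becomes horizontal before the angles are laid out (0 deg toward the lateral
canthus, 90 deg toward the upper lid).  The circle is then partitioned into
k equal segments, a normative model (per-segment mean +- z*SD over a normal
cohort) defines acceptance intervals, and any subject with at least one
out-of-range segment is flagged abnormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from matplotlib.path import Path as _MplPath

from .chain import BoundaryChain
from .errors import MeasurementError, ParameterError
from .morphometry import Calibration

#: the partition counts studied for the sensitivity-vs-granularity sweep
STANDARD_PARTITIONS = (4, 8, 16, 24, 32, 64, 128, 256)

#: two-sided 95% normal quantile used for the normative acceptance interval
Z_95 = 1.959964


@dataclass(frozen=True)
class ReferenceFrame:
    """Intercanthal reference frame: origin on the line, x toward the lateral canthus."""

    origin: tuple[float, float]  # (row, col), sub-pixel
    tilt_deg: float  # angle of the intercanthal line vs the image horizontal
    u: tuple[float, float]  # unit vector (row, col) toward the lateral canthus
    n: tuple[float, float]  # unit vector (row, col) toward the upper lid


@dataclass(frozen=True)
class ContourProfile:
    """360 radial margin distances (mm) about the reference origin."""

    distances_mm: np.ndarray
    frame: ReferenceFrame
    subject_id: str = ""

    def __post_init__(self):
        d = np.asarray(self.distances_mm, dtype=float)
        if d.shape != (360,):
            raise ParameterError("a contour profile has exactly 360 samples")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise MeasurementError("profile distances must be positive and finite")
        object.__setattr__(self, "distances_mm", d)


@dataclass(frozen=True)
class PartitionScheme:
    """Partition of the 360 degrees into ``k`` equal angular segments."""

    k: int
    interval_deg: float
    segment_of_degree: np.ndarray  # degree -> segment index

    @property
    def interval_deg_reported(self) -> float:
        """Interval rounded to one decimal, halves away from zero (360/32 -> 11.3)."""
        return math.floor(self.interval_deg * 10.0 + 0.5) / 10.0


@dataclass(frozen=True)
class NormativeModel:
    """Per-segment acceptance intervals fitted on a normal cohort."""

    scheme: PartitionScheme
    mean_mm: np.ndarray
    sd_mm: np.ndarray
    z_crit: float
    n_normal: int
    method: str = "gaussian"
    lo_mm: np.ndarray | None = None  # percentile method only
    hi_mm: np.ndarray | None = None


@dataclass(frozen=True)
class AbnormalityReport:
    subject_id: str
    k: int
    abnormal_segments: frozenset[int]

    @property
    def is_abnormal_subject(self) -> bool:
        return len(self.abnormal_segments) > 0


@dataclass(frozen=True)
class VerificationCurve:
    """Sensitivity/specificity of subject-level flagging per partition count."""

    ks: tuple[int, ...]
    sensitivity: dict[int, float]
    specificity: dict[int, float]


def build_frame(canthi, center, origin: str = "reflex_foot") -> ReferenceFrame:
    """Construct the rotated intercanthal frame from canthi and reflex centre.

    ``origin="reflex_foot"`` (default) places the origin at the foot of the
    perpendicular from the reflex centre onto the intercanthal line;
    ``origin="intercanthal_midpoint"`` uses the line's midpoint instead.
    """
    (mr, mc), (lr, lc) = canthi
    m = np.array([float(mr), float(mc)])
    l = np.array([float(lr), float(lc)])
    c = np.array([float(center[0]), float(center[1])])
    v = l - m
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ParameterError("canthi are coincident; the intercanthal line is undefined")
    u = v / norm
    if origin == "reflex_foot":
        o = m + np.dot(c - m, u) * u
    elif origin == "intercanthal_midpoint":
        o = 0.5 * (m + l)
    else:
        raise ParameterError(f"unknown origin convention {origin!r}")
    # tilt vs image horizontal, in the y-up sense (row axis points down)
    tilt = math.degrees(math.atan2(-u[0], u[1]))
    n = np.array([-u[1], u[0]])  # 90 deg CCW from u in (row, col)
    if n[0] > 0:  # ensure n points toward the upper lid (decreasing row)
        n = -n
    return ReferenceFrame(
        origin=(float(o[0]), float(o[1])),
        tilt_deg=tilt,
        u=(float(u[0]), float(u[1])),
        n=(float(n[0]), float(n[1])),
    )


def _closed_polyline(upper: BoundaryChain, lower: BoundaryChain) -> np.ndarray:
    """Join the two open margin chains (sharing endpoints) into a closed loop."""
    a, b = upper.vertices, lower.vertices
    if np.allclose(a[-1], b[0]):
        pts = np.vstack([a, b[1:]])
    elif np.allclose(a[-1], b[-1]):
        pts = np.vstack([a, b[::-1][1:]])
    elif np.allclose(a[0], b[0]):
        pts = np.vstack([a[::-1], b[1:]])
    else:
        pts = np.vstack([a[::-1], b[::-1][1:]])
    if not np.allclose(pts[0], pts[-1]):
        raise MeasurementError("margin chains do not share both canthus endpoints")
    return pts[:-1]


def radial_profile(upper: BoundaryChain, lower: BoundaryChain,
                   frame: ReferenceFrame, cal: Calibration,
                   subject_id: str = "") -> ContourProfile:
    """Cast 360 rays from the frame origin and record margin distances in mm.

    Degree d is measured from the lateral-canthus direction, positive toward
    the upper lid; each distance is to the nearest intersection of the ray
    with the combined margin polyline.
    """
    pts = _closed_polyline(upper, lower)
    o = np.array(frame.origin)
    if not _MplPath(pts).contains_point(o):
        raise MeasurementError("reference origin lies outside the fissure boundary")
    u, n = np.array(frame.u), np.array(frame.n)
    deg = np.deg2rad(np.arange(360.0))
    dirs = np.cos(deg)[:, None] * u[None, :] + np.sin(deg)[:, None] * n[None, :]
    a = pts
    b = np.vstack([pts[1:], pts[:1]])
    e = b - a
    ao = a - o
    # solve o + t*dir = a + s*e for each (ray, segment) pair
    denom = dirs[:, None, 0] * e[None, :, 1] - dirs[:, None, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[None, :, 0] * e[None, :, 1] - ao[None, :, 1] * e[None, :, 0]) / denom
        s = (ao[None, :, 0] * dirs[:, None, 1] - ao[None, :, 1] * dirs[:, None, 0]) / denom
    valid = (np.abs(denom) > 1e-12) & (s >= 0.0) & (s < 1.0) & (t > 1e-9)
    t = np.where(valid, t, np.inf)
    dist = t.min(axis=1)
    if not np.all(np.isfinite(dist)):
        raise MeasurementError("a ray found no boundary intersection")
    return ContourProfile(distances_mm=dist * cal.mm_per_px, frame=frame,
                          subject_id=subject_id)


def make_scheme(k: int) -> PartitionScheme:
    """Equal partition of the circle; segment i covers [i*360/k, (i+1)*360/k).

    For even k the segment boundaries at 0 and 90 degrees coincide with the
    intercanthal line and the orthogonal line through the reflex — the two
    drawn lines that give the base case of four partitions.
    """
    if not (2 <= k <= 360):
        raise ParameterError(f"partition count k must be in [2, 360], got {k}")
    interval = 360.0 / k
    seg = np.minimum((np.arange(360) / interval).astype(int), k - 1)
    return PartitionScheme(k=int(k), interval_deg=interval, segment_of_degree=seg)


def segment_values(profile: ContourProfile, scheme: PartitionScheme) -> np.ndarray:
    """Per-segment aggregate: arithmetic mean of the member degrees' distances."""
    return np.bincount(
        scheme.segment_of_degree, weights=profile.distances_mm, minlength=scheme.k
    ) / np.bincount(scheme.segment_of_degree, minlength=scheme.k)


def fit_normative(profiles, scheme: PartitionScheme, z_crit: float = Z_95,
                  method: str = "gaussian") -> NormativeModel:
    """Fit per-segment acceptance intervals on a normal cohort.

    ``method="gaussian"`` (default): mean +- z_crit * sample SD (n-1
    denominator).  ``method="percentile"``: empirical 2.5th-97.5th
    percentile interval, for cohorts where normality is doubtful.
    """
    values = np.array([segment_values(p, scheme) for p in profiles])
    if values.shape[0] < 2:
        raise ParameterError("fitting a normative model requires >= 2 normal profiles")
    lo = hi = None
    if method == "percentile":
        lo = np.percentile(values, 2.5, axis=0)
        hi = np.percentile(values, 97.5, axis=0)
    elif method != "gaussian":
        raise ParameterError(f"unknown normative method {method!r}")
    return NormativeModel(
        scheme=scheme,
        mean_mm=values.mean(axis=0),
        sd_mm=values.std(axis=0, ddof=1),
        z_crit=float(z_crit),
        n_normal=values.shape[0],
        method=method,
        lo_mm=lo,
        hi_mm=hi,
    )


def flag_abnormal(profile: ContourProfile, model: NormativeModel) -> AbnormalityReport:
    """Flag segments outside the normative interval; any flag marks the subject.

    A zero-SD segment (degenerate cohort) accepts only an exact match with
    the cohort mean.
    """
    vals = segment_values(profile, model.scheme)
    if vals.shape[0] != model.mean_mm.shape[0]:
        raise ParameterError("profile segmentation does not match the model's scheme")
    if model.method == "percentile":
        out = (vals < model.lo_mm) | (vals > model.hi_mm)
    else:
        half = model.z_crit * model.sd_mm
        out = np.abs(vals - model.mean_mm) > half
        exact = model.sd_mm == 0.0
        out[exact] = vals[exact] != model.mean_mm[exact]
    return AbnormalityReport(
        subject_id=profile.subject_id,
        k=model.scheme.k,
        abnormal_segments=frozenset(np.flatnonzero(out).tolist()),
    )


def verification_sweep(cohort, ks=STANDARD_PARTITIONS, z_crit: float = Z_95,
                       method: str = "gaussian") -> VerificationCurve:
    """Sensitivity/specificity of abnormal-subject detection per partition count.

    ``cohort`` is a sequence of ``(profile, is_abnormal)`` pairs.  For each
    k the normative model is fitted on the labelled normals and every
    subject is flagged; sensitivity is the fraction of abnormal subjects
    flagged, specificity the fraction of normal subjects not flagged.
    """
    normals = [p for p, lab in cohort if not lab]
    abnormals = [p for p, lab in cohort if lab]
    if len(normals) < 2 or len(abnormals) < 1:
        raise ParameterError("cohort needs >= 2 normals and >= 1 abnormal subject")
    sens, spec = {}, {}
    for k in ks:
        scheme = make_scheme(k)
        model = fit_normative(normals, scheme, z_crit=z_crit, method=method)
        flagged_n = sum(flag_abnormal(p, model).is_abnormal_subject for p in normals)
        flagged_a = sum(flag_abnormal(p, model).is_abnormal_subject for p in abnormals)
        sens[k] = flagged_a / len(abnormals)
        spec[k] = 1.0 - flagged_n / len(normals)
    return VerificationCurve(ks=tuple(ks), sensitivity=sens, specificity=spec)


def plot_verification_curve(curve: VerificationCurve, path) -> None:
    """Save a sensitivity-vs-partitions plot (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ks = list(curve.ks)
    ax.plot(ks, [curve.sensitivity[k] for k in ks], "o-", label="sensitivity")
    ax.plot(ks, [curve.specificity[k] for k in ks], "s--", label="specificity")
    ax.set_xscale("log", base=2)
    ax.set_xticks(ks)
    ax.set_xticklabels([str(k) for k in ks])
    ax.set_xlabel("partitions")
    ax.set_ylabel("rate")
    ax.set_ylim(-0.02, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
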