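"""Synthetic eye-scene generator with pixel-exact masks and analytic truth.

Each scene emulates a standardized clinical face photograph: a palpebral
fissure bounded by two smooth eyelid arcs meeting at the medial and lateral
canthi, a corneal disc carrying a central light-reflex dot, and a circular
forehead marker of known physical diameter (9.0 mm) that provides the
mm-per-pixel scale.  Eyelid arcs are parabolas through both canthi whose
apices sit ``mrd1_mm`` above and ``mrd2_mm`` below the reflex centre along
the image vertical, so the margin–reflex distances are analytic inputs.
Localized contour abnormalities are raised-cosine radial bumps applied about
the intercanthal reference origin.

Masks are exact rasterizations of the analytic shapes (a pixel is foreground
iff its centre lies inside the shape); every ground-truth quantity is
computed from the analytic curves by fine quadrature, never from the
rasters, so the generator doubles as an independent oracle for the
measurement pipeline.

Raster convention (shared by the whole package): 0-based row-major arrays,
row index increasing downward; pixel ``(r, c)`` occupies ``[c, c+1) x
[r, r+1)`` with centre ``(r + 0.5, c + 0.5)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as _sk_polygon

from .errors import ParameterError, SceneIOError

MASK_CLASSES = ("sclera", "cornea", "light_reflex", "marker")

#: Flat rendering colors (RGB).  Deliberately well separated in color space
#: so a rule-based backend can segment by nearest-color classification.
SCENE_COLORS = {
    "skin": (214, 166, 138),
    "sclera": (247, 247, 244),
    "cornea": (92, 62, 40),
    "light_reflex": (255, 249, 196),
    "marker": (36, 90, 174),
}

_DENSE_DEG = 0.1  # boundary sampling step for rasterization (degrees)
_TRUTH_N = 20001  # quadrature points per lid for analytic arc length


@dataclass(frozen=True)
class Bump:
    """Localized radial contour deformation (raised-cosine window).

    ``center_deg`` is the angular position about the reference origin
    (0 deg toward the lateral canthus, 90 deg toward the upper lid),
    ``width_deg`` the full window width, ``amplitude_mm`` the peak radial
    displacement (positive = outward).
    """

    center_deg: float
    width_deg: float
    amplitude_mm: float


@dataclass(frozen=True)
class SceneParams:
    """Analytic description of one synthetic scene.

    Defaults follow the acquisition protocol the generator emulates: a
    1200 x 797 px frame at 0.1 mm/px, a normal adult fissure (MRD1 3.1 mm,
    MRD2 5.8 mm, width 28 mm, canthal tilt 4 deg, corneal radius 5.75 mm)
    and a 9.0 mm forehead marker.
    """

    image_width_px: int = 1200
    image_height_px: int = 797
    mm_per_px_true: float = 0.1
    eye_center: tuple[float, float] = (430.0, 880.0)  # (row, col)
    mrd1_mm: float = 3.1
    mrd2_mm: float = 5.8
    fissure_width_mm: float = 28.0
    canthal_tilt_deg: float = 4.0
    cornea_radius_mm: float = 5.75
    reflex_radius_mm: float = 0.5
    marker_center: tuple[float, float] = (120.0, 600.0)  # (row, col)
    marker_diameter_mm: float = 9.0
    bumps: tuple[Bump, ...] = ()
    scene_rotation_deg: float = 0.0  # rigid rotation of the whole eye about its centre
    noise_sigma: float = 0.0  # additive Gaussian image noise (gray levels)
    seed: int = 0

    def validate(self) -> None:
        if self.mrd2_mm <= 0:
            raise ParameterError("mrd2_mm must be positive")
        if self.mrd1_mm + self.mrd2_mm <= 0:
            raise ParameterError("mrd1_mm + mrd2_mm must be positive (open fissure)")
        if self.fissure_width_mm <= 0:
            raise ParameterError("fissure_width_mm must be positive")
        if self.mm_per_px_true <= 0:
            raise ParameterError("mm_per_px_true must be positive")
        if self.reflex_radius_mm >= self.cornea_radius_mm:
            raise ParameterError("reflex_radius_mm must be smaller than cornea_radius_mm")
        if self.marker_diameter_mm <= 0:
            raise ParameterError("marker_diameter_mm must be positive")
        for b in self.bumps:
            if b.width_deg <= 0:
                raise ParameterError("bumps: width_deg must be positive")


@dataclass(frozen=True)
class SceneGroundTruth:
    """Analytic ground truth of a scene (computed by quadrature, not rasters)."""

    params: SceneParams
    true_mrd1_mm: float
    true_mrd2_mm: float
    true_upper_len_mm: float
    true_lower_len_mm: float
    true_profile_mm: np.ndarray  # 360 radial distances (mm), degree-indexed
    abnormal_degrees: frozenset[int]
    canthi_px: tuple[tuple[float, float], tuple[float, float]]  # (medial, lateral), (row, col)


@dataclass
class Scene:
    """A rendered scene: RGB image, per-class binary masks, and its truth."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    truth: SceneGroundTruth
    subject_id: str = ""


class _EyeGeometry:
    """Analytic eye geometry in millimetres, math frame (x right, y up).

    Image (row, col) maps to (x, y) = (col * s, -row * s).  The lids are
    parabolas y = q(x) through both canthi; the reference origin is the foot
    of the perpendicular from the reflex centre onto the intercanthal line.
    An optional rigid scene rotation is applied to the embedding axes only,
    so all intrinsic quantities (profile, arc lengths) are rotation-free.
    """

    def __init__(self, p: SceneParams):
        s = p.mm_per_px_true
        self.s = s
        self.p = p
        self.C = np.array([p.eye_center[1] * s, -p.eye_center[0] * s])
        th = np.deg2rad(p.canthal_tilt_deg)
        half = p.fissure_width_mm / 2.0
        # left-eye convention on an unmirrored photo: lateral canthus is the
        # leftmost of the pair and is elevated by a positive canthal tilt
        self.L0 = self.C + half * np.array([-np.cos(th), np.sin(th)])
        self.M0 = self.C + half * np.array([np.cos(th), -np.sin(th)])
        self.qu = np.polyfit(
            [self.M0[0], self.C[0], self.L0[0]],
            [self.M0[1], self.C[1] + p.mrd1_mm, self.L0[1]],
            2,
        )
        self.ql = np.polyfit(
            [self.M0[0], self.C[0], self.L0[0]],
            [self.M0[1], self.C[1] - p.mrd2_mm, self.L0[1]],
            2,
        )
        u = self.L0 - self.M0
        self.u0 = u / np.linalg.norm(u)
        self.o0 = self.M0 + np.dot(self.C - self.M0, self.u0) * self.u0
        n = np.array([-self.u0[1], self.u0[0]])
        self.n0 = n if n[1] > 0 else -n  # 90 deg points toward the upper lid
        rho = np.deg2rad(p.scene_rotation_deg)
        R = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
        self.u = R @ self.u0
        self.n = R @ self.n0
        self.o = self.C + R @ (self.o0 - self.C)
        self.M = self.C + R @ (self.M0 - self.C)
        self.L = self.C + R @ (self.L0 - self.C)

    def radii(self, phi_deg: np.ndarray) -> np.ndarray:
        """Radial distance (mm) from the origin to the deformed lid contour."""
        phi_deg = np.asarray(phi_deg, dtype=float) % 360.0
        phi = np.deg2rad(phi_deg)
        dx = self.u0[0] * np.cos(phi) + self.n0[0] * np.sin(phi)
        dy = self.u0[1] * np.cos(phi) + self.n0[1] * np.sin(phi)
        upper = phi_deg <= 180.0
        a = np.where(upper, self.qu[0], self.ql[0])
        b = np.where(upper, self.qu[1], self.ql[1])
        c = np.where(upper, self.qu[2], self.ql[2])
        ox, oy = self.o0
        # intersect ray o + t*d with the parabola y = a x^2 + b x + c
        A = a * dx * dx
        B = 2.0 * a * ox * dx + b * dx - dy
        Cq = a * ox * ox + b * ox + c - oy
        r = np.full(phi.shape, np.nan)
        lin = np.abs(A) < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            r[lin] = -Cq[lin] / B[lin]
            disc = B * B - 4.0 * A * Cq
            sq = np.sqrt(np.maximum(disc, 0.0))
            t1 = (-B - sq) / (2.0 * A)
            t2 = (-B + sq) / (2.0 * A)
        tq = np.where(
            (t1 > 1e-9) & ((t1 <= t2) | (t2 <= 1e-9)),
            t1,
            np.where(t2 > 1e-9, t2, np.nan),
        )
        r[~lin] = tq[~lin]
        r = r + _bump_field(phi_deg, self.p.bumps)
        if not np.all(np.isfinite(r)) or np.any(r <= 1e-3):
            raise ParameterError(
                "bumps: deformed contour is not star-shaped about the reference origin"
            )
        return r

    def boundary(self, phi_deg: np.ndarray) -> np.ndarray:
        """Embedded contour points (mm, math frame), shape (N, 2)."""
        r = self.radii(phi_deg)
        phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
        return (
            self.o[None, :]
            + r[:, None] * (np.cos(phi)[:, None] * self.u[None, :]
                            + np.sin(phi)[:, None] * self.n[None, :])
        )

    def to_px(self, pts: np.ndarray) -> np.ndarray:
        """mm math-frame points -> continuous (row, col) pixel coordinates."""
        pts = np.atleast_2d(pts)
        return np.column_stack([-pts[:, 1] / self.s, pts[:, 0] / self.s])


def _bump_field(phi_deg: np.ndarray, bumps: tuple[Bump, ...]) -> np.ndarray:
    out = np.zeros_like(np.asarray(phi_deg, dtype=float))
    for b in bumps:
        d = np.abs((phi_deg - b.center_deg + 180.0) % 360.0 - 180.0)
        inside = d < b.width_deg / 2.0
        out = out + np.where(
            inside, b.amplitude_mm * 0.5 * (1.0 + np.cos(2.0 * np.pi * d / b.width_deg)), 0.0
        )
    return out


def _disc_mask(shape, center_rc, radius_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr + 0.5 - center_rc[0]) ** 2 + (cc + 0.5 - center_rc[1]) ** 2 <= radius_px**2


def _arc_length(geom: _EyeGeometry, lo_deg: float, hi_deg: float) -> float:
    phi = np.linspace(lo_deg, hi_deg, _TRUTH_N)
    pts = geom.boundary(phi)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _vertical_crossings(geom: _EyeGeometry, n: int = 7200) -> tuple[float, float]:
    """MRD1/MRD2 as vertical distances from the reflex centre to the contour."""
    phi = np.linspace(0.0, 360.0, n, endpoint=False)
    pts = geom.boundary(phi)
    pts = np.vstack([pts, pts[:1]])
    g = pts[:, 0] - geom.C[0]
    ys = []
    for i in np.flatnonzero(g[:-1] * g[1:] < 0):
        t = g[i] / (g[i] - g[i + 1])
        ys.append(pts[i, 1] + t * (pts[i + 1, 1] - pts[i, 1]))
    for i in np.flatnonzero(g == 0.0):  # crossings landing exactly on a sample
        ys.append(pts[i, 1])
    ys = np.array(ys)
    above = ys[ys > geom.C[1]]
    below = ys[ys < geom.C[1]]
    if above.size == 0 or below.size == 0:
        raise ParameterError("eye_center: reflex centre lies outside the fissure column span")
    return float(above.min() - geom.C[1]), float(geom.C[1] - below.max())


def generate_scene(params: SceneParams) -> Scene:
    """Render one scene and compute its analytic ground truth.

    Deterministic given ``params`` (image noise is seeded by ``params.seed``).
    """
    params.validate()
    geom = _EyeGeometry(params)
    s = params.mm_per_px_true
    shape = (params.image_height_px, params.image_width_px)

    degs = np.arange(360.0)
    profile = geom.radii(degs)

    # marker/eye overlap guard: exact distance from the marker disc to the
    # deformed fissure boundary (2 px clearance)
    marker_r_px = params.marker_diameter_mm / 2.0 / s
    bpts = geom.to_px(geom.boundary(np.arange(0.0, 360.0, 0.5)))
    gap = np.min(np.hypot(bpts[:, 0] - params.marker_center[0],
                          bpts[:, 1] - params.marker_center[1]))
    if gap <= marker_r_px + 2.0:
        raise ParameterError("marker_center: marker disc overlaps the eye region")

    if params.bumps or params.scene_rotation_deg != 0.0:
        mrd1, mrd2 = _vertical_crossings(geom)
    else:
        mrd1, mrd2 = params.mrd1_mm, params.mrd2_mm

    abnormal = set()
    for b in params.bumps:
        for d in range(360):
            dd = abs((d - b.center_deg + 180.0) % 360.0 - 180.0)
            if dd < b.width_deg / 2.0:
                abnormal.add(d)

    truth = SceneGroundTruth(
        params=params,
        true_mrd1_mm=mrd1,
        true_mrd2_mm=mrd2,
        true_upper_len_mm=_arc_length(geom, 0.0, 180.0),
        true_lower_len_mm=_arc_length(geom, 180.0, 360.0),
        true_profile_mm=profile,
        abnormal_degrees=frozenset(abnormal),
        canthi_px=(
            tuple(geom.to_px(geom.M)[0]),
            tuple(geom.to_px(geom.L)[0]),
        ),
    )

    phi = np.arange(0.0, 360.0, _DENSE_DEG)
    poly_px = geom.to_px(geom.boundary(phi))
    rr, cc = _sk_polygon(poly_px[:, 0] - 0.5, poly_px[:, 1] - 0.5, shape)
    fissure = np.zeros(shape, dtype=bool)
    fissure[rr, cc] = True

    cornea_disc = _disc_mask(shape, params.eye_center, params.cornea_radius_mm / s)
    reflex_disc = _disc_mask(shape, params.eye_center, params.reflex_radius_mm / s)
    masks = {
        "sclera": fissure & ~cornea_disc,
        "cornea": fissure & cornea_disc,
        "light_reflex": fissure & cornea_disc & reflex_disc,
        "marker": _disc_mask(shape, params.marker_center, marker_r_px),
    }

    image = np.empty(shape + (3,), dtype=np.uint8)
    image[:] = SCENE_COLORS["skin"]
    for name in ("sclera", "cornea", "light_reflex", "marker"):
        image[masks[name]] = SCENE_COLORS[name]
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        noisy = image.astype(float) + rng.normal(0.0, params.noise_sigma, image.shape)
        image = np.clip(noisy, 0, 255).astype(np.uint8)

    return Scene(image=image, masks=masks, truth=truth)


@dataclass(frozen=True)
class CohortVariation:
    """Per-subject jitter of the scene parameters (Gaussian, truncated).

    Means and SDs default to a normal adult cohort: MRD1 3.1 ± 0.8 mm,
    MRD2 5.8 ± 1.1 mm, fissure width 28 ± 1.5 mm, canthal tilt 4 ± 2 deg.
    Truncation keeps the light reflex visible and the fissure open.
    """

    mrd1_mean: float = 3.1
    mrd1_sd: float = 0.8
    mrd2_mean: float = 5.8
    mrd2_sd: float = 1.1
    width_mean: float = 28.0
    width_sd: float = 1.5
    tilt_mean: float = 4.0
    tilt_sd: float = 2.0
    mrd1_min: float = 1.2
    mrd2_min: float = 2.5
    width_min: float = 22.0


@dataclass(frozen=True)
class BumpSpec:
    """Distribution of abnormal contour bumps for cohort generation.

    Centers are drawn uniformly on the lid arcs away from the canthi;
    amplitudes default to 3–6 mm (a severe localized deformation).
    """

    n_bumps: int = 1
    center_ranges: tuple[tuple[float, float], ...] = ((20.0, 160.0), (200.0, 340.0))
    width_deg: float = 10.0
    amplitude_range: tuple[float, float] = (3.0, 6.0)


def _draw_params(rng: np.random.Generator, variation: CohortVariation,
                 bump_spec: BumpSpec | None, base: SceneParams) -> SceneParams:
    v = variation
    mrd1 = max(v.mrd1_min, rng.normal(v.mrd1_mean, v.mrd1_sd)) if v.mrd1_sd else v.mrd1_mean
    mrd2 = max(v.mrd2_min, rng.normal(v.mrd2_mean, v.mrd2_sd)) if v.mrd2_sd else v.mrd2_mean
    width = max(v.width_min, rng.normal(v.width_mean, v.width_sd)) if v.width_sd else v.width_mean
    tilt = rng.normal(v.tilt_mean, v.tilt_sd) if v.tilt_sd else v.tilt_mean
    bumps: tuple[Bump, ...] = ()
    if bump_spec is not None:
        drawn = []
        widths = np.array([hi - lo for lo, hi in bump_spec.center_ranges])
        for _ in range(bump_spec.n_bumps):
            k = rng.choice(len(widths), p=widths / widths.sum())
            lo, hi = bump_spec.center_ranges[k]
            center = rng.uniform(lo, hi)
            amp = rng.uniform(*bump_spec.amplitude_range)
            drawn.append(Bump(center, bump_spec.width_deg, amp))
        bumps = tuple(drawn)
    return dataclasses.replace(
        base,
        mrd1_mm=float(mrd1),
        mrd2_mm=float(mrd2),
        fissure_width_mm=float(width),
        canthal_tilt_deg=float(tilt),
        bumps=bumps,
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n_normal: int,
    n_abnormal: int,
    variation: CohortVariation | None = None,
    bump_spec: BumpSpec | None = None,
    seed: int = 0,
    base_params: SceneParams | None = None,
) -> list[Scene]:
    """Generate ``n_normal`` bump-free and ``n_abnormal`` bumped scenes.

    Per-scene parameters are drawn from ``variation`` (and ``bump_spec`` for
    the abnormal subjects) with a dedicated child RNG per scene, so the
    cohort is reproducible from the master seed.
    """
    if n_normal < 2:
        raise ParameterError("n_normal must be >= 2 (normative SD undefined otherwise)")
    variation = variation or CohortVariation()
    bump_spec = bump_spec or BumpSpec()
    base = base_params or SceneParams()
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_normal):
        p = _draw_params(rng, variation, None, base)
        scenes.append(dataclasses.replace(generate_scene(p), subject_id=f"normal_{i:03d}"))
    for i in range(n_abnormal):
        p = _draw_params(rng, variation, bump_spec, base)
        scenes.append(dataclasses.replace(generate_scene(p), subject_id=f"abnormal_{i:03d}"))
    return scenes


# ---------------------------------------------------------------------------
# scene I/O


def _params_to_dict(p: SceneParams) -> dict:
    d = dataclasses.asdict(p)
    d["bumps"] = [dataclasses.asdict(b) for b in p.bumps]
    return d


def _params_from_dict(d: dict) -> SceneParams:
    d = dict(d)
    d["bumps"] = tuple(Bump(**b) for b in d.get("bumps", []))
    d["eye_center"] = tuple(d["eye_center"])
    d["marker_center"] = tuple(d["marker_center"])
    return SceneParams(**d)


def write_scene(scene: Scene, directory) -> Path:
    """Write a scene to ``directory`` (PNG image + 0/255 mask PNGs + JSON truth).

    Returns the manifest path.  The mask and truth round-trip is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "image.png", scene.image)
    for name, mask in scene.masks.items():
        iio.imwrite(directory / f"mask_{name}.png", (mask.astype(np.uint8)) * 255)
    t = scene.truth
    truth = {
        "params": _params_to_dict(t.params),
        "true_mrd1_mm": t.true_mrd1_mm,
        "true_mrd2_mm": t.true_mrd2_mm,
        "true_upper_len_mm": t.true_upper_len_mm,
        "true_lower_len_mm": t.true_lower_len_mm,
        "true_profile_mm": [float(x) for x in t.true_profile_mm],
        "abnormal_degrees": sorted(t.abnormal_degrees),
        "canthi_px": [list(t.canthi_px[0]), list(t.canthi_px[1])],
    }
    (directory / "truth.json").write_text(json.dumps(truth))
    manifest = {
        "subject_id": scene.subject_id,
        "image": "image.png",
        "masks": {name: f"mask_{name}.png" for name in scene.masks},
        "truth": "truth.json",
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_scene(directory) -> Scene:
    """Read a scene written by :func:`write_scene`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SceneIOError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    try:
        image = iio.imread(directory / manifest["image"])
        masks = {
            name: iio.imread(directory / fname) > 127
            for name, fname in manifest["masks"].items()
        }
        truth_raw = json.loads((directory / manifest["truth"]).read_text())
    except (OSError, KeyError, ValueError) as exc:
        raise SceneIOError(f"corrupt scene directory {directory}: {exc}") from exc
    truth = SceneGroundTruth(
        params=_params_from_dict(truth_raw["params"]),
        true_mrd1_mm=truth_raw["true_mrd1_mm"],
        true_mrd2_mm=truth_raw["true_mrd2_mm"],
        true_upper_len_mm=truth_raw["true_upper_len_mm"],
        true_lower_len_mm=truth_raw["true_lower_len_mm"],
        true_profile_mm=np.array(truth_raw["true_profile_mm"]),
        abnormal_degrees=frozenset(truth_raw["abnormal_degrees"]),
        canthi_px=(tuple(truth_raw["canthi_px"][0]), tuple(truth_raw["canthi_px"][1])),
    )
    return Scene(image=image, masks=masks, truth=truth,
                 subject_id=manifest.get("subject_id", ""))
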