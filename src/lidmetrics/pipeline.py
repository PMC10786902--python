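"""End-to-end orchestration: scenes -> masks -> measurements -> profiles -> reports.

Measurement always happens in original-image coordinates so the marker
calibration and the eye measurements share one scale.  Backends that carry
full-frame masks (oracle, external) are cropped to the eye half and marker
crop after segmentation; the color-rule backend classifies the sub-images
directly.  Batch processing is fail-soft: one bad subject is recorded and
skipped, the rest of the cohort proceeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contour import (
    STANDARD_PARTITIONS,
    Z_95,
    ContourProfile,
    build_frame,
    fit_normative,
    flag_abnormal,
    make_scheme,
    plot_verification_curve,
    radial_profile,
    verification_sweep,
)
from .errors import LidmetricsError, MaskError, ParameterError
from .morphometry import (
    Calibration,
    EyelidMeasurements,
    calibrate,
    estimate_marker_diameter,
    find_canthi,
    fissure_mask,
    measure_eye,
    reflex_center,
    split_margins,
)
from .preprocess import mask_to_original, resize_with_padding, split_image
from .segmentation import (
    ColorRuleBackend,
    ExternalBackend,
    OracleBackend,
    SegmentationBundle,
)
from .synthetic_scene import Scene, read_scene

log = logging.getLogger(__name__)

EYE_CLASSES = ("sclera", "cornea", "light_reflex")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run (serialized into the manifest)."""

    input_dir: str = ""
    output_dir: str = "out"
    backend: str = "oracle"
    origin: str = "reflex_foot"
    z_crit: float = Z_95
    partitions: tuple[int, ...] = STANDARD_PARTITIONS
    marker_diameter_mm: float = 9.0
    resize_side: int = 512
    seed: int = 0
    log_level: str = "INFO"
    verify: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "partitions" in raw:
            raw["partitions"] = tuple(raw["partitions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["partitions"] = list(self.partitions)
        return d


@dataclass
class SubjectResult:
    subject_id: str
    measurements: EyelidMeasurements | None = None
    calibration: Calibration | None = None
    profile: ContourProfile | None = None
    is_abnormal_truth: bool | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _segment_scene(scene: Scene, backend_name: str, *, scene_dir=None,
                   resize_side: int = 512):
    """Produce (eye bundle in half-frame coords, marker mask in crop coords, eye_side)."""
    image = scene.image
    w = image.shape[1]
    left, right, marker_crop = split_image(image)

    if backend_name in ("oracle", "external"):
        if backend_name == "oracle":
            backend = OracleBackend(scene.masks)
        else:
            if scene_dir is None:
                raise ParameterError("external backend requires the scene directory")
            backend = ExternalBackend(scene_dir)
        full = backend.segment(image, set(EYE_CLASSES) | {"marker"})
        cols = np.flatnonzero(full["sclera"].any(axis=0))
        if cols.size == 0:
            raise MaskError("sclera not found in the frame")
        use_right = cols.mean() >= w // 2
        sl = slice(w // 2, w) if use_right else slice(0, w // 2)
        eye = SegmentationBundle({k: full[k][:, sl] for k in EYE_CLASSES})
        marker = full["marker"][:, w // 4: 3 * w // 4]
    else:  # color rule: classify the sub-images themselves
        backend = ColorRuleBackend()

        def _eye_masks(half):
            if backend.wants_resized:
                resized, t = resize_with_padding(half, resize_side)
                b = backend.segment(resized, EYE_CLASSES)
                return SegmentationBundle(
                    {k: mask_to_original(b[k], t) for k in EYE_CLASSES})
            return backend.segment(half, EYE_CLASSES)

        eye = _eye_masks(right)
        use_right = True
        if not eye["sclera"].any():
            eye = _eye_masks(left)
            use_right = False
        marker = backend.segment(marker_crop, {"marker"})["marker"]
    # unmirrored photograph: the right image half shows the subject's left eye
    eye_side = "left" if use_right else "right"
    return eye, marker, eye_side


def process_scene(scene: Scene, backend: str = "oracle", *, scene_dir=None,
                  origin: str = "reflex_foot", marker_diameter_mm: float = 9.0,
                  resize_side: int = 512) -> SubjectResult:
    """Measure one scene: calibration, eyelid measurements, contour profile."""
    res = SubjectResult(subject_id=scene.subject_id,
                        is_abnormal_truth=bool(scene.truth.abnormal_degrees)
                        if scene.truth is not None else None)
    try:
        eye, marker, eye_side = _segment_scene(scene, backend, scene_dir=scene_dir,
                                               resize_side=resize_side)
        cal = calibrate(estimate_marker_diameter(marker), marker_diameter_mm)
        meas = measure_eye(eye, cal, eye_side=eye_side)
        fissure = fissure_mask(eye["sclera"], eye["cornea"])
        canthi = find_canthi(eye["sclera"], eye_side)
        upper, lower = split_margins(fissure, canthi)
        frame = build_frame(canthi, reflex_center(eye["light_reflex"]), origin=origin)
        profile = radial_profile(upper, lower, frame, cal,
                                 subject_id=scene.subject_id)
        res.measurements, res.calibration, res.profile = meas, cal, profile
    except (LidmetricsError, ValueError) as exc:
        log.error("subject %s failed: %s", scene.subject_id, exc)
        res.error = str(exc)
    return res


def results_frame(results) -> pd.DataFrame:
    """One row per eye: the calibrated measurement record (failed rows flagged)."""
    rows = []
    for r in results:
        row = {"subject_id": r.subject_id, "status": "ok" if r.ok else "failed",
               "error": r.error or ""}
        if r.ok:
            m, c = r.measurements, r.calibration
            row.update(
                mrd1_mm=m.mrd1_mm, mrd2_mm=m.mrd2_mm,
                upper_len_mm=m.upper_len_mm, lower_len_mm=m.lower_len_mm,
                cornea_perimeter_mm=m.cornea_perimeter_mm,
                mm_per_px=c.mm_per_px,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_frame(results) -> pd.DataFrame:
    """Wide per-subject profile table: subject_id, label, d000..d359 (mm)."""
    rows = []
    for r in results:
        if not (r.ok and r.profile is not None):
            continue
        row = {"subject_id": r.subject_id,
               "is_abnormal": bool(r.is_abnormal_truth)}
        row.update({f"d{i:03d}": v for i, v in enumerate(r.profile.distances_mm)})
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, scenes=None) -> dict:
    """Execute the full pipeline and write a manifest of every artifact.

    ``scenes`` may be given directly (list of :class:`Scene`); otherwise
    scene subdirectories of ``config.input_dir`` are read.  Returns the run
    manifest (also written to ``manifest.json``); processing is fail-soft
    per subject and the manifest records each failure.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    scene_dirs: dict[str, Path] = {}
    if scenes is None:
        if not config.input_dir:
            raise ParameterError("run_pipeline needs scenes or config.input_dir")
        dirs = sorted(d for d in Path(config.input_dir).iterdir()
                      if (d / "manifest.json").exists())
        scenes = []
        for d in dirs:
            s = read_scene(d)
            if not s.subject_id:
                s.subject_id = d.name
            scenes.append(s)
            scene_dirs[s.subject_id] = d

    results = [
        process_scene(
            s, config.backend, scene_dir=scene_dirs.get(s.subject_id),
            origin=config.origin, marker_diameter_mm=config.marker_diameter_mm,
            resize_side=config.resize_side,
        )
        for s in scenes
    ]

    artifacts = {}
    df = results_frame(results)
    df.to_csv(out / "results.csv", index=False)
    artifacts["results.csv"] = _sha256(out / "results.csv")
    pf = profiles_frame(results)
    pf.to_csv(out / "profiles.csv", index=False)
    artifacts["profiles.csv"] = _sha256(out / "profiles.csv")

    verification = None
    labeled = [(r.profile, bool(r.is_abnormal_truth)) for r in results
               if r.ok and r.is_abnormal_truth is not None]
    n_abn = sum(lab for _, lab in labeled)
    if config.verify and n_abn >= 1 and len(labeled) - n_abn >= 2:
        curve = verification_sweep(labeled, ks=config.partitions,
                                   z_crit=config.z_crit)
        verification = {
            "ks": list(curve.ks),
            "sensitivity": {str(k): curve.sensitivity[k] for k in curve.ks},
            "specificity": {str(k): curve.specificity[k] for k in curve.ks},
        }
        vdf = pd.DataFrame({
            "k": list(curve.ks),
            "sensitivity": [curve.sensitivity[k] for k in curve.ks],
            "specificity": [curve.specificity[k] for k in curve.ks],
        })
        vdf.to_csv(out / "verification.csv", index=False)
        artifacts["verification.csv"] = _sha256(out / "verification.csv")
        plot_verification_curve(curve, out / "verification.png")
        artifacts["verification.png"] = _sha256(out / "verification.png")

    manifest = {
        "config": config.to_dict(),
        "n_subjects": len(results),
        "n_failed": sum(not r.ok for r in results),
        "failures": {r.subject_id: r.error for r in results if not r.ok},
        "artifacts": artifacts,
        "verification": verification,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def normative_to_json(model, path) -> None:
    """Serialize a fitted normative model (scheme, means, SDs, z) to JSON."""
    payload = {
        "k": model.scheme.k,
        "interval_deg": model.scheme.interval_deg,
        "z_crit": model.z_crit,
        "n_normal": model.n_normal,
        "method": model.method,
        "mean_mm": [float(x) for x in model.mean_mm],
        "sd_mm": [float(x) for x in model.sd_mm],
    }
    if model.lo_mm is not None:
        payload["lo_mm"] = [float(x) for x in model.lo_mm]
        payload["hi_mm"] = [float(x) for x in model.hi_mm]
    Path(path).write_text(json.dumps(payload, indent=2))


def profiles_from_frame(pf: pd.DataFrame):
    """Rebuild (profile, label) pairs from a profiles CSV table."""
    from .contour import ReferenceFrame

    dummy = ReferenceFrame(origin=(0.0, 0.0), tilt_deg=0.0, u=(0.0, 1.0), n=(-1.0, 0.0))
    cols = [f"d{i:03d}" for i in range(360)]
    out = []
    for _, row in pf.iterrows():
        p = ContourProfile(distances_mm=row[cols].to_numpy(dtype=float),
                           frame=dummy, subject_id=str(row["subject_id"]))
        out.append((p, bool(row.get("is_abnormal", False))))
    return out
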