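"""Synthetic SHG-like collagen images and patient cohorts.

Fibrillar collagen imaged by second-harmonic generation (SHG) appears as
bright curvilinear fibers on a dark background, with junctions where fibers
branch or cross and detector/speckle noise on top.  This module renders that
appearance from an explicit generative model — fibers as angular random
walks with a Gaussian cross-profile — and builds whole patient cohorts in
which a latent "stromal aggressiveness" drives both the fiber architecture
and, together with clinical covariates, a binary nodal-metastasis outcome.
Every output is a pure function of (parameters, seed), and the generating
draw is returned as ground truth so downstream measurements can be checked
against what was actually rendered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .segmentation import ROIImage

MAX_GRAY = 255  # 8-bit output, matching common SHG export
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FiberFieldParams:
    """Generative parameters for one fiber-field image.

    Lengths and widths are in micrometres; intensities in 8-bit gray units.
    ``orientation_kappa`` is the concentration of a von Mises distribution on
    doubled angles (fiber axes are undirected), ``curvature_sd`` the standard
    deviation of the per-step turning angle of the random walk (radians per
    pixel step), and ``crosslink_rate`` the expected number of branch fibers
    seeded per primary fiber.
    """

    n_fibers: int = 60
    length_mean: float = 250.0
    length_sd: float = 80.0
    width_mean: float = 4.0
    orientation_mode: float = 0.0
    orientation_kappa: float = 2.0
    curvature_sd: float = 0.04
    crosslink_rate: float = 0.5
    fiber_intensity_mean: float = 170.0
    fiber_intensity_sd: float = 30.0
    background_noise_sd: float = 8.0
    image_size_px: int = 512
    pixel_size_um: float = 1000.0 / 512.0
    speckle: bool = False
    start_at_center: bool = False  # controlled layouts for validation images

    def __post_init__(self) -> None:
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        for name in ("length_sd", "curvature_sd", "fiber_intensity_sd",
                     "background_noise_sd", "crosslink_rate",
                     "orientation_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.length_mean <= 0 or self.width_mean <= 0:
            raise ValueError("length_mean and width_mean must be positive")

    @property
    def fov_um(self) -> float:
        return self.image_size_px * self.pixel_size_um


@dataclass
class GroundTruth:
    """The generating draw behind one rendered image."""

    centerlines: list[np.ndarray] = field(default_factory=list)  # (n,2) row,col px
    orientations: list[float] = field(default_factory=list)      # axis angle [0,pi)
    lengths_um: list[float] = field(default_factory=list)        # in-image arc length
    width_um: float = 0.0
    crosslinks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_fibers(self) -> int:
        return len(self.centerlines)

    @property
    def n_crosslinks(self) -> int:
        return int(len(self.crosslinks))


def _sample_axis_angle(rng: np.random.Generator, mode: float, kappa: float) -> float:
    """Axis angle in [0, pi) from a doubled-angle von Mises distribution."""
    phi = rng.vonmises(2.0 * mode, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
    return (phi / 2.0) % np.pi


def _walk(rng: np.random.Generator, start: np.ndarray, theta: float,
          n_steps: int, curvature_sd: float) -> np.ndarray:
    """Angular random walk in pixel units; returns (n_steps+1, 2) row/col points."""
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    if n_steps == 0:
        return pts
    turns = rng.normal(0.0, curvature_sd, n_steps) if curvature_sd > 0 else np.zeros(n_steps)
    angles = theta + np.cumsum(np.concatenate([[0.0], turns[:-1]])) if n_steps > 1 \
        else np.array([theta])
    steps = np.stack([np.sin(angles), np.cos(angles)], axis=1)  # (d_row, d_col)
    pts[1:] = start + np.cumsum(steps, axis=0)
    return pts


def _in_image_length_um(pts: np.ndarray, size: int, px_um: float) -> float:
    inside = (pts[:, 0] >= 0) & (pts[:, 0] < size) & (pts[:, 1] >= 0) & (pts[:, 1] < size)
    seg_inside = inside[:-1] & inside[1:]
    if not seg_inside.any():
        return 0.0
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(seg_len[seg_inside].sum() * px_um)


def simulate_fiber_image(params: FiberFieldParams, seed: int) -> tuple[ROIImage, GroundTruth]:
    """Render one synthetic SHG-like ROI image.

    Fibers are rasterized as polylines carrying a per-fiber intensity and
    convolved with a Gaussian whose FWHM equals ``width_mean``; branch fibers
    seeded from points on existing fibers realize crosslinks.  Additive
    Gaussian background noise is clipped to [0, 255].  Identical
    (params, seed) give bitwise-identical images.
    """
    rng = np.random.default_rng(seed)
    size = params.image_size_px
    px = params.pixel_size_um

    gt = GroundTruth(width_um=params.width_mean)
    impulse = np.zeros((size, size), dtype=np.float64)
    crosslinks: list[np.ndarray] = []

    def add_fiber(start: np.ndarray, theta: float) -> None:
        length_um = max(params.length_mean + params.length_sd * rng.standard_normal(),
                        2.0 * px)
        n_steps = max(int(round(length_um / px)), 1)
        pts = _walk(rng, start, theta, n_steps, params.curvature_sd)
        intensity = max(params.fiber_intensity_mean
                        + params.fiber_intensity_sd * rng.standard_normal(), 10.0)
        rr = np.round(pts[:, 0]).astype(int)
        cc = np.round(pts[:, 1]).astype(int)
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        np.maximum.at(impulse, (rr[keep], cc[keep]), intensity)
        gt.centerlines.append(pts)
        gt.orientations.append(theta % np.pi)
        gt.lengths_um.append(_in_image_length_um(pts, size, px))

    for _ in range(params.n_fibers):
        start = (np.array([size / 2.0, size / 2.0]) if params.start_at_center
                 else rng.uniform(0, size, size=2))
        axis = _sample_axis_angle(rng, params.orientation_mode, params.orientation_kappa)
        theta = axis if rng.random() < 0.5 else axis + np.pi
        add_fiber(start, theta)

    n_branches = rng.poisson(params.crosslink_rate * params.n_fibers) \
        if params.n_fibers > 0 and params.crosslink_rate > 0 else 0
    for _ in range(n_branches):
        parent = gt.centerlines[rng.integers(0, len(gt.centerlines))]
        anchor = parent[rng.integers(0, len(parent))]
        axis = _sample_axis_angle(rng, params.orientation_mode, params.orientation_kappa)
        theta = axis if rng.random() < 0.5 else axis + np.pi
        add_fiber(anchor.copy(), theta)
        if 0 <= anchor[0] < size and 0 <= anchor[1] < size:
            crosslinks.append(anchor.copy())
    gt.crosslinks = np.array(crosslinks) if crosslinks else np.empty((0, 2))

    sigma_px = params.width_mean / px / _FWHM
    if impulse.any():
        img = gaussian_filter(impulse, sigma_px)
        # restore ridge amplitude ~ drawn intensity after line blurring
        img *= math.sqrt(2.0 * math.pi) * sigma_px
    else:
        img = impulse
    if params.speckle:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if params.background_noise_sd > 0:
        img = img + rng.normal(0.0, params.background_noise_sd, img.shape)
    pixels = np.clip(img, 0, MAX_GRAY).astype(np.uint8)
    roi = ROIImage(pixels=pixels, pixel_size_um=px, source_id=f"sim-seed{seed}")
    return roi, gt


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def default_aggressiveness_map(agg: float, base: FiberFieldParams) -> FiberFieldParams:
    """Map latent stromal aggressiveness to fiber-field parameters.

    Monotone by construction: more aggressive stroma has more crosslinks,
    less aligned fibers (lower kappa) and dimmer bulk collagen.
    """
    return replace(
        base,
        crosslink_rate=base.crosslink_rate * math.exp(0.6 * agg),
        orientation_kappa=base.orientation_kappa * math.exp(-0.7 * agg),
        fiber_intensity_mean=float(np.clip(base.fiber_intensity_mean - 28.0 * agg,
                                           40.0, 250.0)),
    )


@dataclass(frozen=True)
class CohortParams:
    """Design of a synthetic patient cohort.

    ``outcome_coefficients`` are on the log-odds scale:
    (intercept, aggressiveness, size>1cm, location upper, capsular invasion).
    Covariate prevalences default to the enrolled-cohort frequencies of the
    clinical setting being emulated; the intercept is set so CLNM prevalence
    lands near 41%.
    """

    n_patients: int = 350
    rois_per_patient: int = 5
    prevalence_size_gt1cm: float = 163.0 / 350.0
    prevalence_location_upper: float = 92.0 / 350.0
    prevalence_tci: float = 170.0 / 350.0
    intercept: float = -1.7
    beta_aggressiveness: float = 1.8
    beta_size: float = 1.1
    beta_location_upper: float = 0.95
    beta_tci: float = 0.8
    base_fiber_params: FiberFieldParams = field(default_factory=FiberFieldParams)
    aggressiveness_to_fiber_map: Callable[[float, FiberFieldParams], FiberFieldParams] = \
        default_aggressiveness_map
    render_images: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.rois_per_patient < 1:
            raise ValueError("rois_per_patient must be >= 1")
        for name in ("prevalence_size_gt1cm", "prevalence_location_upper",
                     "prevalence_tci"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PatientRecord:
    patient_id: str
    covariates: dict[str, int]
    label: int
    aggressiveness: float
    true_probability: float
    images: list[ROIImage] = field(default_factory=list)
    ground_truths: list[GroundTruth] = field(default_factory=list)
    cohort: str | None = None
    features: "np.ndarray | None" = None  # patient-level ROI-mean feature values


def simulate_cohort(cparams: CohortParams, seed: int) -> list[PatientRecord]:
    """Draw a full cohort: covariates, latent aggressiveness, outcome, ROI images.

    Each patient's latent aggressiveness is standard normal; clinical
    covariates are independent Bernoulli draws; the CLNM label is Bernoulli
    with inverse-logit(linear predictor).  ROI images (5 per patient in the
    emulated design) are rendered from the aggressiveness-mapped fiber
    parameters with per-ROI seeds spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    patient_seeds = ss.spawn(cparams.n_patients)
    records: list[PatientRecord] = []
    for i, pss in enumerate(patient_seeds):
        rng = np.random.default_rng(pss)
        agg = float(rng.standard_normal())
        cov = {
            "size_gt1cm": int(rng.random() < cparams.prevalence_size_gt1cm),
            "location_upper": int(rng.random() < cparams.prevalence_location_upper),
            "tci": int(rng.random() < cparams.prevalence_tci),
        }
        lp = (cparams.intercept
              + cparams.beta_aggressiveness * agg
              + cparams.beta_size * cov["size_gt1cm"]
              + cparams.beta_location_upper * cov["location_upper"]
              + cparams.beta_tci * cov["tci"])
        prob = 1.0 / (1.0 + math.exp(-lp))
        label = int(rng.random() < prob)
        rec = PatientRecord(patient_id=f"P{i + 1:04d}", covariates=cov, label=label,
                            aggressiveness=agg, true_probability=prob)
        if cparams.render_images:
            fparams = cparams.aggressiveness_to_fiber_map(agg, cparams.base_fiber_params)
            roi_seeds = pss.spawn(cparams.rois_per_patient)
            for rss in roi_seeds:
                roi_seed = int(rss.generate_state(1)[0] % (2 ** 31))
                img, gt = simulate_fiber_image(fparams, roi_seed)
                rec.images.append(img)
                rec.ground_truths.append(gt)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def save_cohort(records: Sequence[PatientRecord], out_dir: str | Path) -> Path:
    """Write ROI TIFFs, ground-truth JSON sidecars and the cohort CSV table."""
    import pandas as pd
    import tifffile

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = []
        for j, (img, gt) in enumerate(zip(rec.images, rec.ground_truths)):
            stem = f"{rec.patient_id}_roi{j + 1}"
            tif_path = img_dir / f"{stem}.tif"
            tifffile.imwrite(tif_path, img.pixels)
            sidecar = {
                "pixel_size_um": img.pixel_size_um,
                "n_fibers": gt.n_fibers,
                "n_crosslinks": gt.n_crosslinks,
                "lengths_um": [round(v, 3) for v in gt.lengths_um],
                "orientations": [round(v, 5) for v in gt.orientations],
                "crosslinks_px": gt.crosslinks.round(2).tolist(),
            }
            (img_dir / f"{stem}.json").write_text(json.dumps(sidecar))
            paths.append(str(tif_path.relative_to(out)))
        rows.append({
            "patient_id": rec.patient_id,
            **rec.covariates,
            "label": rec.label,
            "aggressiveness": rec.aggressiveness,
            "true_probability": rec.true_probability,
            "cohort": rec.cohort or "",
            "roi_paths": ";".join(paths),
        })
    table = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table
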