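"""The 142-feature collagen vocabulary.

Per ROI: 8 morphological features of the traced fiber network, 6 intensity
statistics of the masked collagen pixels, 80 gray-level co-occurrence matrix
(GLCM) statistics (contrast / correlation / energy / uniformity at pixel
distances 1-5 and angles 0/45/90/135 deg) and 48 Gabor filter-bank
statistics (mean and variance of the response magnitude at 4 scales x 6
orientations) — 142 values in a fixed, named order.  Patient-level vectors
are the element-wise mean over that patient's ROIs.

Conventions for degenerate inputs (empty mask, constant image) return
well-defined values and set named flags instead of raising; see the
individual functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import fft as sfft
from scipy import stats as sstats
from scipy.spatial import cKDTree
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel

from .segmentation import (CollagenMask, FiberSet, ROIImage, SegmentationConfig,
                           extract_fibers, segment_collagen)

GLCM_DISTANCES = (1, 2, 3, 4, 5)
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GABOR_WAVELENGTHS = (2.0, 4.0, 8.0, 16.0)   # px; scales s1..s4
GABOR_N_ORIENT = 6                          # o1..o6 at 0,30,...,150 deg

MORPH_NAMES = tuple(f"morph.{n}" for n in (
    "area", "number", "length", "width", "straightness",
    "crosslink_density", "crosslink_space", "arrangement"))
INTENSITY_NAMES = tuple(f"int.{n}" for n in (
    "mean", "variance", "skewness", "kurtosis", "energy", "entropy"))
GLCM_NAMES = tuple(f"glcm.{stat}.d{d}.a{a}"
                   for stat in ("contrast", "correlation", "energy", "uniformity")
                   for d in GLCM_DISTANCES for a in GLCM_ANGLES_DEG)
GABOR_NAMES = tuple(f"gabor.{stat}.s{s}.o{o}"
                    for stat in ("mean", "variance")
                    for s in range(1, 5) for o in range(1, GABOR_N_ORIENT + 1))
FEATURE_NAMES: tuple[str, ...] = MORPH_NAMES + INTENSITY_NAMES + GLCM_NAMES + GABOR_NAMES
assert len(FEATURE_NAMES) == 142


@dataclass(frozen=True)
class FeatureConfig:
    """Texture-extraction settings."""

    n_gray: int = 32                 # GLCM quantization levels
    gabor_bandwidth: float = 1.0     # octaves
    segmentation: SegmentationConfig = SegmentationConfig()


@dataclass
class FeatureVector:
    """142 named collagen features plus degeneracy flags."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values do not match the feature schema")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


# ---------------------------------------------------------------------------
# morphological (8)
# ---------------------------------------------------------------------------

def morphological_features(fibers: FiberSet, mask: CollagenMask
                           ) -> tuple[dict[str, float], set[str]]:
    """Fiber-network morphology: area fraction, count, mean geometry,
    crosslink density (per mm^2 of collagen), mean crosslink nearest-neighbor
    spacing (um) and arrangement (length-weighted circular variance of the
    doubled axis angles; 0 = perfectly aligned, 1 = isotropic)."""
    flags: set[str] = set()
    out = {name: 0.0 for name in MORPH_NAMES}
    out["morph.area"] = mask.collagen_fraction
    n = fibers.n_fibers
    out["morph.number"] = float(n)
    if n == 0:
        flags.add("no_fibers")
        return out, flags
    lengths = np.array([f.length_um for f in fibers.fibers])
    out["morph.length"] = float(lengths.mean())
    out["morph.width"] = float(np.mean([f.mean_width_um for f in fibers.fibers]))
    out["morph.straightness"] = float(np.mean([f.straightness for f in fibers.fibers]))

    area_mm2 = mask.collagen_area_um2 / 1e6
    k = fibers.n_crosslinks
    out["morph.crosslink_density"] = k / area_mm2 if area_mm2 > 0 else 0.0
    if k >= 2:
        pts = fibers.crosslinks * fibers.pixel_size_um
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=2)
        out["morph.crosslink_space"] = float(dist[:, 1].mean())
    else:
        flags.add("few_crosslinks")

    theta = np.array([f.orientation for f in fibers.fibers])
    w = lengths / lengths.sum()
    resultant = np.abs(np.sum(w * np.exp(2j * theta)))
    out["morph.arrangement"] = float(1.0 - resultant)
    return out, flags


# ---------------------------------------------------------------------------
# intensity (6)
# ---------------------------------------------------------------------------

def intensity_features(img: ROIImage, mask: CollagenMask
                       ) -> tuple[dict[str, float], set[str]]:
    """First-order statistics of collagen pixels: mean, variance, skewness
    (3rd standardized moment), kurtosis (4th, non-excess), and histogram
    energy/entropy over a 256-bin normalized histogram."""
    flags: set[str] = set()
    out = {name: 0.0 for name in INTENSITY_NAMES}
    vals = img.pixels[mask.mask].astype(float)
    if vals.size == 0:
        flags.add("no_collagen")
        return out, flags
    out["int.mean"] = float(vals.mean())
    var = float(vals.var())
    out["int.variance"] = var
    if var > 0:
        out["int.skewness"] = float(sstats.skew(vals))
        out["int.kurtosis"] = float(sstats.kurtosis(vals, fisher=False))
    else:
        flags.add("zero_intensity_variance")
    if np.issubdtype(img.pixels.dtype, np.integer):
        hist, _ = np.histogram(vals, bins=256, range=(0, 256))
    else:
        hist, _ = np.histogram(vals, bins=256)
    p = hist / hist.sum()
    out["int.energy"] = float(np.sum(p ** 2))
    nz = p[p > 0]
    out["int.entropy"] = float(-np.sum(nz * np.log2(nz)))
    return out, flags


# ---------------------------------------------------------------------------
# GLCM (80)
# ---------------------------------------------------------------------------

def _quantize(pixels: np.ndarray, n_gray: int) -> np.ndarray:
    arr = pixels.astype(float)
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        return np.zeros(arr.shape, dtype=np.uint8)
    q = np.floor((arr - vmin) / (vmax - vmin) * n_gray).astype(np.int64)
    return np.clip(q, 0, n_gray - 1).astype(np.uint8)


def glcm_features(img: ROIImage, config: FeatureConfig | None = None
                  ) -> tuple[dict[str, float], set[str]]:
    """Contrast, correlation, energy (angular second moment) and uniformity
    (inverse difference moment) of symmetric, normalized GLCMs.

    The image is quantized to ``n_gray`` levels over its observed range; the
    GLCM is computed over the whole ROI (co-occurrence over an irregular
    mask is ill-defined for fixed offsets).  A constant image yields
    contrast 0, energy 1, uniformity 1 and correlation 0 (flagged).
    """
    config = config or FeatureConfig()
    flags: set[str] = set()
    q = _quantize(img.pixels, config.n_gray)
    if img.pixels.min() == img.pixels.max():
        flags.add("constant_image")
    angles = [math.radians(a) for a in GLCM_ANGLES_DEG]
    P = graycomatrix(q, distances=list(GLCM_DISTANCES), angles=angles,
                     levels=config.n_gray, symmetric=True, normed=True)
    i = np.arange(config.n_gray)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    out: dict[str, float] = {}
    for di, d in enumerate(GLCM_DISTANCES):
        for ai, a in enumerate(GLCM_ANGLES_DEG):
            p = P[:, :, di, ai]
            if p.sum() == 0:  # offset exceeds image extent
                p = np.zeros_like(p)
                p[0, 0] = 1.0
                flags.add("glcm_empty_offset")
            contrast = float(np.sum((ii - jj) ** 2 * p))
            mu_i = float(np.sum(ii * p))
            mu_j = float(np.sum(jj * p))
            var_i = float(np.sum((ii - mu_i) ** 2 * p))
            var_j = float(np.sum((jj - mu_j) ** 2 * p))
            if var_i > 0 and var_j > 0:
                corr = float(np.sum((ii - mu_i) * (jj - mu_j) * p)
                             / math.sqrt(var_i * var_j))
            else:
                corr = 0.0
                flags.add("glcm_zero_variance")
            energy = float(np.sum(p ** 2))
            uniformity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
            out[f"glcm.contrast.d{d}.a{a}"] = contrast
            out[f"glcm.correlation.d{d}.a{a}"] = corr
            out[f"glcm.energy.d{d}.a{a}"] = energy
            out[f"glcm.uniformity.d{d}.a{a}"] = uniformity
    return out, flags


# ---------------------------------------------------------------------------
# Gabor (48)
# ---------------------------------------------------------------------------

def gabor_orientations_rad() -> np.ndarray:
    return np.arange(GABOR_N_ORIENT) * np.pi / GABOR_N_ORIENT


def gabor_bank(config: FeatureConfig | None = None) -> list[tuple[int, int, np.ndarray]]:
    """(scale, orientation, complex kernel) for the 4x6 filter bank."""
    config = config or FeatureConfig()
    bank = []
    for s, lam in enumerate(GABOR_WAVELENGTHS, start=1):
        for o, theta in enumerate(gabor_orientations_rad(), start=1):
            kern = gabor_kernel(frequency=1.0 / lam, theta=theta,
                                bandwidth=config.gabor_bandwidth)
            bank.append((s, o, kern))
    return bank


_KERNEL_FFT_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _kernel_ffts(bandwidth: float, s: int, o: int, n: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Padded FFTs of one Gabor kernel's real/imag parts, cached per grid."""
    key = (bandwidth, s, o, n)
    if key not in _KERNEL_FFT_CACHE:
        lam = GABOR_WAVELENGTHS[s - 1]
        theta = gabor_orientations_rad()[o - 1]
        kern = gabor_kernel(frequency=1.0 / lam, theta=theta, bandwidth=bandwidth)
        Kr = sfft.rfft2(np.ascontiguousarray(kern.real), (n, n))
        Ki = sfft.rfft2(np.ascontiguousarray(kern.imag), (n, n))
        _KERNEL_FFT_CACHE[key] = (Kr, Ki)
    return _KERNEL_FFT_CACHE[key]


def _normalize01(pixels: np.ndarray) -> np.ndarray:
    arr = pixels.astype(float)
    if np.issubdtype(pixels.dtype, np.integer):
        info_max = float(np.iinfo(pixels.dtype).max)
        return arr / info_max
    vmax = arr.max()
    return arr / vmax if vmax > 1 else arr


def gabor_features(img: ROIImage, config: FeatureConfig | None = None
                   ) -> tuple[dict[str, float], set[str]]:
    """Mean and variance of the complex Gabor response magnitude per filter.

    Convolution uses symmetric (reflected) boundary handling, evaluated on a
    shared FFT grid — numerically identical to direct spatial convolution
    with the same kernels and boundary mode; the image is first normalized
    to [0, 1].
    """
    config = config or FeatureConfig()
    flags: set[str] = set()
    arr = _normalize01(img.pixels)
    h, w = arr.shape
    bank = gabor_bank(config)
    kmax = max(max(k.shape) for _, _, k in bank)
    if kmax > min(h, w):
        warnings.warn("image smaller than largest Gabor kernel; responses are "
                      "dominated by boundary support", stacklevel=2)
        flags.add("gabor_kernel_clipped")
    pad = min(kmax // 2, min(h, w))  # symmetric padding cannot exceed extent
    arr_p = np.pad(arr, pad, mode="symmetric")
    hp, wp = arr_p.shape
    n = sfft.next_fast_len(max(hp, wp) + kmax - 1, real=True)
    F = sfft.rfft2(arr_p, (n, n))
    out: dict[str, float] = {}
    for s, o, kern in bank:
        Kr, Ki = _kernel_ffts(config.gabor_bandwidth, s, o, n)
        re = sfft.irfft2(F * Kr, (n, n))
        im = sfft.irfft2(F * Ki, (n, n))
        kh, kw = kern.shape
        r0 = (kh - 1) // 2 + pad
        c0 = (kw - 1) // 2 + pad
        mag = np.hypot(re[r0:r0 + h, c0:c0 + w], im[r0:r0 + h, c0:c0 + w])
        out[f"gabor.mean.s{s}.o{o}"] = float(mag.mean())
        out[f"gabor.variance.s{s}.o{o}"] = float(mag.var())
    return out, flags


# ---------------------------------------------------------------------------
# full vector + patient aggregation
# ---------------------------------------------------------------------------

def extract_feature_vector(img: ROIImage, config: FeatureConfig | None = None
                           ) -> FeatureVector:
    """Segment, trace and summarize one ROI into the 142-feature vector."""
    config = config or FeatureConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = segment_collagen(img, config.segmentation)
        fibers = extract_fibers(mask, img, config.segmentation)
        gab, gab_flags = gabor_features(img, config)
    morph, morph_flags = morphological_features(fibers, mask)
    inten, int_flags = intensity_features(img, mask)
    glcm, glcm_flags = glcm_features(img, config)
    flags = morph_flags | int_flags | glcm_flags | gab_flags
    if mask.degenerate:
        flags.add("no_collagen")
    merged = {**morph, **inten, **glcm, **gab}
    values = np.array([merged[name] for name in FEATURE_NAMES])
    return FeatureVector(values=values, flags=frozenset(flags))


def feature_schema() -> list[dict]:
    """Machine-readable schema: name, group and units of all 142 features."""
    units = {"morph.area": "fraction of ROI", "morph.number": "count",
             "morph.length": "um", "morph.width": "um",
             "morph.straightness": "unitless (0,1]",
             "morph.crosslink_density": "per mm^2 collagen",
             "morph.crosslink_space": "um",
             "morph.arrangement": "circular variance [0,1]"}
    schema = []
    for i, name in enumerate(FEATURE_NAMES):
        group = name.split(".")[0]
        schema.append({"index": i, "name": name, "group": group,
                       "units": units.get(name, "arbitrary (gray-derived)")})
    return schema


def aggregate_patient(rois: Sequence[FeatureVector],
                      expected: int = 5) -> FeatureVector:
    """Element-wise mean of a patient's ROI feature vectors."""
    if len(rois) == 0:
        raise ValueError("need at least one ROI feature vector")
    names = rois[0].names
    if any(fv.names != names for fv in rois):
        raise ValueError("mismatched feature schemas")
    if len(rois) != expected:
        warnings.warn(f"expected {expected} ROIs per patient, got {len(rois)}",
                      stacklevel=2)
    values = np.mean([fv.values for fv in rois], axis=0)
    flags = frozenset().union(*[fv.flags for fv in rois])
    return FeatureVector(values=values, names=names, flags=flags)
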