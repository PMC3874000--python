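"""DAB particle quantification of tissue-core images.

Implements the classic semi-automated brightfield quantification chain used for
tissue-microarray cores: grayscale conversion, thresholding of the dark DAB
chromogen, connected-component ("particle") analysis with size/circularity
filters, and standardization of the stained signal by the amount of tissue in
the core.  Tissue amount is measured on the *inverted* grayscale image, where
tissue is bright against a dark background, using the same particle pipeline.

The per-core outputs mirror a particle-analysis spreadsheet row: particle
count, total stained area TA (pixels), average particle size, area fraction
AF = 100*TA / total image pixels (percent), tissue area, and the
tissue-normalized signal TA / tissue_area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_multiotsu, threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "CoreImage",
    "Particle",
    "ParticleSet",
    "QuantResult",
    "QuantConfig",
    "rgb_to_gray",
    "invert",
    "threshold_mask",
    "label_particles",
    "particle_metrics",
    "filter_particles",
    "quantify_core",
]


@dataclass
class CoreImage:
    """One tissue-core image: 2-D grayscale or (H, W, 3) RGB pixel array."""

    pixels: np.ndarray
    bit_depth: int = 8
    core_id: str = "core"

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def validate(self) -> None:
        vmax = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > vmax:
            raise ValueError(
                f"pixel values outside [0, {vmax}] for bit depth {self.bit_depth}"
            )


@dataclass(frozen=True)
class Particle:
    label: int
    area_px: int
    perimeter_px: float
    circularity: float


@dataclass
class ParticleSet:
    """Labeled connected components of a binary mask."""

    labels: np.ndarray  # per-pixel component map, 0 = background
    particles: list[Particle] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.particles)

    @property
    def total_area(self) -> int:
        return int(sum(p.area_px for p in self.particles))


@dataclass
class QuantResult:
    """Per-core quantification record (one spreadsheet row)."""

    core_id: str
    count: int
    total_area: int
    average_size: float
    area_fraction: float  # percent of total image pixels
    tissue_area: int
    normalized_signal: float  # total_area / tissue_area


@dataclass(frozen=True)
class QuantConfig:
    """Configuration of the full per-core quantification chain.

    ``dab_threshold`` / ``tissue_threshold``: ``("fixed", lo, hi)``,
    ``("otsu_dark",)`` or ``("multiotsu_dark",)`` for the DAB step; tissue is
    always detected on the inverted image as the bright side of an Otsu cut
    plus ``tissue_margin`` gray levels (skips faint vignette).  The DAB default
    is a three-class multi-Otsu taking the darkest class, because a stained
    core has three intensity populations (background, unstained tissue, DAB)
    and a single binary cut merges stain with tissue.
    """

    gray_mode: str = "unweighted"  # or "luma"
    dab_threshold: tuple = ("multiotsu_dark",)
    tissue_margin: int = 10
    connectivity: int = 8
    size_min: float = 0.5
    size_max: float = float("inf")
    circ_min: float = 0.0
    circ_max: float = 1.0


def rgb_to_gray(image: CoreImage, mode: str = "unweighted") -> CoreImage:
    """Convert an RGB core image to 16-bit grayscale.

    ``unweighted`` averages the channels, round((R+G+B)/3), matching the plain
    RGB-to-gray default of common image-analysis tools; ``luma`` uses the
    0.299/0.587/0.114 weights.  The 8-bit result is scaled by 257 into the
    16-bit range.  Grayscale input is returned unchanged with a logged notice.
    """
    if not image.is_rgb:
        logger.info("rgb_to_gray: image %s already grayscale; returned unchanged",
                    image.core_id)
        return image
    rgb = image.pixels.astype(np.float64)
    if mode == "unweighted":
        gray8 = np.round(rgb.sum(axis=2) / 3.0)
    elif mode == "luma":
        gray8 = np.round(rgb @ np.array([0.299, 0.587, 0.114]))
    else:
        raise ValueError(f"unknown grayscale mode: {mode!r}")
    gray16 = (gray8.astype(np.uint16)) * 257
    return CoreImage(pixels=gray16, bit_depth=16, core_id=image.core_id)


def invert(image: CoreImage) -> CoreImage:
    """Invert a grayscale image: v -> (2**bit_depth - 1) - v. An involution."""
    if image.is_rgb:
        raise ValueError("invert expects a grayscale image")
    vmax = 2**image.bit_depth - 1
    return CoreImage(
        pixels=(vmax - image.pixels.astype(np.int64)).astype(image.pixels.dtype),
        bit_depth=image.bit_depth,
        core_id=image.core_id,
    )


def threshold_mask(image: CoreImage, method: tuple = ("otsu_dark",)) -> np.ndarray:
    """Binary mask from a grayscale image.

    ``("fixed", lo, hi)`` keeps lo <= v <= hi.  ``("otsu_dark",)`` computes
    Otsu's inter-class-variance-maximizing cut on the histogram and keeps the
    dark side v <= t (DAB is dark).  ``("multiotsu_dark",)`` computes a
    three-class multi-Otsu and keeps the darkest class.  A constant image under
    an Otsu method yields an empty mask with a warning (no separable classes).
    """
    if image.is_rgb:
        raise ValueError("threshold_mask expects a grayscale image")
    v = image.pixels
    name = method[0]
    if name == "fixed":
        _, lo, hi = method
        if lo > hi:
            raise ValueError("fixed threshold requires lo <= hi")
        return (v >= lo) & (v <= hi)
    if name in ("otsu_dark", "multiotsu_dark"):
        uniq = np.unique(v)
        if uniq.size < 2:
            warnings.warn(
                f"{name}: constant image, no separable classes; empty mask",
                stacklevel=2,
            )
            return np.zeros_like(v, dtype=bool)
        if name == "otsu_dark" or uniq.size < 3:
            t = threshold_otsu(v)
        else:
            # float cast keeps the histogram at 256 bins for 16-bit input
            t = threshold_multiotsu(v.astype(np.float64), classes=3)[0]
        return v <= t
    raise ValueError(f"unknown threshold method: {method!r}")


def _flood_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    conn = 1 if connectivity == 4 else 2
    return measure.label(mask, connectivity=conn)


def particle_metrics(particle_mask: np.ndarray) -> tuple[int, float, float]:
    """Area, perimeter and circularity of one particle mask.

    Perimeter is the crack length: the number of pixel edges on the boundary
    between the particle and its complement (a single pixel has perimeter 4, a
    3x3 square 12).  Circularity = min(1, 4*pi*area / perimeter**2).
    """
    m = particle_mask.astype(bool)
    area = int(m.sum())
    if area == 0:
        raise ValueError("particle must contain at least one pixel")
    padded = np.pad(m, 1)
    # exposed edges: foreground-background transitions along both axes
    perim = int(
        (padded[1:, :] != padded[:-1, :]).sum() + (padded[:, 1:] != padded[:, :-1]).sum()
    )
    circ = min(1.0, 4.0 * np.pi * area / perim**2)
    return area, float(perim), circ


def label_particles(mask: np.ndarray, connectivity: int = 8) -> ParticleSet:
    """Label maximal connected components of a binary mask as particles.

    Connectivity 8 (the common particle-analysis convention) or 4.  Labels are
    dense from 1; each particle carries its area, crack-length perimeter and
    clipped circularity.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels = _flood_label(mask, connectivity)
    particles: list[Particle] = []
    # per-label bounding boxes via regionprops keeps metric computation local
    for region in measure.regionprops(labels):
        sub = labels[region.slice] == region.label
        area, perim, circ = particle_metrics(sub)
        particles.append(Particle(region.label, area, perim, circ))
    return ParticleSet(labels=labels, particles=particles)


def filter_particles(
    ps: ParticleSet,
    size_min: float = 0.5,
    size_max: float = float("inf"),
    circ_min: float = 0.0,
    circ_max: float = 1.0,
) -> ParticleSet:
    """Keep particles with size_min <= area <= size_max and circularity in
    [circ_min, circ_max] (all bounds inclusive).

    With the conventional defaults (size 0.5-Infinity in pixel units,
    circularity 0-1) every particle survives, since any particle has area >= 1.
    """
    if size_min > size_max:
        raise ValueError("size_min must not exceed size_max")
    keep = [
        p
        for p in ps.particles
        if size_min <= p.area_px <= size_max and circ_min <= p.circularity <= circ_max
    ]
    kept_labels = {p.label for p in keep}
    labels = np.where(np.isin(ps.labels, list(kept_labels)), ps.labels, 0)
    return ParticleSet(labels=labels, particles=keep)


def quantify_core(image: CoreImage, config: QuantConfig = QuantConfig()) -> QuantResult:
    """Run the full DAB quantification chain on one core image.

    Grayscale conversion, DAB threshold (dark side), particle labeling and
    filtering give count, total area TA, average size and area fraction
    AF = 100*TA/total pixels.  The grayscale image is then inverted and the
    bright side of an Otsu cut (plus a safety margin) thresholded to measure
    tissue area; ``normalized_signal`` = TA / tissue_area (0 with a warning
    when no tissue is detected).
    """
    gray = rgb_to_gray(image, mode=config.gray_mode) if image.is_rgb else image
    n_px = gray.height_px * gray.width_px

    dab_mask = threshold_mask(gray, method=config.dab_threshold)
    ps = label_particles(dab_mask, connectivity=config.connectivity)
    ps = filter_particles(
        ps, config.size_min, config.size_max, config.circ_min, config.circ_max
    )
    total_area = ps.total_area
    count = ps.count
    average_size = total_area / count if count else 0.0
    area_fraction = 100.0 * total_area / n_px

    # tissue standardization: invert, keep the bright side of the lowest cut.
    # A stained core has three classes on the inverted image too (dark
    # background, mid tissue, bright stain); the first multi-Otsu cut isolates
    # background so tissue + stain are counted as tissue.  A binary Otsu cut
    # would drift up to the tissue/stain boundary when stain is abundant.
    inv = invert(gray)
    v = inv.pixels
    uniq = np.unique(v)
    if uniq.size < 2:
        tissue_mask = np.zeros_like(v, dtype=bool)
    else:
        if uniq.size >= 3:
            t = threshold_multiotsu(v.astype(np.float64), classes=3)[0]
        else:
            t = threshold_otsu(v)
        margin = config.tissue_margin * (257 if inv.bit_depth == 16 else 1)
        tissue_mask = v >= t + margin
    tissue_ps = label_particles(tissue_mask, connectivity=config.connectivity)
    tissue_ps = filter_particles(
        tissue_ps, config.size_min, config.size_max, config.circ_min, config.circ_max
    )
    tissue_area = tissue_ps.total_area

    if tissue_area == 0:
        if total_area > 0:
            warnings.warn(
                f"core {image.core_id}: stain detected but no tissue; "
                "normalized_signal set to 0",
                stacklevel=2,
            )
        normalized = 0.0
    else:
        normalized = total_area / tissue_area

    return QuantResult(
        core_id=image.core_id,
        count=count,
        total_area=total_area,
        average_size=average_size,
        area_fraction=area_fraction,
        tissue_area=tissue_area,
        normalized_signal=normalized,
    )
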