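"""Synthetic tissue-core and fluorescence-stack generators with known ground truth.

Real tissue-microarray images from the study this pipeline emulates were never
deposited, so every downstream stage is exercised on synthetic data in which the
quantity the pipeline is supposed to recover — stained area fraction, channel
correlation, group effect size — is known exactly by construction.

Three generators are provided:

* :func:`generate_core_image` — a brightfield DAB-stained tissue core: a
  disc-like tissue region on a near-white background, with dark-brown elliptical
  "stain" blobs whose union covers a prescribed fraction of the image.  The
  ground-truth tissue and stain masks are returned alongside the RGB image.
* :func:`generate_fluorescence_stack` — a multi-channel 16-bit stack whose
  channels are linear mixes of shared latent Gaussian fields, so every channel
  pair realizes a prescribed Pearson correlation.
* :func:`generate_cohort` — per-core area-fraction samples for a benign and a
  malignant group with prescribed means and standard errors, emulating the
  statistical structure of a tissue-microarray cohort.

All generators are pure functions of their spec (including its seed): the same
spec yields bit-identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoreSpec",
    "FluorSpec",
    "CohortSpec",
    "InvalidSpecError",
    "generate_core_image",
    "generate_fluorescence_stack",
    "generate_cohort",
]

# DAB color model: three well-separated classes so that an unweighted grayscale
# conversion leaves >40 gray levels between stain (~60), tissue (~183) and
# background (>=245).
STAIN_RGB = (90, 60, 30)
TISSUE_RGB = (200, 170, 180)
BACKGROUND_GRAY = 250


class InvalidSpecError(ValueError):
    """A generator spec violates one of its invariants."""


@dataclass(frozen=True)
class CoreSpec:
    """Parameters of one synthetic DAB-stained tissue core.

    ``stained_fraction`` is the ground-truth area fraction divided by 100: the
    proportion of *image* pixels covered by stain.  Stain always lies on
    tissue, so ``stained_fraction <= tissue_fraction`` is required.
    """

    image_width_px: int = 1024
    image_height_px: int = 1024
    tissue_fraction: float = 0.5
    stained_fraction: float = 0.02
    blob_count: int = 30
    noise_sd: float = 4.0
    jpeg_quality: int | str = "lossless"
    seed: int = 0

    def validate(self) -> None:
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise InvalidSpecError("image dimensions must be positive")
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise InvalidSpecError("tissue_fraction must be in (0, 1]")
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise InvalidSpecError("stained_fraction must be in [0, 1]")
        if self.stained_fraction > self.tissue_fraction:
            raise InvalidSpecError(
                "stained_fraction must not exceed tissue_fraction "
                "(stain lies on tissue)"
            )
        if self.blob_count < 1:
            raise InvalidSpecError("blob_count must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.jpeg_quality != "lossless" and not (
            isinstance(self.jpeg_quality, int) and 1 <= self.jpeg_quality <= 100
        ):
            raise InvalidSpecError("jpeg_quality must be 1-100 or 'lossless'")


@dataclass(frozen=True)
class FluorSpec:
    """Parameters of one synthetic multi-channel fluorescence stack.

    ``pairwise_rho`` maps frozenset-able channel-name pairs (given as tuples)
    to target Pearson correlations.  The implied correlation matrix (unit
    diagonal, symmetric) must be positive semi-definite.
    """

    n_slices: int = 8
    channels: tuple[str, ...] = ("FITC", "Cy3", "Cy5")
    pairwise_rho: tuple[tuple[str, str, float], ...] = (("FITC", "Cy3", 0.73),)
    n_pixels_per_slice: int = 128 * 128
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.channels)
        idx = {name: i for i, name in enumerate(self.channels)}
        rho = np.eye(k)
        for a, b, r in self.pairwise_rho:
            if a not in idx or b not in idx:
                raise InvalidSpecError(f"unknown channel in pair ({a}, {b})")
            if not -1.0 <= r <= 1.0:
                raise InvalidSpecError("target correlations must lie in [-1, 1]")
            rho[idx[a], idx[b]] = rho[idx[b], idx[a]] = r
        return rho

    def validate(self) -> None:
        if self.n_slices < 1:
            raise InvalidSpecError("n_slices must be positive")
        if self.n_pixels_per_slice < 4:
            raise InvalidSpecError("n_pixels_per_slice too small")
        if len(set(self.channels)) != len(self.channels):
            raise InvalidSpecError("channel names must be unique")
        rho = self.correlation_matrix()
        eigvals = np.linalg.eigvalsh(rho)
        if eigvals.min() < -1e-9:
            raise InvalidSpecError(
                "target correlation matrix is not positive semi-definite"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort of per-core area fractions.

    Means and standard errors are in area-fraction percent; draws come from a
    gamma or lognormal family matched to the implied group mean and SD
    (SD = SE * sqrt(n)), so all values are strictly positive.
    """

    n_benign: int = 236
    n_malignant: int = 228
    benign_mean_af: float = 1.66
    malignant_mean_af: float = 4.09
    benign_se: float = 0.12
    malignant_se: float = 0.27
    distribution_family: str = "gamma"
    seed: int = 0

    def validate(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise InvalidSpecError("group sizes must be positive")
        if self.benign_mean_af <= 0 or self.malignant_mean_af <= 0:
            raise InvalidSpecError("group mean area fractions must be positive")
        if self.benign_se < 0 or self.malignant_se < 0:
            raise InvalidSpecError("standard errors must be non-negative")
        if self.distribution_family not in ("gamma", "lognormal"):
            raise InvalidSpecError("distribution_family must be gamma or lognormal")


@dataclass
class SyntheticCore:
    """A generated core image plus its ground truth."""

    core_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    tissue_mask: np.ndarray  # (H, W) bool
    stained_mask: np.ndarray  # (H, W) bool
    true_tissue_fraction: float = field(init=False)
    true_stained_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        n = self.pixels.shape[0] * self.pixels.shape[1]
        self.true_tissue_fraction = float(self.tissue_mask.sum()) / n
        self.true_stained_fraction = float(self.stained_mask.sum()) / n


def _tissue_mask(h: int, w: int, tissue_fraction: float) -> np.ndarray:
    """Exact-count disc-like tissue region: the round(tf*H*W) pixels nearest
    the image center, ties broken by raster order (deterministic)."""
    n_tissue = int(round(tissue_fraction * h * w))
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    mask = np.zeros(h * w, dtype=bool)
    mask[order[:n_tissue]] = True
    return mask.reshape(h, w)


def _rasterize_ellipses(
    h: int, w: int, params: np.ndarray, scale: float, tissue: np.ndarray
) -> np.ndarray:
    """Union of ellipses (cy, cx, ry, rx, theta), radii scaled, clipped to tissue.

    Each ellipse is rasterized only inside its bounding box.
    """
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, ry, rx, theta in params:
        ry, rx = max(ry * scale, 0.3), max(rx * scale, 0.3)
        r = max(ry, rx)
        y0, y1 = max(int(cy - r - 1), 0), min(int(cy + r + 2), h)
        x0, x1 = max(int(cx - r - 1), 0), min(int(cx + r + 2), w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        c, s = np.cos(theta), np.sin(theta)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        mask[y0:y1, x0:x1] |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    mask &= tissue
    return mask


def generate_core_image(spec: CoreSpec, core_id: str = "core") -> SyntheticCore:
    """Generate one synthetic DAB-stained tissue core with ground-truth masks.

    The stained mask is the union of ``blob_count`` random ellipses centered on
    tissue, intersected with the tissue mask; a global radius scale is set by
    bisection so the realized stained fraction matches ``spec.stained_fraction``
    well within 0.5 percentage points.  Colors follow the three-class DAB model
    (dark brown stain, pink-gray tissue, near-white background) with optional
    i.i.d. Gaussian noise; ``jpeg_quality`` other than ``"lossless"`` round-trips
    the image through in-memory JPEG compression.
    """
    spec.validate()
    h, w = spec.image_height_px, spec.image_width_px
    rng = np.random.default_rng(spec.seed)

    tissue = _tissue_mask(h, w, spec.tissue_fraction)
    n_px = h * w
    target = spec.stained_fraction * n_px

    if target < 0.5:
        stained = np.zeros((h, w), dtype=bool)
    else:
        ty, tx = np.nonzero(tissue)
        pick = rng.integers(0, len(ty), size=spec.blob_count)
        # unit-scale radii: expected total ellipse area ~ target (pre-overlap)
        base_area = target / spec.blob_count
        base_r = np.sqrt(base_area / np.pi)
        aspect = rng.uniform(0.5, 2.0, size=spec.blob_count)
        rfac = rng.uniform(0.6, 1.6, size=spec.blob_count)
        params = np.column_stack(
            [
                ty[pick].astype(float),
                tx[pick].astype(float),
                base_r * rfac * np.sqrt(aspect),
                base_r * rfac / np.sqrt(aspect),
                rng.uniform(0, np.pi, size=spec.blob_count),
            ]
        )
        # bisection on a global radius scale; union area is monotone in scale
        lo, hi = 0.0, 1.0
        while _rasterize_ellipses(h, w, params, hi, tissue).sum() < target and hi < 64:
            hi *= 2.0
        stained = _rasterize_ellipses(h, w, params, hi, tissue)
        if stained.sum() > target:
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                cand = _rasterize_ellipses(h, w, params, mid, tissue)
                if cand.sum() < target:
                    lo = mid
                else:
                    hi = mid
                    stained = cand
                if abs(stained.sum() - target) <= max(1.0, 2e-4 * n_px):
                    break

    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = BACKGROUND_GRAY
    img[tissue] = TISSUE_RGB
    img[stained] = STAIN_RGB
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    if spec.jpeg_quality != "lossless":
        from PIL import Image

        buf = io.BytesIO()
        Image.fromarray(pixels).save(buf, format="JPEG", quality=int(spec.jpeg_quality))
        buf.seek(0)
        pixels = np.asarray(Image.open(buf).convert("RGB"))

    return SyntheticCore(core_id=core_id, pixels=pixels, tissue_mask=tissue, stained_mask=stained)


@dataclass
class SyntheticStack:
    """A generated fluorescence stack plus realized pairwise correlations."""

    channels: dict[str, np.ndarray]  # name -> (n_slices, H, W) uint16
    realized_rho: dict[tuple[str, str], float]


def generate_fluorescence_stack(spec: FluorSpec) -> SyntheticStack:
    """Generate a multi-channel 16-bit fluorescence stack with controlled
    pairwise Pearson correlations.

    Channels are linear mixes of i.i.d. standard-normal latent fields through
    the Cholesky factor of the target correlation matrix, then affinely mapped
    into the 16-bit range.  Correlations are exact in expectation; the realized
    sample correlations (computed after quantization) are returned as ground
    truth.
    """
    spec.validate()
    rho = spec.correlation_matrix()
    k = len(spec.channels)
    rng = np.random.default_rng(spec.seed)

    # PSD-safe factor: eigen-decomposition with tiny negative eigenvalues clipped
    eigval, eigvec = np.linalg.eigh(rho)
    factor = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))

    side = int(np.floor(np.sqrt(spec.n_pixels_per_slice)))
    hw = (side, max(spec.n_pixels_per_slice // side, 1))
    n = spec.n_slices * hw[0] * hw[1]
    latent = rng.standard_normal(size=(k, n))
    fields = factor @ latent  # (k, n), target correlation structure

    channels: dict[str, np.ndarray] = {}
    for i, name in enumerate(spec.channels):
        f = fields[i]
        lo_v, hi_v = f.min(), f.max()
        span = hi_v - lo_v
        if span == 0:
            scaled = np.full_like(f, 32768.0)
        else:
            scaled = 2000.0 + (f - lo_v) / span * 60000.0
        channels[name] = np.round(scaled).astype(np.uint16).reshape(
            spec.n_slices, hw[0], hw[1]
        )

    realized: dict[tuple[str, str], float] = {}
    for a, b, _ in spec.pairwise_rho:
        x = channels[a].astype(np.float64).ravel()
        y = channels[b].astype(np.float64).ravel()
        if x.std() == 0 or y.std() == 0:
            realized[(a, b)] = float("nan")
        else:
            realized[(a, b)] = float(np.corrcoef(x, y)[0, 1])
    return SyntheticStack(channels=channels, realized_rho=realized)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a two-group cohort of per-core area fractions.

    Returns a tidy table with one row per core: ``core_id``, ``patient_id``,
    ``marker_name``, ``area_fraction`` (percent), ``normalized_signal``,
    ``diagnosis`` (benign/malignant), ``gleason``, ``relapse``.  Group draws
    come from a gamma or lognormal distribution matched to the requested mean
    and SD (SE * sqrt(n)); both families are strictly positive.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def draw(n: int, mean: float, se: float) -> np.ndarray:
        sd = se * np.sqrt(n)
        if sd == 0:
            return np.full(n, mean)
        if spec.distribution_family == "gamma":
            shape = (mean / sd) ** 2
            scale = sd**2 / mean
            return rng.gamma(shape, scale, size=n)
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)

    benign = draw(spec.n_benign, spec.benign_mean_af, spec.benign_se)
    malignant = draw(spec.n_malignant, spec.malignant_mean_af, spec.malignant_se)

    gleason_m = rng.choice(["3+4", "4+3"], size=spec.n_malignant)
    relapse_m = rng.choice(["yes", "no"], size=spec.n_malignant)

    rows = []
    for i, v in enumerate(benign):
        rows.append(
            dict(
                core_id=f"B{i:04d}",
                patient_id=f"P{i % 41:03d}",
                marker_name="synthetic",
                area_fraction=float(np.clip(v, 0.0, 100.0)),
                normalized_signal=float(np.clip(v, 0.0, 100.0)) / 100.0,
                diagnosis="benign",
                gleason="NA",
                relapse="NA",
            )
        )
    for i, v in enumerate(malignant):
        rows.append(
            dict(
                core_id=f"M{i:04d}",
                patient_id=f"P{41 + i % 41:03d}",
                marker_name="synthetic",
                area_fraction=float(np.clip(v, 0.0, 100.0)),
                normalized_signal=float(np.clip(v, 0.0, 100.0)) / 100.0,
                diagnosis="malignant",
                gleason=gleason_m[i],
                relapse=relapse_m[i],
            )
        )
    return pd.DataFrame(rows)
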