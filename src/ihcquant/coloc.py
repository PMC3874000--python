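"""Pearson colocalization of fluorescence channel pairs and group comparison.

Co-expression of two immunofluorescently labeled proteins is measured by the
pixel-wise Pearson correlation of their channels, computed on a maximum
Z-projection of the stack and restricted to a signal mask (background pixels
carry no biology and inflate r).  Matched relapse / non-relapse cores are then
compared with a paired t-test on the per-pair coefficients, optionally after a
Fisher z transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu

__all__ = [
    "ColocResult",
    "max_project",
    "coloc_mask",
    "pearson_coloc",
    "compare_coloc_groups",
]


@dataclass
class ColocResult:
    channel_pair: tuple[str, str]
    pearson_r: float
    n_pixels_used: int
    mask_mode: str


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity Z-projection: per-pixel max across slices.

    Accepts (n_slices, H, W); a 2-D image is returned unchanged (idempotent).
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (n_slices, H, W) stack with >= 1 slice")
    return stack.max(axis=0)


def _otsu_or_min(ch: np.ndarray) -> float:
    u = np.unique(ch)
    if u.size < 2:
        return float(u[0])
    return float(threshold_otsu(ch))


def coloc_mask(ch_a: np.ndarray, ch_b: np.ndarray, mode: str = "either_above",
               t_a: float | None = None, t_b: float | None = None) -> np.ndarray:
    """Pixel mask for colocalization analysis.

    ``all_pixels`` uses the whole frame; ``either_above`` keeps pixels above
    threshold in at least one channel (default mode, per-channel Otsu
    thresholds when not given) — it restricts to tissue signal while keeping
    pixels where only one marker is expressed; ``both_above`` requires both.
    An empty mask raises with a hint to relax the mode.
    """
    ch_a = np.asarray(ch_a)
    ch_b = np.asarray(ch_b)
    if ch_a.shape != ch_b.shape:
        raise ValueError("channels must share the same shape")
    if mode == "all_pixels":
        return np.ones(ch_a.shape, dtype=bool)
    ta = _otsu_or_min(ch_a) if t_a is None else t_a
    tb = _otsu_or_min(ch_b) if t_b is None else t_b
    if mode == "either_above":
        mask = (ch_a > ta) | (ch_b > tb)
    elif mode == "both_above":
        mask = (ch_a > ta) & (ch_b > tb)
    else:
        raise ValueError(f"unknown mask mode: {mode!r}")
    if not mask.any():
        raise ValueError(
            "colocalization mask is empty; lower the thresholds or use "
            "mode='all_pixels'"
        )
    return mask


def pearson_coloc(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: np.ndarray | None = None,
    channel_pair: tuple[str, str] = ("ch_a", "ch_b"),
    mask_mode: str = "custom",
) -> ColocResult:
    """Pearson correlation of two channels over the masked pixels.

    r = sum((a - a_bar)(b - b_bar)) / sqrt(sum((a - a_bar)^2) sum((b - b_bar)^2));
    symmetric in its arguments and invariant under positive affine rescaling
    of either channel.  A constant channel on the mask has no defined
    correlation and raises.
    """
    ch_a = np.asarray(ch_a, dtype=np.float64)
    ch_b = np.asarray(ch_b, dtype=np.float64)
    if ch_a.shape != ch_b.shape:
        raise ValueError("channels must share the same shape")
    if mask is None:
        mask = np.ones(ch_a.shape, dtype=bool)
        mask_mode = "all_pixels"
    a = ch_a[mask]
    b = ch_b[mask]
    if a.size < 2:
        raise ValueError("need at least 2 masked pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant channel on mask: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocResult(
        channel_pair=channel_pair,
        pearson_r=r,
        n_pixels_used=int(a.size),
        mask_mode=mask_mode,
    )


def compare_coloc_groups(
    pairs: list[tuple[float, float]], fisher_z: bool = False
) -> dict:
    """Compare colocalization between matched groups (non-relapse, relapse).

    ``pairs`` holds one (r_nonrelapse, r_relapse) tuple per matched pair.
    Returns group means and SDs of r and the two-sided paired t-test p-value
    on the per-pair differences; with ``fisher_z`` the coefficients are
    arctanh-transformed before testing (the test is still reported on the
    transformed scale, means/SDs on the raw r scale).  All-zero differences
    give p = 1 with a degenerate-variance warning.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    arr = np.asarray(pairs, dtype=float)
    non, rel = arr[:, 0], arr[:, 1]
    out = dict(
        n_pairs=len(pairs),
        nonrelapse_mean=float(non.mean()),
        nonrelapse_sd=float(non.std(ddof=1)),
        relapse_mean=float(rel.mean()),
        relapse_sd=float(rel.std(ddof=1)),
    )
    a, b = (np.arctanh(non), np.arctanh(rel)) if fisher_z else (non, rel)
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            warnings.warn("all pair differences are zero; p = 1", stacklevel=2)
            out["p_two_sided"] = 1.0
            out["t"] = 0.0
            return out
        warnings.warn("pair differences have zero variance; p degenerate",
                      stacklevel=2)
        out["p_two_sided"] = 1.0
        out["t"] = float("inf")
        return out
    t, p = sps.ttest_rel(a, b)
    out["t"] = float(t)
    out["p_two_sided"] = float(p)
    return out
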