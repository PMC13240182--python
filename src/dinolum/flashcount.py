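"""Luminescent-cell counting and intensity quantification from flash videos.

The analysis chain mirrors the study's image pipeline: extract the blue
channel, mask the sample region, subtract a fixed noise threshold
(70/255 by default, clipped at zero), integrate pixel intensities with the
trapezoidal rule, and count cells as suppressed local maxima per frame.
A cell flashing across many frames is counted once via the pixel-wise
maximum projection of the stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .datatypes import ActivationMap, FrameStack, LuminescenceTrace

__all__ = [
    "blue_channel",
    "mask_and_threshold",
    "frame_intensity",
    "detect_maxima",
    "trace_series",
    "unique_cell_count",
    "decay_window",
    "activation_map",
    "auto_mask",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_SEPARATION_PX",
]

DEFAULT_THRESHOLD = 70          # 8-bit signal/noise cut used throughout
DEFAULT_MIN_SEPARATION_PX = 5   # maxima suppression radius


def blue_channel(stack: FrameStack) -> np.ndarray:
    """Blue plane of an RGB stack, 8-bit range preserved.

    Dinoflagellate flashes peak near 470 nm, so the blue channel carries
    essentially all the luminescence signal.
    """
    frames = stack.frames
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("blue_channel requires an RGB stack")
    return frames[..., 2]


def mask_and_threshold(image: np.ndarray, mask: np.ndarray,
                       threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Zero pixels outside the mask; subtract the threshold, clipped at zero."""
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must lie in [0, 255]")
    img = np.asarray(image, dtype=float)
    out = np.clip(img - threshold, 0.0, None)
    out[~np.asarray(mask, dtype=bool)] = 0.0
    return out


def frame_intensity(image: np.ndarray) -> float:
    """Total intensity of a thresholded frame: 2-D trapezoidal integral.

    Unit pixel spacing, integrated along rows then columns; equals the
    plain pixel sum up to edge effects.
    """
    img = np.asarray(image, dtype=float)
    return float(np.trapezoid(np.trapezoid(img, axis=1), axis=0))


def detect_maxima(image: np.ndarray,
                  min_separation_px: float = DEFAULT_MIN_SEPARATION_PX
                  ) -> list[tuple[int, int]]:
    """Strict local maxima above zero with minimum-separation suppression.

    8-connected neighbourhood; a plateau of equal pixels yields one
    representative (its row-major first pixel). Suppression keeps the
    brighter of two maxima closer than ``min_separation_px`` (Euclidean),
    breaking intensity ties in row-major order.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return []
    # local-max criterion on plateaus: pixel equals the 3x3 max and > 0
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (img == ndimage.maximum_filter(img, footprint=footprint,
                                               mode="constant", cval=-np.inf))
    local_max &= img > 0
    # plateau handling: keep one representative per connected component,
    # but only for components that are true maxima (no brighter neighbour)
    labels, n = ndimage.label(local_max, structure=footprint)
    candidates: list[tuple[float, int, int]] = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        # row-major first pixel is the representative
        order = np.lexsort((cols, rows))
        r, c = int(rows[order[0]]), int(cols[order[0]])
        candidates.append((float(img[r, c]), r, c))

    # brighter-first, ties row-major
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[int, int]] = []
    min_sq = min_separation_px ** 2
    for _, r, c in candidates:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sq for kr, kc in kept):
            kept.append((r, c))
    return kept


def auto_mask(stack: FrameStack) -> np.ndarray:
    """Circular sample mask fitted to the bright outline of the mean frame.

    Otsu-thresholds the time-averaged blue channel, takes the largest
    connected component and fits an enclosing circle via its centroid and
    equivalent-area radius. The fit presumes a partly illuminated setup
    where the sample outline dominates the mean frame; when the bright
    region covers under 2% of the frame (a fully dark scene with only a
    few flashes) the whole frame is used instead.
    """
    mean_img = blue_channel(stack).mean(axis=0)
    full = np.ones(mean_img.shape, dtype=bool)
    if mean_img.max() <= mean_img.min():
        return full
    thr = threshold_otsu(mean_img)
    fg = mean_img > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return full
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    if comp.sum() < 0.02 * mean_img.size:
        return full
    rows, cols = np.nonzero(comp)
    r0, c0 = rows.mean(), cols.mean()
    radius = math.sqrt(comp.sum() / math.pi)
    rr, cc = np.mgrid[0:mean_img.shape[0], 0:mean_img.shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2


def trace_series(stack: FrameStack,
                 threshold: float = DEFAULT_THRESHOLD,
                 min_separation_px: float = DEFAULT_MIN_SEPARATION_PX
                 ) -> LuminescenceTrace:
    """Per-frame luminescent-cell count and total intensity for one stack."""
    blue = blue_channel(stack)
    n_frames = stack.n_frames
    n_cells = np.zeros(n_frames, dtype=int)
    intensity = np.zeros(n_frames)
    for k in range(n_frames):
        img = mask_and_threshold(blue[k], stack.mask, threshold)
        n_cells[k] = len(detect_maxima(img, min_separation_px))
        intensity[k] = frame_intensity(img)
    n_max = int(n_cells.max()) if n_frames else 0
    unique, proj_integral = unique_cell_count(
        stack, threshold, min_separation_px, return_integral=True
    )
    return LuminescenceTrace(
        time=stack.timestamps, n_cells=n_cells, total_intensity=intensity,
        n_max=n_max, unique_cells=max(unique, n_max),
        projected_integral=proj_integral,
    )


def unique_cell_count(stack: FrameStack,
                      threshold: float = DEFAULT_THRESHOLD,
                      min_separation_px: float = DEFAULT_MIN_SEPARATION_PX,
                      return_integral: bool = False):
    """Count each cell once via the maximum projection over time.

    The pixel-wise maximum projection collapses repeated flashes of the
    same cell onto one blob; maxima counted on the thresholded projection
    give the de-duplicated cell total. The trapezoidal integral of the
    same projection is also computed (an intensity-weighted alternative
    readout) and returned when ``return_integral`` is set.
    """
    blue = blue_channel(stack)
    if stack.n_frames == 0:
        return (0, 0.0) if return_integral else 0
    projection = blue.max(axis=0)
    img = mask_and_threshold(projection, stack.mask, threshold)
    count = len(detect_maxima(img, min_separation_px))
    if return_integral:
        return count, frame_intensity(img)
    return count


@dataclass
class DecayWindowResult:
    """Time for the luminescent-cell count to fall to a fraction of its peak."""

    seconds: float
    truncated: bool  # clip ended before the trace fell below the fraction


def decay_window(trace: LuminescenceTrace,
                 fraction: float = 0.1) -> DecayWindowResult:
    """Elapsed time from the peak frame until n_cells first falls to
    ``fraction * n_max``, with linear interpolation between frames.

    If the trace never falls that low within the clip, the clip-truncated
    elapsed time is returned with ``truncated=True``.
    """
    if trace.n_max <= 0:
        raise ValueError("decay_window requires n_max > 0")
    n = trace.n_cells.astype(float)
    t = trace.time
    peak_idx = int(np.argmax(n))
    target = fraction * trace.n_max
    for k in range(peak_idx + 1, len(n)):
        if n[k] <= target:
            if n[k - 1] == n[k]:
                crossing = t[k]
            else:
                frac = (n[k - 1] - target) / (n[k - 1] - n[k])
                crossing = t[k - 1] + frac * (t[k] - t[k - 1])
            return DecayWindowResult(seconds=float(crossing - t[peak_idx]),
                                     truncated=False)
    return DecayWindowResult(seconds=float(t[-1] - t[peak_idx]),
                             truncated=True)


def activation_map(results: Sequence[tuple[float, float, int]]) -> ActivationMap:
    """Grid of peak cell counts over (strain, rate), normalised to [0, 1].

    ``results`` holds (strain, rate, n_max) triples; duplicate conditions
    are averaged. Normalisation is by the global maximum, so the map's
    peak entry is 1 whenever any cell emitted.
    """
    if len(results) == 0:
        raise ValueError("activation_map requires at least one result")
    arr = np.asarray(results, dtype=float)
    strains = np.unique(arr[:, 0])
    rates = np.unique(arr[:, 1])
    grid = np.full((len(strains), len(rates)), np.nan)
    for s_idx, s in enumerate(strains):
        for r_idx, r in enumerate(rates):
            sel = (arr[:, 0] == s) & (arr[:, 1] == r)
            if sel.any():
                grid[s_idx, r_idx] = arr[sel, 2].mean()
    grid = np.nan_to_num(grid)
    peak = grid.max()
    if peak > 0:
        grid = grid / peak
    return ActivationMap(strain_levels=strains, rate_levels=rates,
                         normalized_counts=grid)
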