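"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: explicit loops, no morphology or
labeling library calls, so the oracles share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected labeling by explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            stack = [(r0, c0)]
            labels[r0, c0] = current
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels, current


def exhaustive_otsu(gray: np.ndarray) -> tuple[int, float]:
    """Scan all 256 cut points, computing class statistics from scratch.

    Returns (best bin k, between-class variance) where class C0 holds bins
    <= k; the lowest maximising k wins ties.  Bin units throughout.
    """
    bins = np.clip(np.round(np.asarray(gray, float).ravel() * 255.0), 0, 255).astype(int)
    n = len(bins)
    best_k, best_var = -1, -1.0
    for k in range(255):  # cutting after bin 255 leaves a single class
        c0 = bins[bins <= k]
        c1 = bins[bins > k]
        if len(c0) == 0 or len(c1) == 0:
            var = 0.0
        else:
            w0, w1 = len(c0) / n, len(c1) / n
            var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_k = var, k
    return best_k, best_var


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def brute_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion: keep a pixel iff the whole disk fits in foreground
    (out-of-bounds neighbours count as background)."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation: a pixel fires iff any disk neighbour is foreground."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    offs = disk_offsets(radius)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def gray_erode(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale erosion: per-pixel minimum over the disk neighbourhood."""
    img = np.asarray(img, float)
    h, w = img.shape
    offs = disk_offsets(radius)
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = [
                img[r + dr, c + dc]
                for dr, dc in offs
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            out[r, c] = min(vals)
    return out


def gray_dilate(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale dilation: per-pixel maximum over the disk neighbourhood."""
    img = np.asarray(img, float)
    h, w = img.shape
    offs = disk_offsets(radius)
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = [
                img[r + dr, c + dc]
                for dr, dc in offs
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            out[r, c] = max(vals)
    return out


def equalize_cdf(gray: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Plain global histogram equalization via the empirical CDF,
    rescaled so the output spans [0, 1]."""
    gray = np.asarray(gray, float)
    bins = np.clip((gray * (nbins - 1)).round().astype(int), 0, nbins - 1)
    hist = np.bincount(bins.ravel(), minlength=nbins) / bins.size
    cdf = np.cumsum(hist)
    lo = cdf[bins].min()
    return (cdf[bins] - lo) / max(1e-12, cdf.max() - lo)
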