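"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths (scipy.ndimage
labeling, vectorised CLAHE, the packaged ICC formulas) so that agreement is
an actual cross-check.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connectivity connected components by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps: list[set[tuple[int, int]]] = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(comp)
    return comps


def dilate_set(mask: np.ndarray, kernel: int, iters: int) -> np.ndarray:
    """Set-definition dilation: union of kernel-offset translates."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    half = kernel // 2
    out = mask.copy()
    for _ in range(iters):
        nxt = np.zeros_like(out)
        for r, c in zip(*np.nonzero(out)):
            r0, r1 = max(r - half, 0), min(r + half + 1, h)
            c0, c1 = max(c - half, 0), min(c + half + 1, w)
            nxt[r0:r1, c0:c1] = True
        out = nxt
    return out


def global_hist_eq(img: np.ndarray) -> np.ndarray:
    """Textbook global histogram equalization: out = round(255 * cdf(v))."""
    img = np.asarray(img)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    lut = np.rint(255.0 * cdf).astype(np.uint8)
    return lut[img]


def icc_anova_oracle(values: np.ndarray) -> tuple[float, float]:
    """Two-way ANOVA mean squares by explicit summation; returns the
    absolute-agreement (single, average) ICC estimates."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = v.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (v[i].sum() / k - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (v[:, j].sum() / n - grand) ** 2
    ss_tot = float(((v - grand) ** 2).sum())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return single, average
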