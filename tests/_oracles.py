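"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written as plain loops over pixels or
histogram splits, sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


def otsu_bruteforce(values: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance sweep over all split points."""
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_k, best_var = None, -1.0
    total = counts.sum()
    for k in range(n_bins - 1):          # class 0 = bins [0..k]
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
            mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / n1
            var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-12 * max(best_var, 1.0):
            best_var, best_k = var, k
    return float(edges[best_k + 1])


def frst_bruteforce(
    img: np.ndarray,
    radii_um: tuple[float, ...],
    alpha: float,
    gradient_threshold_frac: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Per-pixel vote-accumulation radial symmetry transform (bright)."""
    img = np.asarray(img, dtype=float)
    H, W = img.shape
    gy = np.zeros_like(img)
    gx = np.zeros_like(img)
    gy[1:-1, :] = (img[2:, :] - img[:-2, :]) / 2
    gy[0, :] = img[1, :] - img[0, :]
    gy[-1, :] = img[-1, :] - img[-2, :]
    gx[:, 1:-1] = (img[:, 2:] - img[:, :-2]) / 2
    gx[:, 0] = img[:, 1] - img[:, 0]
    gx[:, -1] = img[:, -1] - img[:, -2]
    mag = np.sqrt(gy**2 + gx**2)
    gmax = mag.max()
    if gmax == 0:
        return np.zeros_like(img)
    thr = gradient_threshold_frac * gmax
    sel = [(r, c) for r in range(H) for c in range(W) if mag[r, c] > thr]
    mean_mag = float(np.mean([mag[r, c] for r, c in sel]))
    out = np.zeros_like(img)
    for r_um in radii_um:
        n = max(1, round(r_um / pixel_size_um))
        o_proj = np.zeros_like(img)
        m_proj = np.zeros_like(img)
        for r, c in sel:
            uy = gy[r, c] / mag[r, c]
            ux = gx[r, c] / mag[r, c]
            pr = r + int(round(n * uy))
            pc = c + int(round(n * ux))
            if 0 <= pr < H and 0 <= pc < W:
                o_proj[pr, pc] += 1
                m_proj[pr, pc] += mag[r, c]
        kappa = 8.0 if n == 1 else 9.9
        f = (np.minimum(np.abs(o_proj), kappa) / kappa) ** alpha * (
            np.abs(m_proj) / (kappa * mean_mag)
        )
        out += gaussian_filter(f, 0.25 * n, mode="constant")
    return out / len(radii_um)


def match_detections(truth_cells, detections, tol_px=None):
    """Greedy one-to-one matching of detections to ground-truth cells.

    A detection matches a cell when their centers are within one nucleus
    radius (or ``tol_px``).  Returns (pairs, precision, recall, f1) with
    ``pairs`` mapping truth index -> detection index.
    """
    if not truth_cells or not detections:
        return {}, 0.0, 0.0, 0.0
    T = np.array([[t.center_row_px, t.center_col_px] for t in truth_cells])
    D = np.array([[d.center_row_px, d.center_col_px] for d in detections])
    dist = np.sqrt(((T[:, None, :] - D[None, :, :]) ** 2).sum(-1))
    used: set[int] = set()
    pairs: dict[int, int] = {}
    for i in np.argsort(dist.min(axis=1)):
        limit = tol_px if tol_px is not None else truth_cells[i].nucleus_radius_px
        for j in np.argsort(dist[i]):
            if dist[i, j] > limit:
                break
            if j not in used:
                used.add(j)
                pairs[i] = j
                break
    tp = len(pairs)
    precision = tp / len(detections)
    recall = tp / len(truth_cells)
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return pairs, precision, recall, f1
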