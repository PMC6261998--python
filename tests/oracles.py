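"""Independent brute-force reference implementations used only by tests.

Every function here is deliberately written as plain loops / exhaustive
scans, independent of the package's own code paths.
"""

import math

import numpy as np


def loop_max_projection(voxels):
    nz, ny, nx = voxels.shape
    out = np.full((ny, nx), -np.inf)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if voxels[z, y, x] > out[y, x]:
                    out[y, x] = voxels[z, y, x]
    return out


def loop_mask(plane, threshold):
    h, w = plane.shape
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            out[y, x] = plane[y, x] > threshold
    return out


def loop_masked_mean(emap, mask):
    total, count = 0.0, 0
    h, w = emap.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                total += emap[y, x]
                count += 1
    return float("nan") if count == 0 else total / count


def loop_local_entropy(quantized, radius):
    """Shannon entropy (bits) of the value histogram over a cropped digital disk."""
    h, w = quantized.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy * dy + dx * dx <= radius * radius:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            vals.append(int(quantized[yy, xx]))
            counts = {}
            for v in vals:
                counts[v] = counts.get(v, 0) + 1
            n = len(vals)
            ent = 0.0
            for c in counts.values():
                p = c / n
                ent -= p * math.log2(p)
            out[y, x] = ent
    return out


def exhaustive_otsu(values, nbins=256):
    """Between-class-variance scan over bin-centre candidate thresholds.

    Mirrors the classic histogram formulation: for each split point the
    threshold candidate is the bin centre, and the best split maximises
    w0 * w1 * (mu0 - mu1)^2; ties break toward the lower threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, None
    for k in range(nbins - 1):
        n0 = hist[: k + 1].sum()
        n1 = hist[k + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        var = n0 * n1 * (mu0 - mu1) ** 2
        # ties (e.g. plateaus across empty bins) break toward the lower threshold
        if var > best_var * (1 + 1e-12):
            best_var, best_thr = var, centers[k]
    return best_thr


def numeric_chord_length(point, direction, center, radius, step=1e-3, max_len=None):
    """Chord length by stepping along the ray and counting in-sphere samples."""
    p = np.asarray(point, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    c = np.asarray(center, float)
    if max_len is None:
        max_len = 4 * radius
    n = int(max_len / step)
    t = (np.arange(n) + 0.5) * step
    pts = p[None, :] + t[:, None] * d[None, :]
    inside = np.linalg.norm(pts - c, axis=1) < radius
    return float(inside.sum() * step)


def pairwise_distances(points):
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(3):
                s += (points[i][k] - points[j][k]) ** 2
            out[i, j] = math.sqrt(s)
    return out


def grid_search_inverse_k(currents, times, lo, hi, n=200001):
    """1D grid search of sum (t - k/I)^2 over k in [lo, hi]."""
    ks = np.linspace(lo, hi, n)
    inv = 1.0 / np.asarray(currents, float)
    t = np.asarray(times, float)
    obj = ((t[None, :] - ks[:, None] * inv[None, :]) ** 2).sum(axis=1)
    return float(ks[np.argmin(obj)])


def fit_gaussian_sigma(profile, spacing):
    """Least-squares sigma of a 1D Gaussian profile (amplitude and sigma free)."""
    from scipy.optimize import curve_fit

    x = (np.arange(len(profile)) - np.argmax(profile)) * spacing
    amp = profile.max()

    def g(x, a, s):
        return a * np.exp(-(x**2) / (2 * s**2))

    popt, _ = curve_fit(g, x, profile, p0=(amp, spacing * 2))
    return abs(popt[1])
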