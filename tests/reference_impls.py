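"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops and its own boundary
handling, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Half-sample symmetric reflection of index i into [0, n)."""
    j = i % (2 * n)
    if j < 0:
        j += 2 * n
    return j if j < n else 2 * n - 1 - j


def conv2_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct correlation with reflect borders.

    Accumulates one shifted copy of the image per kernel element, using its
    own reflected index maps (kernel element (a, b) applies at offset
    (a - kh//2, b - kw//2) from the output pixel).
    """
    h, w = img.shape
    kh, kw = kernel.shape
    out = np.zeros_like(img, dtype=float)
    rows = np.arange(h)
    cols = np.arange(w)
    for a in range(kh):
        ridx = np.array([reflect_index(r + a - kh // 2, h) for r in rows])
        for b in range(kw):
            if kernel[a, b] == 0.0:
                continue
            cidx = np.array([reflect_index(c + b - kw // 2, w) for c in cols])
            out += kernel[a, b] * img[np.ix_(ridx, cidx)]
    return out


SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


def finite_difference_orientation(img: np.ndarray):
    """Central-difference gradient magnitude and edge orientation.

    Not a Sobel: used only to check the orientation *convention* on smooth
    ramps where both estimators agree.
    """
    h, w = img.shape
    mag = np.zeros((h, w))
    orient = np.full((h, w), np.nan)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            gx = (img[r, c + 1] - img[r, c - 1]) / 2.0
            gy = (img[r + 1, c] - img[r - 1, c]) / 2.0
            m = math.hypot(gx, gy)
            mag[r, c] = m
            if m > 0:
                orient[r, c] = (math.degrees(math.atan2(gy, gx)) + 90.0) % 180.0
    return mag, orient


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def brute_force_insertion(
    driver_mag: np.ndarray,
    driver_orient: np.ndarray,
    modulator_mag: np.ndarray,
    blur_sd: float = 5.0,
    corner_block: int = 10,
    corner_k: float = 0.04,
    corner_top_fraction: float = 0.10,
):
    """Noise-free insertion-point selection, recomputed from first principles.

    Returns ((col, row), local_orientation, M).
    """
    h, w = driver_mag.shape

    def norm01(m):
        lo = min(m.flatten())
        hi = max(m.flatten())
        if hi - lo <= 0:
            return np.zeros_like(m)
        return (m - lo) / (hi - lo)

    m_up = norm01(driver_mag)
    m_down = norm01(modulator_mag)
    g1 = gaussian_kernel_1d(blur_sd)
    g2 = np.outer(g1, g1)
    m_down = 1.0 - conv2_reflect(m_down, g2)

    gx = conv2_reflect(m_up, SOBEL_X)
    gy = conv2_reflect(m_up, SOBEL_Y)
    box = np.ones((corner_block, corner_block)) / corner_block**2
    # even-size box window spans offsets [-size//2, size//2 - 1]
    sxx = conv2_reflect(gx * gx, box)
    syy = conv2_reflect(gy * gy, box)
    sxy = conv2_reflect(gx * gy, box)
    harris = (sxx * syy - sxy * sxy) - corner_k * (sxx + syy) ** 2

    # percentile by sorting with linear interpolation (matches np.percentile)
    vals = sorted(harris.flatten())
    q = (1.0 - corner_top_fraction) * (len(vals) - 1)
    lo_i = int(math.floor(q))
    frac = q - lo_i
    thresh = vals[lo_i] * (1 - frac) + vals[min(lo_i + 1, len(vals) - 1)] * frac
    mask = np.where(harris > thresh, 0.0, 1.0)

    m = m_up * mask * m_down

    r0 = 0.4 * w
    sd = 0.1 * w
    for r in range(h):
        for c in range(w):
            d = math.hypot(c - (w - 1) / 2.0, r - (h - 1) / 2.0)
            win = 1.0 if d <= r0 else math.exp(-0.5 * ((d - r0) / sd) ** 2)
            m[r, c] *= win

    best = (0, 0)
    best_v = -np.inf
    for r in range(h):
        for c in range(w):
            if m[r, c] > best_v:
                best_v = m[r, c]
                best = (r, c)
    row, col = best
    return (col, row), driver_orient[row, col], m


def fft_dominant_orientation(patch: np.ndarray, pad: int = 256) -> float:
    """Dominant spectral orientation (edge convention, degrees in [0,180)).

    Zero-pads the mean-subtracted patch, finds the strongest non-DC
    frequency, and returns the orientation of the corresponding grating.
    """
    p = patch - patch.mean()
    f = np.fft.fftshift(np.abs(np.fft.fft2(p, s=(pad, pad))))
    f[pad // 2, pad // 2] = 0.0
    idx = np.unravel_index(np.argmax(f), f.shape)
    fy = idx[0] - pad // 2  # row frequency (y down)
    fx = idx[1] - pad // 2
    # modulation direction (fx, fy); edge orientation is perpendicular
    return (math.degrees(math.atan2(fy, fx)) + 90.0) % 180.0


def normal_quantile_high_precision(p: float) -> float:
    """Inverse normal CDF via mpmath's error function (30 digits)."""
    from mpmath import mp, erfinv, mpf, sqrt

    mp.dps = 30
    return float(sqrt(mpf(2)) * erfinv(2 * mpf(repr(p)) - 1))
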