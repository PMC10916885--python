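"""Probe texture synthesis and the driver/modulator insertion algorithm.

The probe is a small disc (~3 deg diameter, Gaussian-tapered edge of SD
~15 arcmin) carrying the sum of 16 superimposed gratings whose orientations
tile [0, 180) in 11.25-degree steps.  The amplitude vector ``a = n + s`` is
the sum of a Gaussian noise vector ``n`` (typically mean 3% contrast, SD 1%)
and a signal vector ``s`` that is zero except at the component aligned with
(congruent) or orthogonal to (incongruent) the locally defined scene
orientation, where it takes 40% contrast.  Carrier frequency is ~1.2
cycles/degree.

Insertion points are chosen on 90 x 100 image/depth snapshot pairs: both
Sobel edge maps are min-max normalized, the modulator map is blurred
(Gaussian SD 5 px) and inverted, the driver map receives U(0, 0.2) pixel
noise and has its Harris corners (block 10, aperture 3, k = 0.04; top 10%)
zeroed, the product of the two maps is windowed by a central soft disc
(diameter 80% of image width, Gaussian edge SD 10% of width), and the probe
lands on the argmax.

Orientation convention used throughout the package: degrees in [0, 180),
0 = horizontal edge, measured in array coordinates (x = column rightward,
y = row downward); pixel coordinates are 0-based (col, row), origin top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

N_COMPONENTS = 16
COMPONENT_STEP_DEG = 180.0 / N_COMPONENTS  # 11.25
SIGNAL_INDEX_CONGRUENT = 0  # component at +0 deg relative to reference
SIGNAL_INDEX_INCONGRUENT = 8  # component at +90 deg

DEFAULT_FREQUENCY_CPD = 1.2
DEFAULT_WINDOW_SD_ARCMIN = 15.0
DEFAULT_DIAMETER_DEG = 3.0

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


class DegenerateMapError(RuntimeError):
    """Raised when a driver map is constant or locally uninformative."""


class ProbeBoundsError(ValueError):
    """Raised when a probe patch would exceed the snapshot bounds."""


@dataclass
class ProbeSpec:
    """Amplitude/phase specification of one 16-component probe."""

    amplitudes: np.ndarray  # a = n + s, 16 contrast fractions
    phases: np.ndarray  # 16 degrees in [0, 360)
    noise: np.ndarray  # n
    signal: np.ndarray  # s, single nonzero element
    congruent: bool
    reference_orientation: float  # degrees in [0, 180)
    frequency: float = DEFAULT_FREQUENCY_CPD  # cycles/degree
    window_sd: float = DEFAULT_WINDOW_SD_ARCMIN  # arcmin
    diameter: float = DEFAULT_DIAMETER_DEG  # degrees

    def component_orientations(self) -> np.ndarray:
        """Absolute orientations (deg, [0,180)) of the 16 components."""
        base = np.arange(N_COMPONENTS) * COMPONENT_STEP_DEG
        return (base + self.reference_orientation) % 180.0


@dataclass
class EdgeMap:
    """Sobel gradient magnitude and edge orientation of one map."""

    magnitude: np.ndarray  # nonnegative
    orientation: np.ndarray  # degrees in [0, 180); NaN where magnitude == 0


@dataclass
class InsertionResult:
    point: tuple[int, int]  # (col, row), 0-based
    local_orientation: float  # degrees in [0, 180)
    insertion_type: str  # image_driven | object_driven
    insertion_map: np.ndarray  # final map M


def make_probe_spec(
    congruent: bool,
    reference_orientation: float,
    noise_mean: float = 0.03,
    noise_sd: float = 0.01,
    signal_contrast: float = 0.40,
    seed: int | np.random.Generator = 0,
) -> ProbeSpec:
    """Draw one probe specification.

    Phases are uniform on [0, 360); noise amplitudes are i.i.d. Gaussian with
    negative draws clipped to zero (contrast cannot be negative); the signal
    element sits at the congruency-determined component (index 0 for
    congruent, index 8, i.e. +90 deg, for incongruent).
    """
    if not (0.0 <= reference_orientation < 180.0):
        raise ValueError("reference_orientation must lie in [0, 180)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phases = rng.uniform(0.0, 360.0, N_COMPONENTS)
    noise = np.clip(rng.normal(noise_mean, noise_sd, N_COMPONENTS), 0.0, None)
    signal = np.zeros(N_COMPONENTS)
    signal[SIGNAL_INDEX_CONGRUENT if congruent else SIGNAL_INDEX_INCONGRUENT] = signal_contrast
    return ProbeSpec(
        amplitudes=noise + signal,
        phases=phases,
        noise=noise,
        signal=signal,
        congruent=congruent,
        reference_orientation=float(reference_orientation),
    )


def render_probe(
    spec: ProbeSpec, px_per_degree: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Render the probe patch and its disc window.

    Returns ``(patch, window)``: luminance patch 0.5 * (1 + sum of gratings),
    clipped to [0, 1], and the soft disc window (1 inside the disc radius,
    Gaussian falloff of SD ``window_sd`` outside).  The patch is square with
    half-size radius + 3 SD of the window edge.
    """
    radius_deg = spec.diameter / 2.0
    sd_deg = spec.window_sd / 60.0
    half = int(math.ceil((radius_deg + 3.0 * sd_deg) * px_per_degree))
    coords = np.arange(-half, half + 1) / px_per_degree  # degrees
    x, y = np.meshgrid(coords, coords)  # x: col offset, y: row offset
    theta = np.radians(spec.component_orientations())
    # modulation axis perpendicular to the grating orientation
    u = -x[..., None] * np.sin(theta) + y[..., None] * np.cos(theta)
    carrier = np.cos(2 * np.pi * spec.frequency * u + np.radians(spec.phases))
    patch = 0.5 * (1.0 + carrier @ spec.amplitudes)
    patch = np.clip(patch, 0.0, 1.0)
    r = np.hypot(x, y)
    window = np.where(
        r <= radius_deg, 1.0, np.exp(-0.5 * ((r - radius_deg) / sd_deg) ** 2)
    )
    return patch, window


def sobel_edge_map(map2d: np.ndarray) -> EdgeMap:
    """3x3 Sobel gradient magnitude and edge orientation.

    Edge orientation = gradient direction + 90 deg, folded into [0, 180);
    NaN where the gradient magnitude is exactly zero.
    """
    m = np.asarray(map2d, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("map contains non-finite values")
    gx = ndimage.correlate(m, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(m, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    # snap numerical residue (e.g. on constant inputs) to an exact zero
    tol = 64 * np.finfo(float).eps * max(float(np.abs(m).max()), 1.0)
    mag = np.where(mag <= tol, 0.0, mag)
    with np.errstate(invalid="ignore"):
        orient = (np.degrees(np.arctan2(gy, gx)) + 90.0) % 180.0
    orient = np.where(mag > 0, orient, np.nan)
    return EdgeMap(magnitude=mag, orientation=orient)


def _minmax_normalize(m: np.ndarray, *, what: str, allow_constant: bool) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 0:
        if allow_constant:
            return np.zeros_like(m)
        raise DegenerateMapError(f"{what} map is constant; normalization undefined")
    return (m - lo) / (hi - lo)


def harris_response(m: np.ndarray, block_size: int = 10, k: float = 0.04) -> np.ndarray:
    """Harris corner response with 3x3 Sobel gradients and a box window."""
    gx = ndimage.correlate(m, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(m, _SOBEL_Y, mode="reflect")
    sxx = ndimage.uniform_filter(gx * gx, size=block_size, mode="reflect")
    syy = ndimage.uniform_filter(gy * gy, size=block_size, mode="reflect")
    sxy = ndimage.uniform_filter(gx * gy, size=block_size, mode="reflect")
    return (sxx * syy - sxy * sxy) - k * (sxx + syy) ** 2


def insertion_window(shape: tuple[int, int]) -> np.ndarray:
    """Central soft disc: diameter 80% of image width, edge SD 10% of width."""
    h, w = shape
    r0 = 0.4 * w
    sd = 0.1 * w
    rows, cols = np.mgrid[0:h, 0:w]
    r = np.hypot(cols - (w - 1) / 2.0, rows - (h - 1) / 2.0)
    return np.where(r <= r0, 1.0, np.exp(-0.5 * ((r - r0) / sd) ** 2))


def select_insertion_point(
    image_edges: EdgeMap,
    object_edges: EdgeMap,
    insertion_type: str,
    seed: int | np.random.Generator = 0,
    noise_amplitude: float = 0.2,
    blur_sd: float = 5.0,
    corner_block: int = 10,
    corner_k: float = 0.04,
    corner_top_fraction: float = 0.10,
    border_margin: int = 0,
) -> InsertionResult:
    """Driver/modulator insertion-point selection.

    ``insertion_type='image_driven'`` makes the image edge map the driver and
    the depth edge map the modulator; ``'object_driven'`` swaps the roles.
    Set ``noise_amplitude=0`` to disable the stochastic term.  Ties at the
    argmax break toward the lowest (row, col) index.
    """
    if insertion_type == "image_driven":
        driver, modulator = image_edges, object_edges
    elif insertion_type == "object_driven":
        driver, modulator = object_edges, image_edges
    else:
        raise ValueError(f"unknown insertion_type {insertion_type!r}")
    if driver.magnitude.shape != modulator.magnitude.shape:
        raise ValueError("driver and modulator maps must be aligned")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m_up = _minmax_normalize(driver.magnitude, what="driver", allow_constant=False)
    m_down = _minmax_normalize(modulator.magnitude, what="modulator", allow_constant=True)
    m_down = ndimage.gaussian_filter(m_down, sigma=blur_sd, truncate=4.0, mode="reflect")
    m_down = 1.0 - m_down
    if noise_amplitude > 0:
        m_up = m_up + rng.uniform(0.0, noise_amplitude, m_up.shape)
    corner = harris_response(m_up, block_size=corner_block, k=corner_k)
    thresh = np.percentile(corner, 100.0 * (1.0 - corner_top_fraction))
    corner_mask = np.where(corner > thresh, 0.0, 1.0)
    m_up = m_up * corner_mask
    m = m_up * m_down
    m = m * insertion_window(m.shape)
    if border_margin > 0:
        # session-layer support guarantee: the probe patch and pooling box
        # must fit inside the map, so candidates hugging the border are out
        mask = np.zeros_like(m)
        mask[border_margin:-border_margin, border_margin:-border_margin] = 1.0
        m = m * mask
    flat = int(np.argmax(m))  # first occurrence = lowest (row, col)
    row, col = divmod(flat, m.shape[1])
    orientation = float(driver.orientation[row, col])
    if not np.isfinite(orientation):
        raise DegenerateMapError("driver orientation undefined at the selected point")
    return InsertionResult(
        point=(col, row),
        local_orientation=orientation,
        insertion_type=insertion_type,
        insertion_map=m,
    )


def composite_probe(
    scene_map: np.ndarray,
    probe_patch: np.ndarray,
    window: np.ndarray,
    point: tuple[int, int],
) -> np.ndarray:
    """Window-weighted blend of the probe patch into a luminance map.

    ``point`` is the (col, row) patch center.  Raises
    :class:`ProbeBoundsError` if the patch lacks full support.
    """
    col, row = point
    half = probe_patch.shape[0] // 2
    h, w = scene_map.shape
    if row - half < 0 or row + half >= h or col - half < 0 or col + half >= w:
        raise ProbeBoundsError(f"probe at {point} exceeds map bounds {w}x{h}")
    out = np.array(scene_map, dtype=float)
    sl = (slice(row - half, row + half + 1), slice(col - half, col + half + 1))
    out[sl] = (1.0 - window) * out[sl] + window * probe_patch
    return np.clip(out, 0.0, 1.0)
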