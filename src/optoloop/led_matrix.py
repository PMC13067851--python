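"""Physical model of the mLED stimulation matrices.

Covers the four things the control loop needs from the hardware layer:
rasterizing a camera-frame pixel path onto the LED grid, packing a boolean
pattern into the driver's byte frames (eight LEDs per byte), projecting lit
LEDs onto a target plane as a superposition of Lambertian emitters, and the
illumination-uniformity figure of merit as a function of the pitch-to-distance
ratio sigma = D / H.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LEDMatrixSpec:
    """Geometry and photometry of one mLED matrix.

    The two shipped designs: 'small' 48 x 32 at 0.6 mm pitch (116 mW/cm^2
    peak) and 'large' 160 x 160 at 0.9 mm pitch (65.4 mW/cm^2 peak), both at
    450 nm, mounted ~3 mm under the tissue plane.
    """

    rows: int = 48
    cols: int = 32
    pitch_mm: float = 0.6
    emitter_um: tuple = (225.0, 125.0)
    peak_irradiance_mw_cm2: float = 116.0
    wavelength_nm: float = 450.0
    plane_distance_mm: float = 3.0

    def __post_init__(self):
        if self.pitch_mm <= 0:
            raise ConfigError("LED pitch must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ConfigError("LED matrix must have at least one row and column")

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def led_centers_mm(self):
        """(Y, X) LED-center coordinates in mm, origin at the matrix corner."""
        y = (np.arange(self.rows) + 0.5) * self.pitch_mm
        x = (np.arange(self.cols) + 0.5) * self.pitch_mm
        return np.meshgrid(y, x, indexing="ij")


SMALL_MATRIX = LEDMatrixSpec()
LARGE_MATRIX = LEDMatrixSpec(rows=160, cols=160, pitch_mm=0.9, peak_irradiance_mw_cm2=65.4)


@dataclass
class LightPattern:
    """Boolean on/off per LED plus a global intensity scale in [0, 1]."""

    on: np.ndarray
    intensity: float = 1.0
    spec: LEDMatrixSpec = field(default_factory=lambda: SMALL_MATRIX)

    def __post_init__(self):
        self.on = np.asarray(self.on, dtype=bool)
        if self.on.shape != (self.spec.rows, self.spec.cols):
            raise ConfigError(
                f"pattern shape {self.on.shape} does not match spec "
                f"({self.spec.rows}, {self.spec.cols})"
            )


@dataclass(frozen=True)
class CameraToLEDTransform:
    """Affine map from camera pixel (y, x) to fractional LED index (row, col):
    led = scale * px + offset (per-axis)."""

    scale: tuple = (1.0, 1.0)
    offset: tuple = (0.0, 0.0)

    def apply(self, py, px):
        return (
            self.scale[0] * np.asarray(py, dtype=float) + self.offset[0],
            self.scale[1] * np.asarray(px, dtype=float) + self.offset[1],
        )


def rasterize(
    pixel_path, transform: CameraToLEDTransform, spec: LEDMatrixSpec, intensity: float = 1.0
) -> LightPattern:
    """Map a camera-frame pixel path onto the LED grid.

    Every path pixel lands on the LED cell containing its transformed
    coordinate (coverage guarantee); no LEDs outside those cells are lit.
    An empty result (path fully off-matrix) is returned with a warning.
    """
    on = np.zeros((spec.rows, spec.cols), dtype=bool)
    path = np.asarray(pixel_path, dtype=float).reshape(-1, 2)
    ry, rx = transform.apply(path[:, 0], path[:, 1])
    iy = np.floor(ry).astype(int)
    ix = np.floor(rx).astype(int)
    ok = (iy >= 0) & (iy < spec.rows) & (ix >= 0) & (ix < spec.cols)
    on[iy[ok], ix[ok]] = True
    if len(path) and not on.any():
        log.warning("rasterize: path maps entirely off the LED matrix; empty pattern")
    return LightPattern(on, intensity=intensity, spec=spec)


# ---------------------------------------------------------------------------
# Driver frame encoding
# ---------------------------------------------------------------------------


def encode_frame(pattern: LightPattern) -> bytes:
    """Pack the boolean pattern row-major, MSB-first, eight LEDs per byte.

    The byte count equals the pixel count divided by eight; the pixel count
    must be divisible by eight.
    """
    bits = pattern.on.reshape(-1)
    if bits.size % 8 != 0:
        raise ConfigError(f"pixel count {bits.size} not divisible by 8")
    return np.packbits(bits, bitorder="big").tobytes()


def decode_frame(data: bytes, spec: LEDMatrixSpec) -> LightPattern:
    """Inverse of :func:`encode_frame`."""
    if len(data) * 8 != spec.n_pixels:
        raise ConfigError(
            f"byte count {len(data)} does not match {spec.n_pixels} pixels"
        )
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8), bitorder="big")
    return LightPattern(bits.reshape(spec.rows, spec.cols).astype(bool), spec=spec)


# ---------------------------------------------------------------------------
# Lambertian irradiance
# ---------------------------------------------------------------------------


def _lambertian(d2: np.ndarray, H: float) -> np.ndarray:
    """Relative irradiance of one Lambertian point emitter at lateral
    squared distance d2 on a plane at height H; 1 directly above the emitter.

    E proportional to cos(theta) * cos(theta) / r^2 = H^2 / (H^2 + d^2)^2,
    normalized by its on-axis value 1 / H^2.
    """
    return H**4 / (H**2 + d2) ** 2


def irradiance_field(
    pattern: LightPattern,
    spec: LEDMatrixSpec | None = None,
    target_y_mm: np.ndarray | None = None,
    target_x_mm: np.ndarray | None = None,
    oversample: int = 0,
) -> np.ndarray:
    """Irradiance (mW/cm^2) on the target plane from all lit LEDs.

    Additive superposition of per-emitter Lambertian profiles, scaled so a
    single lit LED delivers the spec's peak irradiance directly above itself.
    Default target grid: one sample per LED cell center.
    """
    spec = spec or pattern.spec
    H = spec.plane_distance_mm
    if H <= 0:
        raise ConfigError("plane distance must be positive")
    if target_y_mm is None or target_x_mm is None:
        target_y_mm, target_x_mm = spec.led_centers_mm()
    ly, lx = spec.led_centers_mm()
    ons = pattern.on
    E = np.zeros(np.broadcast(target_y_mm, target_x_mm).shape, dtype=np.float64)
    ys = ly[ons]
    xs = lx[ons]
    ty = np.asarray(target_y_mm, dtype=float)[..., None]
    tx = np.asarray(target_x_mm, dtype=float)[..., None]
    d2 = (ty - ys) ** 2 + (tx - xs) ** 2
    E = _lambertian(d2, H).sum(axis=-1)
    return spec.peak_irradiance_mw_cm2 * pattern.intensity * E


def uniformity(
    sigma: float,
    n_leds: int = 32,
    geometry: str = "line",
    samples_per_pitch: int = 9,
) -> float:
    """Illumination uniformity min/max over the central half of the array
    footprint, for pitch-to-distance ratio sigma = D / H (H fixed at 1).

    The pitch D is the hardware constant; sigma is swept by varying the
    working distance H = D / sigma (moving the plane closer raises sigma and
    deepens the inter-LED ripple).

    geometry 'line': a 1D row of n_leds emitters, sampled along the line.
    geometry 'square': an n x n array sampled over the central patch.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    if n_leds < 2:
        raise ConfigError("need at least two emitters")
    D = 1.0
    H = D / sigma
    # sample the central pitch cell: far from the array ends the pattern is
    # pitch-periodic, so this isolates the inter-LED ripple from the finite
    # array's edge falloff
    if geometry == "line":
        centers = (np.arange(n_leds) - (n_leds - 1) / 2.0) * D
        xs = np.linspace(-D / 2.0, D / 2.0, max(3, samples_per_pitch))
        d2 = (xs[:, None] - centers[None, :]) ** 2
        E = _lambertian(d2, H).sum(axis=1)
    elif geometry == "square":
        c1 = (np.arange(n_leds) - (n_leds - 1) / 2.0) * D
        cy, cx = np.meshgrid(c1, c1, indexing="ij")
        s = np.linspace(-D / 2.0, D / 2.0, max(3, samples_per_pitch))
        sy, sx = np.meshgrid(s, s, indexing="ij")
        d2 = (sy[..., None] - cy.ravel()) ** 2 + (sx[..., None] - cx.ravel()) ** 2
        E = _lambertian(d2, H).sum(axis=-1)
    else:
        raise ConfigError(f"unknown geometry '{geometry}'")
    return float(E.min() / E.max())


__all__ = [
    "LEDMatrixSpec", "LightPattern", "CameraToLEDTransform",
    "SMALL_MATRIX", "LARGE_MATRIX",
    "rasterize", "encode_frame", "decode_frame",
    "irradiance_field", "uniformity",
]
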