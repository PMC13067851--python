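"""Virtual acquisition/stimulation rig: couples the tissue simulator, a
virtual optical-mapping camera and the mLED matrix into a closed loop.

The camera renders simulator voltage to a 100 x 100 raster by area-weighted
block averaging (the simulation grid does not divide the camera raster in
general), applies gain/polarity, and adds seeded Gaussian noise.  LED patterns
are projected back onto the simulation grid as a normalized irradiance field
driving the photocurrent.  All stochastic elements draw from named child
streams of one master seed so a full closed-loop run is replayable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

from .errors import ConfigError, MetadataError
from .led_matrix import LEDMatrixSpec, LightPattern, SMALL_MATRIX, CameraToLEDTransform, irradiance_field
from .movie import VoltageMovie
from .tissue_sim import (
    CellModel,
    HeterogeneityFields,
    S1S2Config,
    Simulation,
    SimulationConfig,
    TissueDomain,
    s1s2_events,
    _events_to_arrays,
)

# ---------------------------------------------------------------------------
# Camera
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraSpec:
    """Virtual optical-mapping camera.

    The raster covers the full tissue field of view; fluorescence is linear
    in membrane potential with selectable polarity, plus additive Gaussian
    noise per pixel per frame (sd in normalized fluorescence units).
    """

    n_px: int = 100
    frame_interval_ms: float = 8.0
    gain: float = 1.0
    noise_sd: float = 0.02
    polarity: int = 1

    def __post_init__(self):
        if self.frame_interval_ms <= 0:
            raise ConfigError("frame interval must be positive")
        if self.polarity not in (-1, 1):
            raise ConfigError("polarity must be +1 or -1")


def resample_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """(n_dst, n_src) area-weighted averaging matrix: destination cell i
    covers source interval [i*n_src/n_dst, (i+1)*n_src/n_dst) with exact
    fractional overlap weights; rows sum to 1."""
    R = np.zeros((n_dst, n_src))
    ratio = n_src / n_dst
    for i in range(n_dst):
        a, b = i * ratio, (i + 1) * ratio
        k0, k1 = int(np.floor(a)), int(np.ceil(b))
        for k in range(k0, min(k1, n_src)):
            R[i, k] = min(b, k + 1) - max(a, k)
    return R / ratio


def render_frame(v_grid_mv: np.ndarray, camera: CameraSpec, R: np.ndarray) -> np.ndarray:
    """Noise-free normalized fluorescence frame from a full-grid mV field."""
    f = (np.asarray(v_grid_mv, dtype=np.float64) + 80.0) / 100.0
    f = R @ f @ R.T
    return camera.polarity * camera.gain * f


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Registration:
    """Affine registration between camera, tissue and LED frames.

    Default geometry: the camera raster spans the tissue field exactly
    (identity up to scale) and the LED matrix is centered on the field.
    ``led_offset_mm`` is an injected misalignment of the LED matrix relative
    to its nominal position (for tolerance experiments).
    """

    side_mm: float
    n_px: int = 100
    led_spec: LEDMatrixSpec = field(default_factory=lambda: SMALL_MATRIX)
    led_offset_mm: tuple = (0.0, 0.0)

    @property
    def px_mm(self) -> float:
        return self.side_mm / self.n_px

    @property
    def led_origin_mm(self) -> tuple:
        """Tissue-frame coordinate of the LED matrix corner (centered)."""
        oy = self.side_mm / 2.0 - self.led_spec.rows * self.led_spec.pitch_mm / 2.0
        ox = self.side_mm / 2.0 - self.led_spec.cols * self.led_spec.pitch_mm / 2.0
        return (oy + self.led_offset_mm[0], ox + self.led_offset_mm[1])

    def camera_to_led(self) -> CameraToLEDTransform:
        """Camera pixel (y, x) -> fractional LED index, with pixel/LED-cell
        centers mapped consistently."""
        oy, ox = self.led_origin_mm
        p = self.led_spec.pitch_mm
        return CameraToLEDTransform(
            scale=(self.px_mm / p, self.px_mm / p),
            offset=((0.5 * self.px_mm - oy) / p, (0.5 * self.px_mm - ox) / p),
        )

    def camera_px_to_mm(self, py, px):
        return ((np.asarray(py) + 0.5) * self.px_mm, (np.asarray(px) + 0.5) * self.px_mm)


def led_to_tissue(
    pattern: LightPattern,
    registration: Registration,
    domain: TissueDomain,
    mode: str = "box",
) -> np.ndarray:
    """Normalized irradiance field on the simulation grid from a pattern.

    'box': each lit LED uniformly illuminates its pitch-sized footprint.
    'lambertian': physical superposition from led_matrix.irradiance_field,
    normalized by the single-emitter peak.
    """
    yy, xx = domain.node_centers_mm()
    oy, ox = registration.led_origin_mm
    spec = pattern.spec
    if mode == "box":
        iy = np.floor((yy - oy) / spec.pitch_mm).astype(int)
        ix = np.floor((xx - ox) / spec.pitch_mm).astype(int)
        ok = (iy >= 0) & (iy < spec.rows) & (ix >= 0) & (ix < spec.cols)
        irr = np.zeros(yy.shape)
        irr[ok] = pattern.on[iy[ok], ix[ok]] * pattern.intensity
        return irr
    if mode == "lambertian":
        E = irradiance_field(pattern, spec, yy - oy, xx - ox)
        return np.clip(E / spec.peak_irradiance_mw_cm2, 0.0, 1.0)
    raise ConfigError(f"unknown projection mode '{mode}'")


# ---------------------------------------------------------------------------
# Movie I/O
# ---------------------------------------------------------------------------

_REQUIRED_ATTRS = ("frame_interval_ms", "spacing_um", "seed")


def write_movie(movie: VoltageMovie, path: str):
    """Write a movie as multi-page float32 TIFF or HDF5, by extension."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        meta = {
            "frame_interval_ms": movie.frame_interval_ms,
            "spacing_um": movie.spacing_um,
            "seed": movie.seed,
        }
        tifffile.imwrite(path, movie.frames.astype(np.float32), description=json.dumps(meta))
    elif path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as fh:
            d = fh.create_dataset("frames", data=movie.frames.astype(np.float32))
            d.attrs["frame_interval_ms"] = movie.frame_interval_ms
            d.attrs["spacing_um"] = movie.spacing_um
            d.attrs["seed"] = movie.seed
    else:
        raise ConfigError(f"unknown movie format for '{path}'")


def read_movie(path: str) -> VoltageMovie:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            try:
                meta = json.loads(desc.value) if desc is not None else {}
            except (TypeError, json.JSONDecodeError):
                meta = {}
        missing = [a for a in _REQUIRED_ATTRS if a not in meta]
        if missing:
            raise MetadataError(f"TIFF movie missing metadata attributes: {missing}")
        return VoltageMovie(frames, meta["frame_interval_ms"], meta["spacing_um"], int(meta["seed"]))
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as fh:
            d = fh["frames"]
            missing = [a for a in _REQUIRED_ATTRS if a not in d.attrs]
            if missing:
                raise MetadataError(f"HDF5 movie missing metadata attributes: {missing}")
            return VoltageMovie(
                d[...], float(d.attrs["frame_interval_ms"]), float(d.attrs["spacing_um"]),
                int(d.attrs["seed"]),
            )
    raise ConfigError(f"unknown movie format for '{path}'")


# ---------------------------------------------------------------------------
# The rig
# ---------------------------------------------------------------------------


class VirtualRig:
    """A dish on the virtual bench: simulator + camera + mLED matrix.

    The camera frame interval must be an integer number of simulator steps.
    Light patterns set via :meth:`set_pattern` stay on until replaced.
    """

    def __init__(
        self,
        domain: TissueDomain,
        het: HeterogeneityFields | None = None,
        model: CellModel | None = None,
        dt_ms: float = 0.1,
        camera: CameraSpec | None = None,
        led_spec: LEDMatrixSpec | None = None,
        registration: Registration | None = None,
        seed: int = 0,
        projection_mode: str = "box",
    ):
        self.domain = domain
        self.camera = camera or CameraSpec()
        self.led_spec = led_spec or SMALL_MATRIX
        self.registration = registration or Registration(
            side_mm=domain.side_mm, n_px=self.camera.n_px, led_spec=self.led_spec
        )
        self.projection_mode = projection_mode
        ratio = self.camera.frame_interval_ms / dt_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("camera frame interval must be an integer number of steps")
        self.seed = seed
        ss = np.random.SeedSequence(seed).spawn(3)
        self._noise_rng = np.random.default_rng(ss[0])
        self.induction_seed = int(ss[1].generate_state(1)[0] % (2**31))
        self.het_seed = int(ss[2].generate_state(1)[0] % (2**31))
        cfg = SimulationConfig(
            dt_ms=dt_ms,
            record_every=int(round(6.0 / dt_ms)) if abs(6.0 / dt_ms - round(6.0 / dt_ms)) < 1e-9 else 1,
            duration_ms=1250.0,
        )
        self._events: list = []
        self.sim = Simulation(domain, het, model, cfg, events=[])
        self._R = resample_matrix(domain.n_rows, self.camera.n_px)
        self.pattern: LightPattern | None = None
        self.pack_index = 0

    # -- stimulation ------------------------------------------------------

    def set_pattern(self, pattern: LightPattern | None):
        if pattern is None:
            self.sim.set_irradiance(None)
            self.pattern = None
            return
        irr = led_to_tissue(pattern, self.registration, self.domain, self.projection_mode)
        self.sim.set_irradiance(irr)
        self.pattern = pattern

    def induce_spiral(self, s1s2: S1S2Config | None = None) -> tuple:
        """Run an S1S2 induction from the rig's induction seed, leaving the
        state just after the stabilization delay.  Returns the S2 anchor."""
        s1s2 = s1s2 or S1S2Config()
        events, anchor = s1s2_events(self.domain, s1s2, self.induction_seed, het=self.sim.het)
        self.sim.events = events
        self.sim._ev_arrays = _events_to_arrays(events, self.domain, self.sim._idx_map)
        self.sim.run(events[-1].t_on_ms + events[-1].duration_ms + s1s2.stabilize_ms)
        return anchor

    # -- acquisition ------------------------------------------------------

    def acquire_frame(self) -> np.ndarray:
        """Advance one camera frame interval and return the noisy frame."""
        self.sim.run(self.camera.frame_interval_ms)
        f = render_frame(self.sim.grid_v_mv(), self.camera, self._R)
        if self.camera.noise_sd > 0:
            f = f + self._noise_rng.normal(0.0, self.camera.noise_sd, size=f.shape)
        return f.astype(np.float32)

    def acquire_pack(self) -> np.ndarray:
        """Five consecutive frames (100 x 100 x 5 pack)."""
        pack = np.stack([self.acquire_frame() for _ in range(5)])
        self.pack_index += 1
        return pack

    @property
    def t_ms(self) -> float:
        return self.sim.t_ms

    def rotor_active(self, excited_fraction: float = 0.005) -> bool:
        """Is a meaningful fraction of the tissue currently excited?  The
        physical survival readout used to score termination outcomes."""
        u = self.sim.grid_u()
        return bool((u > 0.5).mean() > excited_fraction)

    def camera_mask(self) -> np.ndarray:
        """Conducting mask rendered to the camera raster (>=50% coverage)."""
        cov = self._R @ self.domain.conducting_mask.astype(float) @ self._R.T
        return cov >= 0.5


__all__ = [
    "CameraSpec", "Registration", "VirtualRig",
    "resample_matrix", "render_frame", "led_to_tissue",
    "write_movie", "read_movie",
]
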