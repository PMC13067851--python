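"""Labelled training-corpus generation for the core-localization network.

Each base sample is one simulated monolayer: a heterogeneity draw, an S1S2
induction at a random disc location, and a 208-frame recording at 6 ms.
Samples that fail to sustain a spiral (or to propagate at all) are excluded
with the reason recorded.  Ground-truth core positions come from the
phase-singularity detector (topological charge), linked over time; the
longest-lived track is the labelled core.  Movies are rendered to the camera
raster (100 x 100) with seeded sensor noise, augmented by the eight dihedral
transforms (4 rotations x optional mirror, exact on the square raster), cut
into overlapping 5-frame windows preprocessed exactly like the runtime feed
(background subtraction, 3 x 3 Gaussian, center crop to 86 x 86), and paired
with a Gaussian core-probability target at the window's last frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .control_loop import CROP, crop_offset, preprocess
from .errors import ConfigError, IntegrationDivergedError, InvalidGeometryError
from .movie import VoltageMovie
from .ps_detect import CoreTrack, compute_phase, consensus_core, detect_ps_movie
from .tissue_sim import (
    S1S2Config,
    SimulationConfig,
    classify_sample,
    make_domain,
    run_protocol,
    s1s2_events,
    sample_heterogeneity,
)
from .virtual_rig import CameraSpec, resample_matrix, render_frame

log = logging.getLogger(__name__)

SIDE_MM = 15.36          # optical field of view
DISC_MM = 15.0           # conducting well diameter

# desk-scale study conditions: accepted base simulations and windows each
# contributes (x8 dihedral augmentation)
DESK_N_SAMPLES = 56
DESK_WINDOWS_PER_SAMPLE = 1


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    The recording cadence is the optical-mapping cadence (208 frames, 6 ms);
    the default grid is a desk-scale 64 x 64 rendition of the 15.36 mm field
    (paper-scale 256 x 256 is reachable by setting ``grid_points``).
    """

    grid_points: int = 64
    dt_ms: float = 0.1
    frame_interval_ms: float = 6.0
    duration_ms: float = 1250.0
    s1s2: S1S2Config = field(default_factory=S1S2Config)
    camera: CameraSpec = field(default_factory=lambda: CameraSpec(frame_interval_ms=6.0))
    label_sigma_px: float = 3.0
    windows_per_sample: int = 2
    het_ranges: dict | None = None

    @property
    def spacing_um(self) -> float:
        return SIDE_MM * 1000.0 / self.grid_points

    def sim_config(self, seed: int = 0) -> SimulationConfig:
        re = self.frame_interval_ms / self.dt_ms
        if abs(re - round(re)) > 1e-9:
            raise ConfigError("frame interval must be an integer number of time steps")
        return SimulationConfig(
            dt_ms=self.dt_ms, record_every=int(round(re)),
            duration_ms=self.duration_ms, rng_seed=seed,
        )


@dataclass
class Sample:
    """One accepted, labelled base simulation."""

    seed: int
    movie_cam: np.ndarray          # (T, 100, 100) float32 noisy camera frames
    core_cam: np.ndarray           # (T, 2) core (y, x) in camera pixels
    track: CoreTrack
    global_current_scale: float
    coupling_scale: float
    transform: int = 0             # dihedral transform tag (0 = identity)
    chirality: int = 1


@dataclass(frozen=True)
class RejectionRecord:
    seed: int
    reason: str  # 'diverged' | 'propagation_failure' | 'no_sustained_spiral' | 'core_outside_crop'


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def generate_sample(seed: int, config: GeneratorConfig | None = None):
    """Simulate one monolayer and label it; returns Sample or RejectionRecord.

    Acceptance is deterministic per seed: the heterogeneity draw, the S2
    location and the camera noise all derive from child streams of ``seed``.
    """
    config = config or GeneratorConfig()
    het_seed, s2_seed, noise_seed = _child_seeds(seed, 3)
    domain = make_domain(config.grid_points, config.spacing_um, DISC_MM)
    het = sample_heterogeneity(domain, config.het_ranges, het_seed)
    events, _anchor = s1s2_events(domain, config.s1s2, s2_seed, het=het)
    prerecord = events[-1].t_on_ms + events[-1].duration_ms + config.s1s2.stabilize_ms
    try:
        movie = run_protocol(domain, het, events, config.sim_config(seed), prerecord_ms=prerecord)
    except IntegrationDivergedError:
        return RejectionRecord(seed, "diverged")
    label = classify_sample(movie)
    if label != "sustained_spiral":
        return RejectionRecord(seed, label)
    phase = compute_phase(movie)
    track = consensus_core(detect_ps_movie(phase), shape=movie.frames.shape[1:])
    if track is None:
        return RejectionRecord(seed, "no_sustained_spiral")
    T = movie.n_frames
    n_px = config.camera.n_px
    # render to the camera raster with seeded noise
    R = resample_matrix(domain.n_rows, n_px)
    rng = np.random.default_rng(noise_seed)
    cam = np.empty((T, n_px, n_px), dtype=np.float32)
    for t in range(T):
        f = render_frame(movie.frames[t], config.camera, R)
        if config.camera.noise_sd > 0:
            f = f + rng.normal(0.0, config.camera.noise_sd, size=f.shape)
        cam[t] = f
    # core trajectory in camera pixels (grid -> physical -> camera raster)
    scale = n_px / domain.n_rows
    core = np.array(
        [track.position_at(t) for t in range(T)], dtype=np.float64
    )
    core_cam = (core + 0.5) * scale - 0.5
    # the labelled core must stay inside the detector crop
    o = crop_offset(n_px)
    margin = 1.0
    if (
        core_cam.min() < o + margin
        or core_cam.max() > o + CROP - 1 - margin
    ):
        return RejectionRecord(seed, "core_outside_crop")
    return Sample(
        seed=seed,
        movie_cam=cam,
        core_cam=core_cam,
        track=track,
        global_current_scale=het.global_current_scale,
        coupling_scale=het.coupling_scale,
    )


# ---------------------------------------------------------------------------
# Dihedral augmentation
# ---------------------------------------------------------------------------


def dihedral_frames(frames: np.ndarray, transform: int) -> np.ndarray:
    """Apply dihedral transform 0..7 to (..., H, W) square frames:
    transform = 4 * mirror + k, mirror applied first (left-right flip),
    then k counter-clockwise 90-degree rotations."""
    if frames.shape[-1] != frames.shape[-2]:
        raise InvalidGeometryError("dihedral augmentation requires square frames")
    k, mirror = transform % 4, transform // 4
    out = frames[..., :, ::-1] if mirror else frames
    return np.rot90(out, k=k, axes=(-2, -1)).copy()


def dihedral_coords(y, x, side: int, transform: int):
    """Coordinate map matching :func:`dihedral_frames` (pixel-center coords)."""
    k, mirror = transform % 4, transform // 4
    if mirror:
        x = side - 1 - x
    for _ in range(k):
        y, x = side - 1 - x, y
    return y, x


def augment(sample: Sample) -> list[Sample]:
    """All eight dihedral transforms of a sample, frames and core coordinates
    transformed consistently; chirality flips under mirroring."""
    side = sample.movie_cam.shape[-1]
    out = []
    for t in range(8):
        cy, cx = dihedral_coords(sample.core_cam[:, 0], sample.core_cam[:, 1], side, t)
        out.append(
            replace(
                sample,
                movie_cam=dihedral_frames(sample.movie_cam, t),
                core_cam=np.stack([cy, cx], axis=1),
                transform=t,
                chirality=sample.chirality * (-1 if t >= 4 else 1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Label map and windows
# ---------------------------------------------------------------------------


def render_label(core, shape=(CROP, CROP), sigma: float = 3.0) -> np.ndarray:
    """Isotropic Gaussian core-probability target: peak exactly 1 at the pixel
    containing the core, decaying with distance at width ``sigma``."""
    cy, cx = int(round(core[0])), int(round(core[1]))
    if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
        raise InvalidGeometryError(f"core {core} outside label shape {shape}")
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    r2 = (yy - cy) ** 2.0 + (xx - cx) ** 2.0
    return np.exp(-r2 / (2.0 * sigma**2)).astype(np.float32)


def make_windows(movie, n_frames: int = 5, stride: int = 1) -> list[tuple[int, np.ndarray]]:
    """Overlapping n-frame windows (start index, frames); each window is
    paired downstream with the label of its last frame.  A 208-frame movie at
    stride 1 yields 204 windows of 5 x 6 ms = 30 ms."""
    frames = movie.frames if isinstance(movie, VoltageMovie) else np.asarray(movie)
    T = frames.shape[0]
    if T < n_frames:
        log.warning("movie of %d frames is shorter than a %d-frame window", T, n_frames)
        return []
    return [(s, frames[s : s + n_frames]) for s in range(0, T - n_frames + 1, stride)]


# ---------------------------------------------------------------------------
# Manifest and split
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    sample_ids: list          # base sample seeds, one per stored window
    transforms: list          # dihedral tag per window
    window_starts: list
    split: dict               # base seed -> 'train' | 'val'
    generator_seed: int
    format_version: int = 1


def split_bases(base_ids: list[int], fraction: float = 0.8, seed: int = 0) -> dict:
    """Assign base samples to train/val; all augmentations of a base travel
    with it (no leakage across the split)."""
    if not 0.0 < fraction < 1.0:
        raise ConfigError("split fraction must be in (0, 1)")
    if len(base_ids) < 2:
        raise ConfigError("need at least two base samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(base_ids))
    n_train = int(round(fraction * len(base_ids)))
    n_train = min(max(n_train, 1), len(base_ids) - 1)
    assign = {}
    for rank, i in enumerate(order.tolist()):
        assign[base_ids[i]] = "train" if rank < n_train else "val"
    return assign


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------


@dataclass
class Corpus:
    train_x: np.ndarray
    train_y: np.ndarray
    train_cores: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    val_cores: np.ndarray
    manifest: DatasetManifest
    rejections: list = field(default_factory=list)

    def save(self, path: str):
        with h5py.File(path, "w") as fh:
            for name in ("train_x", "train_y", "train_cores", "val_x", "val_y", "val_cores"):
                fh.create_dataset(name, data=getattr(self, name))
            m = self.manifest
            fh.attrs["generator_seed"] = m.generator_seed
            fh.attrs["format_version"] = m.format_version
            fh.attrs["sample_ids"] = np.asarray(m.sample_ids)
            fh.attrs["transforms"] = np.asarray(m.transforms)
            fh.attrs["window_starts"] = np.asarray(m.window_starts)
            fh.attrs["split_bases"] = np.asarray(sorted(m.split))
            fh.attrs["split_labels"] = np.asarray(
                [m.split[b] for b in sorted(m.split)], dtype="S5"
            )

    @classmethod
    def load(cls, path: str) -> "Corpus":
        with h5py.File(path, "r") as fh:
            data = {
                name: fh[name][...]
                for name in ("train_x", "train_y", "train_cores", "val_x", "val_y", "val_cores")
            }
            split = {
                int(b): lab.decode()
                for b, lab in zip(fh.attrs["split_bases"], fh.attrs["split_labels"])
            }
            manifest = DatasetManifest(
                sample_ids=fh.attrs["sample_ids"].tolist(),
                transforms=fh.attrs["transforms"].tolist(),
                window_starts=fh.attrs["window_starts"].tolist(),
                split=split,
                generator_seed=int(fh.attrs["generator_seed"]),
                format_version=int(fh.attrs["format_version"]),
            )
        return cls(**data, manifest=manifest)


def build_corpus(
    n_accepted: int,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    split_fraction: float = 0.8,
    max_attempts: int | None = None,
) -> Corpus:
    """Generate base samples until ``n_accepted`` are accepted, augment by the
    dihedral group, window, preprocess and split into a training corpus.

    Windows start at evenly spaced frames (>= 1, the preceding frame is the
    pack background); each base sample contributes
    ``config.windows_per_sample`` windows x 8 transforms.
    """
    config = config or GeneratorConfig()
    max_attempts = max_attempts or 4 * n_accepted
    samples: list[Sample] = []
    rejections: list[RejectionRecord] = []
    attempt = 0
    while len(samples) < n_accepted and attempt < max_attempts:
        sample_seed = int((seed * 1_000_003 + attempt) % (2**31))
        out = generate_sample(sample_seed, config)
        attempt += 1
        if isinstance(out, RejectionRecord):
            rejections.append(out)
        else:
            samples.append(out)
    if len(samples) < n_accepted:
        raise ConfigError(
            f"only {len(samples)} samples accepted in {attempt} attempts"
        )
    split = split_bases([s.seed for s in samples], split_fraction, seed)
    o = crop_offset(config.camera.n_px)
    buckets = {"train": ([], [], []), "val": ([], [], [])}
    ids, tags, starts = [], [], []
    for s in samples:
        T = s.movie_cam.shape[0]
        # seeded random window starts: spreads rotation phase across the
        # corpus (fixed starts would expose only one phase of the rotation)
        wrng = np.random.default_rng(s.seed ^ 0x5EED)
        w_starts = np.unique(
            wrng.choice(np.arange(1, T - 4), size=config.windows_per_sample, replace=False)
        )
        for aug in augment(s):
            for ws in w_starts:
                raw = aug.movie_cam[ws : ws + 5]
                bg = aug.movie_cam[ws - 1]
                window, _ = preprocess(raw, bg)
                core = aug.core_cam[ws + 4] - o
                label = render_label(core, (CROP, CROP), config.label_sigma_px)
                b = buckets[split[s.seed]]
                b[0].append(window)
                b[1].append(label)
                b[2].append(core)
                ids.append(s.seed)
                tags.append(aug.transform)
                starts.append(int(ws))
    manifest = DatasetManifest(ids, tags, starts, split, seed)
    tx, ty, tc = buckets["train"]
    vx, vy, vc = buckets["val"]
    return Corpus(
        np.asarray(tx, np.float32), np.asarray(ty, np.float32), np.asarray(tc, np.float64),
        np.asarray(vx, np.float32), np.asarray(vy, np.float32), np.asarray(vc, np.float64),
        manifest, rejections,
    )


__all__ = [
    "GeneratorConfig", "Sample", "RejectionRecord", "DatasetManifest", "Corpus",
    "generate_sample", "augment", "dihedral_frames", "dihedral_coords",
    "render_label", "make_windows", "split_bases", "build_corpus",
    "SIDE_MM", "DISC_MM",
]
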