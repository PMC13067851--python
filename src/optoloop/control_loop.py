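"""Real-time decision layer: streaming preprocessing, histogram-based core
stabilization, the 0.7/10-frame trigger, light-line generation, multi-well
partitioning, pulse timing, and the closed-loop driver.

The pipeline mirrors the acquisition software of the physical rig: packs of
five raw 100 x 100 frames arrive at 8 ms intervals; the last frame of a pack
is the background for the next pack (a high-pass in time), frames are blurred
with a 3 x 3 Gaussian kernel and center-cropped to 86 x 86 for the detector.
The detector's per-frame argmax and peak value feed a 10-deep ring buffer;
when the buffer is full and the mean of the 10 peak values exceeds 0.7, the
modal histogram coordinate is declared the core and a light line is drawn
from it to the nearest non-conducting pixel.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InvalidGeometryError
from .led_matrix import rasterize

log = logging.getLogger(__name__)

# 3x3 Gaussian (binomial) low-pass kernel
GAUSS3 = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0

CROP = 86  # detector input side
RAW = 100  # camera raster side
TRIGGER_SCORE = 0.7
TRIGGER_FRAMES = 10


def crop_offset(raw: int = RAW, crop: int = CROP) -> int:
    """Top-left offset of the centered crop (7 for 100 -> 86)."""
    return (raw - crop) // 2


def preprocess(pack: np.ndarray, background: np.ndarray | None):
    """Background-subtract, blur and crop one frame pack.

    Returns ``(window, new_background)`` where ``window`` is 5 x 86 x 86 and
    ``new_background`` is the pack's last raw frame.  For the first pack pass
    ``background=None``: zeros are used and the caller should treat the
    result as warm-up.
    """
    pack = np.asarray(pack, dtype=np.float32)
    if pack.shape != (5, RAW, RAW):
        raise ConfigError(f"expected pack of shape (5, {RAW}, {RAW}), got {pack.shape}")
    if background is None:
        background = np.zeros((RAW, RAW), dtype=np.float32)
    sub = pack - background
    blurred = np.stack([ndimage.convolve(f, GAUSS3, mode="nearest") for f in sub])
    o = crop_offset()
    window = blurred[:, o : o + CROP, o : o + CROP]
    return window.astype(np.float32), pack[-1].copy()


# ---------------------------------------------------------------------------
# Histogram-stabilized trigger
# ---------------------------------------------------------------------------


class CoreHistogram:
    """Ring buffer of the last 10 (argmax coordinate, peak value) pairs plus
    the coordinate count accumulator used for the modal-core readout."""

    def __init__(self, depth: int = TRIGGER_FRAMES):
        self.depth = depth
        self.buffer: deque = deque(maxlen=depth)

    def push(self, coord: tuple, value: float):
        self.buffer.append((coord, float(value)))

    def clear(self):
        self.buffer.clear()

    @property
    def full(self) -> bool:
        return len(self.buffer) == self.depth

    def counts(self) -> Counter:
        return Counter(c for c, _ in self.buffer)

    def mean_peak(self) -> float:
        if not self.buffer:
            return 0.0
        return float(np.mean([v for _, v in self.buffer]))

    def modal_coordinate(self) -> tuple:
        """Most frequent coordinate; ties go to the most recently pushed
        occupant among the tied coordinates (favors a drifting core's current
        position)."""
        cnt = self.counts()
        top = max(cnt.values())
        tied = {c for c, n in cnt.items() if n == top}
        for coord, _ in reversed(self.buffer):
            if coord in tied:
                return coord
        raise RuntimeError("empty histogram")  # pragma: no cover


def update_and_decide(hist: CoreHistogram, prob_map: np.ndarray, edge_margin: int = 6):
    """Push one detector output and apply the trigger rule.

    Returns the histogram's modal (y, x) coordinate when the buffer holds 10
    entries and the mean of their peak values is strictly above 0.7;
    otherwise None.  Frames containing NaN are dropped and logged.  The outer
    ``edge_margin`` pixels are excluded from the peak search: convolutional
    boundary effects concentrate spurious responses on the map frame.
    """
    prob_map = np.asarray(prob_map)
    if np.isnan(prob_map).any():
        log.warning("probability map contains NaN; frame dropped")
        return None
    interior = prob_map
    if edge_margin > 0 and min(prob_map.shape) > 2 * edge_margin:
        interior = prob_map[edge_margin:-edge_margin, edge_margin:-edge_margin]
    flat = int(np.argmax(interior))
    coord = np.unravel_index(flat, interior.shape)
    if interior is not prob_map:
        coord = (coord[0] + edge_margin, coord[1] + edge_margin)
    hist.push((int(coord[0]), int(coord[1])), float(prob_map[coord]))
    if hist.full and hist.mean_peak() > TRIGGER_SCORE:
        return hist.modal_coordinate()
    return None


# ---------------------------------------------------------------------------
# Light-line generation
# ---------------------------------------------------------------------------


def nearest_border_line(
    core: tuple,
    mask: np.ndarray,
    width: int = 1,
    dot_pitch: int | None = None,
) -> np.ndarray:
    """Pixel path of a straight line from the core to the nearest
    non-conducting pixel of ``mask``.

    The nearest border pixel is found by exhaustive Euclidean distance over
    the mask complement; distance ties are broken by the smallest angle from
    the +x axis (measured counter-clockwise in (y, x) image coordinates).
    The returned path contains only mask pixels, 8-connected in order, ending
    adjacent to the chosen border pixel.  ``width`` > 1 inflates the line;
    ``dot_pitch`` keeps every dot_pitch-th pixel (a dotted line).
    """
    from skimage.draw import line as sk_line

    mask = np.asarray(mask, dtype=bool)
    cy, cx = int(round(core[0])), int(round(core[1]))
    if not (0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1]) or not mask[cy, cx]:
        raise InvalidGeometryError(f"core {core} is outside the conducting mask")
    zy, zx = np.nonzero(~mask)
    if zy.size == 0:
        raise InvalidGeometryError("mask has no border: no non-conducting pixels")
    d2 = (zy - cy) ** 2 + (zx - cx) ** 2
    dmin = d2.min()
    tied = np.nonzero(d2 <= dmin)[0]
    if tied.size > 1:
        ang = np.mod(np.arctan2(zy[tied] - cy, zx[tied] - cx), 2 * np.pi)
        best = tied[np.argmin(ang)]
    else:
        best = tied[0]
    ty, tx = int(zy[best]), int(zx[best])
    ry, rx = sk_line(cy, cx, ty, tx)
    inside = mask[ry, rx]
    if not inside.all():
        stop = int(np.argmin(inside))  # first pixel outside the mask
        ry, rx = ry[:stop], rx[:stop]
    path = np.stack([ry, rx], axis=1)
    if dot_pitch:
        path = path[::dot_pitch]
    if width > 1:
        canvas = np.zeros(mask.shape, dtype=bool)
        canvas[path[:, 0], path[:, 1]] = True
        canvas = ndimage.binary_dilation(canvas, iterations=width // 2) & mask
        yy, xx = np.nonzero(canvas)
        path = np.stack([yy, xx], axis=1)
    return path


# ---------------------------------------------------------------------------
# Multi-well partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Well:
    """One rectangular zone of the detector output: rows [y0, y1), cols [x0, x1)."""

    well_id: int
    y0: int
    y1: int
    x0: int
    x1: int
    enabled: bool = True


def _check_layout(layout: list[Well]):
    for i, a in enumerate(layout):
        for b in layout[i + 1 :]:
            if a.y0 < b.y1 and b.y0 < a.y1 and a.x0 < b.x1 and b.x0 < a.x1:
                raise ConfigError(f"wells {a.well_id} and {b.well_id} overlap")


def quadrant_layout(side: int = CROP, disabled: tuple = ()) -> list[Well]:
    """Four quadrant wells over a square map; well ids 0..3 row-major
    (2 = bottom-left)."""
    h = side // 2
    wells = [
        Well(0, 0, h, 0, h), Well(1, 0, h, h, side),
        Well(2, h, side, 0, h), Well(3, h, side, h, side),
    ]
    return [
        Well(w.well_id, w.y0, w.y1, w.x0, w.x1, enabled=w.well_id not in disabled)
        for w in wells
    ]


class MultiWellDecider:
    """The trigger rule applied independently per well zone, each with its
    own 10-deep histogram.  Disabled wells always return None."""

    def __init__(self, layout: list[Well]):
        _check_layout(layout)
        self.layout = layout
        self.hists = {w.well_id: CoreHistogram() for w in layout}

    def update(self, prob_map: np.ndarray) -> dict:
        out = {}
        for w in self.layout:
            if not w.enabled:
                out[w.well_id] = None
                continue
            sub = prob_map[w.y0 : w.y1, w.x0 : w.x1]
            dec = update_and_decide(self.hists[w.well_id], sub)
            out[w.well_id] = None if dec is None else (dec[0] + w.y0, dec[1] + w.x0)
        return out


def partition_wells(prob_map: np.ndarray, layout: list[Well], decider: MultiWellDecider | None = None) -> dict:
    """One update of the per-well decision rule (stateful across calls when a
    decider is passed; a fresh decider needs 10 updates before any trigger)."""
    decider = decider or MultiWellDecider(layout)
    return decider.update(prob_map)


# ---------------------------------------------------------------------------
# Timing policy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingPolicy:
    """Settle 3 s, light pulse 0.5 s, post-pulse blanking 3 s (defaults)."""

    settle_ms: float = 3000.0
    pulse_ms: float = 500.0
    blanking_ms: float = 3000.0

    def __post_init__(self):
        if self.settle_ms < 0 or self.blanking_ms < 0:
            raise ConfigError("settle and blanking delays must be >= 0")
        if self.pulse_ms <= 0:
            raise ConfigError("pulse duration must be positive")


def schedule(policy: TimingPolicy, trigger_times_ms: list[float]) -> list[tuple]:
    """Deterministic pattern-event list from trigger times.

    Each accepted trigger produces settle -> pulse_on -> pulse_off -> blanking
    -> re-arm; triggers arriving before the previous cycle's re-arm time are
    ignored (logged as 'suppressed').
    """
    if any(b < a for a, b in zip(trigger_times_ms, trigger_times_ms[1:])):
        raise ConfigError("trigger times must be monotone")
    events = []
    rearm = -np.inf
    for t in trigger_times_ms:
        if t < rearm:
            events.append((t, "suppressed"))
            log.info("trigger at %.1f ms suppressed (inside blanking)", t)
            continue
        on = t + policy.settle_ms
        off = on + policy.pulse_ms
        rearm = off + policy.blanking_ms
        events.extend([(on, "pulse_on"), (off, "pulse_off"), (rearm, "re-arm")])
    return events


# ---------------------------------------------------------------------------
# Termination detection
# ---------------------------------------------------------------------------


class TerminationDetector:
    """Declares reentry terminated when, over a hold window (default 1 s),
    no core decision fires AND either (a) the high-pass amplitude stays below
    a quiescence threshold, or (b) the trigger was armed the whole time (so
    residual activity the detector never localized - e.g. paced planar
    rhythm - does not count as reentry)."""

    def __init__(self, quiescence_threshold: float = 0.15, hold_ms: float = 1000.0):
        self.threshold = quiescence_threshold
        self.hold_ms = hold_ms
        self._last_loud = -np.inf
        self._last_decision = -np.inf
        self._last_unarmed = -np.inf
        self._t = 0.0

    def update(self, t_ms: float, window: np.ndarray | None, decision, armed: bool) -> bool:
        self._t = t_ms
        if window is not None and float(np.abs(window).max()) >= self.threshold:
            self._last_loud = t_ms
        if decision is not None:
            self._last_decision = t_ms
        if not armed:
            self._last_unarmed = t_ms
        quiet = t_ms - self._last_loud >= self.hold_ms
        silent = t_ms - self._last_decision >= self.hold_ms
        armed_throughout = t_ms - self._last_unarmed >= self.hold_ms
        return silent and (quiet or armed_throughout) and t_ms >= self.hold_ms


# ---------------------------------------------------------------------------
# The closed loop
# ---------------------------------------------------------------------------


@dataclass
class LoopEvent:
    t_ms: float
    kind: str  # detection | trigger | pulse_on | pulse_off | termination | rejection
    payload: dict = field(default_factory=dict)


def run_closed_loop(
    rig,
    model,
    policy: TimingPolicy | None = None,
    horizon_ms: float = 5000.0,
    control_on: bool = True,
    line_intensity: float = 1.0,
    line_width: int = 3,
    terminator: TerminationDetector | None = None,
    max_attempts: int | None = None,
) -> list[LoopEvent]:
    """Drive the full loop against a virtual rig holding an induced spiral.

    Acquire packs -> preprocess -> predict -> decide -> pulse -> blank,
    repeating until the termination detector fires or the horizon elapses.
    With ``control_on=False`` the decision pipeline runs but no light is ever
    projected (the no-light control arm).  The event log is complete (every
    pack produces a detection, rejection, or pulse bookkeeping entry) and
    replayable given the rig's seed.
    """
    policy = policy or TimingPolicy()
    terminator = terminator or TerminationDetector()
    if model.input_side != rig.camera.n_px - 2 * crop_offset(rig.camera.n_px):
        raise ConfigError(
            f"model input side {model.input_side} does not match camera crop"
        )
    events: list[LoopEvent] = []
    hist = CoreHistogram()
    background = None
    t0 = rig.t_ms
    pulse_off_at = None
    rearm_at = policy.settle_ms  # loop-relative time
    attempts = 0
    cam_mask = rig.camera_mask()
    o = crop_offset(rig.camera.n_px)
    while rig.t_ms - t0 < horizon_ms:
        pack = rig.acquire_pack()
        warmup = background is None
        window, background = preprocess(pack, background)
        t = rig.t_ms - t0
        # pulse bookkeeping
        if pulse_off_at is not None and t >= pulse_off_at:
            rig.set_pattern(None)
            events.append(LoopEvent(t, "pulse_off", {}))
            pulse_off_at = None
        # detection runs continuously (as on the physical rig); the LED
        # output is only armed outside the settle / pulse / blanking windows
        armed = (t >= policy.settle_ms) and pulse_off_at is None and t >= rearm_at
        decision = raw_decision = None
        if warmup:
            events.append(LoopEvent(t, "rejection", {"reason": "warm-up pack"}))
        else:
            prob = model.predict(window)
            raw_decision = update_and_decide(hist, prob)
            decision = raw_decision if armed else None
            events.append(
                LoopEvent(t, "detection",
                          {"decision": None if raw_decision is None else list(raw_decision),
                           "armed": armed})
            )
            if raw_decision is not None and not armed:
                events.append(LoopEvent(t, "rejection", {"reason": "settle/pulse/blanking window"}))
        if decision is not None and (max_attempts is None or attempts < max_attempts):
            events.append(LoopEvent(t, "trigger", {"core_crop": list(decision)}))
            core_cam = (decision[0] + o, decision[1] + o)
            if not cam_mask[core_cam]:
                # detector artifact outside the well: snap to the nearest
                # conducting pixel so the line is still drawable
                ys, xs = np.nonzero(cam_mask)
                j = np.argmin((ys - core_cam[0]) ** 2 + (xs - core_cam[1]) ** 2)
                core_cam = (int(ys[j]), int(xs[j]))
            path = nearest_border_line(core_cam, cam_mask, width=line_width)
            pattern = rasterize(path, rig.registration.camera_to_led(), rig.led_spec, line_intensity)
            attempts += 1
            if control_on:
                rig.set_pattern(pattern)
            events.append(
                LoopEvent(t, "pulse_on", {"attempt": attempts, "led_enabled": control_on,
                                          "n_leds": int(pattern.on.sum())})
            )
            pulse_off_at = t + policy.pulse_ms
            rearm_at = t + policy.pulse_ms + policy.blanking_ms
            hist.clear()
        if terminator.update(t, None if warmup else window, raw_decision, armed=not warmup):
            events.append(LoopEvent(t, "termination", {"attempts": attempts}))
            break
    return events


__all__ = [
    "GAUSS3", "CROP", "RAW", "TRIGGER_SCORE", "TRIGGER_FRAMES",
    "preprocess", "crop_offset",
    "CoreHistogram", "update_and_decide",
    "nearest_border_line",
    "Well", "quadrant_layout", "MultiWellDecider", "partition_wells",
    "TimingPolicy", "schedule",
    "TerminationDetector", "LoopEvent", "run_closed_loop",
]
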