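"""Monodomain reaction-diffusion simulator of a circular cardiac monolayer.

The tissue is a square grid of excitable nodes; a centered disc is conducting
(mimicking the area of a culture well) and everything outside is inert, with
zero-flux (Neumann) boundaries implemented as zero coupling weights across the
mask edge.  Each node carries a two-variable phenomenological excitable model
(Aliev-Panfilov form) rescaled to monolayer-like action-potential duration and
conduction velocity; a slot is left open for detailed ionic models.

Sample-to-sample variability is produced by three heterogeneity fields:
a global ionic-current multiplier, an independent per-node multiplier, and a
coupling-coefficient multiplier, matching the variability ranges used to make
monolayers differ in excitability and conduction.

Spiral waves (reentry) are induced with an S1S2 cross-gradient protocol: a
planar conditioning wave (S1) followed by a premature half-plane stimulus (S2)
timed into the refractory tail near a randomly drawn point of the disc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import (
    ConfigError,
    IntegrationDivergedError,
    InvalidGeometryError,
    MeasurementUndefinedError,
)
from .movie import VoltageMovie

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Domain geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueDomain:
    """Square grid with a centered conducting disc.

    Node centers sit at ``(i + 0.5) * spacing`` (row-major, 0-based), so the
    physical side length is ``n_points * spacing``.
    """

    n_rows: int
    n_cols: int
    spacing_um: float
    conducting_mask: np.ndarray  # bool (n_rows, n_cols)

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def side_mm(self) -> float:
        return self.n_cols * self.spacing_mm

    @property
    def n_conducting(self) -> int:
        return int(self.conducting_mask.sum())

    def node_centers_mm(self):
        """(Y, X) arrays of node-center coordinates in mm."""
        y = (np.arange(self.n_rows) + 0.5) * self.spacing_mm
        x = (np.arange(self.n_cols) + 0.5) * self.spacing_mm
        return np.meshgrid(y, x, indexing="ij")


def make_domain(n_points: int, spacing_um: float, conducting_diameter_mm: float) -> TissueDomain:
    """Build a square grid with a centered conducting disc.

    Parameters mirror the optical-mapping geometry: e.g. 256 points of 60 um
    give a 15.36 mm field holding a 15 mm conducting disc.
    """
    if conducting_diameter_mm <= 0:
        raise InvalidGeometryError("conducting diameter must be positive")
    if n_points < 16:
        raise InvalidGeometryError("grid too small (n_points < 16)")
    if spacing_um <= 0:
        raise InvalidGeometryError("spacing must be positive")
    side_mm = n_points * spacing_um / 1000.0
    if conducting_diameter_mm > side_mm + 1e-12:
        raise InvalidGeometryError(
            f"conducting diameter {conducting_diameter_mm} mm exceeds field {side_mm} mm"
        )
    h = spacing_um / 1000.0
    c = side_mm / 2.0
    yy, xx = np.meshgrid(
        (np.arange(n_points) + 0.5) * h, (np.arange(n_points) + 0.5) * h, indexing="ij"
    )
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= (conducting_diameter_mm / 2.0) ** 2
    if not mask.any():
        raise InvalidGeometryError("conducting mask is empty")
    return TissueDomain(n_points, n_points, spacing_um, mask)


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

DEFAULT_RANGES = {
    "global": (0.83, 1.20),     # global ionic-current multiplier
    "cell": (0.5, 2.0),         # per-node multiplier, relative to global
    "coupling": (0.25, 4.0),    # coupling-coefficient multiplier
}


@dataclass(frozen=True)
class HeterogeneityFields:
    """Dimensionless multipliers applied to ionic currents and coupling."""

    global_current_scale: float
    cell_current_scale: np.ndarray  # per-node absolute multiplier (global x cell)
    coupling_scale: float
    rng_seed: int


def sample_heterogeneity(
    domain: TissueDomain, ranges: dict | None = None, seed: int = 0
) -> HeterogeneityFields:
    """Draw a heterogeneity sample reproducibly from ``seed``.

    The global multiplier is uniform on its range; the per-node and coupling
    multipliers are log-uniform on theirs (symmetric multiplicative factors,
    median at the global value / at 1).
    """
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for key, (lo, hi) in r.items():
        if lo > hi:
            raise ConfigError(f"inverted range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    g = rng.uniform(*r["global"])
    lo, hi = r["cell"]
    cell = np.exp(rng.uniform(np.log(lo), np.log(hi), size=domain.conducting_mask.shape))
    clo, chi = r["coupling"]
    coupling = float(np.exp(rng.uniform(np.log(clo), np.log(chi))))
    return HeterogeneityFields(
        global_current_scale=float(g),
        cell_current_scale=(g * cell),
        coupling_scale=float(coupling),
        rng_seed=seed,
    )


def homogeneous_fields(domain: TissueDomain) -> HeterogeneityFields:
    """Unit multipliers everywhere (the reference tissue)."""
    return HeterogeneityFields(1.0, np.ones(domain.conducting_mask.shape), 1.0, 0)


# ---------------------------------------------------------------------------
# Cell model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellModel:
    """Two-variable phenomenological excitable model (Aliev-Panfilov form).

    du/dt = [-k u (u - a)(u - 1) - u v] * s / tau + I_stim + I_photo
    dv/dt = [(eps0 + mu1 v / (u + mu2)) (-v - k u (u - a - 1))] / tau

    with u the normalized membrane variable (V = v_offset + v_gain * u, mV),
    ``s`` the per-node ionic-current multiplier, and ``tau`` (ms) the time
    scale that pins the action-potential duration to monolayer-like values.
    ``diffusivity`` (mm^2/ms) sets the conduction velocity.  The photocurrent
    is an instantaneous depolarizing conductance g * irr * (u_rev - u),
    linear in normalized irradiance irr in [0, 1].
    """

    kind: str = "aliev-panfilov"
    k: float = 8.0
    a: float = 0.08
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    tau_ms: float = 2.2
    diffusivity: float = 0.008       # mm^2/ms at coupling_scale = 1
    u_rest: float = 0.0
    v_rest: float = 0.0
    v_offset_mv: float = -80.0
    v_gain_mv: float = 100.0
    g_photo: float = 1.2            # 1/ms at full irradiance
    u_rev: float = 0.85             # photocurrent reversal, ~0 mV

    def to_mv(self, u: np.ndarray) -> np.ndarray:
        return self.v_offset_mv + self.v_gain_mv * u


def get_cell_model(name: str = "aliev-panfilov", **overrides) -> CellModel:
    """Pluggable cell-model factory.

    Only the phenomenological model is implemented; a detailed neonatal-rat
    ventricular myocyte model can be registered under another name later.
    """
    if name != "aliev-panfilov":
        raise ConfigError(f"unknown cell model '{name}'")
    return CellModel(**overrides)


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    """A timed stimulus over a node set.

    kind 'electrical': ``amplitude`` is added to du/dt (1/ms) while active.
    kind 'optical': depolarizing photocurrent at normalized irradiance
    ``amplitude`` in [0, 1] (values outside are clipped with a warning).
    """

    kind: str                 # 'electrical' | 'optical'
    mask: np.ndarray          # bool (n_rows, n_cols)
    t_on_ms: float
    duration_ms: float
    amplitude: float

    def __post_init__(self):
        if self.kind not in ("electrical", "optical"):
            raise ConfigError(f"unknown stimulus kind '{self.kind}'")
        if self.duration_ms <= 0:
            raise ConfigError("stimulus duration must be positive")
        if self.kind == "optical" and not (0.0 <= self.amplitude <= 1.0):
            log.warning("optical irradiance %.3f outside [0,1]; clipping", self.amplitude)
            object.__setattr__(self, "amplitude", float(np.clip(self.amplitude, 0.0, 1.0)))


def edge_strip_mask(domain: TissueDomain, side: str = "left", width_mm: float = 0.6) -> np.ndarray:
    """Strip of conducting nodes along one edge of the disc."""
    yy, xx = domain.node_centers_mm()
    m = domain.conducting_mask
    if side == "left":
        lim = xx[m].min() + width_mm
        strip = xx <= lim
    elif side == "right":
        lim = xx[m].max() - width_mm
        strip = xx >= lim
    elif side == "top":
        lim = yy[m].min() + width_mm
        strip = yy <= lim
    elif side == "bottom":
        lim = yy[m].max() - width_mm
        strip = yy >= lim
    else:
        raise ConfigError(f"unknown side '{side}'")
    return strip & m


def half_plane_mask(domain: TissueDomain, point_mm, normal) -> np.ndarray:
    """Conducting nodes on the side of the line through ``point_mm`` that the
    ``normal`` (y, x) points away from: nodes with (r - p) . n <= 0."""
    yy, xx = domain.node_centers_mm()
    ny, nx = normal
    s = (yy - point_mm[0]) * ny + (xx - point_mm[1]) * nx
    return (s <= 0) & domain.conducting_mask


def disc_mask(domain: TissueDomain, center_mm, radius_mm: float) -> np.ndarray:
    yy, xx = domain.node_centers_mm()
    m = (yy - center_mm[0]) ** 2 + (xx - center_mm[1]) ** 2 <= radius_mm**2
    return m & domain.conducting_mask


# ---------------------------------------------------------------------------
# Simulation config
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step recording arithmetic: with the defaults (1.25 s at
    dt = 0.005 ms, one frame every 1200 steps) a protocol records 208 frames
    6 ms apart."""

    dt_ms: float = 0.005
    record_every: int = 1200
    duration_ms: float = 1250.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ConfigError("dt must be positive")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        steps = self.duration_ms / self.dt_ms
        if abs(steps - round(steps)) > 1e-6:
            raise ConfigError("duration/dt must be an integer number of steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ms / self.dt_ms))

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.record_every

    @property
    def frame_interval_ms(self) -> float:
        return self.dt_ms * self.record_every


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate(
    u, v, rate, nbr, w,
    ev_kind, ev_t0, ev_t1, ev_amp, ev_ptr, ev_nodes,
    irr, use_irr,
    k, a, eps0, mu1, mu2, inv_tau, g_photo, u_rev,
    dt, n_steps, step0, record_every, frames,
):
    """Advance the monodomain state by ``n_steps`` explicit steps in place.

    ``frames`` is (n_rec, n_nodes); a frame is recorded after every
    record_every-th step of THIS call (recording phase is relative to the
    call, so a recorded window always holds n_steps // record_every frames).
    Returns the global step index of divergence, or -1.
    """
    n = u.shape[0]
    du = np.empty(n)
    dv = np.empty(n)
    n_events = ev_kind.shape[0]
    rec = 0
    for s in range(n_steps):
        t = (step0 + s) * dt
        # reaction + diffusion
        for i in range(n):
            ui = u[i]
            vi = v[i]
            fu = (-k * ui * (ui - a) * (ui - 1.0) - ui * vi) * rate[i] * inv_tau
            fv = ((eps0 + mu1 * vi / (ui + mu2)) * (-vi - k * ui * (ui - a - 1.0))) * inv_tau
            diff = (
                w[i, 0] * (u[nbr[i, 0]] - ui)
                + w[i, 1] * (u[nbr[i, 1]] - ui)
                + w[i, 2] * (u[nbr[i, 2]] - ui)
                + w[i, 3] * (u[nbr[i, 3]] - ui)
            )
            if use_irr:
                fu += g_photo * irr[i] * (u_rev - ui)
            du[i] = dt * fu + diff
            dv[i] = dt * fv
        # stimuli
        for e in range(n_events):
            if ev_t0[e] <= t < ev_t1[e]:
                if ev_kind[e] == 0:  # electrical
                    add = dt * ev_amp[e]
                    for p in range(ev_ptr[e], ev_ptr[e + 1]):
                        du[ev_nodes[p]] += add
                else:  # optical
                    gi = g_photo * ev_amp[e]
                    for p in range(ev_ptr[e], ev_ptr[e + 1]):
                        i = ev_nodes[p]
                        du[i] += dt * gi * (u_rev - u[i])
        for i in range(n):
            u[i] += du[i]
            v[i] += dv[i]
        gstep = step0 + s + 1
        if (s + 1) % record_every == 0 and rec < frames.shape[0]:
            for i in range(n):
                frames[rec, i] = u[i]
            rec += 1
        if gstep % 200 == 0 or s == n_steps - 1:
            bad = False
            for i in range(n):
                if not np.isfinite(u[i]) or abs(u[i]) > 50.0:
                    bad = True
                    break
            if bad:
                return gstep
    return -1


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


def _build_coupling(domain: TissueDomain, het: HeterogeneityFields, model: CellModel, dt: float):
    """Flatten conducting nodes; neighbor indices and coupling weights.

    Zero-flux boundaries: a missing/non-conducting neighbor is replaced by the
    node itself, so its flux term vanishes identically and total u is
    conserved when the reaction is off.
    """
    mask = domain.conducting_mask
    n_rows, n_cols = mask.shape
    idx = -np.ones((n_rows, n_cols), dtype=np.int64)
    ys, xs = np.nonzero(mask)
    n = ys.size
    idx[ys, xs] = np.arange(n)
    nbr = np.empty((n, 4), dtype=np.int64)
    h = domain.spacing_mm
    alpha = model.diffusivity * het.coupling_scale * dt / (h * h)
    w = np.full((n, 4), alpha)
    offs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    for d, (dy, dx) in enumerate(offs):
        yn = ys + dy
        xn = xs + dx
        ok = (yn >= 0) & (yn < n_rows) & (xn >= 0) & (xn < n_cols)
        j = np.full(n, -1, dtype=np.int64)
        j[ok] = idx[yn[ok], xn[ok]]
        inside = j >= 0
        nbr[:, d] = np.where(inside, j, np.arange(n))
        w[~inside, d] = 0.0
    if 4 * alpha >= 1.0:
        raise ConfigError(
            f"diffusion stability violated: 4*D*s*dt/h^2 = {4 * alpha:.3f} >= 1; reduce dt"
        )
    return ys, xs, nbr, w


def _events_to_arrays(events, domain, idx_map):
    n_events = len(events)
    ev_kind = np.zeros(n_events, dtype=np.int8)
    ev_t0 = np.zeros(n_events)
    ev_t1 = np.zeros(n_events)
    ev_amp = np.zeros(n_events)
    ptr = [0]
    nodes = []
    for e, ev in enumerate(events):
        if ev.mask.shape != domain.conducting_mask.shape:
            raise ConfigError("stimulus mask shape does not match domain")
        m = ev.mask & domain.conducting_mask
        ev_kind[e] = 0 if ev.kind == "electrical" else 1
        ev_t0[e] = ev.t_on_ms
        ev_t1[e] = ev.t_on_ms + ev.duration_ms
        ev_amp[e] = ev.amplitude
        ids = idx_map[m]
        nodes.append(ids)
        ptr.append(ptr[-1] + ids.size)
    ev_ptr = np.asarray(ptr, dtype=np.int64)
    ev_nodes = (
        np.concatenate(nodes).astype(np.int64) if nodes else np.zeros(0, dtype=np.int64)
    )
    return ev_kind, ev_t0, ev_t1, ev_amp, ev_ptr, ev_nodes


class Simulation:
    """Stateful monodomain simulation, steppable in chunks.

    Used directly by the virtual rig (which interleaves camera sampling and
    light projection) and by :func:`run_protocol` for one-shot recordings.
    """

    def __init__(
        self,
        domain: TissueDomain,
        het: HeterogeneityFields | None = None,
        model: CellModel | None = None,
        config: SimulationConfig | None = None,
        events: list[StimulusEvent] | None = None,
    ):
        self.domain = domain
        self.het = het if het is not None else homogeneous_fields(domain)
        self.model = model if model is not None else CellModel()
        self.config = config if config is not None else SimulationConfig()
        self.events = list(events or [])
        mask = domain.conducting_mask
        self._idx_map = -np.ones(mask.shape, dtype=np.int64)
        self._idx_map[mask] = np.arange(mask.sum())
        self._ys, self._xs, self._nbr, self._w = _build_coupling(
            domain, self.het, self.model, self.config.dt_ms
        )
        n = self._ys.size
        self.u = np.full(n, self.model.u_rest, dtype=np.float64)
        self.v = np.full(n, self.model.v_rest, dtype=np.float64)
        self._rate = np.ascontiguousarray(self.het.cell_current_scale[mask], dtype=np.float64)
        self.irr = np.zeros(n)
        self.step = 0
        self._ev_arrays = _events_to_arrays(self.events, domain, self._idx_map)

    @property
    def t_ms(self) -> float:
        return self.step * self.config.dt_ms

    def set_irradiance(self, field_2d: np.ndarray | None):
        """Set the ambient normalized irradiance (e.g. a projected LED line)."""
        if field_2d is None:
            self.irr[:] = 0.0
        else:
            self.irr[:] = np.clip(field_2d[self.domain.conducting_mask], 0.0, 1.0)

    def run(self, duration_ms: float, record: bool = False) -> np.ndarray | None:
        """Advance by ``duration_ms``; optionally record frames at the config
        cadence.  Returns recorded conducting-node frames or None."""
        cfg = self.config
        n_steps = int(round(duration_ms / cfg.dt_ms))
        if record:
            frames = np.empty((n_steps // cfg.record_every, self.u.size))
        else:
            frames = np.empty((0, self.u.size))
        m = self.model
        ev = self._ev_arrays
        bad = _integrate(
            self.u, self.v, self._rate, self._nbr, self._w,
            *ev,
            self.irr, bool(self.irr.any()),
            m.k, m.a, m.eps0, m.mu1, m.mu2, 1.0 / m.tau_ms, m.g_photo, m.u_rev,
            cfg.dt_ms, n_steps, self.step, cfg.record_every if record else 2**62, frames,
        )
        self.step += n_steps
        if bad >= 0:
            raise IntegrationDivergedError(bad)
        return frames if record else None

    def grid_u(self) -> np.ndarray:
        """Current state embedded into the full grid (resting outside)."""
        g = np.full(self.domain.conducting_mask.shape, self.model.u_rest)
        g[self.domain.conducting_mask] = self.u
        return g

    def grid_v_mv(self) -> np.ndarray:
        return self.model.to_mv(self.grid_u())

    def frames_to_movie(self, frames: np.ndarray, seed: int = 0) -> VoltageMovie:
        """Embed recorded conducting-node frames into full-grid mV frames."""
        mask = self.domain.conducting_mask
        out = np.full((frames.shape[0],) + mask.shape, self.model.u_rest, dtype=np.float64)
        out[:, mask] = frames
        return VoltageMovie(
            self.model.to_mv(out).astype(np.float32),
            frame_interval_ms=self.config.frame_interval_ms,
            spacing_um=self.domain.spacing_um,
            seed=seed,
            meta={"coupling_scale": self.het.coupling_scale,
                  "global_current_scale": self.het.global_current_scale},
        )


def run_protocol(
    domain: TissueDomain,
    het: HeterogeneityFields | None,
    events: list[StimulusEvent],
    config: SimulationConfig | None = None,
    model: CellModel | None = None,
    prerecord_ms: float = 0.0,
) -> VoltageMovie:
    """Run a stimulation protocol and record a movie at the config cadence.

    ``prerecord_ms`` runs the protocol without recording first (e.g. letting a
    spiral stabilize after induction) before the recorded window starts.
    Event times are relative to protocol start (t = 0).
    """
    events = sorted(events, key=lambda e: e.t_on_ms)
    config = config if config is not None else SimulationConfig()
    sim = Simulation(domain, het, model, config, events)
    try:
        if prerecord_ms > 0:
            sim.run(prerecord_ms, record=False)
        frames = sim.run(config.duration_ms, record=True)
    except IntegrationDivergedError as err:
        raise IntegrationDivergedError(err.step, f"protocol diverged at step {err.step}") from err
    return sim.frames_to_movie(frames, seed=config.rng_seed)


# ---------------------------------------------------------------------------
# S1S2 spiral induction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class S1S2Config:
    """Cross-gradient reentry induction.

    S1 is a planar wave from the left edge; S2 is a half-plane stimulus below
    a horizontal line through a random point P of the disc, delivered when the
    repolarization tail of S1 is expected to cross P.  The timing is scheduled
    from the reference tissue's conduction velocity and action-potential
    duration; per-sample heterogeneity then decides whether reentry actually
    takes hold.
    """

    s1_amplitude: float = 1.5
    s1_duration_ms: float = 4.0
    s2_amplitude: float = 1.5
    s2_duration_ms: float = 6.0
    s1_width_mm: float = 0.8
    ref_cv_mm_ms: float = 0.12     # scheduling estimates for the reference tissue
    ref_apd_ms: float = 110.0
    s2_offset_ms: float = -8.0     # relative to estimated tail arrival at P
    stabilize_ms: float = 150.0


def s1s2_events(
    domain: TissueDomain, cfg: S1S2Config, seed: int,
    het: HeterogeneityFields | None = None,
) -> tuple[list[StimulusEvent], tuple[float, float]]:
    """Build the S1S2 event list; the S2 anchor point P is drawn uniformly
    from the conducting disc (re-drawn from the same stream until inside).

    When ``het`` is given, the S1-S2 interval is individualized to the sample
    (as done per monolayer experimentally): the conduction-velocity estimate
    is scaled by sqrt(coupling_scale)."""
    rng = np.random.default_rng(seed)
    c = domain.side_mm / 2.0
    r_disc = None
    yy, xx = domain.node_centers_mm()
    m = domain.conducting_mask
    x_min = xx[m].min()
    # uniform point in the disc via rejection from the bounding square
    r_max = max(c - x_min, 1e-6)
    for _ in range(1000):
        p = rng.uniform(-r_max, r_max, size=2)
        if p[0] ** 2 + p[1] ** 2 <= r_max**2:
            r_disc = (c + p[0], c + p[1])
            break
    if r_disc is None:  # pragma: no cover
        r_disc = (c, c)
    py, px = r_disc
    s1 = StimulusEvent(
        "electrical", edge_strip_mask(domain, "left", cfg.s1_width_mm), 2.0,
        cfg.s1_duration_ms, cfg.s1_amplitude,
    )
    cv_est = cfg.ref_cv_mm_ms * (np.sqrt(het.coupling_scale) if het is not None else 1.0)
    t_tail = 2.0 + (px - x_min) / cv_est + cfg.ref_apd_ms + cfg.s2_offset_ms
    s2 = StimulusEvent(
        "electrical", half_plane_mask(domain, (py, px), (-1.0, 0.0)), t_tail,
        cfg.s2_duration_ms, cfg.s2_amplitude,
    )
    return [s1, s2], (py, px)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------


def _activation_time(trace: np.ndarray, dt: float, threshold: float) -> float | None:
    """First upward threshold crossing, linearly interpolated (time units of dt)."""
    above = trace >= threshold
    rising = np.nonzero(~above[:-1] & above[1:])[0]
    if rising.size == 0:
        return None
    i = rising[0]
    frac = (threshold - trace[i]) / (trace[i + 1] - trace[i])
    return (i + frac) * dt


def measure_cv(movie: VoltageMovie, threshold_mv: float = -20.0, axis: str = "x") -> float:
    """Conduction velocity (mm/s) from activation-time regression along the
    central probe line, for a wave propagating along ``axis``."""
    frames = movie.frames
    T, H, W = frames.shape
    if axis == "x":
        traces = frames[:, H // 2, :]
        n_probe = W
    else:
        traces = frames[:, :, W // 2]
        n_probe = H
    dt = movie.frame_interval_ms
    h = movie.spacing_um / 1000.0
    ts, xs = [], []
    for j in range(n_probe):
        t = _activation_time(traces[:, j], dt, threshold_mv)
        if t is not None:
            ts.append(t)
            xs.append(j * h)
    if len(ts) < 8:
        raise MeasurementUndefinedError("too few activated probe points for CV")
    ts = np.asarray(ts)
    xs = np.asarray(xs)
    slope = np.polyfit(ts, xs, 1)[0]  # mm/ms
    if not np.isfinite(slope) or abs(slope) < 1e-9:
        raise MeasurementUndefinedError("activation times do not progress along the probe")
    return float(abs(slope) * 1000.0)


def measure_apd(trace: np.ndarray, dt_ms: float, level: float = 0.8) -> float:
    """Action-potential duration at a repolarization level (default APD80):
    time from upstroke to recovery through peak - level * amplitude."""
    trace = np.asarray(trace, dtype=np.float64)
    lo, hi = trace.min(), trace.max()
    amp = hi - lo
    if amp < 1e-6:
        raise MeasurementUndefinedError("flat trace; no action potential")
    thr = hi - level * amp
    above = trace >= thr
    rising = np.nonzero(~above[:-1] & above[1:])[0]
    falling = np.nonzero(above[:-1] & ~above[1:])[0]
    if rising.size == 0 or falling.size == 0:
        raise MeasurementUndefinedError("no full action potential in trace")
    i = rising[0]
    f_candidates = falling[falling > i]
    if f_candidates.size == 0:
        raise MeasurementUndefinedError("action potential does not repolarize in trace")
    j = f_candidates[0]
    t_up = i + (thr - trace[i]) / (trace[i + 1] - trace[i])
    t_dn = j + (thr - trace[j]) / (trace[j + 1] - trace[j])
    return float((t_dn - t_up) * dt_ms)


def measure_spiral_frequency(movie: VoltageMovie, threshold_mv: float = -20.0) -> float:
    """Rotation frequency (Hz) from the median inter-activation interval at a
    ring of probe points at mid-radius."""
    frames = movie.frames
    T, H, W = frames.shape
    cy, cx = H / 2.0, W / 2.0
    r = min(H, W) / 4.0
    intervals = []
    for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
        y = int(round(cy + r * np.sin(ang)))
        x = int(round(cx + r * np.cos(ang)))
        tr = frames[:, y, x]
        above = tr >= threshold_mv
        rising = np.nonzero(~above[:-1] & above[1:])[0]
        if rising.size >= 3:
            intervals.extend(np.diff(rising) * movie.frame_interval_ms)
    if not intervals:
        raise MeasurementUndefinedError("fewer than two rotations at every probe")
    period = float(np.median(intervals))
    return 1000.0 / period


def classify_sample(
    movie: VoltageMovie,
    activity_threshold_mv: float = -20.0,
    min_active_fraction: float = 0.02,
    ps_persist_fraction: float = 0.8,
) -> str:
    """Deterministic sample label:

    - ``propagation_failure``: excitation never covers a meaningful fraction
      of the tissue in any frame;
    - ``sustained_spiral``: a phase singularity is present in at least
      ``ps_persist_fraction`` of the final half of the frames;
    - ``no_sustained_spiral``: otherwise (e.g. a single wave then quiescence).
    """
    from .ps_detect import compute_phase, detect_ps

    frames = movie.frames
    active = (frames > activity_threshold_mv).mean(axis=(1, 2))
    if active.max() < min_active_fraction:
        return "propagation_failure"
    phase = compute_phase(movie)
    n_ph = phase.theta.shape[0]
    tail = range(n_ph // 2, n_ph)
    n_with_ps = sum(1 for f in tail if len(detect_ps(phase.theta[f], phase.valid)) > 0)
    if n_with_ps >= ps_persist_fraction * len(list(tail)):
        return "sustained_spiral"
    return "no_sustained_spiral"


__all__ = [
    "TissueDomain", "HeterogeneityFields", "CellModel", "StimulusEvent",
    "SimulationConfig", "S1S2Config", "Simulation",
    "make_domain", "sample_heterogeneity", "homogeneous_fields", "get_cell_model",
    "edge_strip_mask", "half_plane_mask", "disc_mask",
    "run_protocol", "s1s2_events",
    "measure_cv", "measure_apd", "measure_spiral_frequency", "classify_sample",
    "DEFAULT_RANGES",
]
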