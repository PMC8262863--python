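"""Forward model of fluorescence micrographs of polarly growing rod cells.

Cells are 2D spherocylinders (a rectangle capped by two semicircles).
Three channels can be rendered per frame:

``phase``
    phase-contrast-like image: dark cell bodies on a bright background.
``label``
    a cell-wall label (e.g. a fluorescent D-amino acid incorporated into
    peptidoglycan): the cell envelope is drawn as a thin outline band,
    restricted to the arc-length intervals of wall that existed during the
    labeling pulse, plus filled transverse septal bands.
``cap``
    a polar marker (e.g. an mScar fusion to a wall synthase) rendered as an
    isotropic Gaussian centred on one pole tip, either tip-concentrated
    (small sigma) or pole-broad (large sigma), masked to the cell body.

Every rendered scene carries a :class:`SceneTruth` with the exact geometry,
labeled-wall intervals, septum counts and seeds, so downstream measurements
can be validated against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CellGeometry",
    "GrowthParams",
    "CapModel",
    "OpticsParams",
    "SceneTruth",
    "TimeLapse",
    "SceneSpec",
    "OverlapError",
    "render_population",
    "simulate_pulse_chase",
    "make_strain_scenario",
    "rasterize_cell",
    "spherocylinder_area",
]

# arc positions are measured in µm along the centerline from the tip of
# pole A (the pole at center - u*L/2, u = (cos theta, sin theta))

SEPTUM_HALFWIDTH_UM = 0.075  # transverse septal band full width 0.15 µm


class OverlapError(ValueError):
    """Two cells overlap after dilation by twice the PSF sigma."""

    def __init__(self, pairs: list[tuple[int, int]]):
        self.pairs = pairs
        super().__init__(f"overlapping cell pairs (indices): {pairs}")


@dataclass(frozen=True)
class CellGeometry:
    """A straight spherocylindrical cell in the image plane.

    ``length`` is tip-to-tip, ``width`` the cylinder diameter; both µm.
    ``septa_positions`` are arc-length fractions of transverse septa,
    strictly inside (0.15, 0.85) so septa never sit on a pole cap.
    """

    center: tuple[float, float]
    orientation: float
    length: float
    width: float
    septa_positions: tuple[float, ...] = ()

    def __post_init__(self):
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"need length >= width > 0, got L={self.length}, W={self.width}"
            )
        if not (0.0 <= self.orientation < math.pi):
            raise ValueError("orientation must lie in [0, pi)")
        for f in self.septa_positions:
            if not (0.15 < f < 0.85):
                raise ValueError(f"septum fraction {f} outside (0.15, 0.85)")

    @property
    def axis(self) -> np.ndarray:
        return np.array([math.cos(self.orientation), math.sin(self.orientation)])

    @property
    def tip_a(self) -> np.ndarray:
        return np.asarray(self.center) - self.axis * self.length / 2

    @property
    def tip_b(self) -> np.ndarray:
        return np.asarray(self.center) + self.axis * self.length / 2

    @property
    def n_septa(self) -> int:
        return len(self.septa_positions)


@dataclass(frozen=True)
class GrowthParams:
    """Per-pole elongation rates and pulse-chase timing (minutes, µm/min)."""

    rate_pole_a: float = 0.005
    rate_pole_b: float = 0.005
    pulse_end: float = 6.0
    frame_interval: float = 5.0
    duration: float = 120.0

    def __post_init__(self):
        if self.rate_pole_a < 0 or self.rate_pole_b < 0:
            raise ValueError("rates must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")

    @property
    def total_rate(self) -> float:
        return self.rate_pole_a + self.rate_pole_b


@dataclass(frozen=True)
class CapModel:
    """Polar-marker emission: Gaussian of spread ``sigma`` at one pole tip.

    ``kind`` distinguishes the tip-concentrated pattern (RodA-like) from
    the broader polar distribution (aPBP-like); it is metadata — the
    rendered shape is set entirely by ``sigma``.
    """

    kind: str = "tip"
    sigma: float = 0.2
    amplitude: float = 100.0

    def __post_init__(self):
        if self.kind not in ("tip", "broad"):
            raise ValueError("kind must be 'tip' or 'broad'")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class OpticsParams:
    """Imaging model: sampling, blur, background and noise.

    ``poisson_gain`` converts counts to photons for shot noise
    (counts/photon); set it to 0 to disable shot noise.  ``read_noise_sd``
    is additive Gaussian noise in counts; 0 disables it.
    """

    pixel_size: float = 0.065
    psf_sigma: float = 0.1
    background: float = 100.0
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    @property
    def noiseless(self) -> bool:
        return self.poisson_gain == 0 and self.read_noise_sd == 0


@dataclass
class CellTruth:
    """Ground truth for one cell in one frame."""

    cell_index: int
    time: float
    geometry: CellGeometry
    labeled_intervals: tuple[tuple[float, float], ...]
    unlabeled_length: float
    n_septa: int
    septa_arc_um: tuple[float, ...]


@dataclass
class SceneTruth:
    """Full ground truth of a rendered scene or time lapse."""

    cells: list[CellTruth]
    cap_model: CapModel | None
    optics: OpticsParams
    times: tuple[float, ...]
    cap_pole: tuple[str, ...] = ()  # per cell, "A" or "B"
    seed: int = 0

    def frame(self, time: float) -> list[CellTruth]:
        return [c for c in self.cells if c.time == time]

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)

    def to_table(self):
        """Flat per-cell rows (one per cell per frame) for truth_cells.csv."""
        import pandas as pd

        rows = []
        for c in self.cells:
            g = c.geometry
            rows.append(
                dict(
                    cell_index=c.cell_index,
                    time_min=c.time,
                    center_x_um=g.center[0],
                    center_y_um=g.center[1],
                    orientation_rad=g.orientation,
                    length_um=g.length,
                    width_um=g.width,
                    n_septa=c.n_septa,
                    unlabeled_um=c.unlabeled_length,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class TimeLapse:
    """Time-major stack: frames[t][channel] -> 2D float array."""

    times: tuple[float, ...]
    frames: list[dict[str, np.ndarray]]
    pixel_size: float

    def channel_stack(self, channel: str) -> np.ndarray:
        return np.stack([f[channel] for f in self.frames])


def spherocylinder_area(length: float, width: float) -> float:
    """Analytic area of a 2D spherocylinder: L·W + (π/4 − 1)·W²."""
    return length * width + (math.pi / 4 - 1) * width**2


def _channel_rng(seed: int, frame_index: int, channel_index: int) -> np.random.Generator:
    # counter-style stream split: each (frame, channel) gets its own
    # independent, reproducible stream
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(frame_index, channel_index))
    return np.random.default_rng(ss)


def _cell_fields(
    geom: CellGeometry,
    shape: tuple[int, int],
    pixel_size: float,
    supersample: int = 2,
):
    """Subsampled coordinate fields for one cell's bounding box.

    Returns (row slice, col slice, body coverage, arc position s,
    distance to centerline segment, distance to each tip), where the
    per-pixel values are means over ``supersample``² subpixel samples for
    coverage, and subpixel arrays (ss*h, ss*w) for the rest.
    """
    half = geom.length / 2 + geom.width  # generous margin
    cx, cy = geom.center
    r0 = max(0, int((cy - half) / pixel_size) - 1)
    r1 = min(shape[0], int((cy + half) / pixel_size) + 2)
    c0 = max(0, int((cx - half) / pixel_size) - 1)
    c1 = min(shape[1], int((cx + half) / pixel_size) + 2)
    if r1 <= r0 or c1 <= c0:
        return None
    ss = supersample
    # subpixel sample centres: pixel p covers [p, p+1) px -> physical
    # x = (col + (k+0.5)/ss) * pixel_size
    sub = (np.arange(ss) + 0.5) / ss
    rows = (r0 + np.arange(r1 - r0)[:, None] + sub[None, :]).ravel()
    cols = (c0 + np.arange(c1 - c0)[:, None] + sub[None, :]).ravel()
    y = rows * pixel_size
    x = cols * pixel_size
    X, Y = np.meshgrid(x, y)
    u = geom.axis
    dx = X - cx
    dy = Y - cy
    t = dx * u[0] + dy * u[1]
    perp = -dx * u[1] + dy * u[0]
    hl = (geom.length - geom.width) / 2  # centerline half-length
    tc = np.clip(t, -hl, hl)
    dist = np.hypot(t - tc, perp)
    s = np.clip(t + geom.length / 2, 0.0, geom.length)
    d_tip_a = np.hypot(dx + u[0] * geom.length / 2, dy + u[1] * geom.length / 2)
    d_tip_b = np.hypot(dx - u[0] * geom.length / 2, dy - u[1] * geom.length / 2)
    return (slice(r0, r1), slice(c0, c1)), dist, s, d_tip_a, d_tip_b


def _block_mean(a: np.ndarray, ss: int) -> np.ndarray:
    h, w = a.shape
    return a.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def rasterize_cell(
    geom: CellGeometry,
    shape: tuple[int, int],
    pixel_size: float,
    supersample: int = 2,
) -> np.ndarray:
    """Boolean body mask of one cell (pixel coverage >= 0.5)."""
    out = np.zeros(shape, dtype=bool)
    fields = _cell_fields(geom, shape, pixel_size, supersample)
    if fields is None:
        return out
    (rs, cs), dist, _, _, _ = fields
    cov = _block_mean((dist <= geom.width / 2).astype(float), supersample)
    out[rs, cs] = cov >= 0.5
    return out


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2D segments."""
    def pt_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.hypot(*(p - (a + t * ab))))

    p1, p2, q1, q2 = map(np.asarray, (p1, p2, q1, q2))

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p1, p2, q1), orient(p1, p2, q2)
    d3, d4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    return min(
        pt_seg(q1, p1, p2), pt_seg(q2, p1, p2), pt_seg(p1, q1, q2), pt_seg(p2, q1, q2)
    )


def check_overlaps(geometries: Sequence[CellGeometry], clearance: float) -> None:
    """Raise :class:`OverlapError` if any two cell capsules come closer
    than ``clearance`` (surface-to-surface)."""
    bad = []
    n = len(geometries)
    segs = []
    for g in geometries:
        u = g.axis
        hl = (g.length - g.width) / 2
        c = np.asarray(g.center)
        segs.append((c - u * hl, c + u * hl, g.width / 2))
    for i in range(n):
        a1, a2, ri = segs[i]
        for j in range(i + 1, n):
            b1, b2, rj = segs[j]
            # cheap reject on centre distance
            ci = (a1 + a2) / 2
            cj = (b1 + b2) / 2
            reach = (
                geometries[i].length / 2 + geometries[j].length / 2 + ri + rj + clearance
            )
            if float(np.hypot(*(ci - cj))) > reach:
                continue
            if _segment_distance(a1, a2, b1, b2) < ri + rj + clearance:
                bad.append((i, j))
    if bad:
        raise OverlapError(bad)


def _auto_shape(
    geometries: Sequence[CellGeometry], pixel_size: float, margin_um: float = 1.0
) -> tuple[int, int]:
    if not geometries:
        return (64, 64)
    xs = []
    ys = []
    for g in geometries:
        half = g.length / 2 + g.width / 2
        xs += [g.center[0] - half, g.center[0] + half]
        ys += [g.center[1] - half, g.center[1] + half]
    w = int(math.ceil((max(xs) + margin_um) / pixel_size)) + 1
    h = int(math.ceil((max(ys) + margin_um) / pixel_size)) + 1
    if min(xs) - margin_um < 0 or min(ys) - margin_um < 0:
        # cells assumed placed in positive quadrant with margin
        pass
    return (h, w)


def _render_channels(
    geometries: Sequence[CellGeometry],
    labeled_intervals: Sequence[tuple[tuple[float, float], ...]],
    cap_model: CapModel | None,
    cap_pole: Sequence[str],
    optics: OpticsParams,
    shape: tuple[int, int],
    channels: Sequence[str],
    frame_index: int,
    supersample: int,
    phase_depth: float,
    label_amplitude: float,
    label_mode: str,
    band_width_um: float,
) -> dict[str, np.ndarray]:
    ss = supersample
    emission = {
        ch: np.zeros(shape, dtype=np.float64) for ch in channels if ch != "phase"
    }
    coverage = np.zeros(shape, dtype=np.float64)
    for idx, geom in enumerate(geometries):
        fields = _cell_fields(geom, shape, optics.pixel_size, ss)
        if fields is None:
            continue
        (rs, cs), dist, s, d_a, d_b = fields
        body = dist <= geom.width / 2
        coverage[rs, cs] += _block_mean(body.astype(float), ss)
        if "label" in emission:
            intervals = labeled_intervals[idx]
            in_label = np.zeros_like(body)
            for lo, hi in intervals:
                in_label |= (s >= lo) & (s <= hi)
            if label_mode == "envelope":
                band = np.abs(dist - geom.width / 2) <= band_width_um / 2
                lab = band & in_label
            else:  # filled body
                lab = body & in_label
            # septa: filled transverse bands, always labeled (formed
            # before/during the pulse)
            for fsep in geom.septa_positions:
                lab |= body & (np.abs(s - fsep * geom.length) <= SEPTUM_HALFWIDTH_UM)
            emission["label"][rs, cs] += label_amplitude * _block_mean(
                lab.astype(float), ss
            )
        if "cap" in emission and cap_model is not None:
            # marker density falls off with distance from the pole along
            # the cell axis (how polar distributions are quantified), so
            # the kernel argument is the axial arc distance from the tip
            s_cap = s if cap_pole[idx] == "A" else geom.length - s
            g = cap_model.amplitude * np.exp(-(s_cap**2) / (2 * cap_model.sigma**2))
            emission["cap"][rs, cs] += _block_mean(np.where(body, g, 0.0), ss)
    out: dict[str, np.ndarray] = {}
    psf_px = optics.psf_sigma / optics.pixel_size
    ch_index = {ch: i for i, ch in enumerate(("phase", "label", "cap"))}
    for ch in channels:
        if ch == "phase":
            img = -phase_depth * coverage
        else:
            img = emission[ch]
        if psf_px > 0:
            img = ndimage.gaussian_filter(img, psf_px)
        img = img + optics.background
        if ch == "phase":
            img = np.maximum(img, 0.0)
        if not optics.noiseless:
            rng = _channel_rng(optics.seed, frame_index, ch_index.get(ch, 9))
            if optics.poisson_gain > 0:
                photons = np.maximum(img, 0.0) / optics.poisson_gain
                img = rng.poisson(photons).astype(np.float64) * optics.poisson_gain
            if optics.read_noise_sd > 0:
                img = img + rng.normal(0.0, optics.read_noise_sd, img.shape)
        out[ch] = img.astype(np.float32)
    return out


def render_population(
    geometries: Sequence[CellGeometry],
    cap_model: CapModel | None,
    optics: OpticsParams,
    *,
    channels: Sequence[str] = ("phase", "label", "cap"),
    labeled_intervals: Sequence[tuple[tuple[float, float], ...]] | None = None,
    cap_pole: Sequence[str] | None = None,
    shape: tuple[int, int] | None = None,
    supersample: int = 2,
    phase_depth: float = 80.0,
    label_amplitude: float = 300.0,
    label_mode: str = "envelope",
    band_width_px: float = 2.0,
    time: float = 0.0,
    frame_index: int = 0,
) -> tuple[dict[str, np.ndarray], SceneTruth]:
    """Render one multi-channel frame of a static cell population.

    By default every cell's wall is fully labeled (intervals ``[0, L]``);
    pass ``labeled_intervals`` to restrict the label, and ``cap_pole``
    ("A"/"B" per cell) to choose which pole carries the cap marker
    (default pole A).  Raises :class:`OverlapError` if any two cells come
    closer than twice the PSF sigma, and ValueError if a cell exceeds the
    frame bounds.
    """
    if cap_model is None:
        channels = tuple(ch for ch in channels if ch != "cap")
    geometries = list(geometries)
    if shape is None:
        shape = _auto_shape(geometries, optics.pixel_size)
    check_overlaps(geometries, 2 * optics.psf_sigma)
    for i, g in enumerate(geometries):
        half = g.length / 2 + g.width / 2
        if (
            g.center[0] - half < 0
            or g.center[1] - half < 0
            or g.center[0] + half > shape[1] * optics.pixel_size
            or g.center[1] + half > shape[0] * optics.pixel_size
        ):
            raise ValueError(f"cell {i} exceeds frame bounds")
    if labeled_intervals is None:
        labeled_intervals = [((0.0, g.length),) for g in geometries]
    if cap_pole is None:
        cap_pole = ["A"] * len(geometries)
    frames = _render_channels(
        geometries,
        labeled_intervals,
        cap_model,
        cap_pole,
        optics,
        shape,
        channels,
        frame_index,
        supersample,
        phase_depth,
        label_amplitude,
        label_mode,
        band_width_px * optics.pixel_size,
    )
    cells = []
    for i, g in enumerate(geometries):
        lab = tuple(tuple(iv) for iv in labeled_intervals[i])
        labeled_total = sum(hi - lo for lo, hi in lab)
        cells.append(
            CellTruth(
                cell_index=i,
                time=time,
                geometry=g,
                labeled_intervals=lab,
                unlabeled_length=max(0.0, g.length - labeled_total),
                n_septa=g.n_septa,
                septa_arc_um=tuple(f * g.length for f in g.septa_positions),
            )
        )
    truth = SceneTruth(
        cells=cells,
        cap_model=cap_model,
        optics=optics,
        times=(time,),
        cap_pole=tuple(cap_pole),
        seed=optics.seed,
    )
    return frames, truth


def grow_geometry(geom: CellGeometry, growth: GrowthParams, t: float) -> CellGeometry:
    """Cell geometry after ``t`` minutes of bipolar tip extension.

    Pole A extends at ``rate_pole_a`` along -axis, pole B at
    ``rate_pole_b`` along +axis; width and orientation are constant.
    """
    da = growth.rate_pole_a * t
    db = growth.rate_pole_b * t
    u = geom.axis
    center = (
        geom.center[0] + u[0] * (db - da) / 2,
        geom.center[1] + u[1] * (db - da) / 2,
    )
    new_len = geom.length + da + db
    # septa stay fixed in the old-wall material: arc distance from the
    # (moving) pole-A tip grows by the material pole A adds
    fracs = tuple(
        np.clip((f * geom.length + da) / new_len, 0.1501, 0.8499)
        for f in geom.septa_positions
    )
    return CellGeometry(center, geom.orientation, new_len, geom.width, fracs)


def simulate_pulse_chase(
    initial_geometries: Sequence[CellGeometry],
    growth: GrowthParams,
    optics: OpticsParams,
    *,
    times: Sequence[float] | None = None,
    channels: Sequence[str] = ("phase", "label"),
    shape: tuple[int, int] | None = None,
    **render_kw,
) -> tuple[TimeLapse, SceneTruth]:
    """Simulate an FDAA pulse-chase time lapse with bipolar growth.

    Wall present at ``growth.pulse_end`` carries the label; wall added
    after it is dark.  Each pole advances by its rate × Δt per frame, so
    the true unlabeled total per cell is
    ``(rate_a + rate_b) * (t - pulse_end)`` for t >= pulse_end.
    """
    if growth.pulse_end >= growth.duration:
        raise ValueError("pulse_end must be < duration")
    if times is None:
        times = tuple(
            np.arange(0.0, growth.duration + 1e-9, growth.frame_interval)
        )
    times = tuple(float(t) for t in times)
    if shape is None:
        final = [grow_geometry(g, growth, times[-1]) for g in initial_geometries]
        shape = _auto_shape(final, optics.pixel_size)
    all_cells: list[CellTruth] = []
    frames = []
    for fi, t in enumerate(times):
        geoms_t = [grow_geometry(g, growth, t) for g in initial_geometries]
        intervals = []
        for g0, gt in zip(initial_geometries, geoms_t):
            dt = max(0.0, t - growth.pulse_end)
            ua = growth.rate_pole_a * dt
            ub = growth.rate_pole_b * dt
            intervals.append(((ua, gt.length - ub),))
        try:
            frame, truth_f = render_population(
                geoms_t,
                None,
                dataclasses.replace(optics),
                channels=channels,
                labeled_intervals=intervals,
                shape=shape,
                time=t,
                frame_index=fi,
                **render_kw,
            )
        except ValueError as e:
            if "exceeds frame bounds" in str(e):
                raise ValueError(f"frame {fi} (t={t} min): {e}") from e
            raise
        for c in truth_f.cells:
            c.unlabeled_length = growth.total_rate * max(0.0, t - growth.pulse_end)
        all_cells.extend(truth_f.cells)
        frames.append(frame)
    truth = SceneTruth(
        cells=all_cells,
        cap_model=None,
        optics=optics,
        times=times,
        seed=optics.seed,
    )
    return TimeLapse(times=times, frames=frames, pixel_size=optics.pixel_size), truth


@dataclass
class SceneSpec:
    """A sampled strain scenario: placed cell geometries plus metadata."""

    name: str
    geometries: list[CellGeometry]
    septa_counts: list[int]
    seed: int
    pixel_size: float

    @property
    def n_cells(self) -> int:
        return len(self.geometries)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1 + cv**2)
    mu = math.log(mean) - sigma2 / 2
    return mu, math.sqrt(sigma2)


def make_strain_scenario(
    name: str,
    n_cells: int,
    septa_fractions: Sequence[float],
    *,
    length_mean: float = 3.0,
    length_cv: float = 0.2,
    width_mean: float = 1.0,
    width_cv: float = 0.05,
    seed: int = 0,
    pixel_size: float = 0.065,
    spacing_um: float | None = None,
    extra_spacing_um: float = 0.0,
    orientation: str = "random",
    multi_septa_counts: tuple[int, ...] = (2, 3),
    multi_septa_probs: tuple[float, ...] = (0.7, 0.3),
) -> SceneSpec:
    """Sample a population of cells on a non-overlapping jittered grid.

    ``septa_fractions`` are the probabilities of a cell carrying (0, 1,
    >=2) septa, matching the none/one/multiple classification used for
    cell-separation phenotypes; they must sum to 1.  Deterministic for a
    fixed seed.
    """
    fr = np.asarray(septa_fractions, dtype=float)
    if fr.size != 3:
        raise ValueError("septa_fractions must have 3 entries (none, one, multiple)")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"septa_fractions must sum to 1, got {fr.sum()!r}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mu_l, s_l = _lognormal_params(length_mean, length_cv)
    mu_w, s_w = _lognormal_params(width_mean, width_cv)
    lengths = np.clip(rng.lognormal(mu_l, s_l, n_cells), 1.2, 6.5)
    widths = np.clip(rng.lognormal(mu_w, s_w, n_cells), 0.7, 1.3)
    lengths = np.maximum(lengths, widths + 0.2)
    cats = rng.choice(3, size=n_cells, p=fr)
    if spacing_um is None:
        # extra_spacing_um reserves room for growth during a time lapse
        spacing_um = float(lengths.max()) + 1.5 + extra_spacing_um
    ncol = max(1, int(math.ceil(math.sqrt(n_cells))))
    geoms: list[CellGeometry] = []
    counts: list[int] = []
    for i in range(n_cells):
        row, col = divmod(i, ncol)
        jitter = rng.uniform(-0.15, 0.15, 2) * spacing_um * 0.3
        cx = (col + 0.5) * spacing_um + jitter[0] + 0.5
        cy = (row + 0.5) * spacing_um + jitter[1] + 0.5
        theta = rng.uniform(0, math.pi) if orientation == "random" else 0.0
        L, W = float(lengths[i]), float(widths[i])
        if cats[i] == 0:
            n_sep = 0
        elif cats[i] == 1:
            n_sep = 1
        else:
            n_sep = int(rng.choice(multi_septa_counts, p=multi_septa_probs))
        fracs = _sample_septa_fracs(rng, n_sep, L)
        geoms.append(CellGeometry((cx, cy), theta, L, W, fracs))
        counts.append(n_sep)
    return SceneSpec(name, geoms, counts, seed, pixel_size)


def _sample_septa_fracs(
    rng: np.random.Generator, n_sep: int, length: float, min_sep_um: float = 0.45
) -> tuple[float, ...]:
    """Septum positions as arc fractions, pairwise at least min_sep_um apart
    and away from the pole caps."""
    if n_sep == 0:
        return ()
    lo, hi = 0.2, 0.8
    min_gap = min_sep_um / length
    for _ in range(200):
        fr = np.sort(rng.uniform(lo, hi, n_sep))
        if n_sep == 1 or np.diff(fr).min() >= min_gap:
            return tuple(float(f) for f in fr)
    # fall back to an even spread
    return tuple(float(f) for f in np.linspace(0.3, 0.7, n_sep))
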