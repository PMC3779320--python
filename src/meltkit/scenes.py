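"""Synthetic two-channel yeast time-lapse generator with ground truth.

Emulates the statistical structure that the localization index assumes:
inside a cell, a delocalized fluorophore produces approximately Gaussian
pixel intensities (Poisson shot noise at high counts plus Gaussian read
noise), while a kinetochore-localized fluorophore adds a small bright
sub-diffraction focus on top of the diffuse signal.  Cells are ellipses
that jitter, bud periodically, and carry a focus only during a defined
window of the cell cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "IntensityModel",
    "SceneConfig",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "expected_stack",
    "scenario_presets",
    "save_scene",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel intensity and noise model.

    All levels are in camera counts.  Observed counts are
    ``gain * Poisson(expected / gain) + N(0, read_noise_sd)``, clipped to
    the 16-bit range.  ``focus_amplitude`` is the peak height A of the
    Gaussian focus; the total excess signal it adds integrates to
    ``A * 2 * pi * focus_sigma**2``.  A = 0 models a delocalized
    (diffuse-only) fluorophore.
    """

    background: float = 200.0
    diffuse_level: float = 300.0
    focus_amplitude: float = 800.0
    focus_sigma: float = 1.5
    photon_gain: float = 1.0
    read_noise_sd: float = 3.0

    def validate(self) -> None:
        for name in ("background", "diffuse_level", "focus_amplitude",
                     "focus_sigma", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.photon_gain <= 0:
            raise ValueError("photon_gain must be positive")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic time-lapse scene.

    ``localized_window`` is a pair of cell-cycle fractions (start, end),
    measured from the preceding budding event, during which the focus is
    present.  ``cycle_period`` is in frames; the frame interval is
    deliberately abstract.  Defaults put a cell at roughly 1,500-2,500
    pixels so the brightest-1% pixel set is 15-25 pixels.
    """

    frame_shape: tuple[int, int] = (520, 520)
    pixel_size: float = 0.1          # µm per pixel
    n_cells: int = 6
    cell_radius_range: tuple[float, float] = (2.55, 2.85)   # µm
    n_frames: int = 95
    cycle_period: int = 30
    localized_window: tuple[float, float] = (0.05, 0.40)
    motion_sd: float = 0.3           # pixels / frame centroid jitter
    channels: tuple[IntensityModel, ...] = (IntensityModel(), IntensityModel())
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.localized_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("localized_window must satisfy 0 <= start < end <= 1")
        if self.cycle_period < 4:
            raise ValueError("cycle_period must be >= 4 frames")
        if min(self.cell_radius_range) <= 0:
            raise ValueError("cell radii must be positive")
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("n_cells and n_frames must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        for ch in self.channels:
            ch.validate()


@dataclass
class GroundTruth:
    """Ground truth of a generated scene.

    label_masks: (n_frames, H, W) int32, 0 = background.  Mother cells keep
    label ``cell_id`` (1-based); buds get fresh labels.  bud_events rows are
    (cell_id, bud_label, frame).  focus_positions is (n_cells, n_frames, 2)
    float (row, col), NaN where no focus; localized_flags is the matching
    boolean array.
    """

    label_masks: np.ndarray
    bud_events: list[tuple[int, int, int]]
    focus_positions: np.ndarray
    localized_flags: np.ndarray

    def bud_frames(self, cell_id: int) -> list[int]:
        return [f for (cid, _bid, f) in self.bud_events if cid == cell_id]

    def bud_events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bud_events,
                            columns=["cell_id", "bud_label", "frame"])


# ---------------------------------------------------------------------------
# geometry

_BUD_GAP = 3.0          # px, dark neck between mother and bud boundaries
_BUD_AREA0 = 0.10       # initial bud area as fraction of mother area
_BUD_AREA1 = 0.40       # bud area fraction after one full cycle
_GOLDEN = 2.399963      # radians, successive bud direction increment


@dataclass
class _Mother:
    cell_id: int
    center0: np.ndarray          # (2,) row, col at frame 0
    a: float                     # semi-axis along orientation, px
    b: float                     # perpendicular semi-axis, px
    theta: float                 # orientation, radians
    phase: int                   # frame of first budding event
    bud_angle0: float
    focus_offset: np.ndarray     # (2,) px, fixed offset from center
    centers: np.ndarray = field(default=None)  # (n_frames, 2) after jitter

    def bud_frames(self, n_frames: int, period: int) -> list[int]:
        return list(range(self.phase, n_frames, period))


def _ellipse_mask(shape, center, a, b, theta):
    r0, c0 = center
    rr = int(math.ceil(max(a, b))) + 2
    rlo, rhi = max(0, int(r0) - rr), min(shape[0], int(r0) + rr + 1)
    clo, chi = max(0, int(c0) - rr), min(shape[1], int(c0) + rr + 1)
    if rlo >= rhi or clo >= chi:
        return None, None
    rows, cols = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rows - r0, cols - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(rlo, rhi), slice(clo, chi)), inside


def _place_mothers(config: SceneConfig, rng: np.random.Generator) -> list[_Mother]:
    h, w = config.frame_shape
    rmin, rmax = (r / config.pixel_size for r in config.cell_radius_range)
    mothers: list[_Mother] = []
    # footprint leaves room for the mother, a full-grown bud, and jitter
    margin = 2.4 * rmax
    max_tries = 400
    for cid in range(1, config.n_cells + 1):
        # r is the geometric-mean radius so cell area is pi * r^2 regardless
        # of the aspect ratio
        r = rng.uniform(rmin, rmax)
        aspect = rng.uniform(1.0, 1.4)
        a = r * math.sqrt(aspect)
        b = r / math.sqrt(aspect)
        theta = rng.uniform(0, math.pi)
        placed = False
        for _ in range(max_tries):
            center = np.array([rng.uniform(margin, h - margin),
                               rng.uniform(margin, w - margin)])
            if all(np.linalg.norm(center - m.center0) >= 2.3 * (a + m.a) / 2 + 2.2 * rmax
                   for m in mothers):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {cid} after {max_tries} tries; "
                "reduce n_cells or enlarge frame_shape")
        phase = int(rng.integers(5, config.cycle_period))
        # bud direction points toward the frame center so buds stay in frame
        to_center = math.atan2(h / 2 - center[0], w / 2 - center[1])
        foff_dir = rng.uniform(0, 2 * math.pi)
        focus_offset = 0.25 * b * np.array([math.sin(foff_dir), math.cos(foff_dir)])
        mothers.append(_Mother(cid, center, a, b, theta, phase,
                               to_center + rng.uniform(-0.5, 0.5), focus_offset))
    return mothers


def _jitter_centers(mothers, config, rng):
    steps_sd = config.motion_sd
    for m in mothers:
        steps = (rng.normal(0.0, steps_sd, size=(config.n_frames, 2))
                 if steps_sd > 0 else np.zeros((config.n_frames, 2)))
        steps[0] = 0.0
        m.centers = m.center0 + np.cumsum(steps, axis=0)


@dataclass
class _Bud:
    label: int
    mother: _Mother
    start: int                   # frame of appearance
    end: int                     # removed at this frame (exclusive)
    angle: float

    def geometry(self, frame: int, period: int):
        """Center and radius of the bud at a frame (circle).

        The bud center is placed along the bud direction at the distance
        where the clearance between the circle and the mother's boundary
        equals the neck gap (bisection against the sampled boundary; the
        radial polar distance underestimates clearance for tilted
        ellipses)."""
        m = self.mother
        mother_area = math.pi * m.a * m.b
        frac = _BUD_AREA0 + (_BUD_AREA1 - _BUD_AREA0) * (frame - self.start) / period
        r = math.sqrt(frac * mother_area / math.pi)
        u = np.array([math.sin(self.angle), math.cos(self.angle)])
        phi = np.linspace(0, 2 * math.pi, 360, endpoint=False)
        boundary = np.stack([
            m.a * np.cos(phi) * math.cos(m.theta) - m.b * np.sin(phi) * math.sin(m.theta),
            m.a * np.cos(phi) * math.sin(m.theta) + m.b * np.sin(phi) * math.cos(m.theta),
        ], axis=1)

        def clearance(d):
            c = d * u
            return float(np.min(np.linalg.norm(boundary - c, axis=1))) - r - _BUD_GAP

        # support-function bracket: at lo the circle touches the supporting
        # line (clearance <= 0), at hi the projection bound gives
        # clearance >= 0, so the crossing is always inside
        support = float(np.max(boundary @ u))
        lo = support + r
        hi = lo + _BUD_GAP + 1e-6
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if clearance(mid) < 0:
                lo = mid
            else:
                hi = mid
        mc = m.centers[frame]
        return mc + hi * u, r


def _build_scene(config: SceneConfig, seed: int):
    """Sample all geometry and ground truth (no pixel noise)."""
    config.validate()
    ss = np.random.SeedSequence([int(seed), 0x5ce9e])
    geom_rng = np.random.default_rng(ss.spawn(1)[0])
    mothers = _place_mothers(config, geom_rng)
    _jitter_centers(mothers, config, geom_rng)

    buds: list[_Bud] = []
    bud_events: list[tuple[int, int, int]] = []
    next_label = config.n_cells + 1
    for m in mothers:
        frames = m.bud_frames(config.n_frames, config.cycle_period)
        for j, f in enumerate(frames):
            end = frames[j + 1] if j + 1 < len(frames) else config.n_frames
            buds.append(_Bud(next_label, m, f, end, m.bud_angle0 + j * _GOLDEN))
            bud_events.append((m.cell_id, next_label, f))
            next_label += 1

    n_f = config.n_frames
    focus_pos = np.full((config.n_cells, n_f, 2), np.nan)
    localized = np.zeros((config.n_cells, n_f), dtype=bool)
    lo, hi = config.localized_window
    focus_rng = np.random.default_rng(ss.spawn(2)[1])
    for m in mothers:
        prev_bud = m.phase - config.cycle_period
        bud_iter = m.bud_frames(n_f, config.cycle_period)
        for f in range(n_f):
            while bud_iter and bud_iter[0] <= f:
                prev_bud = bud_iter.pop(0)
            frac = (f - prev_bud) / config.cycle_period
            if lo <= frac < hi:
                localized[m.cell_id - 1, f] = True
                jit = focus_rng.normal(0, 0.5, size=2)
                focus_pos[m.cell_id - 1, f] = m.centers[f] + m.focus_offset + jit

    masks = np.zeros((n_f, *config.frame_shape), dtype=np.int32)
    for f in range(n_f):
        for m in mothers:
            sl, inside = _ellipse_mask(config.frame_shape, m.centers[f], m.a, m.b, m.theta)
            if sl is not None:
                masks[f][sl][inside] = m.cell_id
        for bud in buds:
            if bud.start <= f < bud.end:
                center, r = bud.geometry(f, config.cycle_period)
                sl, inside = _ellipse_mask(config.frame_shape, center, r, r, 0.0)
                if sl is not None:
                    masks[f][sl][inside] = bud.label

    truth = GroundTruth(masks, bud_events, focus_pos, localized)
    return truth


def _expected_frame(config: SceneConfig, truth: GroundTruth, frame: int,
                    channel: int) -> np.ndarray:
    ch = config.channels[channel]
    img = np.full(config.frame_shape, ch.background, dtype=np.float64)
    img[truth.label_masks[frame] > 0] += ch.diffuse_level
    if ch.focus_amplitude > 0:
        sig = ch.focus_sigma
        ext = int(math.ceil(5 * sig))
        for cid in range(config.n_cells):
            pos = truth.focus_positions[cid, frame]
            if np.isnan(pos[0]):
                continue
            r0, c0 = pos
            rlo = max(0, int(r0) - ext)
            rhi = min(config.frame_shape[0], int(r0) + ext + 1)
            clo = max(0, int(c0) - ext)
            chi = min(config.frame_shape[1], int(c0) + ext + 1)
            rows, cols = np.mgrid[rlo:rhi, clo:chi]
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            img[rlo:rhi, clo:chi] += ch.focus_amplitude * np.exp(-d2 / (2 * sig * sig))
    return img


def expected_stack(config: SceneConfig, seed: int | None = None) -> np.ndarray:
    """Noise-free expected intensity stack (n_frames, n_channels, H, W).

    Rebuilds the same geometry as :func:`generate_scene` for the same seed.
    """
    seed = config.seed if seed is None else seed
    truth = _build_scene(config, seed)
    out = np.empty((config.n_frames, len(config.channels), *config.frame_shape))
    for f in range(config.n_frames):
        for c in range(len(config.channels)):
            out[f, c] = _expected_frame(config, truth, f, c)
    return out


def generate_scene(config: SceneConfig, seed: int | None = None):
    """Generate a noisy 16-bit stack (TCYX) and its ground truth.

    Deterministic for a fixed (config, seed); ``seed`` defaults to
    ``config.seed``.
    """
    seed = config.seed if seed is None else seed
    truth = _build_scene(config, seed)
    ss = np.random.SeedSequence([int(seed), 0x6e015])
    noise_rng = np.random.default_rng(ss)
    n_ch = len(config.channels)
    stack = np.empty((config.n_frames, n_ch, *config.frame_shape), dtype=np.uint16)
    for f in range(config.n_frames):
        for c in range(n_ch):
            ch = config.channels[c]
            expected = _expected_frame(config, truth, f, c)
            photons = noise_rng.poisson(expected / ch.photon_gain)
            counts = photons * ch.photon_gain
            if ch.read_noise_sd > 0:
                counts = counts + noise_rng.normal(0, ch.read_noise_sd,
                                                   size=expected.shape)
            stack[f, c] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return stack, truth


def scenario_presets() -> dict[str, SceneConfig]:
    """Named scene presets.

    "wildtype": both channels carry a kinetochore focus during the
    localized window (the red reporter and the kinetochore marker
    co-localize).  "mutant": the red channel is diffuse throughout
    (focus_amplitude = 0), as for a reader that cannot dock on its
    phosphorylated receptor; the green kinetochore marker is unchanged.
    """
    wt = SceneConfig()
    mut = replace(wt, channels=(replace(wt.channels[0], focus_amplitude=0.0),
                                wt.channels[1]))
    return {"wildtype": wt, "mutant": mut}


def save_scene(stack: np.ndarray, truth: GroundTruth, outdir) -> None:
    """Write stack + ground truth: TIFFs (axes TCYX / TYX) and CSV tables."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "stack.tif", stack, metadata={"axes": "TCYX"})
    tifffile.imwrite(outdir / "truth_labels.tif",
                     truth.label_masks.astype(np.int32), metadata={"axes": "TYX"})
    truth.bud_events_frame().to_csv(outdir / "truth_bud_events.csv", index=False)
    rows = []
    n_cells, n_frames, _ = truth.focus_positions.shape
    for cid in range(n_cells):
        for f in range(n_frames):
            r, c = truth.focus_positions[cid, f]
            if not np.isnan(r):
                rows.append((cid + 1, f, r, c))
    pd.DataFrame(rows, columns=["cell_id", "frame", "row", "col"]).to_csv(
        outdir / "truth_focus.csv", index=False)
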