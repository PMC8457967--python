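"""Synthetic top-view pen scenes and environment series with ground truth.

The generator emulates the scene this method was designed for: a
floor-reared pen viewed from directly above — speckled black/white
litter, a white wall strip, a feeder and a drinker whose plastic is
deliberately close to plumage colour on the Cb and b* axes (the
motivating difficulty) but separated on the Q axis, and a flock of
ellipse-shaped birds textured with brown and cream plumage.  Every frame
comes with the exact truth mask of bird pixels, so thresholds, masks,
occupancy maps and activity indices can all be validated end to end.

The environment generator draws (THI, NH3) period pairs from a Gaussian
copula with correlation ``rho``; the population Kendall tau is then
known in closed form, ``tau = (2/pi) arcsin(rho)``, which makes rank
correlation recovery testable.

Default working resolution is 384x216 (a 1/10-scale stand-in for a 4K
overhead camera) so that full-pipeline simulations run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import ellipse as _ellipse

from .envstats import PERIODS, PeriodSummary, period_label

__all__ = [
    "ScenePalette",
    "FlockState",
    "render_frame",
    "simulate_flock",
    "simulate_environment",
    "DEFAULT_SIZE",
]

DEFAULT_SIZE = (216, 384)  # (H, W)


@dataclass(frozen=True)
class ScenePalette:
    """Base RGB colours of the scene materials plus per-pixel jitter sigma.

    The feeder and drinker are reddish-orange: close to plumage in Cb
    and b*, but on the high-Q side, so only the Q cut separates them.
    """

    litter_dark: tuple = (35, 32, 30)
    litter_light: tuple = (215, 213, 210)
    plumage_primary: tuple = (150, 95, 35)  # yellow-brown
    plumage_secondary: tuple = (232, 210, 140)  # cream
    feeder: tuple = (205, 85, 55)
    drinker: tuple = (195, 70, 80)
    wall: tuple = (242, 242, 242)
    jitter_sigma: float = 6.0

    def __post_init__(self):
        for name in ("litter_dark", "litter_light", "plumage_primary",
                     "plumage_secondary", "feeder", "drinker", "wall"):
            c = getattr(self, name)
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"{name} must be an RGB triple in [0, 255]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class FlockState:
    """Positions and shapes of the birds inside the arena."""

    n_birds: int
    positions: np.ndarray  # (n_birds, 2) float (row, col) centres
    axes: tuple = (10.0, 6.0)  # ellipse semi-axes in px
    headings: np.ndarray = None  # radians, per bird
    arena: tuple = DEFAULT_SIZE  # (H, W)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.n_birds == 0:
            self.positions = self.positions.reshape(0, 2)
        if self.positions.shape != (self.n_birds, 2):
            raise ValueError("positions must be (n_birds, 2)")
        if self.headings is None:
            self.headings = np.zeros(self.n_birds)
        h, w = self.arena
        if max(self.axes) * 2 >= min(h, w):
            raise ValueError("bird larger than arena")


def _random_flock(n_birds: int, arena, axes, rng) -> FlockState:
    h, w = arena
    a = max(axes)
    pos = np.column_stack([
        rng.uniform(a, h - 1 - a, size=n_birds),
        rng.uniform(a, w - 1 - a, size=n_birds),
    ]) if n_birds else np.zeros((0, 2))
    return FlockState(n_birds=n_birds, positions=pos, axes=axes,
                      headings=rng.uniform(0, 2 * np.pi, size=n_birds), arena=arena)


def _jitter(base, shape, sigma, rng):
    out = np.empty(shape + (3,), dtype=np.float64)
    out[:] = base
    if sigma > 0:
        out += rng.normal(0.0, sigma, size=out.shape)
    return np.clip(out, 0, 255)


def render_frame(state: FlockState, palette: ScenePalette = ScenePalette(),
                 size=None, seed: int = 0):
    """Render one frame; returns ``(rgb_uint8, truth_mask_uint8)``.

    The scene, back to front: speckled litter, a wall strip along the
    top, a feeder disk (left) and drinker disk (right), then the birds —
    ellipses textured with the two plumage colours.  The truth mask is
    exactly the set of bird pixels.  Fully reproducible under ``seed``.
    """
    size = tuple(size) if size is not None else tuple(state.arena)
    h, w = size
    rng = np.random.default_rng(seed)

    # litter: coarse dark/light speckle
    frame = np.where(
        (rng.random((h, w)) < 0.5)[..., None],
        np.asarray(palette.litter_dark, float),
        np.asarray(palette.litter_light, float),
    )
    # wall strip along the top edge
    wall_h = max(2, h // 24)
    frame[:wall_h, :] = palette.wall

    # feeder and drinker at fixed positions
    r_fd = max(6, min(h, w) // 12)
    for colour, centre in (
        (palette.feeder, (h // 2, w // 5)),
        (palette.drinker, (h // 2, 4 * w // 5)),
    ):
        rr, cc = _disk(centre, r_fd, shape=(h, w))
        frame[rr, cc] = colour

    # birds on top; truth mask records exactly their pixels
    mask = np.zeros((h, w), dtype=np.uint8)
    a, b = state.axes
    for k in range(state.n_birds):
        r0, c0 = state.positions[k]
        rr, cc = _ellipse(r0, c0, a, b, shape=(h, w),
                          rotation=float(state.headings[k]))
        tex = rng.random(rr.size) < 0.65
        frame[rr, cc] = np.where(
            tex[:, None],
            np.asarray(palette.plumage_primary, float),
            np.asarray(palette.plumage_secondary, float),
        )
        mask[rr, cc] = 1

    if palette.jitter_sigma > 0:
        frame = frame + rng.normal(0.0, palette.jitter_sigma, size=frame.shape)
    frame = np.clip(frame, 0, 255).round().astype(np.uint8)
    return frame, mask


def simulate_flock(n_birds: int = 20, n_frames: int = 60,
                   step_sigma: float = 6.0, seed: int = 0,
                   size=DEFAULT_SIZE, axes=(10.0, 6.0),
                   palette: ScenePalette = ScenePalette()):
    """Random-walk flock over an analysis period.

    Bird centres follow a reflected Gaussian random walk inside the
    arena; each frame is rendered with its truth mask, and the truth
    occupancy map counts, per pixel, the frames in which it was bird.

    Returns ``(frames, truth_masks, truth_occupancy)``.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = size
    state = _random_flock(n_birds, (h, w), axes, rng)
    margin = max(axes)
    lo = np.array([margin, margin])
    hi = np.array([h - 1 - margin, w - 1 - margin])

    frames, masks = [], []
    occupancy = np.zeros((h, w), dtype=np.int64)
    # one texture seed for the whole period: the litter, wall and trough
    # are static scenery, so only the birds move between frames
    render_seed = int(rng.integers(0, 2**31))
    for t in range(n_frames):
        frame, mask = render_frame(state, palette, size=(h, w),
                                   seed=render_seed)
        frames.append(frame)
        masks.append(mask)
        occupancy += mask
        if state.n_birds and step_sigma > 0:
            step = rng.normal(0.0, step_sigma, size=state.positions.shape)
            pos = state.positions + step
            # reflect off the walls
            pos = np.where(pos < lo, 2 * lo - pos, pos)
            pos = np.where(pos > hi, 2 * hi - pos, pos)
            pos = np.clip(pos, lo, hi)
            state = replace(state, positions=pos,
                            headings=rng.uniform(0, 2 * np.pi, state.n_birds))
    return frames, masks, occupancy


def training_scene(seed: int = 0, size=DEFAULT_SIZE,
                   palette: ScenePalette = ScenePalette()):
    """A fixed-pose frame with labelled patch origins for each material.

    Two birds are placed at known positions so that 20x20-pixel-scale
    patches can be carved out of plumage, litter and feeder regions with
    certainty; used to learn thresholds on purely synthetic data.

    Returns ``(frame, patches, patch_size)`` where ``patches`` maps each
    class label to patch origins.
    """
    h, w = size
    axes = (12.0, 8.0)
    centres = [(int(h * 0.74), int(w * 0.49)), (int(h * 0.30), int(w * 0.62))]
    state = FlockState(n_birds=2, positions=centres, axes=axes, arena=(h, w))
    frame, _ = render_frame(state, palette, seed=seed)
    ps = 8  # patches inscribed in the bird ellipses
    half = ps // 2
    feeder_centre = (h // 2, w // 5)
    patches = {
        "body": [(r - half, c - half) for r, c in centres],
        "litter": [(h // 4, w // 8), (int(h * 0.8), int(w * 0.8))],
        "feeder": [(feeder_centre[0] - ps, feeder_centre[1] - ps),
                   (feeder_centre[0] + 2, feeder_centre[1] + 2)],
    }
    return frame, patches, ps


def simulate_environment(n_periods: int, rho: float, seed: int = 0,
                         thi_range=(51.0, 62.0), nh3_range=(9.0, 50.0),
                         rh: float = 60.0) -> list[PeriodSummary]:
    """Draw per-period (THI, NH3) pairs from a Gaussian copula.

    Marginals are uniform over ranges typical of a winter rearing trial
    (THI ~ 51-62, NH3 ~ 9-50 ppm).  Because monotone marginal transforms
    leave ranks unchanged, the population Kendall tau equals
    ``(2/pi) arcsin(rho)``.  Temperature and humidity are back-filled so
    that THI(mean_temp, mean_rh) reproduces the drawn THI exactly.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    if n_periods < 2:
        raise ValueError("need at least two periods")
    from scipy import stats

    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_periods)
    u = stats.norm.cdf(z)
    thi = thi_range[0] + u[:, 0] * (thi_range[1] - thi_range[0])
    nh3 = nh3_range[0] + u[:, 1] * (nh3_range[1] - nh3_range[0])
    # invert THI = 1.8T + 32 - (0.55 - 0.0055 RH)(1.8T - 26) at fixed RH
    k = 1.8 - (0.55 - 0.0055 * rh) * 1.8
    temp = (thi - 32 - 26 * (0.55 - 0.0055 * rh)) / k

    out = []
    base = np.datetime64("2019-12-22")
    for i in range(n_periods):
        day = int(i // len(PERIODS))
        hour = PERIODS[i % len(PERIODS)]
        out.append(PeriodSummary(
            date=str(base + np.timedelta64(day, "D")),
            period=period_label(hour),
            mean_nh3=float(nh3[i]),
            mean_temp=float(temp[i]),
            mean_rh=float(rh),
            thi=float(thi[i]),
        ))
    return out
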