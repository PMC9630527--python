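"""Synthetic time-lapse movies with exact ground truth.

The generator emulates the statistical structure the segmentation algorithm
assumes about live-cell imagery: cells are textured elliptical blobs whose
interiors fluctuate frame to frame (standing in for intracellular dynamics)
and whose centers translate with reflecting boundaries; the background is a
static smooth gradient with optional global illumination drift and i.i.d.
sensor noise; debris are small static textured specks that belong to the
background class.  Ground-truth masks are rasterized from the same geometry
that renders the frames, so mask pixel <=> pixel inside a cell support,
exactly.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError
from .io import ImageStack

__all__ = ["SynthConfig", "SynthMovie", "generate_movie", "presets"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic movie.  Intensities are in [0, 1] units."""

    frame_shape: tuple[int, int] = (256, 256)
    n_frames: int = 4
    n_cells: int = 3
    cell_radius_range: tuple[float, float] = (20.0, 27.0)
    cell_speed: float = 3.0              # bulk translation, px/frame
    internal_noise_sigma: float = 0.05   # per-frame intracellular texture refresh
    internal_jitter_px: float = 0.8      # sub-pixel advection of interior texture, px/frame
    texture_sigma: float = 0.08          # persistent interior texture amplitude
    cell_contrast: float = 0.18          # mean cell-background offset
    n_debris: int = 0
    debris_radius_range: tuple[float, float] = (2.0, 4.0)
    background_gradient_amplitude: float = 0.10
    background_texture_sigma: float = 0.02  # static fine-grained mottle
    illumination_drift_per_frame: float = 0.0
    sensor_noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.n_debris > 0 and self.debris_radius_range[1] >= self.cell_radius_range[0]:
            raise ConfigurationError("max debris radius must be < min cell radius")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SynthMovie:
    """A rendered movie plus the exact per-frame ground truth."""

    stack: ImageStack
    truth_masks: list[np.ndarray]   # one exact binary mask per frame
    debris_mask: np.ndarray         # static union of debris supports
    config: SynthConfig

    def __iter__(self):  # allow (stack, masks) = generate_movie(cfg)
        return iter((self.stack, self.truth_masks))


class _Blob:
    """A wobbly-ellipse support with a rigid band-passed interior texture."""

    def __init__(self, rng, radius: float, tex_sigma: float, tex_size: int):
        self.radius = radius
        # smooth random boundary perturbation: low-order Fourier modes
        self.modes = rng.uniform(0.0, 0.08, size=3)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        self.aspect = rng.uniform(0.8, 1.25)
        self.angle = rng.uniform(0.0, np.pi)
        noise = rng.standard_normal((tex_size, tex_size))
        tex = ndi.gaussian_filter(noise, 1.2) - ndi.gaussian_filter(noise, 5.0)
        self.texture = tex / tex.std() * tex_sigma
        self.tex_size = tex_size

    def boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(theta)
        for k, (eps, ph) in enumerate(zip(self.modes, self.phases), start=2):
            r = r + eps * np.cos(k * theta + ph)
        return self.radius * r

    def support_and_texture(self, shape, center, tex_offset=(0.0, 0.0)):
        """Rasterize the support at ``center`` and sample the interior texture.

        ``tex_offset`` advects the texture relative to the cell frame,
        modeling coherent sub-pixel intracellular motion.
        """
        cy, cx = center
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dy = (yy - cy).astype(np.float64)
        dx = (xx - cx).astype(np.float64)
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        u = ca * dx + sa * dy
        v = (-sa * dx + ca * dy) / self.aspect
        rr = np.hypot(u, v)
        theta = np.arctan2(v, u)
        inside = rr <= self.boundary_radius(theta)
        half = self.tex_size / 2.0
        coords = np.stack([dy + half + tex_offset[0], dx + half + tex_offset[1]])
        tex = ndi.map_coordinates(self.texture, coords, order=1, mode="wrap")
        return inside, tex


def generate_movie(config: SynthConfig) -> SynthMovie:
    """Render a reproducible movie and its exact ground-truth masks."""
    rng = np.random.default_rng(config.seed)
    H, W = config.frame_shape
    rmin, rmax = config.cell_radius_range
    margin = rmax * 1.4

    if 2 * margin >= min(H, W) and config.n_cells > 0:
        raise ConfigurationError("cells cannot fit inside the frame")

    # --- static background: smooth linear gradient + base level
    base = 0.45
    gdir = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:H, 0:W]
    ramp = (np.cos(gdir) * xx / max(W - 1, 1) + np.sin(gdir) * yy / max(H - 1, 1))
    ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-12) - 0.5
    background = base + config.background_gradient_amplitude * ramp
    if config.background_texture_sigma > 0:
        # static substrate/illumination mottle: real backgrounds are
        # inhomogeneous but constant frame to frame, which is what keeps
        # their apparent displacement near zero
        mottle = rng.standard_normal((H, W))
        mottle = ndi.gaussian_filter(mottle, 1.5) - ndi.gaussian_filter(mottle, 6.0)
        background = background + mottle / mottle.std() * config.background_texture_sigma

    # --- place cells without heavy overlap (rejection sampling)
    cells, centers, radii = [], [], []
    for _ in range(config.n_cells):
        for _attempt in range(500):
            r = rng.uniform(rmin, rmax)
            c = np.array(
                [rng.uniform(margin, H - 1 - margin), rng.uniform(margin, W - 1 - margin)]
            )
            if all(np.linalg.norm(c - c2) > 0.9 * (r + r2) for c2, r2 in zip(centers, radii)):
                break
        else:
            raise ConfigurationError("could not pack cells into the frame")
        centers.append(c)
        radii.append(r)
        tex_size = int(2 * (rmax + config.cell_speed * config.n_frames) + 8)
        cells.append(_Blob(rng, r, config.texture_sigma, tex_size))
    headings = rng.uniform(0.0, 2.0 * np.pi, size=config.n_cells)
    velocities = config.cell_speed * np.stack(
        [np.sin(headings), np.cos(headings)], axis=-1
    ) if config.n_cells else np.zeros((0, 2))

    # --- precompute cell trajectories (reflecting borders)
    trajectories = np.zeros((config.n_frames, max(config.n_cells, 1), 2))
    tpos = [c.copy() for c in centers]
    tvel = velocities.copy()
    for t in range(config.n_frames):
        for i in range(config.n_cells):
            trajectories[t, i] = tpos[i]
        for i in range(config.n_cells):
            tpos[i] = tpos[i] + tvel[i]
            for ax, limit in ((0, H - 1), (1, W - 1)):
                if tpos[i][ax] < margin:
                    tpos[i][ax] = 2 * margin - tpos[i][ax]
                    tvel[i][ax] *= -1
                elif tpos[i][ax] > limit - margin:
                    tpos[i][ax] = 2 * (limit - margin) - tpos[i][ax]
                    tvel[i][ax] *= -1

    # --- static debris, placed isolated from every cell position at every
    # frame and from other specks, so that exclusion from the final masks
    # measures the size filter rather than geometric luck
    debris_mask = np.zeros((H, W), dtype=bool)
    debris_image = np.zeros((H, W))
    dmin, dmax = config.debris_radius_range
    clearance = rmax * 1.15 + 18.0
    debris_centers: list[np.ndarray] = []
    for _ in range(config.n_debris):
        placed = False
        for _attempt in range(500):
            r = rng.uniform(dmin, dmax)
            c = np.array([rng.uniform(r + 1, H - 2 - r), rng.uniform(r + 1, W - 2 - r)])
            near_cell = config.n_cells > 0 and float(
                np.min(np.linalg.norm(trajectories - c, axis=-1))
            ) < clearance
            near_debris = any(np.linalg.norm(c - d) < 2 * dmax + 24 for d in debris_centers)
            if not near_cell and not near_debris:
                placed = True
                break
        if not placed:
            continue  # frame too crowded; place fewer specks
        debris_centers.append(c)
        dd = np.hypot(yy - c[0], xx - c[1])
        spot = dd <= r
        debris_mask |= spot
        tex = rng.normal(config.cell_contrast, config.texture_sigma, size=(H, W))
        debris_image[spot] = tex[spot]

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    pos = [c.copy() for c in centers]
    # coherent intracellular motion: the interior texture of each cell drifts
    # by a sub-pixel random-walk step every frame, so consecutive frames show
    # displaced (not merely resampled) internal structure
    tex_offsets = [np.zeros(2) for _ in cells]
    for t in range(config.n_frames):
        frame = background + t * config.illumination_drift_per_frame + debris_image
        mask = np.zeros((H, W), dtype=bool)
        for i, blob in enumerate(cells):
            inside, tex = blob.support_and_texture((H, W), pos[i], tex_offsets[i])
            refresh = rng.standard_normal((H, W))
            refresh = ndi.gaussian_filter(refresh, 1.0)
            refresh = refresh / max(refresh.std(), 1e-12) * config.internal_noise_sigma
            frame = np.where(inside, background + config.cell_contrast + tex + refresh
                             + t * config.illumination_drift_per_frame, frame)
            mask |= inside
        frame = frame + rng.normal(0.0, config.sensor_noise_sigma, size=(H, W))
        frames.append(np.clip(frame, 0.0, 1.0))
        masks.append(mask)
        # advance centers with reflecting borders; step texture random walk
        for i in range(len(pos)):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            tex_offsets[i] = tex_offsets[i] + config.internal_jitter_px * np.array(
                [np.sin(ang), np.cos(ang)]
            )
            pos[i] = pos[i] + velocities[i]
            for ax, limit in ((0, H - 1), (1, W - 1)):
                if pos[i][ax] < margin:
                    pos[i][ax] = 2 * margin - pos[i][ax]
                    velocities[i][ax] *= -1
                elif pos[i][ax] > limit - margin:
                    pos[i][ax] = 2 * (limit - margin) - pos[i][ax]
                    velocities[i][ax] *= -1

    stack = ImageStack(frames=frames, source_bit_depth=8)
    return SynthMovie(stack=stack, truth_masks=masks, debris_mask=debris_mask, config=config)


def presets() -> dict[str, SynthConfig]:
    """Named study conditions.

    - "default": clear contrast and moderate bulk motion (3 px/frame).
    - "lowcontrast": near-zero intensity contrast and sub-pixel bulk motion,
      so segmentation leans on internal dynamics and the adaptive threshold.
    - "debris": many static specks plus a stronger illumination gradient,
      exercising background labeling and automated size filtering.
    - "drift": the default scene with slow global illumination drift.
    """
    default = SynthConfig()
    return {
        "default": default,
        "lowcontrast": SynthConfig(
            frame_shape=(128, 128),
            n_cells=2,
            cell_radius_range=(12.0, 16.0),
            cell_speed=0.4,
            internal_noise_sigma=0.04,
            texture_sigma=0.06,
            cell_contrast=0.02,
            background_gradient_amplitude=0.06,
            sensor_noise_sigma=0.008,
        ),
        "debris": replace(default, n_debris=15, background_gradient_amplitude=0.12),
        "drift": replace(default, n_frames=6, illumination_drift_per_frame=0.02),
    }
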