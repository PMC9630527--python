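"""Dense Farneback optical flow between consecutive frames.

The displacement field is estimated by locally approximating each frame with
a quadratic polynomial (Farneback polynomial expansion) and solving for the
shift relating the two expansions, coarse-to-fine on a Gaussian image
pyramid.  For two local expansions

    f1(x) ~ x'A1 x + b1'x + c1,   f2(x) ~ x'A2 x + b2'x + c2

related by a pure translation d, the coefficients satisfy
A d = -(b2 - b1)/2 with A = (A1 + A2)/2.  The per-pixel equations are
aggregated over a smoothing window before solving, which regularises the
field, and the estimate is refined iteratively by warping the second frame's
expansion coefficients with the current displacement.

Everything here is deterministic: the same inputs and parameters produce
bit-identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .errors import DimensionError, ParameterError

__all__ = ["FlowParams", "FlowField", "farneback_displacement", "flow_magnitude", "motion_mask"]


@dataclass(frozen=True)
class FlowParams:
    """Parameters of the multi-resolution Farneback estimator.

    Attributes
    ----------
    pyramid_levels : int
        Number of pyramid levels (1 = single scale).
    pyramid_scale : float
        Down-sampling factor between levels, in (0, 1).
    window_size : int
        Odd side length of the box window that aggregates the per-pixel
        displacement equations.
    poly_neighborhood : int
        Side length of the polynomial-expansion window (5 or 7 typical).
    poly_sigma : float
        Gaussian applicability sigma for the polynomial expansion.
    iterations : int
        Displacement refinement passes per pyramid level.
    """

    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    window_size: int = 15
    poly_neighborhood: int = 5
    poly_sigma: float = 1.1
    iterations: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.pyramid_scale < 1.0):
            raise ParameterError(f"pyramid_scale must be in (0,1), got {self.pyramid_scale}")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ParameterError(f"window_size must be odd and >= 3, got {self.window_size}")
        if self.pyramid_levels < 1:
            raise ParameterError("pyramid_levels must be >= 1")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if self.poly_neighborhood < 3:
            raise ParameterError("poly_neighborhood must be >= 3")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FlowParams":
        return cls(**d)


@dataclass
class FlowField:
    """Per-pixel displacement from frame t-1 to frame t.

    ``dx`` is the displacement along image columns (axis 1), ``dy`` along
    rows (axis 0); ``magnitude`` is the elementwise Euclidean norm.
    """

    dx: np.ndarray
    dy: np.ndarray
    magnitude: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise DimensionError("dx and dy must share the frame shape")
        if self.magnitude is None:
            self.magnitude = np.hypot(self.dx, self.dy)


def _poly_expansion(f: np.ndarray, n: int, sigma: float):
    """Per-pixel quadratic expansion f(u) ~ u'A u + b'u + c.

    Weighted least squares with a separable Gaussian applicability over the
    (2n+1)^2 window; reflective border handling.  Returns the symmetric
    quadratic part ``A`` (shape (H, W, 2, 2), row axis first) and linear part
    ``b`` (shape (H, W, 2)).
    """
    t = np.arange(-n, n + 1, dtype=np.float64)
    a = np.exp(-(t**2) / (2.0 * sigma**2))

    # 1-D moments of the applicability; odd moments vanish by symmetry.
    s0 = float(a.sum())
    s2 = float((a * t**2).sum())
    s4 = float((a * t**4).sum())

    # Normal-equation matrix for basis (1, y, x, y^2, x^2, xy); constant
    # across pixels because certainty is uniform.
    G = np.zeros((6, 6))
    G[0, 0] = s0 * s0
    G[1, 1] = s2 * s0
    G[2, 2] = s0 * s2
    G[3, 3] = s4 * s0
    G[4, 4] = s0 * s4
    G[5, 5] = s2 * s2
    G[0, 3] = G[3, 0] = s2 * s0
    G[0, 4] = G[4, 0] = s0 * s2
    G[3, 4] = G[4, 3] = s2 * s2
    Ginv = np.linalg.inv(G)

    def corr(img, ky, kx):
        out = ndi.correlate1d(img, ky, axis=0, mode="reflect")
        return ndi.correlate1d(out, kx, axis=1, mode="reflect")

    a0, a1, a2 = a, a * t, a * t**2
    m = np.stack(
        [
            corr(f, a0, a0),  # 1
            corr(f, a1, a0),  # y
            corr(f, a0, a1),  # x
            corr(f, a2, a0),  # y^2
            corr(f, a0, a2),  # x^2
            corr(f, a1, a1),  # xy
        ],
        axis=-1,
    )
    r = m @ Ginv.T  # (H, W, 6)

    b = r[..., 1:3]  # (by, bx)
    A = np.empty(f.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = 0.5 * r[..., 5]
    return A, b


def _update_flow(A1, b1, A2, b2, d, window_size):
    """One Farneback displacement update given expansions of both frames and
    the current displacement estimate ``d`` (H, W, 2 as (dy, dx))."""
    H, W = b1.shape[:2]
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    coords = np.stack([yy + d[..., 0], xx + d[..., 1]])

    def warp(img):
        return ndi.map_coordinates(img, coords, order=1, mode="nearest")

    A2w = np.stack(
        [warp(A2[..., i, j]) for i in range(2) for j in range(2)], axis=-1
    ).reshape(H, W, 2, 2)
    b2w = np.stack([warp(b2[..., 0]), warp(b2[..., 1])], axis=-1)

    A = 0.5 * (A1 + A2w)
    db = -0.5 * (b2w - b1) + np.einsum("...ij,...j->...i", A, d)

    # Aggregate G = A'A and h = A'db over the window, then solve 2x2 per pixel.
    G00 = A[..., 0, 0] ** 2 + A[..., 0, 1] ** 2
    G01 = A[..., 0, 1] * (A[..., 0, 0] + A[..., 1, 1])
    G11 = A[..., 1, 1] ** 2 + A[..., 0, 1] ** 2
    h0 = A[..., 0, 0] * db[..., 0] + A[..., 0, 1] * db[..., 1]
    h1 = A[..., 0, 1] * db[..., 0] + A[..., 1, 1] * db[..., 1]

    size = window_size
    G00, G01, G11, h0, h1 = (
        ndi.uniform_filter(arr, size=size, mode="reflect") for arr in (G00, G01, G11, h0, h1)
    )

    det = G00 * G11 - G01 * G01
    eps = 1e-9 * (G00 + G11).mean() + 1e-30
    det = det + eps
    dy = (G11 * h0 - G01 * h1) / det
    dx = (G00 * h1 - G01 * h0) / det
    return np.stack([dy, dx], axis=-1)


def _resize(img: np.ndarray, shape) -> np.ndarray:
    """Bilinear resize via map_coordinates (keeps scipy the only dependency)."""
    H, W = img.shape
    h, w = shape
    ys = np.linspace(0, H - 1, h)
    xs = np.linspace(0, W - 1, w)
    coords = np.stack(np.meshgrid(ys, xs, indexing="ij"))
    return ndi.map_coordinates(img, coords, order=1, mode="nearest")


def farneback_displacement(prev: np.ndarray, curr: np.ndarray, params: FlowParams | None = None) -> FlowField:
    """Estimate the dense displacement field from ``prev`` (t-1) to ``curr`` (t).

    Parameters
    ----------
    prev, curr : ndarray
        Same-shaped 2-D grayscale frames (normalized intensities).
    params : FlowParams, optional
        Estimator settings; defaults are the de-facto standard Farneback
        parameters.

    Returns
    -------
    FlowField
        Per-pixel (dx, dy) in pixels and the magnitude field.
    """
    if params is None:
        params = FlowParams()
    prev = np.asarray(prev, dtype=np.float64)
    curr = np.asarray(curr, dtype=np.float64)
    if prev.ndim != 2 or curr.ndim != 2:
        raise DimensionError("frames must be 2-D grayscale arrays")
    if prev.shape != curr.shape:
        raise DimensionError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    if min(prev.shape) < params.window_size:
        raise ParameterError(
            f"frame {prev.shape} smaller than window_size {params.window_size}"
        )

    n = params.poly_neighborhood // 2
    # Gaussian anti-alias smoothing per level; skip levels that would shrink
    # below the analysis windows.
    shapes = []
    for lvl in range(params.pyramid_levels):
        s = params.pyramid_scale**lvl
        shape = (max(int(round(prev.shape[0] * s)), 1), max(int(round(prev.shape[1] * s)), 1))
        if min(shape) < max(2 * n + 1, params.window_size):
            break
        shapes.append(shape)
    if not shapes:
        shapes = [prev.shape]

    d = None
    for shape in reversed(shapes):  # coarse to fine
        if shape == prev.shape:
            p, c = prev, curr
        else:
            sigma = 0.5 / (shape[0] / prev.shape[0])  # anti-alias before decimation
            p = _resize(ndi.gaussian_filter(prev, sigma, mode="reflect"), shape)
            c = _resize(ndi.gaussian_filter(curr, sigma, mode="reflect"), shape)
        A1, b1 = _poly_expansion(p, n, params.poly_sigma)
        A2, b2 = _poly_expansion(c, n, params.poly_sigma)
        if d is None:
            d = np.zeros(shape + (2,))
        else:
            ry = shape[0] / d.shape[0]
            rx = shape[1] / d.shape[1]
            d = np.stack(
                [_resize(d[..., 0], shape) * ry, _resize(d[..., 1], shape) * rx], axis=-1
            )
        for _ in range(params.iterations):
            d = _update_flow(A1, b1, A2, b2, d, params.window_size)

    return FlowField(dx=d[..., 1].copy(), dy=d[..., 0].copy())


def flow_magnitude(flow: FlowField) -> np.ndarray:
    """Elementwise Euclidean norm of the displacement field, in pixels."""
    return np.hypot(flow.dx, flow.dy)


def motion_mask(magnitude: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels whose displacement magnitude exceeds ``threshold``."""
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    return np.asarray(magnitude) > threshold
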