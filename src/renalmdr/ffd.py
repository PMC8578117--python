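"""Free-form deformation (FFD) model with linear (tent) interpolation kernels.

Deformations are parameterised by displacement vectors on a rectangular
control-point lattice with spacing ``Delta`` (pixels per axis); the dense
field at any location is the tent-kernel interpolation of the control-point
vectors. Images are resampled with the same tent kernel between voxel
centres (backward warping: the corrected image samples the source image at
the deformed coordinates).

Conventions: coordinates are voxel-centre, 0-based, in pixel units; the
lattice origin sits at the image corner and the outermost control points lie
on or beyond the opposite corner. Out-of-bounds sampling clamps to the edge,
so large shifts replicate border values instead of injecting zeros.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControlGrid",
    "tent_weight",
    "sample_linear",
    "sample_vector",
    "splat_linear",
    "interpolate_displacement",
    "deform_image",
    "warp",
    "refine_grid",
    "image_gradient",
    "voxel_coordinates",
]


def tent_weight(offset) -> np.ndarray:
    """Separable tent (linear interpolation) weight.

    `offset` is the coordinate offset in units of the grid spacing; for an
    array whose last axis indexes spatial axes, the per-axis weights
    w(u) = max(1 - |u|, 0) are multiplied together. Weights lie in [0, 1]
    and vanish for |u| >= 1 on any axis.
    """
    u = np.asarray(offset, dtype=float)
    w = np.clip(1.0 - np.abs(u), 0.0, None)
    if u.ndim == 0:
        return w
    return np.prod(w, axis=-1)


def voxel_coordinates(shape) -> np.ndarray:
    """Voxel-centre coordinates of an image grid, flattened to (N, d)."""
    axes = [np.arange(n, dtype=float) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def _corner_terms(shape, coords):
    """Base indices, fractions and clamp masks for multilinear sampling.

    Returns (base (d, N) int, frac (d, N), clamped (d, N) bool); coordinates
    are clamped to [0, n-1] per axis and `clamped` marks points outside,
    where the interpolant derivative is zero.
    """
    coords = np.asarray(coords, dtype=float)
    d = coords.shape[-1]
    base = np.empty((d, coords.shape[0]), dtype=np.intp)
    frac = np.empty((d, coords.shape[0]))
    clamped = np.empty((d, coords.shape[0]), dtype=bool)
    for ax in range(d):
        n = shape[ax]
        c = coords[:, ax]
        clamped[ax] = (c < 0) | (c > n - 1)
        cc = np.clip(c, 0.0, float(n - 1))
        b = np.clip(np.floor(cc).astype(np.intp), 0, n - 2)
        base[ax] = b
        frac[ax] = cc - b
    return base, frac, clamped


def sample_linear(field: np.ndarray, coords: np.ndarray, gradient: bool = False):
    """Multilinear (tent-kernel) sampling of a scalar field at fractional
    coordinates with clamp-to-edge extrapolation.

    If `gradient` is True, also returns the *exact* spatial derivative of the
    interpolant at each point (one-sided cell differences, per-axis; zero
    where the coordinate is clamped). This is the derivative consistent with
    the sampling rule, which is what the registration cost differentiates.
    """
    field = np.asarray(field, dtype=float)
    coords = np.asarray(coords, dtype=float)
    d = field.ndim
    N = coords.shape[0]
    base, frac, clamped = _corner_terms(field.shape, coords)
    strides = np.array(
        [int(np.prod(field.shape[ax + 1:], dtype=np.intp)) for ax in range(d)],
        dtype=np.intp)
    flat = field.ravel()
    vals = np.zeros(N)
    grads = np.zeros((N, d)) if gradient else None
    for corner in itertools.product((0, 1), repeat=d):
        idx = np.zeros(N, dtype=np.intp)
        for ax in range(d):
            idx += (base[ax] + corner[ax]) * strides[ax]
        g = flat[idx]
        w_axes = [frac[ax] if corner[ax] else 1.0 - frac[ax] for ax in range(d)]
        w = w_axes[0].copy()
        for ax in range(1, d):
            w *= w_axes[ax]
        vals += w * g
        if gradient:
            for ax in range(d):
                wd = np.ones(N) if corner[ax] else -np.ones(N)
                for other in range(d):
                    if other != ax:
                        wd = wd * w_axes[other]
                grads[:, ax] += wd * g
    if gradient:
        for ax in range(d):
            grads[clamped[ax], ax] = 0.0
        return vals, grads
    return vals


def sample_vector(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Multilinear sampling of a vector field (*spatial, C) -> (N, C)."""
    field = np.asarray(field, dtype=float)
    C = field.shape[-1]
    out = np.empty((coords.shape[0], C))
    for c in range(C):
        out[:, c] = sample_linear(field[..., c], coords)
    return out


def splat_linear(values: np.ndarray, coords: np.ndarray, grid_shape) -> np.ndarray:
    """Adjoint of multilinear sampling: scatter (N, C) values onto a lattice.

    Each point deposits its value onto the 2^d enclosing lattice nodes with
    tent weights; this is the summation over the kernel support used by the
    analytical registration gradient.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != coords.shape[0]:
        values = values.T
    C = values.shape[1]
    d = len(grid_shape)
    base, frac, _ = _corner_terms(grid_shape, coords)
    strides = np.array(
        [int(np.prod(grid_shape[ax + 1:], dtype=np.intp)) for ax in range(d)],
        dtype=np.intp)
    size = int(np.prod(grid_shape, dtype=np.intp))
    out = np.zeros((size, C))
    for corner in itertools.product((0, 1), repeat=d):
        idx = np.zeros(coords.shape[0], dtype=np.intp)
        for ax in range(d):
            idx += (base[ax] + corner[ax]) * strides[ax]
        w_axes = [frac[ax] if corner[ax] else 1.0 - frac[ax] for ax in range(d)]
        w = w_axes[0].copy()
        for ax in range(1, d):
            w *= w_axes[ax]
        for c in range(C):
            out[:, c] += np.bincount(idx, weights=w * values[:, c], minlength=size)
    return out.reshape(*grid_shape, C)


def _n_ctrl(image_shape, spacing) -> tuple:
    """Number of lattice nodes per axis so the lattice covers the image."""
    return tuple(int(np.ceil((n - 1) / s)) + 1 for n, s in zip(image_shape, spacing))


@dataclass
class ControlGrid:
    """FFD control-point lattice with per-frame displacement vectors.

    `spacing` is the lattice spacing in pixels per axis (anisotropic spacing
    is allowed); `disp` holds displacement vectors D_j(t) - x_j with shape
    ``(n_frames, *ctrl_shape, d)`` — all-zero displacements are the identity
    transform, which is the initialisation at the lowest resolution.
    """

    spacing: np.ndarray
    image_shape: tuple
    disp: np.ndarray

    def __post_init__(self):
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        self.image_shape = tuple(int(n) for n in self.image_shape)
        d = len(self.image_shape)
        if self.spacing.size == 1:
            self.spacing = np.full(d, float(self.spacing))
        self.disp = np.asarray(self.disp, dtype=float)
        expect = (self.disp.shape[0],) + _n_ctrl(self.image_shape, self.spacing) + (d,)
        if self.disp.shape != expect:
            raise ValueError(f"disp shape {self.disp.shape} != expected {expect}")

    @classmethod
    def identity(cls, image_shape, n_frames: int, spacing) -> "ControlGrid":
        spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
        if spacing.size == 1:
            spacing = np.full(len(image_shape), float(spacing))
        shape = _n_ctrl(image_shape, spacing)
        disp = np.zeros((n_frames,) + shape + (len(image_shape),))
        return cls(spacing=spacing, image_shape=tuple(image_shape), disp=disp)

    @property
    def ndim(self) -> int:
        return len(self.image_shape)

    @property
    def n_frames(self) -> int:
        return self.disp.shape[0]

    @property
    def ctrl_shape(self) -> tuple:
        return self.disp.shape[1:-1]

    def points(self) -> np.ndarray:
        """Lattice node coordinates, shape (*ctrl_shape, d), pixel units."""
        axes = [np.arange(n) * s for n, s in zip(self.ctrl_shape, self.spacing)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def dense_displacement(self, t: int) -> np.ndarray:
        """Dense displacement field of frame t, shape (*image_shape, d)."""
        vox = voxel_coordinates(self.image_shape)
        u = vox / self.spacing
        out = sample_vector(self.disp[t], u)
        return out.reshape(*self.image_shape, self.ndim)

    def dense_map(self, t: int) -> np.ndarray:
        """Dense coordinate map D(x, t) = x + displacement."""
        vox = voxel_coordinates(self.image_shape).reshape(*self.image_shape, self.ndim)
        return vox + self.dense_displacement(t)

    def copy(self) -> "ControlGrid":
        return ControlGrid(self.spacing.copy(), self.image_shape, self.disp.copy())


def interpolate_displacement(grid: ControlGrid, x, t: int) -> np.ndarray:
    """Deformed coordinate D(x, t) at arbitrary points.

    Exact at control points; points outside the lattice hull are clamped to
    the nearest lattice cell (with a warning), matching the edge rule of the
    dense evaluation.
    """
    x = np.asarray(x, dtype=float)
    pts = np.atleast_2d(x)
    hull = (np.array(grid.ctrl_shape) - 1) * grid.spacing
    if np.any(pts < 0) or np.any(pts > hull):
        warnings.warn("point outside the control lattice hull; clamped",
                      stacklevel=2)
    u = pts / grid.spacing
    disp = sample_vector(grid.disp[t], u)
    out = pts + disp
    return out.reshape(x.shape)


def warp(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Backward-warp: sample `image` at flattened coordinates (N, d),
    returning an array shaped like `image`."""
    vals = sample_linear(image, coords)
    return vals.reshape(image.shape)


def deform_image(image: np.ndarray, grid: ControlGrid, t: int,
                 voxel_dims=None) -> np.ndarray:
    """Apply the FFD of frame t to an image by backward warping.

    Output(x) = image(D(x, t)) with tent-kernel sampling between voxel
    centres and clamp-to-edge outside. `voxel_dims` is accepted for interface
    completeness; deformations operate in pixel units.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    coords = grid.dense_map(t).reshape(-1, grid.ndim)
    return warp(image, coords)


def refine_grid(grid: ControlGrid) -> ControlGrid:
    """Halve the lattice spacing, resampling displacements from the old field.

    Piecewise-linear fields are closed under midpoint refinement: the dense
    deformation field is reproduced exactly. Refuses to refine when the new
    spacing would fall below one pixel.
    """
    new_spacing = grid.spacing / 2.0
    if np.any(new_spacing < 1.0):
        raise ValueError("refusing to refine: spacing would fall below 1 pixel")
    new_shape = _n_ctrl(grid.image_shape, new_spacing)
    axes = [np.arange(n) * s for n, s in zip(new_shape, new_spacing)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    u = pts / grid.spacing
    new_disp = np.empty((grid.n_frames,) + new_shape + (grid.ndim,))
    for t in range(grid.n_frames):
        new_disp[t] = sample_vector(grid.disp[t], u).reshape(*new_shape, grid.ndim)
    return ControlGrid(spacing=new_spacing, image_shape=grid.image_shape,
                       disp=new_disp)


def image_gradient(image: np.ndarray, voxel_dims=None) -> np.ndarray:
    """Spatial image gradient: central differences in the interior, one-sided
    at the borders, stacked on the last axis. Units are intensity per pixel
    unless `voxel_dims` supplies a physical spacing per axis."""
    image = np.asarray(image, dtype=float)
    if any(n < 2 for n in image.shape):
        raise ValueError("need at least 2 voxels per axis")
    if voxel_dims is None:
        grads = np.gradient(image)
    else:
        grads = np.gradient(image, *np.atleast_1d(voxel_dims))
    if image.ndim == 1:
        grads = [grads]
    return np.stack(grads, axis=-1)
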