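"""Model-driven registration (MDR) of dynamic contrast-enhanced series.

MDR removes breathing motion from a dynamic series by alternating two steps
that optimise one joint least-squares cost

    chi^2(D, P) = 1/2 * sum_{x,t} ( S_D(x,t) - Sigma(P(x), t) )^2

(1) at fixed deformations D, fit the tracer-kinetic model pixel-by-pixel to
the deformed series, producing the target stack Sigma; (2) at fixed Sigma,
fit the free-form deformation of each frame by gradient descent with a
back-tracking line search, using the analytical cost gradient over the
control points. The two steps iterate inside a multi-resolution schedule
that starts with a control-grid spacing equal to the field of view and
halves it down to a user-defined minimum.

Because the linearised kinetic model builds its regressors from the deformed
data itself, the registration target moves when the data move (generalised
MDR). The production path adopts the identity approximation for the residual
derivative (frames decouple and are registered independently); the exact
generalised residual is available as a diagnostic
(:func:`generalized_residual`). Two engine details follow from this: the
analytical gradient is the exact derivative of the tent-kernel sampling rule
(so it matches finite differences of the implemented cost to rounding), and
a refitted target is accepted only if it does not increase chi^2, which
keeps the cost trace monotone within every resolution level even though the
moving target voids the textbook guarantee.

Everything is deterministic: identical inputs and configuration give
bit-identical results, and the per-frame registrations are independent of
the order in which frames are processed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import kinetics
from .ffd import (ControlGrid, refine_grid, sample_linear, voxel_coordinates)
from .kinetics import AIF, DynamicSeries

__all__ = [
    "MDRConfig",
    "ModelDrivenRegistration",
    "MDRResults",
    "cost",
    "gradient_control_points",
    "generalized_residual",
    "partial_residual_matrix",
]


@dataclass
class MDRConfig:
    """Configuration of the MDR optimiser.

    grid_spacing_min : minimum control-grid spacing in pixels (scalar or
        per-axis). Documented operating points: 32 for 2D clinical data and
        the digital reference object, 4 for 3D data.
    tolerance : stopping tolerance delta_min in pixels on the largest
        control-point displacement change (0.3 for 2D clinical data, 0.2 for
        the DRO and 3D data).
    n0 : number of pre-contrast frames averaged into the baseline; None
        takes it from the series.
    model : 'linear_2cfm' (production) or 'modified_tofts' (model-bias
        experiments).
    max_line_search_steps : back-tracking trials per descent step.
    max_outer_iterations : cap on model-fit/registration alternations per
        resolution level.
    max_descent_steps : cap on gradient-descent steps per frame per sweep.
    step_expand / step_contract : line-search step multipliers (x2 on
        first-try success, x0.5 on failure); the accepted step preconditions
        the next search.
    frame_order : diagnostic override of the frame processing order (results
        are order-independent).
    """

    grid_spacing_min: float | tuple = 32.0
    tolerance: float = 0.3
    n0: int | None = None
    model: str = "linear_2cfm"
    max_line_search_steps: int = 20
    max_outer_iterations: int = 50
    max_descent_steps: int = 200
    step_expand: float = 2.0
    step_contract: float = 0.5
    frame_order: tuple | None = None

    def __post_init__(self):
        if np.any(np.atleast_1d(self.grid_spacing_min) < 1):
            raise ValueError("grid_spacing_min must be >= 1 pixel")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.model not in ("linear_2cfm", "modified_tofts"):
            raise ValueError(f"unknown model {self.model!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        g = np.atleast_1d(d["grid_spacing_min"])
        d["grid_spacing_min"] = [float(v) for v in g] if g.size > 1 else float(g[0])
        return d


def cost(series_deformed: np.ndarray, target: np.ndarray) -> float:
    """Joint MDR cost chi^2 = 1/2 * sum of squared residuals."""
    a = np.asarray(series_deformed, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between series and target")
    r = a - b
    return 0.5 * float(np.dot(r.ravel(), r.ravel()))


class _LevelOps:
    """Precomputed tent weights linking voxels and the control lattice.

    The weights depend only on the resolution level; both the dense-field
    evaluation (gather) and the gradient accumulation over each kernel
    support (scatter) reuse the same corner indices and weights.
    """

    def __init__(self, image_shape, spacing, ctrl_shape):
        self.image_shape = tuple(image_shape)
        self.ctrl_shape = tuple(ctrl_shape)
        d = len(image_shape)
        self.d = d
        vox = voxel_coordinates(image_shape)
        self.vox = vox
        u = vox / np.asarray(spacing, dtype=float)
        base = np.empty((d, u.shape[0]), dtype=np.intp)
        frac = np.empty((d, u.shape[0]))
        for ax in range(d):
            b = np.clip(np.floor(u[:, ax]).astype(np.intp), 0, ctrl_shape[ax] - 2)
            base[ax] = b
            frac[ax] = u[:, ax] - b
        strides = np.array(
            [int(np.prod(ctrl_shape[ax + 1:], dtype=np.intp)) for ax in range(d)],
            dtype=np.intp)
        self.size = int(np.prod(ctrl_shape, dtype=np.intp))
        self.corners = []
        for corner in itertools.product((0, 1), repeat=d):
            idx = np.zeros(u.shape[0], dtype=np.intp)
            w = np.ones(u.shape[0])
            for ax in range(d):
                idx += (base[ax] + corner[ax]) * strides[ax]
                w = w * (frac[ax] if corner[ax] else 1.0 - frac[ax])
            self.corners.append((idx, w))

    def dense_disp(self, ctrl_disp: np.ndarray) -> np.ndarray:
        """(*ctrl_shape, d) control displacements -> (N, d) dense field."""
        flat = ctrl_disp.reshape(self.size, self.d)
        out = np.zeros((self.vox.shape[0], self.d))
        for idx, w in self.corners:
            out += w[:, None] * flat[idx]
        return out

    def splat(self, q: np.ndarray) -> np.ndarray:
        """(N, d) per-voxel vectors -> (*ctrl_shape, d) kernel-weighted sums."""
        out = np.zeros((self.size, self.d))
        for idx, w in self.corners:
            for c in range(self.d):
                out[:, c] += np.bincount(idx, weights=w * q[:, c],
                                         minlength=self.size)
        return out.reshape(*self.ctrl_shape, self.d)


def gradient_control_points(grid: ControlGrid, residuals: np.ndarray,
                            image: np.ndarray, t: int) -> np.ndarray:
    """Analytical gradient G_j(t) of the frame cost over control points.

    G_j(t) = sum_{x in N_j} W_j(x) * R(x,t) * grad(S)(D(x,t)), where the
    summation runs over the tent-kernel support N_j of each control point and
    the image gradient is the exact derivative of the tent-kernel sampling
    rule evaluated at the deformed coordinates. The product R * grad(S)_D is
    computed once per frame and shared by all control points.
    """
    ops = _LevelOps(grid.image_shape, grid.spacing, grid.ctrl_shape)
    coords = ops.vox + ops.dense_disp(grid.disp[t])
    _, grads = sample_linear(np.asarray(image, dtype=float), coords,
                             gradient=True)
    r = np.asarray(residuals, dtype=float).reshape(-1)
    return ops.splat(r[:, None] * grads)


# ---------------------------------------------------------------------------
# generalised residual (diagnostic)
# ---------------------------------------------------------------------------

def _integration_matrix(K: int) -> np.ndarray:
    """Dimensionless cumulative-trapezoid operator M (dt*M y = running
    integral of y), matching :func:`kinetics.cumulative_integral`."""
    M = np.zeros((K, K))
    for k in range(1, K):
        M[k, 0] = 0.5
        M[k, 1:k] = 1.0
        M[k, k] = 0.5
    return M


def partial_residual_matrix(alpha1: float, alpha2: float, K: int, dt: float,
                            n0: int) -> np.ndarray:
    """Residual derivative dR_{ts} = dR(t)/dS_D(s) at fixed coefficients.

    dR = (I - alpha1*(dt M) - alpha2*(dt M)^2)(I - M0) with M the
    cumulative-trapezoid operator and M0 the baseline-averaging matrix
    (first n0 columns equal 1/n0). Reduces to the identity when the
    coefficients vanish and n0 -> infinity.
    """
    M = dt * _integration_matrix(K)
    M0 = np.zeros((K, K))
    M0[:, :n0] = 1.0 / n0
    I = np.eye(K)
    return (I - alpha1 * M - alpha2 * (M @ M)) @ (I - M0)


def generalized_residual(residuals: np.ndarray, coeffs: kinetics.LinearCoeffs,
                         dt: float, n0: int,
                         identity: bool = False) -> np.ndarray:
    """Generalised residual for the moving-target (groupwise) gradient.

    curly-R(x, s) = sum_t R(x, t) * dR_{ts}(x), i.e. the residual propagated
    through the derivative of the linearised fit with respect to the data.
    With `identity=True` (the approximation adopted in production) the
    residual is returned unchanged. Shipped as a diagnostic of the identity
    approximation, not as an optimiser mode.
    """
    R = np.asarray(residuals, dtype=float)
    if identity:
        return R.copy()
    flat = R.reshape(-1, R.shape[-1])
    K = flat.shape[1]
    a1 = np.asarray(coeffs.alpha1, dtype=float).reshape(-1, 1)
    a2 = np.asarray(coeffs.alpha2, dtype=float).reshape(-1, 1)
    Mm = dt * _integration_matrix(K)
    # dR^T R = (I - M0)^T (I - a1*M - a2*M^2)^T R, applied without
    # materialising per-pixel K x K matrices: row-vector form r M == (M^T r)^T
    z1 = flat @ Mm
    z2 = z1 @ Mm
    w = flat - a1 * z1 - a2 * z2
    # (M0^T w)_t = (sum_s w_s)/n0 for t < n0, 0 otherwise
    out = w.copy()
    out[:, :n0] -= w.sum(axis=1, keepdims=True) / n0
    return out.reshape(R.shape)


# ---------------------------------------------------------------------------
# the Model / Results pair
# ---------------------------------------------------------------------------

class ModelDrivenRegistration:
    """Model-driven registration of a dynamic contrast-enhanced series.

    Parameters
    ----------
    series : DynamicSeries
        The motion-corrupted dynamic series, shape (*spatial, n_frames).
    aif : AIF or array
        Arterial input function; an :class:`AIF` is resampled to the frame
        times, an array is taken as already sampled at them.
    config : MDRConfig, optional

    Examples
    --------
    >>> model = ModelDrivenRegistration(series, aif,
    ...                                 MDRConfig(grid_spacing_min=32,
    ...                                           tolerance=0.2))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, series: DynamicSeries, aif, config: MDRConfig | None = None):
        if not isinstance(series, DynamicSeries):
            raise TypeError("series must be a DynamicSeries")
        self.series = series
        self.config = config if config is not None else MDRConfig()
        if isinstance(aif, AIF):
            self.ca = np.interp(series.frame_times, aif.times, aif.values)
        else:
            self.ca = np.asarray(aif, dtype=float)
            if self.ca.shape != (series.n_frames,):
                raise ValueError("AIF array must be sampled at the frame times")
        self.n0 = self.config.n0 if self.config.n0 is not None else series.n0
        if not (1 <= self.n0 < series.n_frames):
            raise ValueError("n0 out of range")

    # -- model-fit step ----------------------------------------------------
    def _fit_model(self, sd_flat: np.ndarray):
        """Fit the configured kinetic model to the deformed series.

        Returns (sigma (N, K), info dict). Aborts if more than half of the
        pixels fail the solve (flat pixels are not failures).
        """
        dt = self.series.frame_dt
        if self.config.model == "linear_2cfm":
            coeffs, sigma = kinetics.fit_linear_pixels(sd_flat, self.ca, dt,
                                                       self.n0)
            failed_frac = float(np.mean(coeffs.failed))
            info = {"coeffs": coeffs}
        else:
            maps, sigma = kinetics.fit_tofts_pixels(sd_flat, self.ca, dt,
                                                    self.n0)
            failed_frac = float(np.mean(maps.failed))
            info = {"tofts": maps}
        if failed_frac > 0.5:
            raise RuntimeError(
                f"model fit failed on {failed_frac:.0%} of pixels; "
                "check the input series and AIF")
        return sigma, info

    # -- deformation step --------------------------------------------------
    def _fit_deformation_frame(self, frame: np.ndarray, target_flat: np.ndarray,
                               grid: ControlGrid, t: int, ops: _LevelOps,
                               steps: np.ndarray) -> float:
        """Register one frame against its frozen target.

        Gradient descent with back-tracking line search; updates are accepted
        only on strict cost decrease, so the per-frame cost is monotone. The
        descent stops once an accepted step changes no control point by more
        than the tolerance. Returns the largest accepted-step displacement
        change (pixels) produced during the sweep, which drives the outer
        (level) stopping rule.
        """
        cfg = self.config
        disp = grid.disp[t]
        h = steps[t]
        max_change = 0.0
        for _ in range(cfg.max_descent_steps):
            coords = ops.vox + ops.dense_disp(disp)
            vals, grads = sample_linear(frame, coords, gradient=True)
            r = vals - target_flat
            c0 = 0.5 * float(np.dot(r, r))
            G = ops.splat(r[:, None] * grads)
            gmax = float(np.max(np.linalg.norm(G.reshape(-1, ops.d), axis=1)))
            if gmax == 0.0:
                break
            if not np.isfinite(h) or h <= 0:
                h = 1.0 / gmax  # first trial moves the worst point ~1 px
            # trust-region cap: one update moves no control point further
            # than 10x the tolerance, so the deformations co-evolve with the
            # (moving) target instead of jumping across cost-landscape lobes
            h = min(h, 10.0 * cfg.tolerance / gmax)
            # back-tracking line search, initialised at the previously
            # accepted step; expand x2 for the next search on a first-try
            # success, contract x0.5 on failure
            accepted = False
            first_try = True
            for _ in range(cfg.max_line_search_steps):
                cv = ops.vox + ops.dense_disp(disp - h * G)
                rv = sample_linear(frame, cv) - target_flat
                c1 = 0.5 * float(np.dot(rv, rv))
                if c1 < c0:
                    accepted = True
                    break
                h *= cfg.step_contract
                first_try = False
            if not accepted:
                break  # line search exhausted: frame declared converged
            disp -= h * G
            change = h * gmax
            max_change = max(max_change, change)
            steps[t] = h * cfg.step_expand if first_try else h
            h = steps[t]
            # converged only when the step is curvature-limited (the search
            # had to back-track) and still below tolerance; a small step in
            # the expanding phase keeps doubling instead of stopping early
            if change < cfg.tolerance and not first_try:
                break
        return max_change

    # -- the multi-resolution schedule -------------------------------------
    def _level_spacings(self):
        sp = np.array(self.series.spatial_shape, dtype=float)
        gmin = np.atleast_1d(np.asarray(self.config.grid_spacing_min, dtype=float))
        if gmin.size == 1:
            gmin = np.full(sp.size, float(gmin[0]))
        out = [sp.copy()]
        s = sp.copy()
        while np.all(s / 2 >= gmin):
            s = s / 2
            out.append(s.copy())
        return out

    def fit(self, verbose: bool = False) -> "MDRResults":
        """Run the alternating multi-resolution optimisation."""
        cfg = self.config
        series = self.series
        S = series.data
        spatial = series.spatial_shape
        K = series.n_frames
        frames = [np.ascontiguousarray(S[..., t]) for t in range(K)]
        spacings = self._level_spacings()
        grid = ControlGrid.identity(spatial, K, spacings[0])
        trace = []
        grids = []
        target = None
        info = None
        chi2_cur = np.inf

        frame_order = (cfg.frame_order if cfg.frame_order is not None
                       else range(K))

        for li, spacing in enumerate(spacings):
            if li > 0:
                grid = refine_grid(grid)
            ops = _LevelOps(spatial, spacing, grid.ctrl_shape)
            steps = np.full(K, np.nan)  # per-frame line-search preconditioner
            target = None  # refit at the start of every level
            chi2_cur = np.inf
            for it in range(cfg.max_outer_iterations):
                sd = self._warp_all(frames, grid, ops)
                sigma, new_info = self._fit_model(sd)
                chi2_fit = cost(sd, sigma)
                reverted = False
                if chi2_fit <= chi2_cur or target is None:
                    target = sigma
                    info = new_info
                    chi2_cur = chi2_fit
                else:
                    reverted = True  # moving-target refit rejected
                trace.append(dict(level=li, spacing=float(np.max(spacing)),
                                  iteration=it, step="model", chi2=chi2_cur,
                                  max_change=np.nan, reverted=reverted))
                max_change = 0.0
                for t in frame_order:
                    mc = self._fit_deformation_frame(
                        frames[t], target[:, t], grid, t, ops, steps)
                    max_change = max(max_change, mc)
                sd = self._warp_all(frames, grid, ops)
                chi2_cur = cost(sd, target)
                trace.append(dict(level=li, spacing=float(np.max(spacing)),
                                  iteration=it, step="deform", chi2=chi2_cur,
                                  max_change=max_change, reverted=False))
                if verbose:
                    print(f"level {li} (spacing {np.max(spacing):.1f} px) "
                          f"iter {it}: chi2={chi2_cur:.6g} "
                          f"max_change={max_change:.3f} px")
                if max_change <= cfg.tolerance:
                    break
            grids.append(grid.copy())

        # final guarded model fit for the output maps
        sd = self._warp_all(frames, grid,
                            _LevelOps(spatial, grid.spacing, grid.ctrl_shape))
        sigma, new_info = self._fit_model(sd)
        chi2_fit = cost(sd, sigma)
        if chi2_fit <= chi2_cur:
            target, info, chi2_cur = sigma, new_info, chi2_fit
        trace.append(dict(level=len(spacings) - 1,
                          spacing=float(np.max(grid.spacing)),
                          iteration=-1, step="final", chi2=chi2_cur,
                          max_change=np.nan, reverted=chi2_fit > chi2_cur))

        corrected = DynamicSeries(
            sd.reshape(*spatial, K), voxel_dims=series.voxel_dims,
            frame_times=series.frame_times, n0=series.n0)
        return MDRResults(model=self, corrected=corrected,
                          target=target.reshape(*spatial, K),
                          grid=grid, grids=grids, fit_info=info,
                          cost_trace=pd.DataFrame(trace))

    def _warp_all(self, frames, grid: ControlGrid, ops: _LevelOps) -> np.ndarray:
        """Deform every frame with its current field; (N, K) output.

        With all-zero displacements this is exactly the input series (the
        identity-initialisation invariant)."""
        K = len(frames)
        out = np.empty((ops.vox.shape[0], K))
        for t in range(K):
            disp = grid.disp[t]
            if not disp.any():
                out[:, t] = frames[t].ravel()
                continue
            coords = ops.vox + ops.dense_disp(disp)
            out[:, t] = sample_linear(frames[t], coords)
        return out


class MDRResults:
    """Results of a model-driven registration fit.

    Attributes
    ----------
    corrected : DynamicSeries
        Motion-corrected series S_D.
    target : ndarray
        Fitted model stack Sigma, same shape as the input data.
    grid / grids : ControlGrid
        Final control grid and the per-resolution-level grids.
    coeffs : LinearCoeffs (linear_2cfm model)
    params : dict of parameter maps in physiological units; invalid pixels
        carry 0 with the validity recorded in ``params_valid``.
    cost_trace : DataFrame with (level, spacing, iteration, step, chi2,
        max_change, reverted) per accepted update.
    """

    def __init__(self, model, corrected, target, grid, grids, fit_info,
                 cost_trace):
        self.model = model
        self.corrected = corrected
        self.target = target
        self.grid = grid
        self.grids = grids
        self.cost_trace = cost_trace
        spatial = corrected.spatial_shape
        self.coeffs = None
        if "coeffs" in fit_info:
            c = fit_info["coeffs"]
            self.coeffs = kinetics.LinearCoeffs(
                alpha1=c.alpha1.reshape(spatial),
                alpha2=c.alpha2.reshape(spatial),
                beta1=c.beta1.reshape(spatial),
                beta2=c.beta2.reshape(spatial),
                S0=c.S0.reshape(spatial),
                flat=c.flat.reshape(spatial),
                failed=c.failed.reshape(spatial))
            pm = kinetics.coeffs_to_params(self.coeffs)
            self.params = pm.as_dict(fill_invalid=0.0)
            self.params["S0"] = np.array(self.coeffs.S0)
            self.params_valid = pm.valid
        else:
            tof = fit_info["tofts"]
            self.params = {k: v.reshape(spatial)
                           for k, v in tof.as_dict().items()}
            self.params_valid = ~tof.failed.reshape(spatial)

    @property
    def chi2(self) -> float:
        return float(self.cost_trace["chi2"].iloc[-1])

    def deformation_fields(self) -> np.ndarray:
        """Dense displacement fields, shape (n_frames, *spatial, d)."""
        g = self.grid
        return np.stack([g.dense_displacement(t) for t in range(g.n_frames)])

    def mean_displacement(self, frames=None) -> float:
        """Mean |D(x,t) - x| over voxels (and the selected frames), pixels."""
        fields = self.deformation_fields()
        if frames is not None:
            fields = fields[np.asarray(frames)]
        return float(np.mean(np.linalg.norm(fields, axis=-1)))

    def summary(self) -> str:
        s = self.model.series
        cfg = self.model.config
        lines = [
            "Model-Driven Registration Results",
            "=" * 48,
            f"Kinetic model:        {cfg.model}",
            f"Image size:           {s.spatial_shape}, {s.n_frames} frames",
            f"Frame interval:       {s.frame_dt:.3f} s (n0 = {self.model.n0})",
            f"Grid spacing min:     {cfg.grid_spacing_min} px",
            f"Tolerance:            {cfg.tolerance} px",
            f"Resolution levels:    {len(self.grids)}",
            f"Final chi^2:          {self.chi2:.6g}",
            f"Mean |displacement|:  {self.mean_displacement():.3f} px",
            "-" * 48,
            "level  spacing  iterations  final chi^2",
        ]
        tr = self.cost_trace
        for li, sub in tr[tr.step == "deform"].groupby("level"):
            lines.append(f"{li:5d}  {sub.spacing.iloc[0]:7.1f}  "
                         f"{len(sub):10d}  {sub.chi2.iloc[-1]:12.6g}")
        lines.append("-" * 48)
        for name, m in self.params.items():
            vals = m[np.isfinite(m)]
            lines.append(f"{name:>6s}: median {np.median(vals):10.4g}  "
                         f"max {vals.max():10.4g}")
        return "\n".join(lines)

    def plot_cost(self, ax=None):
        """Cost trace chi^2 per accepted update, one line per level."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for li, sub in self.cost_trace.groupby("level"):
            ax.plot(np.arange(len(sub)), sub["chi2"].values, label=f"level {li}")
        ax.set_xlabel("accepted update")
        ax.set_ylabel(r"$\chi^2$")
        ax.set_yscale("log")
        ax.legend()
        return ax
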