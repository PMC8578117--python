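"""Tracer-kinetic signal models for dynamic contrast-enhanced MR renography.

The signal is assumed linear in tissue concentration, ``S(x,t) = S0(x) + C(x,t)``,
with the relaxivity calibration absorbed into the amplitude parameters so that
concentrations are carried in signal units. Tissue concentration follows a
two-compartment filtration model (2CFM): a plasma compartment with mean transit
time ``TP`` fed by the arterial input at plasma flow ``FP``, draining into a
tubular compartment with mean transit time ``TT`` at tubular flow ``FT``. The
impulse response is a bi-exponential, so ``C`` is a bi-exponential convolved
with the arterial input function (AIF).

Fitting uses the *linearised* form of the 2CFM: the baseline-subtracted signal
is regressed on its own running time-integrals and those of the AIF,

    y(t) = a1 * I[y](t) + a2 * II[y](t) + b1 * I[ca](t) + b2 * II[ca](t)

where ``I`` and ``II`` denote single and double cumulative integration. This
avoids non-linear optimisation and initial values entirely; the physiological
parameters are recovered in closed form from the regression coefficients
(:func:`coeffs_to_params`). A simplified 3-parameter modified Tofts model is
also provided for model-bias experiments.

Flows are carried in mL/min/100mL externally and converted to 1/s internally
(divide by 6000); transit times are in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.signal import fftconvolve

__all__ = [
    "FLOW_PER_SEC",
    "AIF",
    "DynamicSeries",
    "KineticParams2CFM",
    "LinearCoeffs",
    "ParamMaps2CFM",
    "ToftsParamMaps",
    "cumulative_integral",
    "simulate_concentration_2cfm",
    "simulate_concentration_2cfm_ode",
    "concentration_to_signal",
    "signal_to_concentration",
    "params_to_coeffs",
    "coeffs_to_params",
    "epsilons",
    "fit_linear_2cfm",
    "fit_modified_tofts",
    "simulate_concentration_tofts",
]

#: conversion factor mL/min/100mL -> 1/s
FLOW_PER_SEC = 1.0 / 6000.0

_UNIFORM_RTOL = 1e-6


def _check_uniform(times: np.ndarray) -> float:
    """Return the (uniform) spacing of `times`, or raise on invalid sampling."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two time points")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=_UNIFORM_RTOL, atol=0):
        raise ValueError("invalid sampling: time spacing is not uniform")
    return float(dt[0])


@dataclass
class AIF:
    """Arterial input function sampled on a uniform time grid.

    Parameters
    ----------
    times : array
        Sample times in seconds, strictly increasing with constant spacing.
    values : array
        Arterial concentration in arbitrary (signal) units; finite, >= 0.
    baseline_duration : float
        Duration in seconds of the pre-contrast baseline over which the
        concentration is zero.
    """

    times: np.ndarray
    values: np.ndarray
    baseline_duration: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        self._dt = _check_uniform(self.times)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AIF values must be finite")
        if np.any(self.values < 0):
            raise ValueError("AIF values must be non-negative")
        base = self.times < self.baseline_duration - 1e-9
        tol = 1e-9 * max(1.0, float(np.max(self.values, initial=0.0)))
        if np.any(np.abs(self.values[base]) > tol):
            warnings.warn(
                "AIF values are not zero over the declared baseline",
                stacklevel=2,
            )

    @property
    def dt(self) -> float:
        return self._dt

    def resample(self, new_times: np.ndarray) -> "AIF":
        """Linear resampling onto a new uniform grid."""
        new_times = np.asarray(new_times, dtype=float)
        vals = np.interp(new_times, self.times, self.values)
        return AIF(new_times, vals, self.baseline_duration)

    def downsample(self, factor: int) -> "AIF":
        """Block-average consecutive samples.

        Frame k averages fine samples [k*factor, (k+1)*factor) and is stamped
        with the centre time of that window, matching the dynamic-series
        down-sampling convention.
        """
        factor = int(factor)
        n = self.values.size // factor
        vals = self.values[: n * factor].reshape(n, factor).mean(axis=1)
        times = self.times[: n * factor].reshape(n, factor).mean(axis=1)
        n_zero = int(np.argmax(vals > 0)) if np.any(vals > 0) else n
        new_dt = factor * self.dt
        return AIF(times, vals, baseline_duration=n_zero * new_dt)


@dataclass
class DynamicSeries:
    """A 2D or 3D image stack over acquisition times.

    `data` has shape ``(*spatial, n_frames)``; `voxel_dims` are in mm per
    spatial axis; `frame_times` are the (uniformly spaced) acquisition
    mid-point times in seconds; `n0` counts the pre-contrast frames used for
    baseline estimation.
    """

    data: np.ndarray
    voxel_dims: np.ndarray | None = None
    frame_times: np.ndarray | None = None
    n0: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 3:
            raise ValueError("data must have at least 2 spatial axes + time")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 frames")
        if any(n < 2 for n in self.data.shape[:-1]):
            raise ValueError("each spatial axis must have at least 2 voxels")
        if self.voxel_dims is None:
            self.voxel_dims = np.ones(self.data.ndim - 1)
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.voxel_dims.size != self.data.ndim - 1:
            raise ValueError("voxel_dims must have one entry per spatial axis")
        if self.frame_times is None:
            self.frame_times = np.arange(self.data.shape[-1], dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size != self.data.shape[-1]:
            raise ValueError("frame_times must have one entry per frame")
        self._dt = _check_uniform(self.frame_times)
        if not (1 <= self.n0 < self.data.shape[-1]):
            raise ValueError("n0 must satisfy 1 <= n0 < n_frames")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:-1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def frame_dt(self) -> float:
        return self._dt


@dataclass
class KineticParams2CFM:
    """Two-compartment filtration model parameters.

    FP : plasma flow (mL/min/100mL); TP : plasma mean transit time (s);
    FT : tubular flow (mL/min/100mL); TT : tubular mean transit time (s).
    """

    FP: float
    TP: float
    FT: float
    TT: float

    def __post_init__(self):
        for name in ("FP", "TP", "FT", "TT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.TP >= self.TT > 0:
            warnings.warn(
                "TP >= TT: not kidney-like (plasma transit should be faster "
                "than tubular transit)",
                stacklevel=2,
            )


@dataclass
class LinearCoeffs:
    """Per-pixel coefficients of the linearised 2CFM.

    alpha1/alpha2 multiply the single/double integrals of the
    baseline-subtracted signal; beta1/beta2 the single/double integrals of the
    AIF; S0 is the pre-contrast signal. `flat` flags pixels with no signal
    variation, `failed` flags rank-deficient (non-flat) solves; both are
    returned with zero coefficients so whole-image fitting never aborts.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    S0: np.ndarray
    flat: np.ndarray = field(default=None)
    failed: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.flat is None:
            self.flat = np.zeros(np.shape(self.alpha1), dtype=bool)
        if self.failed is None:
            self.failed = np.zeros(np.shape(self.alpha1), dtype=bool)


@dataclass
class ParamMaps2CFM:
    """Recovered 2CFM parameter maps with validity flags.

    Pixels whose coefficient quadratic has complex or non-positive roots are
    flagged invalid (NaN in the maps); `single_compartment` marks the
    one-compartment limit where only one transit time exists (TT is NaN).
    """

    FP: np.ndarray
    TP: np.ndarray
    FT: np.ndarray
    TT: np.ndarray
    valid: np.ndarray
    single_compartment: np.ndarray

    def as_dict(self, fill_invalid: float | None = None) -> dict:
        out = {}
        for name in ("FP", "TP", "FT", "TT"):
            m = np.array(getattr(self, name), dtype=float, copy=True)
            if fill_invalid is not None:
                m[~np.isfinite(m)] = fill_invalid
            out[name] = m
        return out


@dataclass
class ToftsParamMaps:
    """Modified Tofts parameters: vp (plasma volume fraction), Ktrans (1/s),
    kep (1/s), plus a failure flag (flagged pixels carry zeros)."""

    vp: np.ndarray
    ktrans: np.ndarray
    kep: np.ndarray
    failed: np.ndarray

    def as_dict(self) -> dict:
        return {"vp": np.asarray(self.vp), "Ktrans": np.asarray(self.ktrans),
                "kep": np.asarray(self.kep)}


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def cumulative_integral(series, dt, order=1, times=None, axis=-1):
    """Running trapezoid integral (order 1) or its running integral (order 2).

    The quadrature rule is the cumulative trapezoid with ``out[0] = 0``; the
    identical rule is used in model fitting and in the generalised-residual
    diagnostic. `times`, if given, is validated for uniform spacing `dt`.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if times is not None:
        dt_obs = _check_uniform(times)
        if not np.isclose(dt_obs, dt, rtol=_UNIFORM_RTOL):
            raise ValueError("invalid sampling: times do not match dt")
    y = np.asarray(series, dtype=float)
    out = cumulative_trapezoid(y, dx=dt, axis=axis, initial=0.0)
    if order == 2:
        out = cumulative_trapezoid(out, dx=dt, axis=axis, initial=0.0)
    return out


def _biexp_amplitudes(params: KineticParams2CFM):
    """Bi-exponential impulse-response amplitudes of the 2CFM (1/s units)."""
    fp = params.FP * FLOW_PER_SEC
    ft = params.FT * FLOW_PER_SEC
    tp, tt = params.TP, params.TT
    if tp <= 0 or tt <= 0:
        raise ValueError("TP and TT must be positive")
    return fp, ft, tp, tt


def simulate_concentration_2cfm(params: KineticParams2CFM, aif: AIF,
                                dt: float | None = None) -> np.ndarray:
    """Forward 2CFM concentration by bi-exponential convolution with the AIF.

    The impulse response is H(t) = A1 exp(-t/TP) + A2 exp(-t/TT) with
    A2 = FT*TT/(TT-TP), A1 = FP - A2 (confluent limit handled); the
    convolution uses trapezoid weights, second-order accurate in dt.
    Returns C on the AIF grid (or on a grid with spacing `dt` if given).
    """
    if dt is not None and not np.isclose(dt, aif.dt, rtol=_UNIFORM_RTOL):
        grid = np.arange(aif.times[0], aif.times[-1] + dt / 2, dt)
        aif = aif.resample(grid)
    fp, ft, tp, tt = _biexp_amplitudes(params)
    h = aif.dt
    t = aif.times - aif.times[0]
    if abs(tt - tp) > 1e-9 * max(tt, tp):
        a2 = ft * tt / (tt - tp)
        a1 = fp - a2
        H = a1 * np.exp(-t / tp) + a2 * np.exp(-t / tt)
    else:  # confluent (equal transit times) limit
        H = (fp + ft * t / tp) * np.exp(-t / tp)
    ca = aif.values
    full = fftconvolve(H, ca)[: t.size]
    C = h * (full - 0.5 * (H[0] * ca + H * ca[0]))
    C[0] = 0.0
    return C


def simulate_concentration_2cfm_ode(params: KineticParams2CFM, aif: AIF,
                                    dt: float | None = None) -> np.ndarray:
    """Forward 2CFM concentration by stiff-safe ODE integration.

    Independent of the convolution route; used as a cross-check. Solves
    cp' = FP*ca - cp/TP,  ct' = (FT/(FP*TP))*cp*... expressed with tubular
    inflow FT * (plasma concentration) where plasma concentration is
    cp/(FP*TP); C = cp + ct.
    """
    if dt is not None and not np.isclose(dt, aif.dt, rtol=_UNIFORM_RTOL):
        grid = np.arange(aif.times[0], aif.times[-1] + dt / 2, dt)
        aif = aif.resample(grid)
    fp, ft, tp, tt = _biexp_amplitudes(params)
    times, ca = aif.times, aif.values

    def rhs(t, y):
        cat = np.interp(t, times, ca)
        cp, ct = y
        dcp = fp * cat - cp / tp
        dct = (ft / (fp * tp)) * cp - ct / tt if fp > 0 else -ct / tt
        return [dcp, dct]

    # max_step bounds the solver so it cannot leap over a narrow bolus
    sol = solve_ivp(rhs, (times[0], times[-1]), [0.0, 0.0], t_eval=times,
                    method="LSODA", rtol=1e-9, atol=1e-13,
                    max_step=max(10 * aif.dt, (times[-1] - times[0]) / 1000))
    return sol.y[0] + sol.y[1]


def concentration_to_signal(S0, conc) -> np.ndarray:
    """S = S0 + C elementwise (calibration absorbed into the amplitudes)."""
    S0 = np.asarray(S0, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if S0.ndim > 0 and S0.shape == conc.shape[:-1]:
        S0 = S0[..., None]
    try:
        return S0 + conc
    except ValueError as err:
        raise ValueError(f"shape mismatch: {S0.shape} vs {conc.shape}") from err


def signal_to_concentration(S, S0) -> np.ndarray:
    """Inverse of :func:`concentration_to_signal`."""
    S = np.asarray(S, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    if S0.ndim > 0 and S0.shape == S.shape[:-1]:
        S0 = S0[..., None]
    return S - S0


# ---------------------------------------------------------------------------
# coefficient <-> parameter mapping
# ---------------------------------------------------------------------------

def params_to_coeffs(params: KineticParams2CFM):
    """Closed-form linear coefficients implied by (FP, TP, FT, TT).

    With rates a = 1/TP, b = 1/TT (a > b for kidney-like tissue):
    alpha1 = -(a+b), alpha2 = -a*b, beta1 = FP [1/s], beta2 = FP*b + FT*a.
    """
    fp, ft, tp, tt = _biexp_amplitudes(params)
    a, b = 1.0 / tp, 1.0 / tt
    return -(a + b), -(a * b), fp, fp * b + ft * a


def coeffs_to_params(coeffs: LinearCoeffs, dt: float | None = None) -> ParamMaps2CFM:
    """Recover (FP, TP, FT, TT) from linearised-model coefficients.

    The transit-time rates are the roots of z^2 + alpha1*z - alpha2 = 0; the
    larger root is 1/TP (plasma transit faster than tubular). Complex or
    non-positive roots are flagged invalid and returned as NaN rather than
    raising. The `dt` argument is accepted for interface symmetry with the
    generalised-residual diagnostic (see :func:`epsilons`) and does not enter
    the recovery.
    """
    a1 = np.asarray(coeffs.alpha1, dtype=float)
    a2 = np.asarray(coeffs.alpha2, dtype=float)
    b1 = np.asarray(coeffs.beta1, dtype=float)
    b2 = np.asarray(coeffs.beta2, dtype=float)
    scalar = a1.ndim == 0
    a1, a2, b1, b2 = np.atleast_1d(a1, a2, b1, b2)

    disc = a1 * a1 + 4.0 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.maximum(disc, 0.0))
        ra = 0.5 * (-a1 + sq)   # larger rate = 1/TP
        rb = 0.5 * (-a1 - sq)   # smaller rate = 1/TT

        scale = np.maximum(np.abs(a1), 1e-300)
        single = (np.abs(a2) <= 1e-12 * scale**2) & (np.abs(b2) <= 1e-12 * np.abs(b1) * scale + 1e-300)
        valid = (disc >= 0) & (ra > 0) & ((rb > 0) | single)

        TP = np.where(ra > 0, 1.0 / ra, np.nan)
        TT = np.where(rb > 0, 1.0 / rb, np.nan)
        FP = b1 / FLOW_PER_SEC
        FT = np.where(ra > 0, (b2 - b1 * rb) / ra, np.nan) / FLOW_PER_SEC

        TT = np.where(single, np.nan, TT)
        FT = np.where(single, 0.0, FT)

        for arr in (FP, TP, FT, TT):
            arr[~valid] = np.nan
    if scalar:
        FP, TP, FT, TT = (x[0] for x in (FP, TP, FT, TT))
        valid, single = valid[0], single[0]
    return ParamMaps2CFM(FP=FP, TP=TP, FT=FT, TT=TT, valid=valid,
                         single_compartment=single)


def epsilons(coeffs: LinearCoeffs, dt: float):
    """Small quantities eps1 = dt/T1 + dt/T2 and eps2 = dt/sqrt(T1*T2).

    Computed directly from the coefficients: eps1 = -alpha1*dt,
    eps2 = sqrt(-alpha2)*dt. Both are << 1 whenever the frame spacing is much
    shorter than the transit times.
    """
    a1 = np.asarray(coeffs.alpha1, dtype=float)
    a2 = np.asarray(coeffs.alpha2, dtype=float)
    return -a1 * dt, np.sqrt(np.maximum(-a2, 0.0)) * dt


# ---------------------------------------------------------------------------
# per-pixel fitting
# ---------------------------------------------------------------------------

def _series_inputs(series, aif, n0):
    """Normalise (series, aif, n0) into (data2d, spatial_shape, ca, dt, n0)."""
    if isinstance(series, DynamicSeries):
        data = series.data
        dt = series.frame_dt
        if n0 is None:
            n0 = series.n0
        if isinstance(aif, AIF):
            ca = np.interp(series.frame_times, aif.times, aif.values)
        else:
            ca = np.asarray(aif, dtype=float)
    else:
        raise TypeError("series must be a DynamicSeries; use fit_linear_pixels "
                        "for raw arrays")
    spatial = data.shape[:-1]
    return data.reshape(-1, data.shape[-1]), spatial, ca, dt, int(n0)


def fit_linear_pixels(data: np.ndarray, ca: np.ndarray, dt: float, n0: int):
    """Vectorised OLS of the linearised 2CFM over pixels.

    Parameters: `data` (n_pixels, n_frames), `ca` AIF at frame times, `dt`
    frame spacing, `n0` baseline frames averaged into S0. Returns
    (LinearCoeffs with flat arrays, fitted stack Sigma of the same shape).
    Degenerate pixels (flat signal or rank-deficient regressors) get zero
    coefficients and Sigma = S0.
    """
    data = np.asarray(data, dtype=float)
    npx, K = data.shape
    if K < 5:
        raise ValueError("need at least 5 frames (4 regressors + baseline)")
    if not (1 <= n0 < K):
        raise ValueError("n0 must satisfy 1 <= n0 < n_frames")
    S0 = data[:, :n0].mean(axis=1)
    y = data - S0[:, None]
    ca = np.asarray(ca, dtype=float)

    I1y = cumulative_integral(y, dt, 1)
    I2y = cumulative_integral(I1y, dt, 1)
    I1a = cumulative_integral(ca, dt, 1)
    I2a = cumulative_integral(I1a, dt, 1)

    X = np.empty((npx, K, 4))
    X[:, :, 0] = I1y
    X[:, :, 1] = I2y
    X[:, :, 2] = I1a
    X[:, :, 3] = I2a

    scale = np.max(np.abs(y), axis=1)
    flat = scale <= 1e-12 * np.maximum(1.0, np.abs(S0))

    G = np.einsum("nki,nkj->nij", X, X)
    bv = np.einsum("nki,nk->ni", X, y)
    d = np.sqrt(np.einsum("nii->ni", G))
    d[d == 0] = 1.0
    Gs = G / (d[:, :, None] * d[:, None, :])
    bs = bv / d

    ev = np.linalg.eigvalsh(Gs)
    degenerate = ev[:, 0] < 1e-10 * np.maximum(ev[:, -1], 1e-300)
    solvable = ~(flat | degenerate)

    coef = np.zeros((npx, 4))
    if np.any(solvable):
        coef[solvable] = (np.linalg.solve(Gs[solvable], bs[solvable][..., None])
                          [..., 0] / d[solvable])
    bad = ~np.all(np.isfinite(coef), axis=1)
    coef[bad] = 0.0
    failed = (degenerate & ~flat) | bad

    sigma = S0[:, None] + np.einsum("nki,ni->nk", X, coef)
    coeffs = LinearCoeffs(alpha1=coef[:, 0], alpha2=coef[:, 1],
                          beta1=coef[:, 2], beta2=coef[:, 3], S0=S0,
                          flat=flat, failed=failed)
    return coeffs, sigma


def fit_linear_2cfm(series: DynamicSeries, aif, n0: int | None = None):
    """Pixel-by-pixel linear least-squares fit of the 2CFM.

    Returns ``(LinearCoeffs, sigma)`` where `sigma` is the model-predicted
    series (the MDR registration target), shaped like ``series.data``. The
    AIF may be an :class:`AIF` (resampled to frame times) or an array already
    sampled at the frame times.
    """
    data2d, spatial, ca, dt, n0 = _series_inputs(series, aif, n0)
    coeffs, sigma = fit_linear_pixels(data2d, ca, dt, n0)
    reshape = lambda a: a.reshape(spatial)
    coeffs = LinearCoeffs(
        alpha1=reshape(coeffs.alpha1), alpha2=reshape(coeffs.alpha2),
        beta1=reshape(coeffs.beta1), beta2=reshape(coeffs.beta2),
        S0=reshape(coeffs.S0), flat=reshape(coeffs.flat),
        failed=reshape(coeffs.failed))
    return coeffs, sigma.reshape(*spatial, -1)


# ---------------------------------------------------------------------------
# modified Tofts
# ---------------------------------------------------------------------------

def _exp_convolve(ca: np.ndarray, kep, dt: float) -> np.ndarray:
    """exp(-kep*t) (*) ca on a uniform grid, exact for piecewise-linear ca.

    `kep` may be a scalar, a (m,) grid (returns (m, K)) or a per-pixel array.
    kep = 0 degenerates to the running integral of ca.
    """
    ca = np.asarray(ca, dtype=float)
    kep = np.atleast_1d(np.asarray(kep, dtype=float))
    K = ca.size
    E = np.exp(-kep * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(kep > 0, (1.0 - E) / kep, dt)
        B = np.where(kep > 0, dt / kep - (1.0 - E) / kep**2, dt**2 / 2)
    out = np.zeros(kep.shape + (K,))
    for n in range(1, K):
        out[..., n] = (E * out[..., n - 1] + ca[n - 1] * A
                       + (ca[n] - ca[n - 1]) / dt * B)
    return out


def simulate_concentration_tofts(vp, ktrans, kep, aif: AIF) -> np.ndarray:
    """Modified Tofts forward model C = vp*ca + Ktrans * exp(-kep t) (*) ca."""
    conv = _exp_convolve(aif.values, kep, aif.dt)[0]
    return vp * aif.values + ktrans * conv


def fit_modified_tofts(series: DynamicSeries, aif, n0: int | None = None,
                       kep_grid: np.ndarray | None = None):
    """Fit the simplified 3-parameter modified Tofts model per pixel.

    Strategy (deterministic, no non-linear optimiser): for each kep on a
    log-spaced grid the model is linear in (vp, Ktrans), solved in closed
    form per pixel; the best kep is then refined by parabolic interpolation
    of the residual in log(kep) and the linear pair re-solved. Negative
    amplitudes are projected to zero. Non-convergent pixels are flagged and
    carry Sigma = S0.

    Returns ``(ToftsParamMaps, sigma)``.
    """
    data2d, spatial, ca, dt, n0 = _series_inputs(series, aif, n0)
    maps, sigma = fit_tofts_pixels(data2d, ca, dt, n0, kep_grid)
    K = data2d.shape[1]
    maps = ToftsParamMaps(vp=maps.vp.reshape(spatial),
                          ktrans=maps.ktrans.reshape(spatial),
                          kep=maps.kep.reshape(spatial),
                          failed=maps.failed.reshape(spatial))
    return maps, sigma.reshape(*spatial, K)


def fit_tofts_pixels(data2d: np.ndarray, ca: np.ndarray, dt: float, n0: int,
                     kep_grid: np.ndarray | None = None):
    """Vectorised modified-Tofts fit over flat pixels (n_pixels, n_frames)."""
    data2d = np.asarray(data2d, dtype=float)
    ca = np.asarray(ca, dtype=float)
    npx, K = data2d.shape
    if kep_grid is None:
        kep_grid = np.logspace(-4, 0, 128)
    kep_grid = np.asarray(kep_grid, dtype=float)

    S0 = data2d[:, :n0].mean(axis=1)
    y = data2d - S0[:, None]
    yy = np.einsum("nk,nk->n", y, y)
    b1 = y @ ca
    m11 = float(ca @ ca)

    conv = _exp_convolve(ca, kep_grid, dt)        # (m, K)
    m12 = conv @ ca                               # (m,)
    m22 = np.einsum("mk,mk->m", conv, conv)
    b2 = y @ conv.T                               # (n, m)

    det = m11 * m22 - m12**2
    det[det <= 0] = np.inf
    c1 = (m22 * b1[:, None] - m12 * b2) / det     # vp
    c2 = (m11 * b2 - m12 * b1[:, None]) / det     # Ktrans
    sse = yy[:, None] - (c1 * b1[:, None] + c2 * b2)

    best = np.argmin(sse, axis=1)
    # parabolic refinement of kep in log-space for interior minima
    logk = np.log(kep_grid)
    kep = kep_grid[best]
    interior = (best > 0) & (best < kep_grid.size - 1)
    if np.any(interior):
        i = best[interior]
        f0 = sse[interior, i - 1]
        f1 = sse[interior, i]
        f2 = sse[interior, i + 1]
        denom = f0 - 2 * f1 + f2
        shift = np.where(np.abs(denom) > 0, 0.5 * (f0 - f2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = logk[1] - logk[0]
        kep_ref = np.exp(logk[i] + shift * step)
        kep[interior] = kep_ref

    # re-solve the linear pair at the per-pixel refined kep
    conv_px = _exp_convolve_per_pixel(ca, kep, dt)    # (n, K)
    p12 = conv_px @ ca
    p22 = np.einsum("nk,nk->n", conv_px, conv_px)
    q2 = np.einsum("nk,nk->n", y, conv_px)
    det = m11 * p22 - p12**2
    ok = det > 1e-300
    vp = np.zeros(npx)
    kt = np.zeros(npx)
    vp[ok] = (p22[ok] * b1[ok] - p12[ok] * q2[ok]) / det[ok]
    kt[ok] = (m11 * q2[ok] - p12[ok] * b1[ok]) / det[ok]

    # project negative amplitudes (non-negativity of the physical parameters)
    neg_kt = kt < 0
    vp[neg_kt] = np.where(m11 > 0, b1[neg_kt] / m11, 0.0)
    kt[neg_kt] = 0.0
    neg_vp = vp < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        kt[neg_vp] = np.where(p22[neg_vp] > 0, q2[neg_vp] / p22[neg_vp], 0.0)
    vp[neg_vp] = 0.0
    kt[kt < 0] = 0.0

    failed = ~(np.isfinite(vp) & np.isfinite(kt)) | ~ok
    vp[failed] = 0.0
    kt[failed] = 0.0

    sigma = S0[:, None] + vp[:, None] * ca + kt[:, None] * conv_px
    sigma[failed] = S0[failed, None]
    maps = ToftsParamMaps(vp=vp, ktrans=kt, kep=kep, failed=failed)
    return maps, sigma


def _exp_convolve_per_pixel(ca: np.ndarray, kep: np.ndarray, dt: float) -> np.ndarray:
    """Same recursion as :func:`_exp_convolve` with one kep per pixel."""
    return _exp_convolve(ca, kep, dt)
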