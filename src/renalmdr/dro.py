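"""Digital reference object (DRO): a kidney-mimicking dynamic phantom.

The phantom models two kidneys as three concentric ellipses each (cortex,
medulla, pelvis) with region-wise two-compartment filtration parameters
drawn from physiological ranges (plasma flow 30-300 mL/min/100mL, plasma
transit 6-20 s, tubular flow 40-60 mL/min/100mL, tubular transit 90-300 s).
Signals are generated at pseudo-continuous temporal resolution (0.1 s) with
S0 = 1 and block-averaged down to the frame interval (1.1 s), giving the
default 135 x 135 x 120-frame series.

Motion corruption is applied by backward warping with known per-frame
deformation fields: rigid sinusoidal vertical shifts (default amplitude
12 px, period 4 s) or a synthetic smooth non-rigid field (a seeded
control-point sinusoid standing in for fields measured on clinical data,
with amplitudes scaled up to stress the registration). The ground-truth
parameter maps are warped with the *same* fields, so error quantification
can pick the breathing state closest to the reconstruction
(:func:`select_reference_state`). Gaussian noise is specified through the
contrast-to-noise ratio CNR = max(c_a)/SD and added after motion corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ffd import ControlGrid, voxel_coordinates, warp
from .kinetics import (AIF, DynamicSeries, KineticParams2CFM,
                       concentration_to_signal, simulate_concentration_2cfm)

__all__ = [
    "Region",
    "RigidMotion",
    "NonRigidMotion",
    "DROSpec",
    "DROInstance",
    "population_aif",
    "default_kidneys",
    "build_phantom",
    "rigid_motion_fields",
    "synthetic_nonrigid_fields",
    "apply_motion",
    "add_noise",
    "select_reference_state",
    "make_dro",
]


def population_aif(times: np.ndarray, baseline: float = 15.0) -> AIF:
    """Population arterial input function: gamma-variate bolus with
    biexponential washout, zero-padded over the baseline.

    c_a(t') = g(t') + 0.4 * W(t') * (0.6 exp(-t'/80) + 0.4 exp(-t'/600))
    with t' = t - baseline, the bolus g(t') = (t'/tp)^4 exp(4(1-t'/tp))
    peaking at tp = 8 s, and W the cumulative bolus (normalised) feeding the
    washout tail. The peak is normalised to 1 (arbitrary units). Constants
    are package defaults for a realistic first pass plus recirculation tail;
    any tabulated AIF can be supplied instead wherever an AIF is accepted.
    """
    times = np.asarray(times, dtype=float)
    tp = 8.0
    t = times - baseline
    g = np.where(t > 0, (np.maximum(t, 0) / tp) ** 4
                 * np.exp(4 * (1 - np.maximum(t, 0) / tp)), 0.0)
    dt = times[1] - times[0]
    W = np.cumsum(g) * dt
    if W[-1] > 0:
        W = W / W[-1]
    tail = 0.4 * W * (0.6 * np.exp(-np.maximum(t, 0) / 80.0)
                      + 0.4 * np.exp(-np.maximum(t, 0) / 600.0))
    values = g + np.where(t > 0, tail, 0.0)
    peak = values.max()
    if peak > 0:
        values = values / peak
    return AIF(times, values, baseline_duration=baseline)


@dataclass
class Region:
    """An elliptical region: centre and semi-axes as fractions of the
    matrix, with its kinetic parameters."""

    center: tuple
    semiaxes: tuple
    params: KineticParams2CFM

    def mask(self, shape) -> np.ndarray:
        coords = voxel_coordinates(shape).reshape(*shape, len(shape))
        c = np.array(self.center) * (np.array(shape) - 1)
        a = np.array(self.semiaxes) * np.array(shape)
        r2 = np.sum(((coords - c) / a) ** 2, axis=-1)
        return r2 <= 1.0


@dataclass
class RigidMotion:
    """Sinusoidal vertical (axis-0) rigid shifts."""

    amplitude: float = 12.0   # pixels
    period: float = 4.0       # seconds


@dataclass
class NonRigidMotion:
    """Synthetic smooth periodic motion on a coarse control grid (a seeded
    stand-in for deformation fields measured on clinical data)."""

    amplitude: float = 6.0    # max per-point displacement, pixels
    period: float = 4.0       # seconds
    ctrl_points: int = 4      # control points per axis


def default_kidneys():
    """Two kidneys, three concentric ellipses each (cortex, medulla, pelvis),
    with parameters at the endpoints/midpoints of the physiological ranges.
    Listed outside-in; later regions overwrite earlier ones."""
    cortex = KineticParams2CFM(FP=300.0, TP=6.0, FT=60.0, TT=90.0)
    medulla = KineticParams2CFM(FP=150.0, TP=13.0, FT=50.0, TT=180.0)
    pelvis = KineticParams2CFM(FP=30.0, TP=20.0, FT=40.0, TT=300.0)
    kidneys = []
    for cy in (0.28, 0.72):
        kidneys.append([
            Region((0.50, cy), (0.20, 0.12), cortex),
            Region((0.50, cy), (0.13, 0.078), medulla),
            Region((0.50, cy), (0.065, 0.040), pelvis),
        ])
    return kidneys


@dataclass
class DROSpec:
    """Specification of a DRO realisation.

    `frame_dt` must be an integer multiple of `fine_dt` (block averaging);
    `motion` is None, a :class:`RigidMotion` or a :class:`NonRigidMotion`;
    `cnr` is the contrast-to-noise ratio max(c_a)/SD, or None for noise-free.
    """

    matrix: tuple = (135, 135)
    n_frames: int = 120
    frame_dt: float = 1.1
    fine_dt: float = 0.1
    baseline: float = 15.0
    kidneys: list = field(default_factory=default_kidneys)
    motion: object = None
    cnr: float | None = None
    seed: int = 0

    def __post_init__(self):
        ratio = self.frame_dt / self.fine_dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("frame_dt must be an integer multiple of fine_dt")
        if isinstance(self.motion, (RigidMotion, NonRigidMotion)):
            if getattr(self.motion, "amplitude") < 0:
                raise ValueError("motion amplitude must be >= 0")

    @property
    def block(self) -> int:
        return int(round(self.frame_dt / self.fine_dt))

    def to_dict(self) -> dict:
        d = dict(matrix=list(self.matrix), n_frames=self.n_frames,
                 frame_dt=self.frame_dt, fine_dt=self.fine_dt,
                 baseline=self.baseline, cnr=self.cnr, seed=self.seed)
        d["kidneys"] = [[dict(center=list(r.center), semiaxes=list(r.semiaxes),
                              params=vars(r.params)) for r in k]
                        for k in self.kidneys]
        if isinstance(self.motion, RigidMotion):
            d["motion"] = dict(type="rigid", amplitude=self.motion.amplitude,
                               period=self.motion.period)
        elif isinstance(self.motion, NonRigidMotion):
            d["motion"] = dict(type="nonrigid", amplitude=self.motion.amplitude,
                               period=self.motion.period,
                               ctrl_points=self.motion.ctrl_points)
        else:
            d["motion"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DROSpec":
        d = dict(d)
        if "kidneys" in d and d["kidneys"] is not None:
            d["kidneys"] = [
                [Region(tuple(r["center"]), tuple(r["semiaxes"]),
                        KineticParams2CFM(**r["params"])) for r in k]
                for k in d["kidneys"]]
        else:
            d.pop("kidneys", None)
        m = d.get("motion")
        if isinstance(m, dict):
            kind = m.pop("type")
            d["motion"] = RigidMotion(**m) if kind == "rigid" else NonRigidMotion(**m)
        if "matrix" in d:
            d["matrix"] = tuple(d["matrix"])
        return cls(**d)


@dataclass
class DROInstance:
    """A realised DRO: ground truth, motion-free series, applied fields,
    per-frame moving truth maps and the corrupted (noisy) series."""

    spec: DROSpec
    aif_fine: AIF
    aif: AIF
    truth: dict                      # FP, TP, FT, TT, S0 maps
    motion_free: DynamicSeries
    kidney_mask: np.ndarray
    series: DynamicSeries = None     # corrupted series (== motion_free if no motion/noise)
    fields: np.ndarray = None        # (n_frames, *matrix, d) displacements
    moving_truth: dict = None        # name -> (n_frames, *matrix)

    @property
    def n0(self) -> int:
        return self.motion_free.n0


def build_phantom(spec: DROSpec, aif: AIF | None = None) -> DROInstance:
    """Construct the motion-free phantom.

    Region concentrations are simulated at `fine_dt` with the 2CFM forward
    model and S0 = 1, then block-averaged to the frame interval; background
    pixels stay at S0 = 1. Raises if the kidneys overlap.
    """
    shape = tuple(spec.matrix)
    n_fine = spec.n_frames * spec.block
    fine_times = (np.arange(n_fine) + 0.5) * spec.fine_dt
    if aif is None:
        aif = population_aif(fine_times, baseline=spec.baseline)
    elif aif.times.size != n_fine or not np.isclose(aif.dt, spec.fine_dt):
        aif = aif.resample(fine_times)

    outer = [k[0].mask(shape) for k in spec.kidneys]
    for i in range(len(outer)):
        for j in range(i + 1, len(outer)):
            if np.any(outer[i] & outer[j]):
                raise ValueError("kidneys overlap")
    kidney_mask = np.zeros(shape, dtype=bool)
    for m in outer:
        kidney_mask |= m

    truth = {name: np.zeros(shape) for name in ("FP", "TP", "FT", "TT")}
    truth["S0"] = np.ones(shape)
    frames = np.ones(shape + (spec.n_frames,))

    # simulate one curve per unique parameter set, assign region-wise
    cache = {}
    for kidney in spec.kidneys:
        for region in kidney:   # outside-in; inner regions overwrite
            p = region.params
            key = (p.FP, p.TP, p.FT, p.TT)
            if key not in cache:
                c_fine = simulate_concentration_2cfm(p, aif)
                c_frames = c_fine.reshape(spec.n_frames, spec.block).mean(axis=1)
                cache[key] = concentration_to_signal(1.0, c_frames)
            mask = region.mask(shape)
            frames[mask] = cache[key]
            for name, val in zip(("FP", "TP", "FT", "TT"), key):
                truth[name][mask] = val

    frame_times = fine_times.reshape(spec.n_frames, spec.block).mean(axis=1)
    aif_frames = aif.downsample(spec.block)
    n0 = max(1, min(int(spec.baseline // spec.frame_dt), spec.n_frames - 1))
    series = DynamicSeries(frames, frame_times=frame_times, n0=n0)
    return DROInstance(spec=spec, aif_fine=aif, aif=aif_frames, truth=truth,
                       motion_free=series, kidney_mask=kidney_mask,
                       series=series)


def rigid_motion_fields(amplitude: float, period: float, frame_times,
                        shape) -> np.ndarray:
    """Uniform vertical backward-warp shifts A*sin(2*pi*t/period) per frame,
    shape (n_frames, *shape, d); zero at t = 0."""
    if period <= 0:
        raise ValueError("period must be positive")
    frame_times = np.asarray(frame_times, dtype=float)
    shifts = amplitude * np.sin(2 * np.pi * frame_times / period)
    d = len(shape)
    fields = np.zeros((frame_times.size,) + tuple(shape) + (d,))
    fields[..., 0] = shifts.reshape(-1, *([1] * d))
    return fields


def synthetic_nonrigid_fields(shape, frame_times, amplitude: float = 6.0,
                              period: float = 4.0, ctrl_points: int = 4,
                              seed: int = 0) -> np.ndarray:
    """Synthetic smooth, periodic, seeded non-rigid motion fields.

    Each point of a coarse control lattice follows a sinusoid of random
    phase and random per-component amplitude bounded by `amplitude`;
    the dense field is the tent-kernel FFD interpolation. The map is
    checked for invertibility (positive numerical Jacobian determinant on
    the voxel grid); folding raises with the offending frame index.
    """
    shape = tuple(shape)
    d = len(shape)
    frame_times = np.asarray(frame_times, dtype=float)
    K = frame_times.size
    rng = np.random.default_rng(seed)
    cshape = (ctrl_points,) * d
    amp = rng.uniform(0.3, 1.0, size=cshape + (d,)) * amplitude
    phase = rng.uniform(0, 2 * np.pi, size=cshape + (d,))
    spacing = [(n - 1) / (ctrl_points - 1) for n in shape]
    disp = np.empty((K,) + cshape + (d,))
    for t in range(K):
        disp[t] = amp * np.sin(2 * np.pi * frame_times[t] / period + phase)
    grid = ControlGrid.identity(shape, K, spacing)
    # the identity lattice of this spacing has exactly ctrl_points nodes/axis
    if grid.ctrl_shape != cshape:
        raise RuntimeError("control lattice shape mismatch")
    grid.disp[...] = disp
    fields = np.stack([grid.dense_displacement(t) for t in range(K)])
    for t in range(K):
        jac = _jacobian_determinant(fields[t])
        if np.min(jac) <= 0:
            raise ValueError(f"deformation folds at frame {t}; "
                             "reduce the amplitude")
    return fields


def _jacobian_determinant(disp: np.ndarray) -> np.ndarray:
    """det(I + grad(u)) of a dense displacement field (*spatial, d)."""
    d = disp.shape[-1]
    J = np.empty(disp.shape[:-1] + (d, d))
    for c in range(d):
        grads = np.gradient(disp[..., c])
        if d == 1:
            grads = [grads]
        for ax in range(d):
            J[..., c, ax] = grads[ax]
    J += np.eye(d)
    return np.linalg.det(J)


def apply_motion(instance: DROInstance, fields: np.ndarray) -> DROInstance:
    """Corrupt the phantom with per-frame fields (backward warping).

    Each frame of the motion-free series and every ground-truth parameter
    map are warped with that frame's field — the identical field object —
    so the moving truth maps track the images exactly.
    """
    mf = instance.motion_free
    shape = mf.spatial_shape
    K = mf.n_frames
    fields = np.asarray(fields, dtype=float)
    if fields.shape != (K,) + shape + (len(shape),):
        raise ValueError("fields shape does not match the series")
    vox = voxel_coordinates(shape)
    corrupted = np.empty_like(mf.data)
    moving = {name: np.empty((K,) + shape)
              for name in ("FP", "TP", "FT", "TT")}
    for t in range(K):
        coords = vox + fields[t].reshape(-1, len(shape))
        corrupted[..., t] = warp(mf.data[..., t], coords)
        for name in moving:
            moving[name][t] = warp(instance.truth[name], coords)
    series = DynamicSeries(corrupted, voxel_dims=mf.voxel_dims,
                           frame_times=mf.frame_times, n0=mf.n0)
    return replace(instance, series=series, fields=fields,
                   moving_truth=moving)


def add_noise(series: DynamicSeries, cnr: float, aif: AIF,
              seed: int = 0) -> DynamicSeries:
    """Additive Gaussian noise with SD = max(c_a)/CNR, independent per voxel
    per frame, seeded."""
    if cnr is None or np.isinf(cnr):
        return series
    if cnr <= 0:
        raise ValueError("cnr must be positive")
    sd = float(np.max(aif.values)) / cnr
    rng = np.random.default_rng(seed)
    noisy = series.data + rng.normal(0.0, sd, size=series.data.shape)
    return DynamicSeries(noisy, voxel_dims=series.voxel_dims,
                         frame_times=series.frame_times, n0=series.n0)


def select_reference_state(reconstructed_fp: np.ndarray,
                           moving_truth_fp: np.ndarray) -> int:
    """Frame index of the breathing state closest to the reconstruction.

    Returns argmin over frames of the sum of squared differences between the
    reconstructed plasma-flow map and each frame's moving ground-truth
    plasma-flow map; ties break to the earliest frame.
    """
    recon = np.asarray(reconstructed_fp, dtype=float)
    stack = np.asarray(moving_truth_fp, dtype=float)
    if stack.shape[1:] != recon.shape:
        raise ValueError("map shapes do not match")
    sse = np.sum((stack - recon) ** 2, axis=tuple(range(1, stack.ndim)))
    return int(np.argmin(sse))


def make_dro(spec: DROSpec, aif: AIF | None = None) -> DROInstance:
    """Build a complete DRO realisation: phantom, motion, noise.

    Seeds for the non-rigid fields and the noise are derived independently
    from `spec.seed`; zero amplitude and CNR = None reproduce the motion-free
    phantom bit for bit.
    """
    inst = build_phantom(spec, aif)
    ss = np.random.SeedSequence(spec.seed).generate_state(2) % (2**31)
    if isinstance(spec.motion, RigidMotion):
        fields = rigid_motion_fields(spec.motion.amplitude, spec.motion.period,
                                     inst.motion_free.frame_times, spec.matrix)
        inst = apply_motion(inst, fields)
    elif isinstance(spec.motion, NonRigidMotion):
        fields = synthetic_nonrigid_fields(
            spec.matrix, inst.motion_free.frame_times,
            amplitude=spec.motion.amplitude, period=spec.motion.period,
            ctrl_points=spec.motion.ctrl_points, seed=int(ss[0]))
        inst = apply_motion(inst, fields)
    if spec.cnr is not None:
        inst = replace(inst, series=add_noise(inst.series, spec.cnr,
                                              inst.aif_fine, seed=int(ss[1])))
    return inst
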