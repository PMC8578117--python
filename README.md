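# renalmdr — model-driven registration for free-breathing MR renography

Free-breathing dynamic contrast-enhanced MRI of the kidney (MR renography)
measures renal perfusion and filtration, but breathing moves the kidneys by
many pixels between frames while the contrast agent reverses the image
contrast — conditions under which conventional pairwise registration fails.
`renalmdr` implements **model-driven registration (MDR)**: the tracer-kinetic
model that will be fitted anyway is used to generate the registration
targets, and deformations and parameter maps are estimated jointly.

It is aimed at quantitative-MRI researchers who need motion-corrected
perfusion maps from 2D or 3D dynamic series, and at method developers who
need a transparent, fully synthetic validation bench (the kidney digital
reference object, DRO).

## The model

The signal is linear in concentration, `S(x,t) = S0(x) + C(x,t)`, and the
tissue is a two-compartment filtration system (2CFM): a plasma compartment
(flow `FP`, mean transit time `TP`) feeding a tubular compartment (flow
`FT`, mean transit time `TT`), so `C` is a bi-exponential convolved with the
arterial input function `c_a(t)`. Fitting uses the linearised form

    y = α₁ ∫y + α₂ ∬y + β₁ ∫c_a + β₂ ∬c_a,      y = S − S0,

solved per pixel by ordinary least squares; `(FP, TP, FT, TT)` follow in
closed form from `(α, β)`.

Motion is a free-form deformation `D(x,t)` interpolated with linear (tent)
kernels from displacement vectors on a control-point grid. Registration
minimises the joint least-squares cost

    χ²(D, P) = ½ Σ_{x,t} ( S(D(x,t), t) − Σ(P(x), t) )²

by alternating (1) pixelwise model fits at fixed deformations with (2)
frame-by-frame gradient descent on the control points, using an analytical
gradient and a back-tracking line search, inside a multi-resolution schedule
that halves the grid spacing from the field of view down to a configurable
minimum. Because the linearised model builds its regressors from the data,
the target moves with the deformations (generalised MDR); the production
path adopts the identity approximation for the residual derivative and the
exact generalised residual ships as a diagnostic.

## Worked example

Generate a motion-corrupted phantom, register it, and score the maps against
the co-moving ground truth:

```python
import numpy as np
from renalmdr import (DROSpec, MDRConfig, ModelDrivenRegistration,
                      RigidMotion, bias_precision, make_dro, percent_error,
                      select_reference_state)

spec = DROSpec(matrix=(64, 64), n_frames=60,
               motion=RigidMotion(amplitude=6.0, period=4.0),
               cnr=1000.0, seed=1)
dro = make_dro(spec)

config = MDRConfig(grid_spacing_min=32, tolerance=0.2)
result = ModelDrivenRegistration(dro.series, dro.aif, config).fit()
print(result.summary())

k = select_reference_state(result.params["FP"], dro.moving_truth["FP"])
for name in ("FP", "TT"):
    bp = bias_precision(percent_error(result.params[name],
                                      dro.moving_truth[name][k]))
    print(f"{name}: bias {bp.bias:+.2f}%, 90% CI width {bp.precision:.2f}%")
```

which prints

```
Model-Driven Registration Results
================================================
Kinetic model:        linear_2cfm
Image size:           (64, 64), 60 frames
Frame interval:       1.100 s (n0 = 13)
Grid spacing min:     32 px
Tolerance:            0.2 px
Resolution levels:    2
Final chi^2:          0.550624
Mean |displacement|:  2.992 px
------------------------------------------------
level  spacing  iterations  final chi^2
    0     64.0           8      0.660144
    1     32.0           2      0.561558
------------------------------------------------
    FP: median          0  max      311.9
    TP: median          0  max      41.51
    FT: median          0  max       125.7
    TT: median          0  max       6871
    S0: median          1  max      1.001
FP: bias +0.00%, 90% CI width 17.11%
TT: bias +0.00%, 90% CI width 29.12%
```

The cost trace is monotone within each resolution level; the mean recovered
displacement (~3 px) matches the mean of the applied 6 px sinusoid; the
plasma-flow error distribution is unbiased, and the 90% CI width quantifies
the residual edge errors at this deliberately small phantom scale (see
`docs/methods.md` for what does and does not transfer to full-size data).
`result.corrected` holds the motion-corrected series, `result.params` the
parameter maps, and `result.deformation_fields()` the dense per-frame
displacement fields.

The same pipeline is available from the shell:

```sh
mdr dro --spec dro.yaml --out dro/
mdr fit --series dro/series.nii.gz --aif dro/aif.csv --config run.yaml --out out/
mdr eval --recon out/ --truth dro/ --out report.csv
```

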