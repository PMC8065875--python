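# bbbsim

Four-dimensional simulation of DCE-MRI measurement of **subtle blood–brain
barrier (BBB) leakage**.

Dynamic contrast-enhanced MRI is the standard technique for quantifying BBB
breakdown in small-vessel disease and dementia, where the leakage of
gadolinium contrast agent into brain tissue is extremely slow: the Patlak
parameters of interest are of order *PS* ≈ 3×10⁻⁴ min⁻¹ and *v*_P ≈ 0.01,
producing signal changes of only a few percent over a ~25-minute scan.  At
this level, spatio-temporal measurement effects — finite k-space sampling
(Gibbs ringing and partial-volume averaging), gross head motion, intra-frame
motion artefacts and noise — can rival or exceed the biological signal.

`bbbsim` generates **digital reference objects (DROs)**: synthetic 4D image
series from a labelled head phantom with *known* ground-truth parameters,
degrades them with a realistic acquisition model, then runs the standard
measurement pipeline and reports the error each degradation introduces.  It
is aimed at imaging scientists designing or auditing low-leakage DCE-MRI
protocols.

## Model

Tissue concentration follows the Patlak model for irreversible slow leakage,

```
C_t[t] = v_P · c_p[t] + PS · ∫₀ᵗ c_p dt′
```

with `c_p` the arterial input function (population biexponential for a
0.1 mmol/kg bolus by default).  Concentration modulates relaxation linearly,
`1/T_i[t] = 1/T_i0 + r_i · C_t[t]` (i = 1, 2*), and the measured signal is
the spoiled gradient-echo steady state

```
S = S0 (1 − E1) sin θ / (1 − E1 cos θ) · exp(−TE/T2*),   E1 = exp(−TR/T1).
```

Acquisition is simulated in five steps per frame: random starting head
position (±5°, ±2.5 mm uniform), per-frame rigid motion (random-walk
trajectories in low / moderate / high severity classes), 3D Cartesian
k-space truncation to the acquired matrix, composite-k-space motion
artefacts (a random fraction of phase-encode planes acquired at the previous
head position), and complex Gaussian k-space noise followed by magnitude
reconstruction (Rician image noise).  Analysis mirrors clinical practice:
rigid realignment to frame 0, SPGR inversion to concentration using a
regional T10 map, voxelwise Patlak fitting by OLS on {c_p, ∫c_p} with the
first three post-contrast frames excluded, and per-tissue summaries (mean /
median of the parameter maps, or a single fit of the mean / median ROI
signal), with optional mask erosion and Bessel k-space low-pass filtering.

The shipped fixtures hold the reference 1.5 T protocol (TR 8.24 ms, TE
3.1 ms, flip 12°, 24×24×18.4 cm FOV at 0.9375×1.25×4 mm, 73 s temporal
resolution, 1 pre- + 20 post-contrast frames) and per-tissue ground truth
(e.g. normal-appearing white matter: S0 9726, T10 0.99 s,
PS 2.75×10⁻⁴ min⁻¹, v_P 0.57×10⁻²).

## Worked example

```python
import numpy as np
from bbbsim import (
    PhantomSpec, build_synthetic_head, demo_protocol, load_fixtures,
    make_aif, simulate_acquisition, realign_frames, propagate_segmentation,
    build_T10_map, fit_parameter_maps, summarize_roi,
)
from bbbsim.acquisition import generate_trajectory, random_start_position

proto = demo_protocol((64, 64, 64), (1.5, 1.5, 1.5), acquired_matrix=(32, 24, 16))
_, table = load_fixtures()
labels = build_synthetic_head(PhantomSpec(shape=(64, 64, 64), spacing=(1.5, 1.5, 1.5)), seed=1)
aif = make_aif(proto)

rng = np.random.default_rng(0)
series, record = simulate_acquisition(
    labels, table, aif, proto,
    start=random_start_position(rng),
    trajectory=generate_trajectory("moderate", proto.n_frames, rng),
    rng=rng,
)
series, _ = realign_frames(series, mode="oracle", trajectory=record.positions)
label_map, _ = propagate_segmentation(labels, series.frame(0), proto,
                                      mode="oracle", transform=record.positions[0])
pmap = fit_parameter_maps(series, build_T10_map(label_map, table), aif, proto)
df = summarize_roi(pmap, series, label_map, table, aif, proto,
                   estimators=("median_parameter",))
print(df[["tissue", "PS_est", "rel_err_PS_pct"]].to_string(index=False))
```

```
     tissue   PS_est  rel_err_PS_pct
       nawm 0.000229      -16.626351
        wmh 0.000637       62.962636
     stroke 0.000449      -38.115479
cortical_gm 0.002662      591.354305
    deep_gm 0.001087      182.401611
```

Even *moderate* head motion distorts the recovered leakage rates by tens to
hundreds of percent despite perfect realignment — white matter is biased
low, while thin or small structures (the cortical ribbon, WMH, the stroke
lesion) are swamped by signal mixed in from their surroundings.  Under ideal conditions (no motion,
no noise, matched grids) the same pipeline recovers every tissue's PS and
v_P to better than 1% (see the acceptance tests).

A command-line interface wraps the same pipeline:

```sh
bbbsim simulate --seed 1 --out out/            # one run + analysis artefacts
bbbsim montecarlo --seed 1 --n-runs 25 --out mc/
bbbsim fit --no-realign --interp sinc --seed 1 --out fit/
```

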