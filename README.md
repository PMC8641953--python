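# prfmap

Population receptive field (pRF) mapping for visually driven brain signals.

A population receptive field is the region of visual space that drives the
aggregate response of the neural population sampled by one fMRI voxel or one
electrode.  `prfmap` implements the forward-model approach to estimating
pRFs from bar-sweep mapping experiments, for three kinds of response data:
BOLD time series (percent signal change per TR), multi-unit spiking activity
(MUA), and local field potential (LFP) band power — plus the conventional
moving-bar receptive-field estimator used as an electrophysiological ground
truth, and the population-level statistics needed to compare pRF properties
across signal types.  It is aimed at visual neuroscientists who want a
tested, scriptable pRF pipeline and a synthetic-data harness with known
ground truth for validating it.

## The models

The stimulus is reduced to a binary "effective stimulus" movie S(x, y) over
visual space (1 where the bar is, 0 elsewhere).  Each pRF is an isotropic
2-D Gaussian G(x, y) with center (x₀, y₀) and width σ, and the predicted
response to one frame is

    Resp_pred = g · [ Σₓ,ᵧ S(x, y) · G(x, y) ]ⁿ

Four model variants are fitted and compared:

| model | summation | gain | notes |
|-------|-----------|------|-------|
| P-LIN | linear (n = 1) | g > 0 | classic linear pRF |
| U-LIN | linear (n = 1) | g free | negative g = stimulus-driven suppression ("negative pRF") |
| CSS   | power law, n < 1 typical | g > 0 | compressive spatial summation |
| DoG   | linear, center − surround | g > 0 | G₁(σ₁) − a·G₂(σ₂), σ₂ > σ₁ |

Because σ and the static nonlinearity interact, pRF size is defined for all
models as the SD of the predicted response profile to a point stimulus,
σ/√n (for DoG, center size σ₁ and surround size σ₂ are reported
separately).  For BOLD, predictions are convolved with a hemodynamic
response function (monkey: time-to-peak 4.2 s, peak-to-fall 6.2 s; human:
4.8 s / 12.6 s) at TR/2 resolution and decimated to the TR.

Fitting is multi-start bounded nonlinear least squares (coarse grid with
closed-form gain, then local refinement), scored by split-half
cross-validated variance explained: each half (odd/even runs) is fitted and
scored on the other half, and the two R² values are averaged.

## Worked example

Simulate an electrophysiology mapping session with known ground truth, fit
the CSS model, and check recovery:

```python
import numpy as np
from prfmap import (make_protocol, render_effective_stimulus,
                    sample_population, synth_ephys, fit_prf)

stim = render_effective_stimulus(make_protocol("ephys", pixels_per_dva=2))
pop = sample_population("V1", n_units=3, seed=1)
ds = synth_ephys(pop, stim, noise_sd=0.0, n_repeats=2, model="CSS", seed=3)
for u in range(3):
    fr = fit_prf("CSS", ds, u)
    t = pop.table.iloc[u]
    print(f"true n {t.exponent:.2f} est n {fr.params.exponent:.2f} "
          f"sigma {t.sigma:.2f}->{fr.params.sigma1:.2f} r2cv {fr.r2_cv:.2f}")
```

prints

```
true n 0.38 est n 0.38 sigma 0.99->0.99 r2cv 100.00
true n 0.35 est n 0.35 sigma 1.40->1.40 r2cv 100.00
true n 0.40 est n 0.40 sigma 0.85->0.85 r2cv 100.00
```

i.e. on noise-free data the fit recovers the generating center, size and
exponent exactly, with 100% cross-validated variance explained.  The same
round trip with realistic noise is what the test suite uses to bound the
estimator's center/size/exponent errors.

The same machinery is available as a scikit-learn style estimator
(`PRFRegressor(model="CSS").fit(design, y)` with fitted attributes `x0_`,
`sigma1_`, `size_`, `r2_train_`) and from the shell:

```bash
prf simulate --scenario ephys_v1 --seed 1 --n-units 20 --out run/
prf fit --stim run/stim.h5 --data run/dataset.h5 --model css --out fits.csv
prf compare --fits fits_bold.csv --fits fits_mua.csv --analysis slopes --out report.json
```

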