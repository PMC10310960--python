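# cvrkit

Model-free temporal-feature analysis of BOLD cerebrovascular-reactivity
(CVR) gas-challenge experiments.

## The problem

Cerebrovascular reactivity is the vascular response to a vasoactive
stimulus, usually measured as the BOLD-fMRI signal change per mmHg of
end-tidal CO₂ (PETCO₂) during a hypercapnia challenge. Conventional
analyses fit a general linear model whose regressor is the PETCO₂ trace (or
paradigm boxcar) convolved with a hemodynamic response function — a single
summary that assumes the BOLD response tracks the stimulus shape and that
pools successive challenges. In clinical populations (cognitive impairment,
sleep apnea, small-vessel disease) responses can be slow, non-linear, or
differ between consecutive challenges, which is exactly where those
assumptions break.

`cvrkit` implements a model-free alternative for two-challenge boxcar
paradigms, for researchers analyzing ROI-mean BOLD time series:

* **Per-challenge non-parametric CVR.** Over the dilation window of each
  challenge, the Sen's (Theil–Sen) slope is the median of all n(n−1)/2
  pairwise slopes

  $$b = \mathrm{median}\left(\frac{x_j - x_i}{j - i}\right),\ j > i,$$

  converted to a unit-less percent signal change
  %ΔBOLD = b · n / (mean baseline BOLD) · 100 and normalized to
  CVR = %ΔBOLD / ΔPETCO₂ in % per mmHg. Medians make the estimate robust
  to outlier volumes (breakdown ≈ 29%) without assuming a response shape.
* **Transition rate.** The hyper-to-normocapnia washout is read out as the
  OLS rate τ of BOLD on time (s) over the transition window, normalized as
  τ / ΔPETCO₂.
* **Conventional comparator.** A gamma-HRF-convolved boxcar GLM (COPE) and
  a Gaussian AIC that scores the parametric and non-parametric fits on
  equal footing, driven by a fast/slow response simulator.
* **Group models.** Model 1 regresses CVR-2 on the preceding transition
  rate plus age, sex, clinical group, and experimental design (continuous
  terms z-scored, so parameter estimates are standardized); Model 2 adds
  CVR-1 and orthogonalizes the transition rate against it. Bonferroni
  thresholding (0.05/4 ROIs = 0.0125) and Pearson correlation matrices
  round out the statistics.
* **Synthetic data.** Everything is testable without scanner data: single
  epochs, full two-challenge subjects (Designs A and B, with PETCO₂
  traces), and cohorts with a planted washout-rate → CVR-2 effect.

Inputs are preprocessed 4-D NIfTI BOLD images plus ROI masks (or
pre-extracted CSV series), CO₂ traces as delimited text (or scalar ΔPETCO₂
values), and a breathing-paradigm config. Motion correction, smoothing and
registration are out of scope and assumed done upstream.

## Worked example

`examples/single_subject_metrics.py` builds a noise-free Design A subject
(2% responses to both challenges, 10 mmHg PETCO₂ step) and runs the full
pipeline:

```
CVR-1: 0.2002 %/mmHg  (Sen slope 0.1292 a.u./sample over 155 samples, baseline 1000.0 a.u.)
CVR-2: 0.1987 %/mmHg
transition rate 1: -0.01834 a.u./s/mmHg (tau -0.1834 a.u./s)
COPE-CVR (HRF-GLM comparator): 0.0769 %/mmHg
```

A 2% rise over a 10 mmHg step is 0.2 %/mmHg, which both challenges
recover; the negative transition rate is the BOLD decline during CO₂
washout. `examples/cohort_group_models.py` fits the group models on a
54-subject synthetic cohort with a planted negative washout-rate effect:

```
Model 1: CVR-2 ~ transition rate + age + sex + group + design
  transition rate: standardized PE -0.616, p = 1.1e-07 (significant at the 4-ROI Bonferroni threshold 0.0125)
  adjusted R2 = 0.509 (n = 54)
Model 2: + CVR-1, transition rate orthogonalized against CVR-1
  CVR-1:                 PE +0.522, p = 1.5e-06
  orthogonalized rate:   PE -0.417, p = 6.9e-05
  adjusted R2 = 0.589
```

The other examples cover the AIC simulation grid
(`simulation_grid_aic.py`) and end-tidal extraction from a breathing trace
(`petco2_from_trace.py`). A thin CLI mirrors the library:
`cvrkit extract | metrics | compare | synth | group` (see `cvrkit --help`).

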