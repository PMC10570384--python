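# campari

Quantification toolkit for **snapshot neuronal-activity recording with
photoconvertible calcium sensors** (CaMPARI-style experiments). A 400-nm
light pulse irreversibly switches the sensor's emission from green to red
— but only in neurons with elevated calcium while the light is on. A
single post-hoc two-photon volume therefore encodes, cell by cell, how
active each neuron was during the illuminated behaviour: the readout is
the per-cell **red-to-green ratio (RGR)**.

The package is aimed at labs analysing such two-channel volumetric
acquisitions. It provides:

- **Channel corrections** — the red channel mixes three nuisances with
  the converted signal: PMT dark current, spectral bleed-through of the
  green emission (a fixed ratio ρ of the green signal), and a
  per-hemisphere additive autofluorescence offset β from the cranial
  window. ρ and β are estimated by regressing red on green across cells
  imaged *before* photoconversion (where all red is nuisance), then
  subtracted in a fixed order:

  ```
  g_corr = g − dark_g
  r_corr = r − dark_r − β(hemisphere) − ρ·g_corr
  RGR    = r_corr / g_corr
  ```

- **Per-cell measurement extraction** — depth-slab averaging (mean of 3
  adjacent z-slices, skip 2, so consecutive slabs share almost no
  cells), a deterministic fallback somata labeler (masks from dedicated
  tools such as CellPose are first-class input), and mutual-nearest-
  neighbour matching of cells across pre/post acquisitions.

- **Population metrics** — region summaries (median, percentile bands,
  the 5–95 percentile range as a heterogeneity measure) and the
  sensitivity index separating two RGR distributions,

  d′ = (μ_A − μ_B) / √(½(σ²_A + σ²_B)).

- **Fitted models** in the Model → `fit()` → Results idiom:
  `ExponentialDecayModel` (y = 2^(−t/t½), the decay of the imprinted
  ratio over days), `DoseResponseModel` (polynomial fit locating the
  optimal photoconversion light dose), and `BehaviorRegression`
  (regional activity vs behavioural scores, F-test against the
  constant model).

- **Light-dose arithmetic** — intensity = power / illumination
  cross-section; dose = intensity × illumination time, reported in
  mW/mm²·s (= mJ/mm²).

- **A synthetic-data generator** that renders ground-truth cells of
  known activity through the same optical model the corrections invert,
  so the whole chain is testable end to end without animal data, plus
  decay cohorts and drifting-grating calcium traces for the
  stimulus-response integral sum(F_resp/2) − sum(F_base).

## Worked example

Simulate a two-region scene (visual cells more active than
somatosensory), run the correction chain, and compare the regions:

```python
import numpy as np
from campari import (DecayCohortSpec, DoseSpec, ExponentialDecayModel,
                     OpticalModel, PhotoconversionModel, SyntheticScene,
                     compute_rgr, correct_cell_table, dprime,
                     extract_cell_fluorescence, fit_corrections, light_dose,
                     render_scene, simulate_decay_cohort)

acts = np.where(np.arange(40) % 2 == 0, 0.65, 0.35) \
     + np.random.default_rng(0).normal(0, 0.1, 40)
scene = SyntheticScene.random(n_cells=40, shape=(12, 280, 280),
                              regions=("V1m", "S1"),
                              activity=np.clip(acts, 0, 1), seed=0)
optical, pc = OpticalModel(), PhotoconversionModel()

pre, labels = render_scene(scene, optical, pc, dose=0, phase="pre", seed=1)
post, _ = render_scene(scene, optical, pc, dose=300, phase="post", seed=2)

meta = {c.cell_id: c for c in scene.cells}
cells_pre = extract_cell_fluorescence(labels, pre.green, pre.red, phase="pre")
cells_pre["hemisphere"] = [meta[i].hemisphere for i in cells_pre["cell_id"]]
params = fit_corrections(cells_pre, dark_green=optical.dark_green,
                         dark_red=optical.dark_red)
print(f"rho = {params.rho():.4f}, beta = {params.beta('left'):.3f}")

cells_post = extract_cell_fluorescence(labels, post.green, post.red, phase="post")
cells_post["hemisphere"] = "left"
cells_post["region"] = [meta[i].region for i in cells_post["cell_id"]]
rgr = compute_rgr(correct_cell_table(cells_post, params))
d = dprime(rgr.loc[rgr.region == "V1m", "rgr"],
           rgr.loc[rgr.region == "S1", "rgr"])
print(f"median RGR V1m = {rgr.loc[rgr.region=='V1m','rgr'].median():.3f}, "
      f"S1 = {rgr.loc[rgr.region=='S1','rgr'].median():.3f}, d' = {d:.2f}")

res = ExponentialDecayModel.from_cohort(
    simulate_decay_cohort(DecayCohortSpec(seed=1))).fit()
print(res.summary())

dose = light_dose(DoseSpec(power_mw=200, aperture_diameter_mm=6.5,
                           cycle_duration_s=1, n_cycles=50))
print(f"intensity = {dose.intensity_mw_per_mm2:.2f} mW/mm^2, "
      f"cumulative dose = {dose.cumulative_dose:.0f} mJ/mm^2")
```

Output:

```
rho = 0.1179, beta = 3.355
median RGR V1m = 0.682, S1 = 0.363, d' = 3.20
Exponential ratio-decay fit: y = a * 2^(-t/t_half) + c
  n points        : 8
  half-life (days): 1.021 +/- 0.00994 (SE)
  R^2 (vs constant model): 0.9998
intensity = 6.03 mW/mm^2, cumulative dose = 301 mJ/mm^2
```

The estimated bleed-through (true value 0.12) and window offset (true
3.0) come back from 40 noisy cells; the two simulated populations
separate with d′ ≈ 3; the 73-cell decay cohort refits to its ~1-day
half-life; and 50 one-second cycles at 6 mW/mm² deliver a ~300 mJ/mm²
dose — the optimum of the sensitivity-vs-dose curve.

## Command line

`campari` exposes the stages as subcommands — `simulate`, `correct`,
`segment`, `rgr`, `dprime`, `dose`, `fit-decay`, `fit-dose-response`,
`integrate-response`, `stats` — and `run`, which executes the whole
pipeline from a YAML config with one global seed fanned out
deterministically to every stage (see `campari run --help`).

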