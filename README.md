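# nvjquant

Quantitative toolkit for studying how budding yeast concentrate HMG-CoA
reductase (Hmg1) at the nucleus–vacuole junction (NVJ) during acute glucose
restriction, aimed at microscopists and modellers who need the image
statistic and photobleaching analyses behind that phenotype in a tested,
scriptable form.

The package covers four connected analyses:

* **NVJ partitioning index.** After subtracting a Gaussian-blurred duplicate
  of the image (σ = 5 px), five-pixel-wide line scans are taken across the
  nuclear envelope (NE) at the NVJ and at the antipodal NE region. The
  partitioning index is the ratio of the areas under the two profiles,

  *P* = AUC(NVJ) / AUC(opposite),

  and a cell with *P* > 2.0 (strictly) is classified as NVJ-partitioned;
  fields of view are summarised as the percentage of partitioned cells.

* **FRAP / FLIP normalization and halftimes.** FRAP traces use double
  normalization, *I*(t) = (*I*<sub>wc,pre</sub>/*I*<sub>wc</sub>(t)) ·
  (*I*<sub>roi</sub>(t)/*I*<sub>roi,pre</sub>), then full normalization
  rescales the curve so the pre-bleach frame reads 1 and the bleach frame 0.
  FLIP traces are normalized to the pre-bleach ROI intensity. Halftimes
  come from one-phase exponential fits, *y* = *Y*<sub>∞</sub>(1 −
  e<sup>−kt</sup>) for recovery and *y* = *y*<sub>0</sub>e<sup>−kt</sup> for
  loss, with *t*<sub>½</sub> = ln 2 / *k*.

* **Mechanistic ground truth.** A fluorophore diffuses on a 1-D NE ring and
  binds reversibly inside the NVJ domain (rates *k*<sub>on</sub>,
  *k*<sub>off</sub>; the bound pool is immobile). Driven by the standard
  acquisition schedules — FRAP: one pre-bleach frame, one bleach of a
  0.77 µm² spot, frames every 500 ms for 25 s; FLIP: 50 bleach cycles over
  300 s — it emits intensity traces with known retention parameters, so the
  normalization and fitting pipeline can be validated against truth.

* **Growth resumption.** Empirical P(resumed ≤ t) curves from single-cell
  budding times after glucose replenishment (censored cells stay in the
  denominator), compared between genotypes with a two-sample
  Kolmogorov–Smirnov test (statistic and asymptotic p-value implemented
  directly).

A synthetic-image generator renders two-channel yeast cells (NE ring with an
NVJ-enriched arc, vacuole disc) with Poisson + read noise, together with the
ground-truth scan lines, so the partitioning statistic is testable against a
known enrichment factor.

## Worked example

```python
from nvjquant import (CellSpec, ImagingConfig, render_cell, QuantConfig,
                      RingParams, default_protocols, simulate, flip_normalize)
from nvjquant.partition import quantify_image
from nvjquant.photobleach import fit_flip_decay

# a 15x NVJ-enriched cell, rendered with camera noise, quantified blind
spec = CellSpec(nucleus_center=(6.4, 6.4), nucleus_radius=1.05,
                vacuole_center=(9.0, 6.4), vacuole_radius=1.5,
                enrichment_factor=15.0)
img = render_cell(spec, ImagingConfig(rng_seed=1))
row = quantify_image(img.pixels[0].astype(float), img.ground_truth,
                     QuantConfig(), pixel_size=0.1)[0]
print(f"ratio = {row['ratio']:.2f}, partitioned = {row['partitioned']}")

# FLIP on a ring with NVJ binding: fitted NVJ residence halftime
params = RingParams(k_on=1.0, k_off=0.05)
_, flip = default_protocols(params)
fit = fit_flip_decay(flip_normalize(simulate(params, flip)["nvj"]))
print(fit.summary())
```

prints

```
ratio = 15.57, partitioned = True
One-phase exponential decay fit
----------------------------------------
n points        250
rate k          0.00390754 1/s (SE 2.89e-06)
halftime        177.387 s
amplitude       1.01695
offset          0
rmse            0.00221
converged       True
```

The recovered partitioning index (15.57) matches the 15× enrichment built
into the synthetic cell within the resolution of the raster and PSF, and the
cell is classified as partitioned. Under repeated distal bleaching, the
NVJ-bound pool decays with a ~177 s halftime — far slower than the ~28 s of
a freely diffusing pool on the same ring (`calibrate_demo()` reports both),
which is the signature of selective retention at the junction.

A command-line interface mirrors the library:
`nvjquant simulate-image`, `nvjquant quantify`, `nvjquant simulate-bleach`,
`nvjquant fit`, `nvjquant resume` (see `nvjquant --help`).

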