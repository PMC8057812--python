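# Methods

This note documents the models, parameter choices and numerical decisions
behind `nvjquant`, in the order the pipeline uses them.

## Synthetic imaging model

A cell is rendered from geometric ground truth. The nuclear-envelope (NE)
signal is a radial Gaussian around the nuclear circle,

    I(r, θ) = A(θ) · exp(−(r − R)² / 2σ_r²),

where the angular amplitude A(θ) equals `base_intensity` outside the NVJ
arc and `enrichment_factor × base_intensity` inside it. A soft radial
profile rather than a hard annulus was chosen because it is
convolution-friendly and matches the diffraction-limited appearance of a
membrane in widefield/confocal data. The NVJ arc is centred on the point of
the nuclear circle nearest the vacuole centre. A uniform disc of
`cytoplasm_intensity` (default 100 a.u., radius 1.8× the nuclear radius)
stands in for cytoplasmic haze; the vacuole channel is a filled disc used
only for context, never by quantification.

Optics and camera: isotropic Gaussian PSF (σ default 0.1 µm), Poisson noise
on expected counts, additive Gaussian read noise (σ default 5 a.u.), then
clipping and quantization to 16 bit. Rendering is bit-reproducible for a
fixed seed. Pixel size defaults to 0.1 µm/px and is config-exposed, since
instrument sampling varies.

Default geometry: nucleus radius 1.05 µm, NVJ arc halfwidth 1.0 rad
(≈ 2.1 µm of NE), reflecting the expansion of the junction to roughly 2 µm
of nucleus–vacuole apposition under glucose restriction. The arc halfwidth
also keeps the enrichment step more than two blur lengths away from the
scan line at the arc centre, so the background-subtraction filter treats
the two NE crossings symmetrically; with narrower arcs the index acquires a
positive bias of up to ~15% because the subtracted background under the
bright peak is attenuated by the nearby enrichment boundary while the dim
peak's is not. This bias is a property of the unsharp-mask procedure, not
of the ratio itself.

## Partitioning index

Processing follows the standard Fiji workflow: background subtraction as
`image − Gaussian(image, σ = 5 px)` with negatives clamped to zero (the
behaviour of unsigned-integer arithmetic in Fiji), then line scans of
default length 1.5 µm, five pixels wide, perpendicular-averaged with
bilinear interpolation, across the NE at the NVJ and at the antipodal
point. The AUC is the plain sum of the profile times the sample spacing —
no further baseline is applied because none is part of the standard
procedure. The index is AUC(NVJ)/AUC(opposite); classification uses a
strict `> 2.0`, so a tie at the threshold is *not* partitioned.

Two readings of the published blur parameter exist ("sigma (radius) =
5.0"); the dominant convention — Gaussian σ of 5 px — is the default and
the value is config-exposed rather than guessed silently. Two separate
scan lines (NVJ-side and antipodal) are used rather than one diameter scan,
which avoids integrating nucleoplasm signal between the crossings.

What passing tests show: on synthetic cells the pipeline recovers a 15×
enrichment within 10%, is exactly scale-invariant, monotone in enrichment,
and produces no false positives over 100 noisy unenriched cells. What they
do not show: robustness to out-of-focus light, mCherry bleed-through,
misplaced scan lines, or irregular nuclear shapes — real images carry all
of these, and the generator does not emulate them.

## FRAP/FLIP normalization

Double normalization corrects the bleached-ROI signal for monitoring loss:

    I_norm(t) = (I_wc(pre) / I_wc(t)) · (I_roi(t) / I_roi(pre)).

Full normalization is implemented as min–max rescaling of the
double-normalized curve between its pre-bleach and bleach values,
v_full = (v − v_bleach)/(v_pre − v_bleach), which is the only reading
consistent with the stated endpoint convention (pre → 1, bleach → 0); the
published formula's denominator is ambiguous about whether its intensities
are raw or normalized. FLIP normalization is simply
I(t)/I(pre-bleach); the whole-cell channel is ignored.

## Halftime fitting

One-phase exponentials with the bleach frame as time origin:
association y = Y∞(1 − e^(−kt′)) for FRAP recovery; decay
y = y₀e^(−kt′) + c for FLIP, with the floor c fixed at 0 by default (an
optional free offset is available behind a flag, but halftimes are the
reported quantity and a free floor trades off against the rate on
truncated movies). FLIP fits use acquisition frames from the first bleach
onward; bleach pulses are instantaneous events, not data points.

Fits are deterministic: k is initialized from a log-linear regression on
the exponentially transformed curve, the amplitude/plateau from endpoint
values, and bounded least squares (k ∈ [10⁻⁶, 10³] s⁻¹) refines them — no
random restarts. A rate pinned at a bound, or an optimizer failure, is
reported as `converged = False` with a message, never as a silent number.
Monte-Carlo recovery (200 replicates, Gaussian noise σ = 0.02 on a 50-frame
movie) places the median fitted halftime within 5% of truth.

## Ring simulator

Geometry is a periodic 1-D ring of circumference 6.4 µm (nucleus radius
≈ 1.02 µm) — 1-D because FRAP/FLIP observables are ROI-integrated totals,
which a ring captures at a fraction of the cost of a 2-D membrane; ROI
areas (0.77 µm² bleach spot → 0.99 µm arc) are carried as metadata. Free
molecules diffuse with D = 0.45 µm²/s (an ER/NE membrane-protein scale);
inside the 1.2 µm NVJ domain they bind at `k_on` and release at `k_off`,
and the bound pool does not diffuse — the minimal mechanism for selective
retention. The initial state is the binding equilibrium, so pre-bleach
frames are stationary.

Numerics: operator splitting between explicit finite-difference diffusion
and an exact local update of the linear binding exchange (relaxation toward
the site equilibrium with rate k_on + k_off). The time step is chosen
automatically below 0.8× the diffusion stability bound 0.5Δx²/D and below
0.2/(k_on + k_off); a user-supplied step violating stability is rejected
with the bound in the message. ROIs, the binding domain and bleach spots
use partial-volume weights, so edge cells contribute fractionally; this
makes ROI traces converge smoothly under grid refinement (doubling
`n_sites` from the default 128 moves traces by ≪ 1%) and keeps bleached
mass independent of the grid. Bleaching is instantaneous multiplicative
survival (default 0.1) since the 100 ms dwell is short against the 500 ms
frame interval. Mass is conserved to machine precision without bleaching,
and the no-binding FRAP recovery matches the spectral (Fourier-mode)
solution of ring diffusion to better than 1%.

Protocol timing: the published FLIP cycle description (~2.5 s of imaging
per cycle) is inconsistent with 50 cycles spanning 300 s, so cycles are
padded to a 6.0 s period (pre frame, bleach at +0.25 s, four post frames to
+2.0 s, then dead time) with a terminal frame at 300 s. The FRAP bleach
sits at 0.25 s, between the pre-bleach frame at 0 and the first post-bleach
frame at 0.5 s.

`calibrate_demo` runs the default FLIP schedule on two documented parameter
sets — with binding (k_on = 1 s⁻¹, k_off = 0.05 s⁻¹) and without — and fits
the NVJ-trace decays. The retained pool's halftime (~177 s) exceeds 100 s
and the free pool's (~28 s) sits at the tens-of-seconds scale set by the
bleach-cycle rate; the parameters were chosen once on physical grounds to
demonstrate that ordering, not fitted to any measured cell, and the
simulator makes no claim about in vivo D, k_on or k_off.

## Growth resumption and KS

Resumption curves are empirical CDFs of budding times after glucose
replenishment; cells that never bud within the observation window (4 h)
are censored — they stay in every denominator and never enter a numerator.
The KS comparison requires uncensored samples, so censored cells are
excluded from it and their counts reported alongside D and p. The
statistic is computed by a sorted-merge ECDF walk; the p-value uses the
asymptotic Kolmogorov series 2Σ(−1)^(j−1)e^(−2j²λ²) (≥ 25 terms, summed to
convergence) with the standard effective-sample-size correction
λ = (√nₑ + 0.12 + 0.11/√nₑ)·D. Exact small-sample p-values are out of
scope; under the null at n = m = 100 the observed rejection rate at
α = 0.05 is within 2 points of nominal.

## Problem sizes

Tests run the simulator mostly at 64 grid sites (Δx = 0.1 µm), the
refinement check at 128 vs 256, partitioning recovery on single 128×128
cells and one 10-cell field, 200 fit replicates for the Monte-Carlo study,
and 1000 KS null replicates — sizes at which every check completes in
seconds while the discretization error remains far below the tolerances
being asserted.

## Known limitations

- The generator's cells are circles with a single arc-shaped NVJ; no
  z-dimension, no focus drift, no bleed-through, no segmentation errors.
- The ring model has a single binding site class and no bleaching during
  acquisition frames (only at bleach events).
- FLIP halftimes from truncated movies underestimate slow residence times;
  no correction is attempted (the fitted value is reported as-is).
- The KS p-value is asymptotic; for very small groups it is approximate.
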