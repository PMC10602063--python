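# iscatflow

Computational pipeline for a label-free optofluidic single-particle
imaging platform: from raw camera frames of an interferometric-scattering
(holographic) microscope to localized single-particle contrasts,
surface-defect and binding densities, binding-kinetics curves, and
multiplexed extracellular-vesicle (EV) surface-biomarker fingerprints.
A synthetic holographic-scene generator with full ground truth stands in
for the instrument and the microfluidic chip, so every stage of the
analysis is testable against exact truth.

## The problem

Label-free surface assays detect nanoparticles (EVs, liposomes, protein
aggregates, gold nanoparticles) as diffraction-limited spots whose signed
**contrast** — the fractional deviation of a pixel from the local
background reflectivity, (I − I_bg)/I_bg — encodes particle size and
refractive index. On a supported-lipid-bilayer (SLB) sensor inside a
microfluidic channel, immunocaptured particles must be counted against a
background of substrate roughness and bilayer defects. The pipeline
implements the platform's full computational chain:

1. **Preprocessing** — normalise counts to the robust background level,
   divide by a flat field (pixel-wise median of ≥ 60 frames at distinct
   positions), subtract a 17-px spatial median to remove out-of-focus
   structure, and stitch raster scans by phase correlation.
2. **Detection** — global noise from the median absolute deviation
   (× 1.4826), a local RMS noise map over 65×65 windows restricted to
   pixels within 2.5× the global scale, an SNR image (both polarities),
   candidates as 8-connected groups of pixels with SNR ≥ 4 holding ≥ 3
   such pixels in some 3×3 window, sub-pixel centres by the
   radial-symmetry-centres algorithm, and signed + integrated contrast
   per spot.
3. **Quantification** — classify localisations as background
   (|contrast| ≤ 7.5×10⁻³) vs signal, and report densities in counts per
   100 μm² with Poisson errors.
4. **Kinetics** — time series, steady-state detection (trailing-window
   relative slope), zero-intercept dose-response linear range,
   along-channel segment profiles with depletion-length fits, and
   fold-changes with Poisson-bootstrap CIs.
5. **Fingerprinting** — per-marker densities normalised to the isotype
   control (IgG1), positivity calls at control mean + k·CV, and the
   Spearman correlation between median contrast magnitude and density.
6. **Assay calculators** — closed-form FOV/irradiance/packing arithmetic,
   bilayer anchor-site densities, reagent molarities, effective
   capture-probe concentration, and the two-plate Péclet/Damköhler
   transport analysis.

## Worked example

Simulate a channel binding EVs at 2×10¹⁰ particles/mL and locate steady
state:

```python
from iscatflow import (KineticScenario, simulate_binding_timelapse,
                       timelapse_to_series, detect_steady_state)

scn = KineticScenario(concentration=2e10, duration_h=12.0,
                      frame_interval_h=0.5)
tl = simulate_binding_timelapse(scn, area_um2=2e5, seed=2)
ss = detect_steady_state(timelapse_to_series(tl))
print(f"steady state reached at t = {ss.t_ss_h:.1f} h, "
      f"plateau = {ss.plateau_density:.1f} EVs per 100 um^2")
```

prints

```
steady state reached at t = 7.5 h, plateau = 198.0 EVs per 100 um^2
```

— the channel plateaus inside the 5–9 h window expected at this
concentration and saturates just below the 200 per 100 μm² surface
capacity. A three-replicate fingerprint of a CaOV3-like EV population
(tetraspanins high, CD326 ≫ HE4 > CA125, isotype control null):

```python
from iscatflow import (caov3_like_scenario, simulate_fingerprint_scenario,
                       density_record_from_counts, build_fingerprint,
                       call_positive)

recs = {}
for rep in range(3):
    tls = simulate_fingerprint_scenario(caov3_like_scenario(),
                                        duration_h=5.0, seed=10 + rep)
    for m, t in tls.items():
        recs.setdefault(m, []).append(density_record_from_counts(
            t.n_events, t.area_um2, channel_id=m))
table = call_positive(build_fingerprint(recs))
print(table[["marker", "density", "normalized", "positive"]]
      .round(2).to_string(index=False))
```

prints

```
marker  density  normalized  positive
  IgG1     1.50        1.00     False
   CD9   135.57       90.40      True
  CD63   106.18       70.80      True
  CD81   149.73       99.84      True
 CD326   127.03       84.71      True
   HE4    45.37       30.25      True
 CA125    15.84       10.56      True
```

`density` is in counts per 100 μm², `normalized` divides by the grand
mean of the control channel, and `positive` applies the
control-mean + 3·CV rule. All six biomarkers are called positive and the
CD326 ≫ HE4 > CA125 ordering of the ground truth survives the counting
statistics.

The same chain runs from the shell on TIFF scans:

```sh
iscatflow simulate --out run0 --seed 3 --n-signal 20   # synthetic chip
iscatflow process --input-dir run0 --output-dir run0/out
iscatflow calc --k-on 1e6                              # assay arithmetic
```

`process` writes `localisations.csv` (sub-pixel positions, signed
contrast, SNR per spot) and `densities.csv`; `kinetics` and
`fingerprint` subcommands run the corresponding downstream analyses.

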