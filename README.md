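# organoidscreen

Multi-parametric 3D image analysis of organoid drug responses, built as a
tested, reusable pipeline with a synthetic-screen generator, so the whole
chain runs without patient data.

Patient-derived colorectal-cancer organoids are screened in multi-well
plates: each well is imaged as a two-channel confocal z-stack (Hoechst
nuclei + phalloidin F-actin, 25 sections at 10 µm), and drug effect shows
up as morphology — organoids shrink, lumens collapse, nuclei become
sparse, debris appears. This package quantifies that response:

1. **simulate** — renders ground-truth-labelled synthetic screens:
   spherical epithelial shells with concentric lumens and shell-bound
   nuclei, whose morphology shifts with dose through a Hill model
   θ(d) = E_max·dⁿ/(dⁿ + EC50ⁿ), on a 9-point 2-fold dilution plate with
   8 replicate wells and DMSO controls.
2. **segmentation** — maximum-intensity projection per channel, combined
   two-channel Otsu foreground, watershed separation, organoid-local lumen
   detection, nucleus detection, and removal of out-of-focus and
   border-clipped objects.
3. **morphometry** — ~700 aggregated per-well feature columns: counts,
   areas, solidity, skeleton branching, intensity statistics for the
   organoid/lumen/nucleus masks, aggregated mean/median/SD/sum over the
   organoids of each well.
4. **phenoscore** — selects the top-10 features discriminating DMSO
   controls from high-dose wells (PCA on class centroids in z-space) and
   scores every well by the Euclidean distance

       D = sqrt( Σ_f ((x_f − μ_f)/σ_f − c_f)² )

   to the standardized control centroid: the phenotypic fingerprint
   distance.
5. **doseresponse** — fits the four-parameter logistic
   r(d) = bottom + (top − bottom)/(1 + (EC50/d)^hill) to per-well
   distances (or percent viability), reports EC50 ± a fit/"No fit"
   decision, plus percent-of-DMSO viability normalization, ΔΔCt fold
   changes and the culture-derivation rate.

## Worked example

The numbered scripts under `analysis/` run a small demo screen (two
compounds with true EC50s of 2 nM and 36 nM, 3 replicate wells, 128×128
frames) end to end:

```bash
cd analysis
python 01_simulate_screen.py   # TIFF stacks + layout to scratch/demo_plate
python 02_segment_plate.py     # label masks + parent-map CSV
python 03_extract_features.py  # wide per-well feature table
python 04_train_and_score.py   # top-10 selection + distances per compound
python 05_fit_dose_response.py # 4PL fits
```

The final script prints, for this seed:

```
C1: EC50 1.5 nM (hill 0.90, r2 0.99)
C2: EC50 25.6 nM (hill 1.06, r2 0.99)
```

— the fitted EC50s recover the generator's 2 nM and 36 nM ground truth
(within the sampling error of 3-replicate wells), and the per-condition
summary written by step 04 shows control wells at distance ≈ 2 versus
≈ 85 at the top dose, i.e. a large phenotypic window. Tables land in
`results/`, regenerable image stacks in `scratch/`.

## Layout

```
src/organoidscreen/   library: simulate, segmentation, morphometry,
                      phenoscore, doseresponse, pipeline
analysis/             numbered demo-screen drivers
tests/                pytest suite (unit, property, end-to-end)
docs/methods.md       model, parameters, and design notes
```
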