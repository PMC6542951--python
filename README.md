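# flairseg

Automatic segmentation of sub-acute ischemic stroke lesions from
single-channel FLAIR MRI, for researchers who need lesion volumes as a
trial endpoint from follow-up imaging where FLAIR is often the only
sequence available.

The method is a two-stage classifier:

1. **Bayesian initialization on Gabor textures.** Each axial slice is
   decomposed with a multi-window 2-D Gabor filter bank
   (Gaussian windows σ_r modulated at octave-matched frequencies); every
   brain voxel's coefficient-modulus vector `I_i^G` is classified
   lesion / non-lesion by the MAP rule
   `P(C_i | I_i^G) ∝ P(I_i^G | C_i) P(C_i)` with full-covariance
   Gaussian class models.
2. **Customized 4-class MRF.** Labels C_i ∈ {CSF, GM, WM, Les} minimize

   ```
   U(C_i|I) = −log P(I_i|C_i) − log P(T_i|C_i) − log P(C_i)
              − Σ_{j∈N_i} log P(ΔI_ij|C_i,C_j) + α Σ_{k∋i} m(C_k)
   ```

   combining intensity, texture, neighborhood intensity differences and
   learned clique label-configuration potentials m over 2–4-voxel
   cliques of an anisotropic neighborhood (8 in-plane + adjacent-slice
   neighbors; α = in-plane / through-plane spacing ratio). Inference is
   asynchronous iterated conditional modes (max 10 sweeps, seeded random
   visit order), initialized from stage 1, with provably non-increasing
   total energy.

Intensity standardization (histogram-quartile landmarks → [0, 1]),
a pluggable bias-field correction, evaluation metrics (Dice, PPV,
sensitivity, ASD, Hausdorff, volumes, Spearman, small-lesion TP/FP
counting) and a seeded synthetic FLAIR phantom generator are included,
so the whole pipeline is testable without clinical data. See
`docs/methods.md` for the full model description.

## Worked example

Leave-one-out evaluation on a six-case synthetic cohort (each case is a
~310 mL schematic brain with one textured lesion of ~9–16 mL, three
white-matter-hyperintensity confounders, bias field and noise):

```python
import flairseg as fs

cases = fs.generate_cohort(6, fs.PhantomConfig(), seed=1)
result = fs.run_loocv(cases, fs.RunConfig(seed=1))
print(result.aggregate.round(3))
```

prints

```
dice                 0.970
ppv                  0.944
sensitivity          0.998
asd_mm               0.765
hd_mm               29.193
vol_manual_ml       13.172
vol_auto_ml         13.884
dice_sd              0.014
n_cases              6.000
spearman_volumes     1.000
```

i.e. the held-out lesions are recovered with mean Dice 0.97, sub-voxel
mean surface distance (0.77 mm at 2 mm in-plane spacing), near-perfect
volume rank agreement, and a slight (+5%) volumetric over-segmentation.
The Hausdorff distance is dominated by occasional small false-positive
components far from the lesion (see the limitations section of the
methods note).

The same flow is available from the shell:

```bash
flairseg phantom --n 6 --seed 1 --out-dir cases/
flairseg loocv --n 6 --seed 1 --out-dir results/
flairseg segment --flair case_flair.nii.gz \
    --priors csf.nii.gz --priors gm.nii.gz --priors wm.nii.gz \
    --bayes bayes.yaml --mrf mrf.yaml --seed 1 --out lesion.nii.gz
```

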