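# strokesem

Quantifying how much preexisting white-matter damage — rather than the acute
infarct itself — explains cognitive state after a mild-to-moderate stroke or
TIA. The package implements the full measurement-and-modeling chain as a
tested library with synthetic data generators, so every stage runs and is
validated without any clinical data:

1. **Synthetic subjects** — multimodal 3-D phantoms (FLAIR, DWI b0/b1000, a
   15-direction diffusion series) with planted white-matter lesions (WML) and
   acute ischemic lesions of known geometry, plus simulated cohort tables
   drawn from a user-specified path model.
2. **DTI maps** — per-voxel diffusion tensor by ordinary least squares on
   log-signals; FA, MD, axial (Da = λ₁) and radial (Dr = (λ₂+λ₃)/2)
   diffusivity maps, with MD = (Da + 2·Dr)/3 holding exactly.
3. **Tissue segmentation** — two-cluster FLAIR split into parenchyma vs
   CSF/hyperintensity, lesion candidates strictly above mean + 2 SD of the
   parenchymal reference, acute-vs-chronic split by DWI conjunction, and a
   normal-appearing white matter (NAWM) mask at FA > 0.2; absolute volumes
   (mm³), volumes relative to intracranial volume (ICV), and per-tissue
   diffusivity means.
4. **Integrity factor** — the first principal component of the per-subject
   NAWM eigenvalues (λ₁, λ₂, λ₃), oriented so higher = more diffusivity =
   worse integrity.
5. **Path analysis** — from-scratch recursive SEM: implied covariance
   Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ, maximum-likelihood fit of
   F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p with analytic gradients,
   χ² = (n−1)F, and CFI/GFI/AGFI/RMSEA fit indices. Two competing models are
   built in: Model 1 routes the acute ischemic lesion volume (ILV) into
   cognition (WML → ILV → cognition); Model 2 drops ILV.
6. **Statistical battery** — log-transformed lesion volumes, Pearson/Spearman
   correlation matrices at a strict p < 0.005, unadjusted-then-multiple
   standardized regression, ANOVA by infarct location, and the
   lesion-presence t-test with WML-volume-adjusted ANCOVA.

## Worked example

```python
import strokesem as sk

spec = sk.PhantomSpec(
    grid_shape=(40, 40, 32), voxel_size=(2, 2, 2),
    lesions=(sk.Lesion("wml", (30, 20, 16), 6.0),
             sk.Lesion("ischemic", (20, 10, 16), 5.0)),
    seed=1,
)
phantom = sk.make_phantom(spec)
tensor = sk.fit_tensor(phantom.dwi_series, phantom.brain_mask)
maps = sk.diffusivity_maps(tensor)
seg = sk.segment_subject(phantom.flair, phantom.dwi_b1000, maps, phantom.brain_mask)
print(sk.summarize_tissues(seg, maps)[["volume_mm3", "relative_volume_pct", "mean_md"]])
```

prints (volumes in mm³, relative volumes in % of ICV, MD in mm²/s):

```
                 volume_mm3  relative_volume_pct   mean_md
tissue
csf_other            3712.0             2.269171  0.002902
parenchyma_band    158240.0            96.733177  0.000826
wml                   984.0             0.601526  0.001223
ischemic              648.0             0.396127  0.000351
nawm                94944.0            58.039906  0.000843
```

The WML mean diffusivity 0.0012 mm²/s and the NAWM 0.00084 mm²/s follow
directly from the planted eigenvalue profiles (1.6, 1.1, 0.97)·10⁻³ and
(1.2, 0.78, 0.55)·10⁻³ mm²/s; every planted lesion voxel is recovered on this
noiseless phantom.

The analysis drivers under `analysis/` run the full study flow — simulate a
142-subject cohort, push 12 phantom subjects through the imaging chain, fit
and compare both path models, and run the supporting statistics:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_imaging_pipeline.py
python analysis/03_path_models.py
python analysis/04_stats_battery.py
```

On the default seeds the comparison prefers Model 2 (no ILV path): CFI 0.915
vs 0.728, GFI 0.974 vs 0.935, with the ILV→cognition standardized coefficient
estimated at −0.005 — the acute lesion volume adds nothing once WML burden
and NAWM integrity are in the model.

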