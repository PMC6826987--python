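# fuzzyfuse

Multimodal brain-tissue quantification and one-class classification:
a hybrid fuzzy–genetic–possibilistic segmentation chain for paired
anatomical (MRI-like) and functional (PET-like) images, possibilistic
fusion of the per-tissue maps, a decision stage (labels, partial
volumes, tissue volumetry, synthesis image), and a support vector data
description (SVDD) classifier with divide-and-conquer training —
validated end to end on synthetic phantoms with known ground truth.

## Who this is for

Researchers building computer-aided-diagnosis pipelines on
co-registered multimodal brain images, who need (a) tissue maps for
CSF, grey matter and white matter that are robust to noise and scanner
intensity inhomogeneity, (b) a principled way to combine an anatomical
and a functional channel, and (c) a one-class classifier that models
the control population and rejects outliers. No clinical data ships
with the package: a phantom module generates image pairs with known
mixing fractions, bias fields and noise levels, so every stage is
testable quantitatively.

## The model

**Tissue modelling** is a three-step hybrid per modality:

1. *Bias-corrected fuzzy c-means (BCFCM)* minimises

   J = Σᵢⱼ uᵢⱼᵐ ‖xⱼ − βⱼ − bᵢ‖² + (α/N_R) Σᵢⱼ uᵢⱼᵐ Σ_{k∈N(j)} ‖xₖ − βₖ − bᵢ‖²

   over memberships U (column-stochastic), centroids B and a smooth
   additive bias field β, with a neighbourhood regulariser of weight α.
   The estimated β is subtracted from the image before the later
   stages — correcting intensity inhomogeneity is the point of this
   step, not just seeding the next one.
2. *Genetic refinement*: a small population of BCFCM centroid sets is
   evolved (fitness = within-cluster dispersion about cluster gravity
   centres, one-point crossover, Gaussian mutation, elitism); the
   fittest chromosome initialises step 3.
3. *Possibilistic-fuzzy c-means (PFCM)* produces relative memberships
   uᵢⱼ, absolute typicalities tᵢⱼ = 1/(1 + (b‖xⱼ−bᵢ‖²/γᵢ)^{1/(η−1)})
   and centroids weighted by a·uᵐ + b·tᵎ. The typicality rows,
   reshaped to the grid, are the per-tissue possibility maps π_T.

**Fusion** combines π_T from the two modalities with context-dependent
operators steered by the agreement h = 1 − mean|π₁ − π₂|, e.g. the
default FOP4: π_fus = max( min(π₁,π₂)/h, min(max(π₁,π₂), 1−h) ).
CSF always passes through from the anatomical channel, since the
functional channel carries no reliable CSF signal.

**Decision**: labels by the maximum-possibility rule, partial volumes
p_T = π_T / Σπ, volumetry (soft and hard volumes in mm³), and a
synthesis image v = Σ_T b_T p_T(v) that redistributes the mean
functional activity b_T at anatomical resolution.

**Classification**: SVDD encloses the control cohort's feature vectors
in a minimum-volume kernel hypersphere (dual: max Σαᵢ K(xᵢ,xᵢ) −
Σαᵢαⱼ K(xᵢ,xⱼ) s.t. Σα = 1, 0 ≤ α ≤ C); a subject is accepted when
its kernel distance to the centre is at most the radius R. Grid search
selects (σ, C); k-means divide-and-conquer training cuts the QP cost
from O(N³) to about k·O((N/k)³).

**Evaluation**: Tanimoto coefficient TC = v_ART/(v_AT + v_RT − v_ART)
and Jaccard overlap for segmentation; sensitivity, specificity,
accuracy, ROC/AUC and an equal-error rate for classification, with a
10× stratified 70/30 resampling harness.

## Worked example

```python
import fuzzyfuse as ff

spec = ff.PhantomSpec(shape=(48, 48), snr_noise=0.05, seed=11)
sample = ff.generate_phantom(spec)
cfg = ff.PipelineConfig(ga=ff.GaConfig(pop_size=6, generations=10), seed=0)
res = ff.run_full(sample.anat, sample.func, cfg)

print({t: round(h, 3) for t, h in res.fused.h_per_tissue.items()})
print(res.report.table.to_string(index=False))
print({t: round(ff.tanimoto(res.labels.labels, sample.truth_labels, i), 3)
       for i, t in enumerate(ff.TISSUES)})
```

prints

```
{'CSF': 0.906, 'GM': 0.951, 'WM': 0.88}
tissue  voxel_count  soft_volume_mm3  hard_volume_mm3
   CSF          209       533.579708            209.0
    GM          579       711.911575            579.0
    WM         1516      1058.508716           1516.0
{'CSF': 0.919, 'GM': 0.941, 'WM': 0.988}
```

The agreement values h show the two channels agree most about grey
matter; the volume table integrates partial-volume fractions (soft)
and counts argmax labels (hard); the per-tissue Tanimoto coefficients
compare the fused labelling against the phantom's ground truth — at
5% noise the boundaries blur slightly (partial-volume voxels), white
matter is recovered almost perfectly.

A CLI mirrors the stages:

```bash
fuzzyfuse phantom --out ph/ --shape 64 64 --noise 0.05 --seed 1
fuzzyfuse segment ph/anat.nii --out seg_a/ --seed 1
fuzzyfuse segment ph/func.nii --modality functional --out seg_f/ --seed 1
fuzzyfuse fuse --anat-dir seg_a/ --func-dir seg_f/ --out fused/
fuzzyfuse decide --fused-dir fused/ --centroids seg_f/centroids.json --out dec/
fuzzyfuse evaluate --auto dec/labels.nii --ref ph/truth_labels.nii --out overlap.csv
```

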