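# mtlmorph

Longitudinal morphometry of the medial temporal lobe (MTL) for studies of
early Alzheimer's disease: per-structure volumetric atrophy rates, large
deformation diffeomorphic metric mapping (LDDMM) with varifold surface
matching, laminar thickness of the entorhinal/transentorhinal cortex
(ERC/TEC) from normal-constrained flows, subregional amygdala mapping
against a high-field-style atlas, and tau-PET SUVR quantification.

The package is aimed at neuroimaging researchers who want these estimators
as tested, composable library code. Cohorts of the kind this pipeline
analyzes (serial 3T T1 MRI with MTL segmentations, coregistered tau PET) are
restricted-access, so the package ships a first-class synthetic-phantom
module that generates label volumes, laminar shells, subregion phantoms and
PET volumes with analytically known ground truth; every estimator is
validated against those phantoms.

## The estimators

**Atrophy rate.** For a structure with volumes `V(t_k)` at ages `t_k`, the
annualized rate is the OLS slope `dV/dt` (mm^3/yr), also expressed as
percent of baseline per year. Outlier scans are removed first: a timepoint
is excluded when its volume deviates from the subject's mean by more than
2.5 cohort-level standard deviations for that region.

**LDDMM.** Deformations are geodesic flows of point momenta under a Gaussian
reproducing-kernel Hilbert space metric, minimizing

    E(v) = lambda * int ||v_t||_V^2 dt + D_varifold(phi . S, T)

where the fidelity `D_varifold` compares surfaces through face centroids and
area-weighted normals with a Gaussian spatial kernel and the sign-invariant
Binet orientation kernel. Gradients are exact hand-derived adjoint passes;
no autodiff framework is required.

**Laminar thickness.** The inner ERC/TEC boundary is registered to the outer
boundary with momenta constrained to the surface normals; each vertex's
flow-line length is its thickness, summarized by the median (the 50% point
of the vertex CDF) and fitted over age to a thinning rate in %/yr.

**Subregion mapping.** A two-stage deformation carries an amygdala atlas
(BMA/BLA/CMA/LA/PA) to each subject and timepoint: joint alignment of all
timepoints, a subject midpoint template from the averaged initial momenta,
then volume LDDMM to every timepoint, with subregion labels riding through
the maps — so the subregions partition the deformed amygdala exactly.

**SUVR.** ROI mean tracer concentration normalized by the cerebellar
gray-matter reference mean, with interhemispheric consistency summaries and
OLS association of SUVR against atrophy rate (95% CI band).

## Worked example

The numbered scripts under `analysis/` run the full demo study on the
synthetic cohort (2 groups x 5 subjects, 3 scans each over 4 years):

```sh
python analysis/01_simulate_cohort.py      # writes results/demo/
python analysis/02_volumetry_rates.py
python analysis/03_laminar_thickness.py
python analysis/04_amygdala_subregions.py
python analysis/05_pet_suvr.py
```

`02_volumetry_rates.py` prints the pooled group-mean atrophy rates (%/yr):

```
Pooled group-mean atrophy rates (%/yr):
group    MCI  control
region
AMY     2.19     1.36
ERC     3.91     2.80
HIPP    0.54    -0.09
```

The generative regimes were control (ERC 2.90, AMY 1.26, HIPP 0.01) and MCI
(ERC 4.03, AMY 2.22, HIPP 0.70): the fitted means recover them to within
sampling error of 5 subjects per group, and the ordering
ERC > amygdala > hippocampus — the signature of early-stage MTL
degeneration — is preserved in both groups.

Library use mirrors the scripts:

```python
from mtlmorph.containers import TriMesh
from mtlmorph.thickness import compute_thickness

inner, outer = TriMesh.icosphere(3, 10.0), TriMesh.icosphere(3, 12.5)
tf = compute_thickness(inner, outer)
print(tf.summary_median)   # 2.4999 (analytic shell thickness: 2.5 mm)
```

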