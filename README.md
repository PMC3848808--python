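# lvatlas

Statistical shape atlases register corresponding anatomical locations of the
left ventricle (LV) across subjects, enabling population-level comparison of
regional wall shape and motion from cardiovascular MR.  When cohorts are
imaged with different cine protocols — steady-state free precession (SSFP)
versus gradient-recalled echo (GRE) — a systematic, regionally varying shape
bias contaminates such comparisons: SSFP yields larger cavity volumes and
smaller LV mass than GRE, with the strongest local differences in the apical
endocardium and around the basal ring.

`lvatlas` implements an atlas-based correction of this protocol bias for
researchers pooling multi-study CMR shape data.  Every LV is represented as a
pair of radial surfaces λ(u, v) in prolate spheroidal coordinates, controlled
by nodal shape parameters on a tensor-spline grid.  Given a training set of
subjects imaged with *both* protocols, each shape parameter x is corrected by
the per-parameter maximum-likelihood **z-score transform**

```
x_SSFP' = (x_GRE − μ_GRE) / σ_GRE · σ_SSFP + μ_SSFP
```

where (μ_GRE, σ_GRE) and (μ_SSFP, σ_SSFP) are the ML-estimated Gaussian
moments of that parameter over the two training populations.  The corrected
GRE population reproduces the SSFP mean *and* spread of every parameter
exactly, so downstream statistics see GRE-derived hearts as if they had been
imaged with SSFP.  Six alternative regression families (intercept-only,
slope+intercept, slope-only, identity-slope+intercept, per-node multivariate,
global pseudo-inverse) are provided for comparison, along with:

- surface sampling at arbitrary resolution (default 33×33 = 1,089 registered
  points per surface), cavity volume / LV mass by divergence-theorem
  integration, and AHA 17-segment labelling;
- a calibrated synthetic paired-cohort generator (no patient data are
  distributed) reproducing published healthy-population global indices and
  protocol biases;
- leave-one-out validation (volume/mass errors, residual surface bias RMS),
  training-size curves, and a seven-way transform-family comparison;
- unequal-variance Hotelling T² maps and LGE-graded segment statistics for
  cohort comparisons, exportable as ASCII VTK/PLY meshes.

## Worked example

Correct a synthetic paired cohort of 46 volunteers and validate by
leave-one-out:

```python
from lvatlas import (default_population_model, generate_paired_cohort,
                     leave_one_out, precorrection_report)

pop = default_population_model()                 # calibrated population
cohort = generate_paired_cohort(pop, n=46, seed=7)

pre = precorrection_report(cohort).summary()     # raw GRE vs measured SSFP
post = leave_one_out(cohort, "mle_zscore").summary()

print(f"pre:  EDV error {pre['edv_error_mean']:+.1f} ml, "
      f"surface RMS ED {pre['surface_rms_ed']:.2f} mm")
print(f"post: EDV error {post['edv_error_mean']:+.2f} ml, "
      f"surface RMS ED {post['surface_rms_ed']:.4f} mm")
```

which prints

```
pre:  EDV error -7.9 ml, surface RMS ED 0.86 mm
post: EDV error -0.01 ml, surface RMS ED 0.0007 mm
```

Before correction the GRE-derived end-diastolic volume underestimates the
SSFP measurement by 7.9 ml on average and the registered surfaces carry a
0.86 mm population-level bias; after the z-score correction the held-out
volume bias is a few hundredths of a millilitre and the residual surface
bias is below a micrometre on this idealized cohort.  The same pipeline is
available from the shell:

```bash
lvatlas simulate --n 46 --seed 7 --out pairs.csv
lvatlas fit-transform --kind mle_zscore --frame ED --in pairs.csv --out T.json
lvatlas validate-loo --kind mle_zscore --in pairs.csv --out report/
```

The estimator follows scikit-learn conventions
(`ProtocolBiasCorrector(kind="mle_zscore").fit(X_gre, X_ssfp).transform(X)`)
and composes with sklearn pipelines and model selection.

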