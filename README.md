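# collagensig

Collagen-architecture quantification for second-harmonic-generation (SHG)
microscopy, and a collagen *signature* for predicting central lymph node
metastasis (CLNM) risk from the tumor microenvironment.

## The problem

In papillary thyroid carcinoma, deciding whether to dissect the central
neck compartment hinges on predicting occult nodal metastasis, and the
usual clinicopathological factors (tumor size, location, capsular invasion)
discriminate poorly on their own. Stromal collagen remodeling — crosslinking,
loss of fiber alignment, changes in texture — is a candidate structural
biomarker visible in label-free SHG images of the invasive margin. This
package implements that idea end to end, for anyone who wants to build or
stress-test such a signature:

1. **Quantify** each 1000 um x 1000 um ROI with a fixed vocabulary of 142
   features: 8 morphological (area, fiber number/length/width/straightness,
   crosslink density and spacing, arrangement), 6 intensity statistics, and
   128 textural (GLCM contrast/correlation/energy/uniformity at 5 distances
   x 4 angles; Gabor response mean/variance at 4 scales x 6 orientations).
   Patient values average 5 ROIs.
2. **Compress** to a scalar signature: z-score with training-cohort
   parameters, then LASSO logistic regression with lambda chosen by 5-fold
   cross-validated binomial deviance; the signature is
   `intercept + sum_i coef_i z_i` over the selected features.
3. **Integrate** with clinical covariates in a multivariate logistic model
   presented as a nomogram (points re-parameterization, probability
   identical to the logistic model).
4. **Evaluate**: Mann-Whitney AUC / C-index with 1000-resample bootstrap
   CIs, DeLong model comparison, Youden-thresholded sensitivity /
   specificity / PPV / NPV / accuracy, quantile-binned calibration, and
   decision-curve analysis.

No SHG cohort is distributed, so the package ships a synthetic generator
(`collagensig.simulate`) that renders SHG-like fiber images and whole
cohorts with known ground truth; all tests and the reproduction script run
against it. See `docs/methods.md` for the model details and what the
synthetic data does and does not emulate.

## Worked example

```python
import numpy as np
import collagensig as cs

# one synthetic ROI and its feature vector
img, truth = cs.simulate_fiber_image(cs.FiberFieldParams(), seed=7)
fv = cs.extract_feature_vector(img)
print(len(fv.values))                      # 142
print(round(fv["morph.crosslink_density"], 1))   # 1556.1 junctions / mm^2
print(round(fv["morph.arrangement"], 3))         # 0.469 (0 = aligned)

# full protocol on a synthetic cohort
cfg = cs.PipelineConfig(seed=5, n_patients=40, image_size_px=64,
                        bootstrap_B=200)
res = cs.run_pipeline(cfg, "runs/demo")
rep = res.reports["test"]
print(round(rep.auc, 3))                         # 0.933  integrated model
print(round(rep.extras["clinical_auc"], 3))      # 0.283  clinical-only
print(res.signature_model.selected_features_[:3])
# ['morph.length', 'morph.straightness', 'morph.crosslink_density']
```

The first block renders a 512 x 512 SHG-like field (bright curvilinear
fibers, junctions, Gaussian noise) and measures it: 1556 junctions per mm^2
of collagen and an arrangement (orientation-dispersion) of 0.47 for a
moderately aligned field. The second block runs the whole protocol on a
small 40-patient cohort — simulate, extract 142 features per ROI, average 5
ROIs per patient, split 6:4, fit the signature on training patients only,
fit integrated and clinical-only models, evaluate on the held-out cohort —
and shows the integrated model beating the clinical-only model (at this toy
size the test cohort is only 16 patients, hence the noisy clinical AUC; the
reproduction script below runs the full 350-patient design).

The same flow is available from a shell:

```bash
collagensig run-all --seed 5 --out runs/demo   # full protocol
collagensig report --run-dir runs/demo         # headline numbers
```

with subcommands `simulate`, `extract`, `fit-signature`, `fit-model` and
`evaluate` for the individual stages.

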