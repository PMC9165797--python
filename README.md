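# pollenmorph

Synthetic pollen-grain morphometrics for discriminating *Leptospermum
scoparium* s.l. (mānuka) from *Kunzea* spp. (kānuka) pollen — the species
pair whose pollen is routinely lumped together in New Zealand
melissopalynology even though mānuka honey commands a premium.

The pollen of the two genera looks nearly identical under a light
microscope: both are isopolar, oblate, tricolporate grains, triangular in
polar view and flattened-oval in equatorial view. They differ statistically
in size (equatorial diameter E = 19.08 ± 1.28 μm for *Leptospermum* vs
16.30 ± 0.95 μm for *Kunzea*), in amb-side curvature (concave vs
straight-to-slightly-convex), and in exine texture (scabrate vs psilate).
`pollenmorph` turns those descriptions into a fully ground-truthed simulator
of automated dark-field captures and re-implements the downstream analysis
chain used with automated palynology instruments:

- **synthetic grains** — parametric amb model (circular-arc sides with
  sagitta = curvature × side length, tangent apex fillets), dark-field
  raster rendering with band-limited exine speckle, degraded (poor-focus)
  grains, ground-truth manifests;
- **morphometry** — the 7 core shape/size features (area, maximum Feret
  diameter, elongation, compactness = 4πA/P², solidity, Heywood
  circularity, hydraulic radius) computed exactly from the contour, a
  frozen set of 43 texture/extra-shape features from the raster, and the
  manual measurement protocol (E and P with 0.3125 μm graticule rounding);
- **QC** — the compactness < 0.55 exclusion rule and polar/equatorial view
  partitioning;
- **statistics** — genus size summaries (1-s.d./2-s.d. ranges),
  correlation PCA with deterministic sign convention, 2-D
  highest-posterior-density envelopes of ordination scores;
- **discrimination** — 99-iteration randomised 80:20 SVM cross-validation
  (RBF kernel, per-split standardization), the 1-s.d. size rule, and
  maximum-likelihood / EM estimation of the *Leptospermum* proportion in a
  mixed sample from its E distribution:
  f(e) = w·N(e | μ_L, σ_L²) + (1 − w)·N(e | μ_K, σ_K²).

## Worked example

```python
import pollenmorph as pm

config = pm.CohortConfig(profiles={"leptospermum": 600, "kunzea": 200},
                         view_mix=1.0, seed=11)
features = pm.build_feature_table(config)        # 50 features per grain
kept, qc = pm.compactness_filter(features)       # drop poorly focused grains
report = pm.svm_cv(kept[list(pm.FEATURE_COLUMNS)], kept["taxon"],
                   pm.CVConfig(n_iter=25, seed=1))
print(qc.n_discarded, round(report.mean_accuracy, 1))
```

which prints

```
37 97.5
```

37 of 800 grains (4.6%) fall below the compactness threshold and are
discarded, and the SVM separates the remaining grains with a mean test-set
accuracy of ~97% (against a 75% majority-class baseline). The narrated
scripts in `examples/` walk through each capability — simulation and manual
measurement, QC + ordination, SVM discrimination, and the size rule /
mixture estimator; e.g. `examples/04_size_rule_and_mixture.py` recovers a
70:30 mixture as 0.716 with a 95% bootstrap CI of (0.680, 0.751).

A thin CLI mirrors the pipeline stages:

```bash
pollenmorph simulate --out run/ --seed 1
pollenmorph qc --features run/features.csv
pollenmorph classify --features run/features.csv --feature-set all50 --views polar
pollenmorph run --out run/   # end to end
```

## Layout

```
src/pollenmorph/   profiles, sampling, shapes, render, texture, morphometry,
                   cohort, qc, ordination, classify, mixture, io, pipeline,
                   plotting, cli
examples/          one narrated script per capability
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model, parameter and calibration notes
```
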