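# tonescale

Tools for evaluating skin-tone labeling schemes for dermatology image
datasets. AI melanoma classifiers underperform on darker skin, and fixing
that requires skin-tone labels — but the scales used to produce those
labels differ in kind: Fitzpatrick Skin Type (FST) classifies
*photosensitivity* (I always burns … VI never burns), the Monk Skin Tone
scale (MST) has 10 visual shades, the Pantone SkinTone Guide has 138
physical swatches, and a colorimeter measures CIELAB color objectively.
`tonescale` implements the statistical machinery to compare them, for
researchers auditing labeling protocols or classifier fairness:

* **Color extraction** — per-channel median RGB of an image patch, the
  sRGB → linear → XYZ → CIELAB chain, and the individual typology angle
  ITA = arctan((L\* − 50)/b\*)·180/π, with explicit handling of neutral
  (degenerate) chromaticity.
* **Agreement** — linear-weighted Cohen's κ for ordinal scales, ICC(2,1)
  for repeated continuous measurements, paired t-tests, chi-squared
  independence, per-class concordance, per-anatomic-site heatmap tables.
* **Dispersion** — how tightly each scale's categories cluster in the 2-D
  (L\*, b\*) colorimeter space: Davies-Bouldin index (DBI, lower = tighter)
  and mean silhouette (RSI, singleton classes contribute +1).
* **Crowd aggregation** — trailing-accuracy qualification (top 80% of
  users) and the ≥70%-of-≥3-reads / >12-read-plurality majority rule.
* **Fairness** — two-sample Kolmogorov-Smirnov statistics between
  per-class malignancy-score distributions, percentile ranks, and mean KS
  as a function of ordinal class distance Δ.
* **Synthetic study generator** — a seeded, fully configurable cohort
  (FST-balanced recruitment, class-conditional CIELAB color model, ordinal
  rater noise, colorimeter triplicates, lighting-mode biases, a skill-
  heterogeneous crowd, class-dependent score distributions) with known
  ground truth, so every estimator is testable by parameter recovery.

## Worked example

Generate a synthetic study and run all four analyses:

```bash
tonescale all --seed 1 --out results/
```

or from Python:

```python
from tonescale.synthetic_study import StudyConfig, generate
from tonescale import pipeline

study = generate(StudyConfig(master_seed=1))
res = pipeline.run_all(study.sites, study.images, study.patches,
                       study.crowd, study.scores, seed=1)

kap = res["inperson"]["mst_kappa"].set_index("group")
print("MST inter-rater kappa (all sites):", round(float(kap.loc["all", "kappa"]), 3))
print("Colorimeter ITA ICC:",
      round(float(res["inperson"]["colorimeter_ita_icc"].set_index("group").loc["all", "icc"]), 3))
print("DBI fst/mst/pantone:",
      [round(res["dispersion"][s].dbi, 2) for s in ("fst", "mst", "pantone")])
print("Crowd concordance %:", round(res["photo"]["crowd_concordance"].overall, 1))
```

prints

```
MST inter-rater kappa (all sites): 0.898
Colorimeter ITA ICC: 1.0
DBI fst/mst/pantone: [4.38, 2.18, 7.72]
Crowd concordance %: 60.2
```

Read: the two simulated raters agree substantially on MST (κ 0.90, set by
the generator's 70%-exact noise kernel); triplicate colorimetry is nearly
noise-free (ICC ≈ 1.00); MST categories cluster tighter in objective color
space than FST (DBI 2.18 vs 4.38 — FST spans a wide color range by
construction, because photosensitivity is not color), with Pantone's many
small swatch classes most dispersed; and the simulated crowd, whose
annotators share per-image perception errors, matches in-person FST on 60%
of resolved images.

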