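# oarqa — knowledge-based QA of organ-at-risk contours

Radiotherapy treatment planning for head-and-neck cancer relies on dozens
of organ-at-risk (OAR) contours per patient. Reviewing them by hand is slow
and error-prone, and both manual contouring and auto-segmentation tools
produce failures: distorted boundaries, missing or extra volumes, stray
single-slice "ditzels", and grossly misplaced or mislabelled structures.

`oarqa` implements a knowledge-based outlier-detection framework that
learns, per OAR type, what an acceptable contour looks like from a corpus
of curated structure sets (one-class training) and flags contours that
deviate. It is aimed at medical-physics and auto-segmentation researchers
who want a transparent, fully scriptable QA baseline that runs on binary
masks — no patient data are required to exercise it, because the package
ships a synthetic head-and-neck phantom with a ground-truth error injector.

## The models

For a contour with feature vector **x** (20 features: centroid relative to
the brainstem, first/second principal-component orientation vectors,
volume, covariance-eigenvalue ratios λ₂/λ₁ and λ₃/λ₁, axis extents, Wadell
sphericity, and CT statistics under the mask):

* **z-score** — max over features of z = |x − μ| / σ;
* **Mahalanobis distance** — D(x) = (x − μ̂)ᵀ Σ⁻¹ (x − μ̂), with a
  shrinkage-regularised covariance;
* **autoencoder** — mean squared reconstruction error of a single
  hidden-layer network (20 → 18 → 20, sigmoid hidden, linear output, L2
  weight penalty 0.005, ≤ 7000 epochs) trained on feature z-scores;
* **contour-to-contour relationship (CCR)** — for configured organ pairs,
  the minimum surface distance (gamma-distributed in training) and the
  directional fractional overlap (beta-distributed) must fall inside the
  central-99% interval of the fitted distribution, expanded by 2 mm /
  0.02 and widened so no acceptable validation pair is flagged;
* **connectedness** — the number of 26-connected parts must not exceed a
  99.95% gamma quantile of the training counts.

Training rows straying more than 12 (unscaled) median absolute deviations
from any feature median are discarded first. The final verdict is the
logical OR of the three kinds of flags; single-model thresholds are tuned
on a validation split to maximise the combined balanced accuracy
(mean of sensitivity and specificity), and the test split always reuses
the validation thresholds.

## Worked example

```bash
python examples/03_train_and_classify.py
```

trains on 30 phantom structure sets and scores a held-out set; its output
(abridged):

```
trained 17 per-organ model bundles (29 contours each after MAD filtering)

acceptable set, score summary (lower = more typical):
       oar_type  zscore       md    ae  ccr_flag  conn_flag
          brain    1.19     8.98  0.09     False      False
           cord    2.27    88.55  0.78     False      False
submandibular_l    3.34   103.08  0.59     False      False
      parotid_l    1.69    32.87  0.23     False      False
        thyroid    1.48    33.00  0.26     False      False
      ...

same gland displaced by 30 mm:
       oar_type  zscore      md    ae  ccr_flag  conn_flag
submandibular_l   18.50 1871.79  41.6      True      False
```

The displaced gland scores roughly an order of magnitude higher on every
one-class metric and violates its pairwise bound against the mandible
(`ccr_flag True`) — exactly the behaviour a reviewer wants surfaced.
`examples/04_full_study.py` runs the complete 100-set study and prints the
per-model classification table for the validation and test splits.

A thin CLI mirrors the library: `oarqa simulate | extract-features |
train | classify | evaluate` (see `oarqa --help`).

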