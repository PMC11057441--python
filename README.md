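# dtboundary

One-class novelty detection with distance-to-boundary severity scoring for
cognitive-decline screening.

## The problem

Screening for mild cognitive impairment (MCI) and Alzheimer's-type dementia
(AD) from routine tabular data — cognitive and functional assessments (CFA),
blood panels, imaging volumes, demographics — faces a structural obstacle:
clinical cohorts are dominated by healthy controls (HC), and impaired cases
are scarce, heterogeneous, and expensive to label. Instead of training a
balanced classifier, `dtboundary` trains **one-class (novelty detection)
models on healthy controls only**. Whatever the model has not seen — any
systematic departure from the healthy pattern — is flagged, which makes the
approach natively robust to class imbalance and usable before impaired data
accumulate.

Class labels derive from the Clinical Dementia Rating: CDR 0 → HC,
CDR 0.5 → MCI, CDR ≥ 1 → AD.

## The method

Four interpretable detectors reduce to a common interface — a continuous
anomaly score `s(x)` (higher = more anomalous) plus a threshold `t`:

| method | score |
|---|---|
| KNN | ‖x − NN_k(x)‖ / ‖NN_k(x) − NN_k(NN_k(x))‖, the k-th-neighbor distance ratio |
| MoG | −log Σⱼ aⱼ N(x; μⱼ, Σⱼ), a Gaussian-mixture density fitted by EM |
| KMEANS | minₖ ‖x − μₖ‖, distance to the nearest of k centroids |
| SVDD | ‖φ(x) − c‖² − R², squared RBF-kernel distance to the minimum enclosing hypersphere, R² = 1 − 2Σᵢ aᵢK(xᵢ, xₛ) + Σᵢⱼ aᵢaⱼK(xᵢ, xⱼ) |

Thresholds are calibrated uniformly to a target **false rejection rate θ**
(default 0.1): `t` is the empirical (1 − θ) quantile of the training scores,
deliberately placing a θ fraction of training HC outside the boundary.

On top of any calibrated detector, the package:

* approximates the closed **decision boundary** {x : s(x) = t} as a point
  cloud with outward normals (ray root-finding from an interior anchor);
* computes the signed **distance to boundary (DtB)** of each subject —
  negative inside (healthy-like), positive outside — whose magnitude reads
  as a continuous severity axis;
* derives a quartile-based **severity scale** (HC / MCI / AD bands,
  normalized 0–10) from reference DtB values;
* evaluates everything under **nested 5×5 cross-validation** (inner loop:
  hyperparameter tuning on development HC + validation on held-out HC and
  all development non-HC; outer loop: untouched test folds) reporting
  sensitivity per impaired class, specificity for HC, and rank-based AUC
  with 95% CI;
* selects features by three filters (information gain ratio, |Pearson r|
  against the numeric CDR encoding, chi-square) aggregated with a
  Cross-Entropy Monte Carlo rank-aggregation search (weighted Spearman
  footrule), keeping the top ten.

Because the cohorts this design targets are access-restricted, a
first-class synthetic generator emulates their structure: bimodal HC on a
few informative CFA-like axes, MCI/AD shifted by Δ and 2Δ standard
deviations along a fixed direction (creating the characteristic HC/MCI
overlap), many class-independent noise features, and realistic imbalance
(600/260/160 by default).

## Worked example

```sh
dtboundary simulate --n-hc 120 --n-mci 40 --n-ad 30 --seed 5 --out-dir run/
dtboundary dtb --input run/cohort.csv --schema run/schema.yaml \
    --modality CFA --method mog --param 2 --seed 5 --out-dir run/
```

prints

```
mean DtB(HC) = -0.1638
mean DtB(MCI) = -0.0769
mean DtB(AD) = +0.1200
severity cuts: Q1_HC=-0.2384 Q3_HC=-0.1120 Q1_AD=0.0811 upper=0.4204
```

Healthy controls sit well inside the boundary (mean DtB −0.16), MCI
subjects straddle it, and AD subjects lie outside on average — the class
ordering the DtB score is designed to expose. The cuts are the HC and AD
quartiles of the reference DtB distribution; a subject's DtB above
`Q3_HC` falls in the AD band, between `Q1_AD` and `Q3_HC` in the (flagged,
HC-overlapping) MCI band, and `upper` (= Q3_AD + 1.5·IQR_AD) anchors 10 on
the 0–10 severity axis. The same library calls are available in Python;
`dtboundary evaluate` adds the nested cross-validated performance table.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch on a freshly simulated cohort: feature
selection (top ten of 33), the nested cross-validated evaluation of the
Gaussian-mixture detector at θ = 0.1, threshold calibration, boundary
construction on all HC, and per-subject DtB with the severity scale,
printing the resulting tables and writing the results JSON.
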