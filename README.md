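# lesionfuse

Dermoscopic melanoma classification for image-analysis researchers: a
double-deck CNN pipeline that triages samples by prediction confidence,
removes hair artefacts, extracts the clinical ABCDE features with the Total
Dermoscopy Score, detects the blue-white veil (BWV) and its shape-based
"flag" features, fuses handcrafted and CNN bottleneck features, and
evaluates seven tabular classifiers with a with/without-flag ablation.
A built-in synthetic lesion generator with pixel-level ground truth makes
every stage testable without downloading any dermoscopy archive.

## The method

**Confidence triage.** A small baseline CNN (four 3×3/15-filter conv blocks,
softmax head) classifies every sample and assigns the *confidence factor*
(intra-class variance score) `|p_benign − p_malignant|`. Samples with
confidence ≥ j = 0.999995 are accepted as easy and keep the baseline
prediction; the rest form the Baseline Separated Channel (BSC) of hard
samples, which are hair-cleaned, class-balanced by augmentation, and handed
to the second deck.

**Clinical scores.** After Otsu segmentation (darker class, 3×3 binary
dilation + erosion, largest component), with lesion area `a_aff`, frame
remainder `a_non_aff` and perimeter `p`:

    A = ((a_aff / a_non_aff)·100) / 10          asymmetry
    B = (p² / (4π·a_aff)) / 10                  border irregularity
    C = pooled HSV std / 10                     colour variegation
    D = √(4·a_aff / (10·p))                     diameter
    TDS = 1.3·A + 0.1·B + 0.5·C + 0.5·D

with TDS < 4.75 benign, 4.75–5.45 suspicious, > 5.45 malignant.

**Flag features.** A per-pixel grey-blue rule (or a depth-3 decision tree
over the F7 grey-blue and F13 pigment-network responses) plus a 3×3 majority
filter yields the BWV mask; `S_Flag1` is its area fraction of the lesion,
`S_Flag2 = mean/std` of the centroid-to-boundary distances (circularity) and
`S_Flag3 = 16π²M` (folded through its reciprocal), where
`M = (μ20·μ02 − μ11²)/μ00⁴` equals `1/(16π²)` exactly for ellipses. Circular
or elliptical veiled lesions (blue nevi) are thereby separated from
melanomas.

**Fusion and classification.** The second deck CNN (32/64/128/256 conv
filters, dense 256-128-64-32-2 sigmoid) supplies the 64-unit bottleneck
activations; fused vectors are `[64 bottleneck | A,B,C,D]` (68 features) or
extended with `E` and the three flags (72). Seven classifiers (MLP, gradient
boosting with 20 estimators, bagging over 10 trees, XGBoost with 100
estimators and η = 0.1, Gini decision tree, sigmoid-kernel SVM, logistic
regression) are evaluated with accuracy/precision/sensitivity/specificity,
ROC-AUC, stratified splits and k-fold cross-validation; the flag ablation
retrains each classifier with the flag columns removed and reports the
specificity change.

## Worked example

```python
import lesionfuse as lf

sample = lf.generate_lesion(lf.LesionSpec(seed=3, bwv_fraction=0.3,
                                          hair_count=5, n_tones=3,
                                          border_wave_amplitude=3))
cleaned, hair_mask = lf.remove_hair(sample.image)
seg = lf.segment_lesion(cleaned)
feats = lf.compute_abcde(cleaned, seg)
flags = lf.flag_features(cleaned, seg.full_mask)
print(f"A={feats.A:.2f} B={feats.B:.2f} C={feats.C:.3f} D={feats.D:.2f}")
print(f"TDS={feats.TDS:.2f} -> {lf.tds_classify(feats.TDS)}")
print(f"S_Flag1={flags.S_Flag1:.2f} S_Flag2={flags.S_Flag2:.2f} "
      f"S_Flag3={flags.S_Flag3:.2f}")
```

prints

```
A=4.11 B=0.16 C=0.023 D=1.96
TDS=6.34 -> malignant
S_Flag1=0.22 S_Flag2=6.35 S_Flag3=0.94
```

— a sizeable lesion (the asymmetry area-ratio score A dominates the TDS,
pushing it past the 5.45 malignant cut-off), slightly irregular in outline
(B above the 0.10 of a perfect disc), with roughly a fifth of its area under
a grey-blue veil.

The full pipeline is also available from the shell:

```bash
lesionfuse synth --n 100 --seed 1 --out data/
lesionfuse run --out runs/demo --seed 1
lesionfuse hair --in data/img.png --out clean.png --mask-out mask.png
```

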