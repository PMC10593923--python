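# stentexpand

Prediction of coronary stent under-expansion from pre-stent intravascular
OCT (IVOCT) segmentation masks.

Stents deployed in heavily calcified coronary lesions may fail to expand
fully; under-expanded stents are linked to thrombosis and in-stent
restenosis, and expansion cannot be meaningfully improved once the stent is
in place. Interventional cardiologists therefore want to know **before**
stenting whether a lesion needs plaque modification (e.g. atherectomy).
This package implements an IVOCT-based pipeline for that question: it takes
per-frame lumen/calcification label masks of a pre-stent pullback,
extracts geometric plaque features, trains regression models to predict the
post-stent lumen area along the vessel, and converts the prediction into a
stent-expansion verdict.

## The quantities involved

For each frame *f* of the stented segment the stent expansion index is

```
SEI(f) = post-stent lumen area(f) / mean(A_ref,prox, A_ref,dist) × 100 %
```

with the reference areas taken as the largest lumen adjacent to the stented
segment. The minimum over frames, **mSEI**, grades the deployment:
mSEI ≤ 80 % means *under-expanded* (the positive class), > 80 %
*well-expanded*.

The pipeline predicts the post-stent area curve from pre-stent features at
three granularities — per frame (24 features), per moving segment (odd
window lengths 3–63 frames; each feature summarized by 7 first-order
statistics, 168 aggregated columns), and per lesion (volumetric features) —
with LASSO feature ranking, a hand-picked 20-feature "calcification lesion
expansion" (CLE) subset, and linear / Gaussian-process / tree / SVR /
forest regressors under lesion-grouped five-fold cross-validation.

As a baseline it also implements the IVOCT calcium score (2 points for
maximum calcium angle > 180°, 1 point for maximum thickness > 0.5 mm,
1 point for calcium length > 5 mm; a total of 4 predicts poor expansion)
and a machine-learning variant trained on exactly those three
measurements.

Because the patient images behind this problem are not distributable, the
package ships a seeded synthetic lesion generator (`stentexpand.synth`)
that renders labeled pullbacks — stenotic tapering lumen, calcific deposits
of the three clinical phenotypes (eruptive nodule / protrusion / superficial
sheet), scattered spotty calcium — together with ground-truth post-stent
areas from a documented expansion-response model. All tests run on it;
see `docs/methods.md` for what it does and does not emulate.

## Worked example

```python
from stentexpand import (SyntheticConfig, generate_cohort, truth_msei,
                         calcium_score, score_label, sei, classify)
from stentexpand.fujino import fujino_lesion_features

cohort, truth = generate_cohort(SyntheticConfig.fast(n_lesions=4), seed=7)
print(truth[["lesion_id", "phenotype", "msei", "label"]].round(1).to_string(index=False))

p = cohort[0]
res = truth_msei(p)
print(f"lesion {p.lesion_id}: mSEI = {res.msei:.1f}% at frame {res.msei_frame} -> {res.label}")

f = fujino_lesion_features(p)
s = calcium_score(f["calc_max_arc_angle_lesion"], f["calc_max_thickness_lesion"], f["calc_length"])
print(f"calcium score -> {s.total} points ({score_label(s)})")
print(f"SEI example: post 5.0 mm2 vs refs 8.0/8.0 -> {sei(5.0, 8.0, 8.0):.1f}%")
```

prints

```
lesion_id phenotype  msei          label
     L000     sheet  96.5  well_expanded
     L001     sheet  91.8  well_expanded
     L002     sheet  90.3  well_expanded
     L003     sheet  68.5 under_expanded
lesion L000: mSEI = 96.5% at frame 67 -> well_expanded
calcium score -> 0 points (adequate)
SEI example: post 5.0 mm2 vs refs 8.0/8.0 -> 62.5%
```

Lesion L003 carries enough calcification that the restored lumen falls to
68.5 % of the reference caliber — an under-expanded stent; L000's sparse
sheet calcium (score 0) leaves expansion essentially unimpeded.

The same workflow is available from the shell:

```bash
stentexpand synth --seed 0 --n-lesions 110 --out run/data
stentexpand features --data run/data --mode segmental --window 31 --out run/feat
stentexpand train --features-dir run/feat --mode segmental --model gaussian_process \
                  --feature-set cle --seed 0 --out run/model
stentexpand predict --model run/model/model.pkl --data run/data --out run/pred
stentexpand evaluate --predictions run/pred/expansion.csv --out run/eval
stentexpand fujino --data run/data --out run/fujino
```

Each stage writes a manifest (config, seed, version, input hashes), so every
numeric output is reproducible from config + seed alone.

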