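# cvaffect

Automated coding of **positive and negative facial affect intensity** from
action-unit (AU) evidence time-series, with interpretable-ML analysis of
which AUs carry the signal.

Computer-vision AU detectors (FACET, OpenFace, ...) emit a signed per-frame
evidence score for each of ~20 facial action units. Human coders, in
contrast, rate whole recordings for positive and negative emotion intensity
on 1–7 Likert scales. `cvaffect` implements the full pipeline that connects
the two:

1. **Featurization** — each recording × AU evidence series becomes a
   *normalized AUC*: the trapezoidal area under the evidence curve over
   face-detected spans divided by total face-detected time (a time-weighted
   mean evidence level). Recordings with a face-undetected gap ≥ 1 s are
   excluded; a participant with ≥ 50% exclusions is dropped entirely.
2. **Rating model** — a random forest (ntrees = 500, mtry = ⌊p/3⌋) regresses
   the coder-panel mean rating on the 20 AU features, with train/test splits
   stratified within participant (66%/34%) and a repeated-split sensitivity
   analysis.
3. **Agreement statistics** — Pearson r with Fisher-z CIs and McGraw–Wong
   intraclass correlations from ANOVA mean squares: ICC(1) for model-vs-human
   item agreement, ICC(3) for coder panels and importance profiles, ICC(2)
   for subsampling reliability; all six model/unit variants implemented.
4. **Interpretation** — exact partial dependence (PD):
   PD(v) = meanᵢ f(xᵢ with x_s := v). Importance of an AU is the SD of its PD
   curve (equal to |β|·SD(grid) for a linear model); pairwise interaction
   importance is a two-direction conditional-SD statistic on the 2-D PD
   surface, enumerated over all 190 AU pairs. A numba tree-traversal kernel
   makes the exact computation fast enough to scan every pair of a 500-tree
   forest.
5. **Coder analysis** — per-coder model fits plus a randomization test for
   the minimum number of rated recordings needed to recover a coder's AU
   importance profile (ICC(2) vs the full-data profile as a function of
   subsample size).
6. **Synthetic study generator** — a fully specified generative model of the
   study design (125 participants × 42 recordings, 3 instruction conditions ×
   2 image valences, 30 Hz AR(1) evidence with occlusion gaps, a 3-coder
   panel with ~.9 reliability) with known ground-truth AU weights, so every
   stage is testable without any data download.

## Worked example

```python
import cvaffect as cv
from cvaffect.model import (ModelSpec, average_coder_ratings,
                            split_by_participant, train_rating_model,
                            predict_ratings)
from cvaffect.agreement import agreement_report
from cvaffect.interpret import pd_importance, pd_interaction_importance

cfg = cv.SimulationConfig(n_participants=30, seed=7)
recordings, truth, ratings = cv.simulate_study(cfg)
features, report = cv.featurize_recordings(recordings)
print(f"retained {report.n_retained} of {report.n_input} recordings")

outcome = average_coder_ratings(ratings, "positive").loc[features.index]
plan = split_by_participant(features, train_fraction=0.66, seed=1)
model = train_rating_model(features.loc[plan.train_ids],
                           outcome.loc[plan.train_ids], ModelSpec(), seed=2)
pred = predict_ratings(model, features.loc[plan.test_ids])
rep = agreement_report(pred, outcome.loc[plan.test_ids].to_numpy())
print(f"test r = {rep.pearson_r:.2f} [{rep.r_ci[0]:.2f}, {rep.r_ci[1]:.2f}], "
      f"ICC(1) = {rep.icc_value:.2f}  (n = {rep.n_items})")

full = train_rating_model(features, outcome, ModelSpec(), seed=2)
profile = pd_importance(full, features, seed=0)
print("top AUs:", ", ".join(profile.top(5)))
inter = pd_interaction_importance(full, features, seed=0)
for row in inter.top(2).itertuples():
    print(f"{row.feature_i} x {row.feature_j}: share {row.share:.1%}")
```

prints

```
retained 1107 of 1260 recordings
test r = 0.90 [0.88, 0.91], ICC(1) = 0.85  (n = 377)
top AUs: AU06, AU12, AU25, AU18, AU04
AU12 x AU18: share 17.7%
AU06 x AU18: share 11.6%
```

Reading the output: 153 of 1,260 simulated recordings were dropped by the
occlusion filter; on held-out recordings the forest's ratings correlate .90
with the coder-panel mean and agree absolutely at ICC(1) = .85; the smile
components AU6 (cheek raiser), AU12 (lip corner pull) and AU25 (lips part)
dominate positive-intensity importance, and the strongest of the 190 pairwise
interactions is AU12 × AU18 (lip pucker masking a smile) — exactly the
structure the generator planted.

## Command line

Each stage is also a subcommand (CSV in, CSV out):

```bash
cvaffect simulate --config sim.yaml --out data/ --seed 1
cvaffect featurize --in data/au_timeseries.csv --out features.csv \
         --gap-threshold 1.0 --participant-threshold 0.5
cvaffect train --features features.csv --ratings data/ratings.csv \
         --valence positive --ntrees 500 --seed 1 --model-out model.joblib
cvaffect evaluate --model model.joblib --features features.csv \
         --ratings data/ratings.csv
cvaffect interpret --model model.joblib --features features.csv --out interp/
cvaffect coder-curve --features features.csv --ratings data/ratings.csv \
         --coder 1 --valence positive --iterations 30 --seed 1 --out curve.csv
cvaffect run-all --config run.yaml --out results/   # the whole pipeline
```

`read_au_timeseries` accepts the native dialect written by `simulate` as well
as OpenFace-style columns (`timestamp`, `success`, `AUxx_r`).

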