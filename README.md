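# sfascreen

Structure–function-association (SFA) screening for cognitive decline:
can the mapping from regional brain morphometry to cognitive test
performance, learned separately in cognitively normal (CN), MCI and
dementia cohorts, tell the three groups apart in new subjects?

The package is written for biostatisticians and neuroimaging analysts
working with FreeSurfer-derived regional measures (ADNI-style tables or
raw `aseg.stats` / `?h.aparc.stats` files) and the standard dementia
battery: MMSE, ADAS-13, RAVLT immediate recall, TMT part B, DSST.

## The method

1. **SFA stamps.** For every (cohort *g*, test *t*, feature set) fit a
   ridge regression ŷ = b + wᵀz(x) with penalty α = 0.5 on z-scored
   features — volumes as bilaterally averaged % of total intracranial
   volume (VBM), cortical thickness and surface area (SBM).
2. **Min-residual voting.** For a new subject, each cohort's model
   predicts each test; the cohort with the smallest |ŷ_g − y| wins that
   test's vote, and the modal vote over the battery
   ({MMSE, ADAS-13, RAVLT} by default) is the screening label.
3. **Supporting analytics.** Per-cohort age trendlines with
   age×group slope interactions and trendline convergence ages;
   impurity-importance feature rankings over four tree ensembles;
   Pearson region–score correlation tables; MAE and MAE/range%
   evaluation under subject-grouped repeated k-fold CV.

Real cohort data of this kind is access-controlled, so the package
ships a calibrated generator: three synthetic cohorts whose score
means/SDs, age slopes, slope interactions, gray-matter atrophy rates and
late-life DSST/TMT trendline convergence are set to the published cohort
values, with known cohort-specific morphometry weights planted as ground
truth. See `docs/methods.md` for the generative model and its limits.

## Worked example

```python
import sfascreen as s

data = s.generate_cohorts(s.default_config(seed=1))   # 287/646/369 visits
cm = s.cross_validated_confusion(data, feature_set="SBM", n_folds=5, seed=1)
print(cm.counts)
print({k: round(float(v), 2) for k, v in cm.tpr_per_class.items()})
```

prints

```
           CN  MCI  Dementia
CN        270   15         2
MCI       123  447        76
Dementia   17   37       315
{'CN': 94.08, 'MCI': 69.2, 'Dementia': 85.37}
```

Rows are true cohorts, columns assigned labels, from subject-grouped
5-fold refits. Reading it: 94% of CN subjects are recognised by their
own SFA stamp and almost none are mislabelled demented; dementia
recovery is 85%; MCI — wedged between the two neighbouring classes on
every scale — is hardest at 69%, its errors splitting toward both
neighbours. The chance level under the exchangeable null is ~33% per
class.

The numbered drivers under `analysis/` run the full study sequence and
write their tables to `results/`:

```bash
python analysis/01_simulate_cohorts.py 1   # cohort descriptives + group tests
python analysis/02_age_trends.py 1         # trendlines, interactions, convergence
python analysis/03_fit_sfa_models.py 1     # MAE / MAE-range% per cohort x test x set
python analysis/04_rank_features.py 1      # importance rankings, region correlations
python analysis/05_screen_classify.py 1    # confusion matrices, TPR summary
```

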