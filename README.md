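# notchtsp

Pathway-constrained k-top-scoring-pairs (k-TSP) signature discovery for
predicting the response to neoadjuvant chemotherapy (NACT) in
triple-negative breast cancer, with bootstrap regularized-random-forest
feature selection, ROC/DeLong evaluation, and relapse-free-survival
association. The package ships the fixed **Notch 5-TSPs** classifier —
five gene pairs (*GARS* > *PDCD10*, *CCND1* > *FNDC3A*, *CMA1* > *PTHLH*,
*F2R* > *KLF4*, *PCDH7* > *TOX*) voting with a two-vote threshold — and
the complete machinery to re-derive such signatures on new cohorts.

## The method

Patients either achieve pathological complete response (pCR) or retain
residual disease (RD) after NACT. A top-scoring pair (u, d) classifies by
the *within-sample ordering* of two genes: the pair votes "RD" in sample
*s* iff x<sub>u,s</sub> > x<sub>d,s</sub>. Its discriminative value is the
switch score

> Δ(u, d) = P(x<sub>u</sub> > x<sub>d</sub> | RD) − P(x<sub>u</sub> > x<sub>d</sub> | pCR) ∈ [−1, 1],

which depends only on ranks, so the classifier is invariant to any
monotone per-sample normalization — a key robustness property across
microarray platforms.

Rather than searching all gene pairs, the search space is constrained to
a biological *mechanism*: the cross product of genes up-regulated by
Notch signalling with genes down-regulated by it (e.g. 189 × 120 =
22,680 candidate pairs after removing cross-listed symbols), Notch being
a known driver of chemoresistance in breast cancer. Discovery then runs:

1. **Preprocess** — Z-score each dataset separately, merge on common
   genes, and draw a covariate-balanced stratified 70/30 train/test split.
2. **Constrained search** — score every mechanism pair; keep pairs with
   Δ > 0, ranked by Δ and a secondary within-sample rank statistic.
3. **Feature selection** — refit a regularized random forest (RRF;
   regularization coefficient 0.5, candidate-feature fraction 0.1, class
   prior weights 1.0/0.6 for pCR/RD) on 100 bootstrap resamples of the
   training data and rank pairs by how often the forest uses them; the
   top 5 pairs form the final signature with vote threshold
   ceil(0.4·k) = 2.
4. **Evaluate** — AUC with DeLong confidence intervals and tests (vs 0.5
   and paired vs competing signatures refit as ridge logistic models),
   PR area, balanced accuracy, sensitivity, specificity, MCC.
5. **Survival** — dichotomize samples by the vote rule, compare
   relapse-free survival by Kaplan–Meier/log-rank and a multivariate Cox
   model (Efron ties).

Real GEO/METABRIC cohorts are not bundled; a first-class synthetic
generator (`notchtsp.synthetic_data`) produces cohorts with planted
rank-switching pairs, dataset batch structure, 2:1 class imbalance,
clinical covariates, and vote-linked survival, so every stage is
testable end to end.

## Worked example

```python
import notchtsp as nt

cfg = nt.SimConfig(seed=11)                     # n=300, 5 planted pairs
cohort, pheno, truth = nt.simulate_cohort(cfg)
z = nt.zscore_by_dataset(cohort)

mech = nt.fixture_mechanism(truth, extra_null_pairs=50)
labels = pheno.response()
scored = nt.constrained_search(z, labels, mech)
print(f"{len(scored)} candidate pairs with a positive switch score")

features = nt.pair_indicators(z, scored)
freq, sig = nt.bootstrap_frequency(
    features, labels.to_numpy(), nt.RRFConfig(seed=11), scored, B=100, top_k=5
)
print("signature:", ", ".join(f"{p.gene_up}>{p.gene_down}" for p in sig.pairs))

preds = nt.predict(z, sig)
report = nt.evaluate_predictions(preds, labels)
print(f"AUC {report.auc_roc:.3f} (95% CI {report.auc_ci_low:.3f}-{report.auc_ci_high:.3f})")
print(f"sensitivity {report.sensitivity:.3f}, specificity {report.specificity:.3f}, MCC {report.mcc:.3f}")
```

prints

```
27 candidate pairs with a positive switch score
signature: UP02>DN02, UP04>DN04, UP01>DN01, UP00>DN00, UP03>DN03
AUC 1.000 (95% CI 0.999-1.000)
sensitivity 1.000, specificity 0.910, MCC 0.933
```

All five planted pairs (`UP00>DN00` … `UP04>DN04`) are recovered from
among 50 decoy pairs — order within the top 5 varies with the bootstrap
seed — and the resulting voting classifier separates RD from pCR almost
perfectly, as expected at the generator's 0.9/0.1 switch probabilities.
The sensitivity/specificity asymmetry reflects the two-of-five vote
threshold, which favours catching RD (the clinically costly miss).

A shell interface mirrors the same stages
(`notchtsp simulate | build-mechanism | preprocess | train | select |
predict | evaluate | compare | survive`); see `notchtsp --help`.

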