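# afpdomains

Identify antifreeze proteins (AFPs) from their functional-domain
composition. AFPs — the proteins that let fish, insects, plants and
microbes survive subzero temperatures by binding ice — are structurally
too heterogeneous to recognise by sequence similarity alone. This package
instead encodes every protein as a binary vector over InterPro domain
accessions and learns which *domains* discriminate AFPs from non-AFPs.

The engine, for bioinformaticians with an InterProScan annotation table
and a label list:

1. **Encode** proteins as a sparse binary protein × domain matrix
   (proteins without any annotated domain are removed).
2. **Rank** domains by minimum-redundancy-maximum-relevance (mRMR):
   greedily pick the feature maximising
   `I(f, class) − mean_{s∈S} I(f, s)`, with `I` the plug-in discrete
   mutual information in bits.
3. **Select** by incremental feature selection (IFS): for each nested
   prefix F1 ⊂ F2 ⊂ … of the ranked list, cross-validate a 100-tree
   random forest (stratified 10-fold, pooled confusion counts) and score
   it by sensitivity, specificity, accuracy, and the Matthews correlation
   coefficient (MCC). The prefix with peak MCC — the balanced measure
   under heavy class imbalance — defines the optimum domain set and
   classifier.

## Worked example

Simulate a matrix with planted signal (10 informative domains among 1,030,
~4.5 % positives) and run the whole pipeline:

```sh
afpdomains simulate --outdir sim --seed 1
afpdomains all --matrix sim/matrix.tsv --outdir run --seed 1 \
    --top-n 20 --k-max 20
```

The run logs end with:

```
... afpdomains INFO optimum subset: k=20 MCC=0.9519 SN=0.9300 SP=0.9990 ACC=0.9957
... afpdomains INFO pipeline complete: optimum k=20 MCC=0.9519
```

meaning the IFS sweep peaked at the top-20 ranked domains: that forest
recovers 93.0 % of the planted positives (SN) while misclassifying 0.10 %
of negatives (1 − SP), and the balanced MCC of 0.952 reflects genuinely
recovered signal rather than the 95 % accuracy a constant all-negative
predictor would already achieve. `run/` contains the
matrix, the ranking TSV (`rank, column_index, domain_id, score, relevance,
redundancy`), the IFS curve (`k, SN, SP, ACC, MCC`), the optimum feature
list, the fitted model, and a manifest (config, seed, versions, input
checksums) from which the run is reproducible byte-for-byte.

The same machinery is available as scikit-learn estimators:

```python
from afpdomains import MRMRRanker, IFSRandomForest

clf = IFSRandomForest(top_n=20, k_max=20, random_state=1).fit(X, y)
clf.optimum_k_, clf.best_metrics_.MCC, clf.ifs_curve_
```

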