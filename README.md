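# rifs

Randomly re-started incremental feature selection (RIFS) for binary
classification of "large p, small n" feature matrices — e.g. transcriptome
profiles with tens of thousands of features and tens of samples.

Features are ranked by two-sample t-test significance. The unit search
`sIFS(k, D)` starts at rank *k* and grows a prefix of consecutively ranked
features, tolerating up to *D* consecutive strict decreases in cross-validated
accuracy before stopping (one decrease — the classical rule — quits too early
when a dip is followed by a larger rise). RIFS repeats the unit search from
many randomly drawn start ranks and keeps the best prefix found anywhere. This
recovers pairs of features that are individually near-null under univariate
tests but jointly discriminative, which no top-of-ranking filter can find.

Subsets are scored by stratified, randomly seeded k-fold cross-validation,
with accuracy maximized over a pluggable classifier set (default: SVM, KNN,
decision tree, Gaussian naive Bayes, logistic regression — scikit-learn
defaults; a fast numpy linear-discriminant plug-in `LDA` is available for
large search sweeps). Same-size filter baselines (t-test, ANOVA-F, rank-sum)
and a synthetic-data generator with planted marginal and joint signal are
included.

## Library quick start

```python
from rifs import RIFSConfig, SynergyPairSpec, SyntheticSpec, generate, rifs

ds, truth = generate(SyntheticSpec(
    n_features=2000, m_pos=30, m_neg=30,
    synergy_pairs=(SynergyPairSpec(),), seed=0))

cfg = RIFSConfig(start_pct=0.10, depth=4, classifiers=("LDA",))
result = rifs(ds, cfg)
print(result.selected_features, result.final_report.mAcc)
```

## CLI

```sh
# make a synthetic benchmark (matrix.csv, labels.csv, truth.json)
rifs generate --n-features 2000 --m-pos 30 --m-neg 30 --n-pairs 1 --out-dir data/

# select features; the positive class must be named explicitly
rifs run --matrix data/matrix.csv --labels data/labels.csv \
    --positive-label positive --classifiers LDA --out-dir out/

# same-size filter comparison and master-seed sweep
rifs compare   --matrix data/matrix.csv --labels data/labels.csv --positive-label positive --classifiers LDA
rifs seed-sweep --matrix data/matrix.csv --labels data/labels.csv --positive-label positive --classifiers LDA --sweep-seeds 0-9
```

The quick-start profile uses `--start-pct 0.05`; `--full-budget` restores the
tuned operating point (45% of the feature count as start ranks, expensive on
real-size matrices). Other defaults: `--depth 4`, `--folds 10`, report seeds
`0-19`, search seed `0`.

## Tests and acceptance report

```sh
python -m pytest -q                 # full suite; the planted-synergy
                                    # acceptance test takes ~10 min alone
python -m pytest -q --deselect tests/test_acceptance.py::test_criterion_5_planted_synergy_recovery

python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion (metric
identities, stopping-rule oracle, brute-force window equivalence, cross-method
ranking oracle, planted-synergy recovery over 100 generator seeds, depth
tolerance benefit, determinism/seed semantics). `scripts/acceptance.py` emits
an empty target object — there are no offline-reproducible numeric headline
targets, since the original evaluation datasets are external downloads — after
running an end-to-end smoke pipeline that fails loudly if the install is
broken.
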