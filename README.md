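# dls — discriminative local-subspace gene function prediction

`dls` predicts genes involved in a biological process of interest from
log-ratio gene-expression data. Instead of relying on global correlation,
it searches — for each known positive gene — a *local subspace*: the
subset of experimental comparisons on which that gene is strongly
co-expressed with the other positives and weakly co-expressed with the
negatives (an **expression signature**). Signatures are scored with a
bounded discriminativeness score (ESS), converted into genome-wide
predictions through a kernel-density Bayes classifier whose confidence
adapts per signature, and assembled into a directed, confidence-weighted
**discriminative co-expression network**. Because negative labels derived
from an ontology are noisy, an iterative **false-negatives discovery**
procedure identifies mislabeled negatives and refines the training set.

## What is in the package

| module | role |
| --- | --- |
| `dls.preprocess` | replicated raw intensities → paired log2-ratio (`X_LR`) and rank-product FDR (`X_FDR`) matrices; automatic control–test pair generation with redundancy filtering |
| `dls.ontology` | OBO-style DAG + GAF-style annotation parsing, upward propagation, positive/negative training-set derivation |
| `dls.signatures` | absolute-cosine co-expression, logistic soft threshold, ESS, the greedy `signfs` feature-subset search, bootstrap discard of suspect negatives |
| `dls.classify` | class-conditional Gaussian KDEs + Bayes rule → posterior confidence per (signature, gene) pair |
| `dls.network` | build/export the prediction network (TSV edge list, GraphML, SIF), node degrees |
| `dls.fnd` | iterative false-negative discovery and training-set refinement |
| `dls.evaluation` | stratified k-fold cross-validation (precision-weighted F-beta), hypergeometric enrichment, co-expression-network guilt-by-association baseline |
| `dls.synthetic` | planted-ground-truth generators (expression matrices, ontologies, noisy labels) used by the test suite |

## Command-line usage

All artifacts are plain tab-delimited text (matrices, labels, signatures,
predictions, networks) plus JSON/YAML sidecars for parameters.

```bash
# generate a synthetic dataset with planted signatures
dls synth --spec spec.yaml --out data/synth

# or preprocess raw intensity tables (one <id>.tsv + <id>.conditions.tsv per experiment)
dls preprocess --experiments raw/ --mode auto --max-redundancy 0.9 \
    --n-perm 100 --seed 1 --out data/expr

# derive training labels from an ontology + annotations
dls labels --obo go.obo --gaf annotations.tsv --term GO:0006950 \
    --p 0.05 --exclude-evidence IEA --out labels.tsv

# train signatures, predict, build the network
dls train   --dataset data/expr --labels labels.tsv --out model
dls predict --model model --dataset data/expr --labels labels.tsv \
    --confidence 0.9 --out predictions.tsv
dls network --predictions predictions.tsv --threshold 0.9 \
    --format graphml --out dcn.graphml
dls degrees --network dcn.tsv

# refine noisy negative labels
dls fnd --dataset data/expr --labels labels.tsv --max-iter 10 --out refined

# evaluate (dls | fnd-dls | cn baseline)
dls evaluate --dataset data/expr --labels labels.tsv --method dls \
    --folds 10 --repeats 3 --seed 1 --out report.tsv
dls enrich --predictions predictions.tsv --new-annotations new.txt \
    --universe universe.txt
```

A minimal YAML for `dls synth`:

```yaml
n_genes: 200
n_features: 60
groups:
  - {n_genes: 15, features: [0,1,2,3,4,5,6,7,8,9,10,11], strength: 2.0}
noise_sd: 0.2
n_planted_fns: 0
seed: 1
```

## Notes on conventions

- Fold changes are log base 2; the rank-product FDR merges separate up-
  and down-regulation analyses by the sign of the log ratio, and switches
  to exhaustive label enumeration whenever the number of distinct
  control/test assignments is at most 10,000 (making small tests exact).
- F-beta here is *precision*-weighted: `(1+β²)·P·R / (β²·R + P)` with
  β = 2 by default, so β > 1 favours accurate models over high-recall
  ones. This is the mirror image of the common recall-weighted form.
- The greedy signature search only ever adds features from the
  lowest-FDR fraction (default 20%) of all features for the gene under
  consideration; moves are best-improvement single-feature additions or
  removals with deterministic tie-breaking, so training is fully
  deterministic.
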