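# gsda — gene-set distance analysis

`gsda` tests whether the expression of a *gene set* is associated with a
phenotype — a quantitative measurement, a categorical label, or a censored
event time — using the bias-corrected **distance correlation t-test**. It is
a *self-contained*, model-free procedure: the p-value for a gene set depends
only on that set's genes and the endpoint, no regression model is fitted,
and no resampling is needed to obtain a p-value. Because it compares whole
pairwise-distance structures rather than per-gene locations, it detects
non-monotone and *differential-correlation* signals (gene pairs whose
correlation flips sign between phenotype groups with no mean shift) that
per-gene rank or regression tests cannot see.

It is aimed at statisticians and computational biologists screening
collections of gene sets (e.g. GMT pathway collections) against clinical or
experimental endpoints.

## The statistic

For `n` subjects, let `X*` be the `n × n` Euclidean distance matrix of the
gene-set expression submatrix and `Y*` the endpoint distance matrix. Each
matrix is **U-centered**,

```
ã_ij = a*_ij − (a*_i· + a*_·j)/(n−2) + a*_··/((n−1)(n−2)),    i ≠ j,
```

and the inner product `(Ã·B̃) = Σ_{i≠j} ã_ij b̃_ij / (n(n−3))` is an unbiased
estimator of squared distance covariance. The bias-corrected distance
correlation and its t-statistic are

```
r_d = (X̃·Ỹ) / √((X̃·X̃)(Ỹ·Ỹ)),      t_d = r_d/√(1−r_d²) · √ν,     ν = n(n−3)/2 − 1,
```

and under independence `t_d` is approximately t-distributed with ν degrees
of freedom. The package reports the two-sided p-value `2·P(T_ν > |t_d|)`
(see `docs/methods.md` for why), and verifies small p-values with a fast
permutation test that re-randomises subjects of the U-centered endpoint
matrix and recomputes only the inner products.

Endpoint distances: `|y_i − y_j|` for quantitative endpoints; the 0/1
indicator of different labels for categorical ones; and for censored event
times `(o_i, s_i)` (status 1 = event) the number of unique event times
falling between the pair's observation windows, counted from subjects that
actually had the event — a rank-like metric invariant to monotone time
transformations.

Beyond single-set tests the package provides FDR screening of whole
collections (Benjamini–Hochberg by default), backward-elimination search for
the *empirical driver* genes of a significant association (optionally
wrapped in a permutation test for selection-adjusted significance), and a
simulation harness for level/power studies.

## Worked example

Simulate a cohort of 100 subjects with a quantitative endpoint driven by a
latent variable that also drives 10 of 100 genes, and test one of the
gene sets containing planted signal:

```python
from gsda import GSDA, SimulationConfig, generate_dataset

cfg = SimulationConfig(collection="A", endpoint="quantitative",
                       association="simple", n=100, seed=7)
X, endpoint, truth = generate_dataset(cfg, 0)

model = GSDA(endpoint, X)
sets = {s.name: s for s in truth.collection}
res = model.fit(sets[truth.associated_sets[0]], permutations=10_000, seed=7)
print(res.summary())
```

```
     Gene-Set Distance Analysis
====================================
                            value
------------------------------------
Gene set                         A01
Genes tested                       9
No. subjects                     100
Distance correlation r_d    0.173363
t statistic                  12.2577
Degrees of freedom              4849
P (t-test, two-sided)    4.85055e-34
P (permutation, B=10000)   9.999e-05
------------------------------------
```

The t-test finds a strong association (r_d = 0.17, p ≈ 5e-34); the
permutation p-value is at its add-one floor 1/(B+1) ≈ 1e-4, confirming that
the significance is not an artifact of the t approximation. Backward
elimination (`model.drivers(...)`) then narrows the 9-gene set to the
planted driver gene `g054`, and `model.screen(truth.collection, ...)`
ranks all 60 sets with q-values — the ten sets containing planted genes
come out on top.

The same analyses run from the shell on TSV/GMT files:

```sh
gsda screen --expression expr.tsv --phenotype pheno.tsv --column logWBC \
            --gene-sets pathways.gmt --permutations 10000 --seed 1 --out screen.tsv
gsda drivers --expression expr.tsv --phenotype pheno.tsv --endpoint-type survival \
             --time-col efs_time --status-col efs_event \
             --gene-sets pathways.gmt --set-name KEGG_AML --out trace.tsv
gsda simulate --endpoint-type categorical --association null --n 50 \
              --reps 500 --seed 1 --out level.tsv
```

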