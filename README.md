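# fuzzpat — unsupervised fuzzy pattern discovery in gene expression data

`fuzzpat` discovers statistically significant high-order association
patterns in samples × genes expression tables **without class labels**.
It is aimed at transcriptomics datasets (bulk or single-cell, microarray
or counts) where tissue/condition annotation is missing, unreliable, or
deliberately held out, and at mixed-mode tables that combine continuous
expression levels with categorical covariates.

## The method

Write the data as `T` tuples over attributes `G = {G_1, …, G_N}` (genes).
The pipeline has five label-free stages and one optional labelled stage:

1. **Interdependence redundancy.** Every attribute pair is scored by
   `R(G_i : G_j) = I(G_i : G_j) / H(G_i : G_j)` — mutual information over
   joint entropy — a symmetric similarity in [0, 1] that is insensitive
   to the number of attribute states. Continuous attributes are first
   partitioned into `m = max(2, ⌊ln(|T|/α)⌋)` equal-frequency bins, with
   `α` (default 3) the rule-of-thumb minimum points per contingency cell.
2. **Attribute clustering (k-modes).** Attributes are partitioned into k
   disjoint clusters; each cluster is summarized by its *mode*, the
   member with maximal multiple interdependence redundancy
   `MR(G_i) = Σ_{j∈cluster} R(G_i : G_j)` — the most representative gene.
   k is selected by maximizing `SR`, the sum of the modes' MR.
3. **Fuzzification.** The crisp partition is softened into memberships
   `μ_r(G_i) ∝ R(G_i : G^r)^{1/(f−1)}` (rows sum to 1), so genes coupled
   to several groups can enter several clusters and patterns straddling
   crisp boundaries become discoverable. `f = 2` is linear
   normalization; `f → 1⁺` is winner-take-all (default `f = 1.5`).
4. **Mode-driven discretization.** In each fuzzy cluster the mode is cut
   into three maximum-entropy states L/N/H (lowly / normally / highly
   expressed); every other continuous member is discretized against the
   mode by class-dependent optimal discretization (OCDD): the cut set
   maximizing `R(discretized gene : mode states)`.
5. **Pattern discovery.** Treating each (gene, interval) assertion as a
   primary event, event sets from distinct attributes are tested against
   the independence model with the adjusted residual
   `d = (o − e)/√v`, `e = n·Πpᵢ`, `v = e·Π(1 − pᵢ)`; `|d| ≥ 1.96` marks
   95% significance. Duplicates rediscovered in several fuzzy clusters
   are merged.
6. **Rules and classification (optional, post hoc).** With labels
   restored *after* discretization, class-supporting patterns become
   rules weighted by the weight of evidence
   `WofE = log₂[P(antecedent|c) / P(antecedent|¬c)]` (Laplace-smoothed);
   a sample is assigned the class with the largest summed evidence.

## Worked example

The bundled generator builds a 1800 × 20 mixed-mode benchmark (5
categorical + 15 continuous attributes, three wired-in attribute groups
driven by A1, A13 and A6, five imposed classes, 25% of tuples replaced
by noise):

```python
import fuzzpat as fp
from fuzzpat.pipeline import run_pipeline, PipelineConfig, render_report

ds = fp.generate(seed=1)
cfg = PipelineConfig(k_min=2, k_max=6, restarts=10, max_order=3, seed=1)
res = run_pipeline(ds.table, cfg)
print(render_report(res, top=3))
```

prints

```
Attribute clusters (ranked by member MR)

 AC  mode      MR(mode)  members
  1  A6          0.3706  A6, A4, A5
  2  A1          0.6714  A1, A10, A11, A9, A7, A8, A12
  3  A13         1.0973  A13, A3, A14, A15, A16, A17, A20, A19, A18, A2

SR = 2.1392 at k = 3

Top 3 patterns (by |adjusted residual|)

  d=+118.76 o= 1124 e=   663.6  {A18=I3 & A19=I3 & A20=I2} [AC2]  Conf(P->C1)=0.37 ...
  d=+117.48 o= 1110 e=   645.6  {A16=I1 & A18=I3 & A20=I2} [AC2]  ...
  d=+117.47 o= 1121 e=   667.7  {A14=I1 & A18=I3 & A19=I3} [AC2]  ...

Top 3 rules (by weight of evidence)

  WofE=+6.8487 conf=0.97 sup= 306  if {A1=F & A20=I1 & A3=Z} then {C4}
  WofE=+6.6100 conf=0.98 sup= 386  if {A12=I3 & A14=I1 & A3=X} then {C1}
  WofE=+6.5200 conf=0.97 sup= 300  if {A11=I1 & A19=I2 & A3=Z} then {C4}
```

Model selection lands on the three wired-in groups with the intended
modes A1, A13, A6 purely from attribute interdependence. The top
patterns here happen to be discovered inside the *fuzzified* A1 cluster:
A14–A20 carry small but non-zero membership there, so their mutual
associations surface in that table too — exactly the overlap behaviour
fuzzification exists to expose. The rules recover the class structure
(e.g. A1=F together with low A20 pins class C4) even though no label was
used before rule scoring; `conf` is the fraction of antecedent-matching
samples in the consequent class.

The same stages are available as scikit-learn-style estimators
(`AttributeClusterer`, `WofEClassifier` with `fit`/`transform`/
`predict`/`get_params`) and from the shell:

```sh
fuzzpat synth --seed 7 -o synth.tsv
fuzzpat run synth.tsv --class-column class --seed 7 -o out/
```

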