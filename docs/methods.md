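# Methods

This note documents the models and procedures implemented in `moaclust`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and the known limitations.

## The protocol

The package predicts the point of the NF-κB cascade at which a compound
acts (ROS-mediated/any point, IKK inhibition, IκB-degradation inhibition
or activation, translocation inhibition, DNA binding) by nearest-cluster
label transfer.  A labelled training library is clustered by structural
similarity; clusters are annotated with their predominant interaction
class; a query compound receives the predominant label of its most
similar cluster, or abstains.  The working assumption is the similar
property principle; it is used as a general rule, and the abstention
machinery (predominance levels, minimum cluster sizes, similarity
threshold) exists precisely because the rule has exceptions.

Compounds whose point of interaction is unreported stay in the training
set and participate in clustering.  Two analysis modes control everything
downstream: *include-unknown* counts them in cluster sizes and label
denominators; *known-only* drops them from the accounting (never from the
clustering).  Cluster scoring against queries always uses all members —
a compound's structure is informative regardless of its annotation.

## Descriptors and similarity

Seven 2D descriptor sets are supported; molecules are RDKit graphs parsed
from SMILES with implicit hydrogens, so all counting descriptors operate
on heavy atoms.

* **ECFP4** — RDKit's sparse Morgan fingerprint at radius 2 (diameter 4):
  iterative neighbourhood hashing with deduplication, unfolded integer
  feature ids.  Unfolded ids avoid folding collisions, so Tanimoto
  similarity is exact on feature sets.  Two empty sets count as identical
  (similarity 1).
* **Property** — AlogP (Crippen atom-contribution), molecular weight,
  H-bond acceptors, H-bond donors, heavy-atom count, rotatable bonds,
  ring count (SSSR), aromatic rings, in that order.
* **BCUT** — per atom-weight scheme, the lowest and highest eigenvalue of
  the heavy-atom adjacency matrix with bond orders off-diagonal
  (aromatic = 1.5) and the atom weights on the diagonal.  Default scheme
  triple: atomic mass, Gasteiger partial charge (implicit-hydrogen charge
  folded into the heavy atom; NaN → 0), atomic polarizability from a
  built-in element table (unlisted elements default to 2.0 Å³).  Six
  values total; the schemes are configurable, including arbitrary
  callables.
* **GCUT** — as BCUT but with topological (bond-count) distances
  off-diagonal.  Disconnected structures use a per-fragment block matrix
  (cross-fragment entries 0).
* **Combined sets** (ECFP4+Property, BCUT+GCUT, GCUT+Property) — the
  unweighted arithmetic mean of their component similarities, the
  simplest defensible fusion.

Continuous blocks compare by `1 − mean |Δ|` after per-component min–max
scaling.  The scaling bounds come from the **training library only** and
are frozen before query scoring; out-of-range query values clamp into
[0, 1].  This keeps the measure bounded, monotone in distance and
parameter-free.  Zero-range components scale to a constant and contribute
zero difference.

## Clustering

*Selection.*  Maximal-dissimilarity (MaxMin) selection: the first
representative is a chosen seed compound; each next one minimizes its
maximum similarity to those already chosen, ties broken by input order.
The greedy representatives are nested — the first *n* picks of a long run
are the picks of every shorter run — so one O(N²) pass supports the whole
cluster-count grid.

*Assignment.*  Every compound joins its most similar representative; ties
go to the earlier representative in selection order, and representatives
always belong to their own cluster.

*Cluster-count selection.*  For n = 1..min(200, N/2) the average
self-similarity avg-s(n) is computed: the unweighted mean over clusters
of the mean pairwise within-cluster similarity, with singletons
contributing 1.0 (a lone molecule is perfectly self-similar; this biases
avg-s upward at large n and is deliberate and documented).  The selected
n is the one with the biggest decrease avg-s(n−1) − avg-s(n); when the
curve never decreases the same argmax (the smallest increase) is returned
with a warning.  The grid cap N/2 keeps the average cluster occupancy at
two or more compounds and scales the historical cap of 200 (chosen for
~400-compound training sets) down to small libraries.

*Cluster centre.*  The medoid: the member with maximal mean similarity to
its co-members (ties → first member).  A medoid is the only
member-valued centre compatible with fingerprint similarity.

*Partition comparison.*  Pair-based Tanimoto c/(a+b−c) where a and b
count co-clustered compound pairs in each partition and c the pairs
co-clustered in both; two all-singleton partitions count as identical.
When partitions cover different compound universes (different training
splits), the pipeline first restricts both to their common compounds.

### Known limitation: the biggest-drop rule on clean series data

On libraries composed of well-separated structural series — exactly what
the synthetic generator produces — cross-series fingerprint similarities
are mostly *exactly zero*.  Greedy MaxMin then covers one series per
step, every per-series cluster is pure, and avg-s(n) rises monotonically
with n.  The only material *decreases* occur when a structurally hybrid
compound (a dual-interaction compound built as the union of two series)
joins its parent series' freshly created cluster and dilutes it.  The
biggest-drop rule therefore stops at the first such contamination event —
typically n ≈ 20 on the default 460-compound library, although it
contains ~61 series.  The downstream consequence is *abstention, not
error*: mixed clusters rarely reach the 66.6% predominance level, so with
the selected n the protocol predicts for only about half of the queries
(those predictions are ~100% correct); with any cluster count at or above
the series count, accuracy over all queries is 96–100%.  The rule is kept
because it is the protocol's defining selection criterion, the curve and
the warning are exported so users can inspect the choice, and
`select_centers`/`partition` accept any n directly if a user prefers a
different criterion.

## Annotation

A cluster's profile counts each member's labels (multi-label compounds
increment every one of their labels, so fractions can sum above 1); the
denominator is the member count — total members or labelled members,
depending on the mode.  Two predominance notions are used:

* for **label transfer**: the unique maximal label whose fraction reaches
  the level; ties or a missed level yield no label (abstention);
* for **summaries**: the share of clusters where *some* label reaches the
  level, ties allowed — a 50/50 two-label cluster does have "at least
  50% of members with the same interaction" even though no single label
  can be transferred from it.

Levels are 0.5, exactly 2/3 (rendered 66.6%), and 0.75; level comparisons
use an absolute tolerance of 1e-9 so a fraction of 2/3 passes the level
however it was entered.  Size filters (minimum 1–5 members, sizes per
mode) are applied before percentages; when no cluster passes the filter
the percentage is reported as NaN, never 0.

## Prediction and baselines

Three nearest-cluster rules: most similar member, most similar medoid,
highest average member similarity; ties go to the lower cluster index.
A prediction is made only if (i) some cluster passes the size filter,
(ii) the winning score reaches the similarity threshold when one is set
(score ≥ 0.7 predicts; the comparison is inclusive), and (iii) the
winning cluster has a unique predominant label at the level.  Metrics
report both the strict headline (`pct_correct_all`, abstentions counted
incorrect) and `pct_correct_predicted` (over made predictions, NaN when
everything abstained), plus the number of predictions and of queries
passing the threshold.

The random baseline redraws, per repetition and query, a uniformly random
size-eligible cluster and applies the same predominance rule.  Alongside
the Monte-Carlo estimate the analytic expectation `Σ_l f(l)·q(l)` is
reported (f = fraction of eligible clusters predominant for label l,
q = fraction of queries carrying l), which makes tests deterministic.
Note that with one class near 46% of labelled compounds and ~50% of
queries, this baseline is floored near 25–40% whenever clusters are
coherent — a structural property of the class frequencies, not of the
method.  A second negative control, `shuffle_training_labels`, permutes
the label sets among labelled training compounds per split (clustering is
label-free, so partitions are unchanged); under it, accuracy collapses to
the random baseline within sampling error.

## The synthetic generator

The generator emulates the statistical shape of the curated NF-κB
library: class marginals ROS 14, translocation 7, DNA binding 60, IKK
inhibition 138, IκB-degradation inhibition 76, IκB-degradation activation
6 (dual-label compounds count toward both classes), 163 unknown-label
compounds, 4 dual-label compounds — 460 compounds total — organized into
structurally coherent analogue series so the similar-property principle
holds.  Interpretation choices:

* **Series size 8** by default: a typical published analogue-series
  scale, small enough that even the 6-compound class forms a coherent
  series.
* **Unknown-label compounds form their own series**, produced by a
  randomly chosen class's structure generator but carrying no label —
  emulating unstudied analogue series (in the real library the unknowns
  cluster into coherent series of their own) rather than uniform noise.
* **Dual-label compounds are structural hybrids** of one series from each
  of their two classes (feature-set union / single-bond-linked scaffolds)
  and members of both classes.

Fingerprint fidelity: each series has a prototype feature set of 48
random ids from a 2³¹ space (disjoint across series with overwhelming
probability); each member keeps each prototype feature with probability
1 − ε and gains Binomial(48, ε) fresh features; ε defaults to 0.05,
giving within-series Tanimoto ≈ 0.82 and cross-series ≈ 0.  SMILES
fidelity: 15 aromatic scaffold templates × fixed ring substituents define
a series; members enumerate one variable ring position over a 16-entry
substituent alphabet; every output parses.

What the generator does **not** emulate: the continuous, partially
overlapping similarity structure of real chemical space (real cross-series
similarities are graded, not zero), assay noise and label errors,
activity cliffs, salts/mixtures, stereochemistry.  Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
label transfer works when structure determines class; they do not certify
accuracy figures on real libraries, where cluster purity is far lower.

## Protocol orchestration

`run_protocol` sweeps (splits × descriptor sets × clustering seeds ×
prediction configurations).  Splits draw 60 labelled test compounds
(rejection-resampled until every interaction class is represented);
unlabelled compounds always train.  Five clustering seed compounds are
drawn once per split and shared across descriptor sets, recorded in the
manifest together with the config hash and every chosen n.  Aggregates
are means and standard deviations over the 25 (split × seed) runs per
descriptor set.  Everything is deterministic under a fixed RNG seed, and
re-running `report` reproduces byte-identical CSVs.

Problem sizes: the test-suite and the reproduction script exercise the
full 460-compound library in fingerprint space (where descriptor
computation is free) and 36–50-compound SMILES libraries for the
chemistry path — series structure, not library size, is what the
correctness of the machinery depends on.

## Numerical choices

* Similarity values are clipped into [0, 1] after averaging; matrix
  diagonals are set to exactly 1.
* All argmax/argmin tie-breaks take the first (lowest-index) candidate,
  matching the stated tie rules; numpy's `argmax`/`argmin` provide this.
* Level comparisons use a 1e-9 absolute tolerance (see Annotation).
* Gasteiger charges: NaN/inf → 0 before eigendecomposition; eigenvalues
  via `numpy.linalg.eigvalsh` (symmetric input, cannot fail).
* Random seeds derived from user seeds stay below 2³¹.

## Limitations

* Predictions are only as good as the structural neighbourhood: a query
  unlike anything in the training library is either abstained on (with a
  threshold) or matched to a structurally unrelated cluster (without).
  Scaffold-hopping representations are out of scope.
* The avg-s biggest-drop rule is fragile on cleanly separated series (see
  above); users clustering series-structured libraries should inspect the
  exported avg-s curve.
* The analytic random baseline is class-frequency dependent and high for
  imbalanced libraries; comparisons should use the matched baseline
  reported per configuration, not an absolute figure.
* No structure standardization, tautomer handling, chirality (2D only),
  or name-to-structure resolution; real-world input must be pre-cleaned.
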