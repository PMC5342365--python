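# Methods

## Model

A pathway is a directed multigraph of namespaced nodes (`gene:…`,
`mirna:…`) with signed edge weights β: positive for interactions that
increase the target's expression or activity, negative for those that
decrease it, zero for irrelevant ones. Zero-weight edges are pruned at load
time: the propagation normalisation sums |β| over a node's outgoing edges,
so a zero edge contributes nothing and only risks a zero denominator.
Parallel edges between the same ordered pair are kept in the data model and
summed into a single effective β at analysis time, since the propagation
equation admits exactly one weight per ordered pair.

### Perturbation factors

Node perturbation follows the linear recursion

PF(n) = ΔE(n) + Σ_{u∈U(n)} β(u,n)/Σ_{d∈D(u)}|β(u,d)| · PF(u)

with ΔE the log2 fold change (0 for nodes absent from the input). The
recursion is resolved *globally* as the linear system (I − M)x = ΔE with
M[n,u] = β(u,n)/Σ_d|β(u,d)|, not by fixed-point iteration, so feedback
loops and miRNA feed-forward loops are handled exactly. When (I − M) is
singular (e.g. an undamped two-cycle) the solver falls back to the
minimum-norm least-squares solution via the pseudoinverse and records the
residual norm; a relative residual above 1e−6·‖ΔE‖ marks the pathway
unsolvable, and the pipeline excludes it and reports it in a skip list
rather than returning a misleading score. Singularity is detected from the
diagonal of the LU factorisation (threshold 1e−10 relative to the matrix
magnitude).

### Pathway statistics

* Impact factor: IF = ln(1/p_ORA) + Σ_n|PF(n)| / (|ΔĒ|·N_de). The
  logarithm is natural — the base is a pure rescaling of a reported (never
  thresholded) score, and the natural log matches the lineage of
  impact-factor methods. |ΔĒ| is the mean of |ΔE| over the DE nodes *of the
  pathway*, not of the whole input: the quantity normalises the pathway's
  own perturbation mass, and the absolute value keeps the denominator from
  vanishing by sign cancellation. A pathway with no DE node (or zero mean
  |ΔE|) gets IF = 0 and p_ORA = 1: an unexpressed pathway is a valid,
  uninteresting result, not an error.
* Accumulators: Acc_gene and Acc_mir sum PF − ΔE over gene-side and miRNA
  nodes respectively; subtracting each node's own ΔE removes the dominant
  direct effect of its expression change. Nodes of class `other` count on
  the gene side. The total Acc = Acc_gene − Acc_mir − E[Acc] is stored as
  that exact expression, so the identity holds bitwise in every result row.
* ORA term: upper-tail hypergeometric probability of at least the observed
  number of DE members, with the pathway's assayed nodes as draws from the
  input universe.

### Permutation null

Each repetition assigns fold changes drawn *without replacement* from the
input DE pool (all DE features of the input, genes and miRNAs pooled — the
pool is input-wide, not pathway-wide) to a uniformly random subset of
pathway nodes of the observed DE size; all other nodes get ΔE = 0, and the
raw accumulator Acc_gene − Acc_mir is recomputed. 2000 repetitions resolve
the p-value to two decimal places; E[Acc] is the null median. Both observed
and null accumulators are centred by that same median before the tail
count, and the count ratio is clamped to [1/(n_reps+1), 1] so an
observation beyond every draw yields 1/2001 rather than an exact zero that
would break the inverse-normal transform.

The tail is one-sided ("null ≥ observed") by default, reading the counting
rule literally; a `two_sided` switch compares |null| ≥ |observed| instead.
The decoy benchmark uses the two-sided form (and the CLI `benchmark`
command defaults to it) because planted deregulation has an arbitrary net
direction, and the benchmark asks whether the *magnitude* of coherent
deregulation is distinguishable from chance.

Because (I − M) is fixed per pathway, the factorisation is computed once
and all repetitions are solved as one multi-column right-hand side, which
keeps 2000 repetitions per pathway in the low milliseconds at the default
pathway sizes.

### Combination, adjustment, ranking

The ORA and permutation p-values are combined by the Stouffer inverse-normal
method (inputs clamped to [1e−16, 1−1e−16]), adjusted across pathways by
Benjamini–Hochberg, and ranked by adjusted p-value ascending with ties
broken by descending |Acc| — the sign of the accumulator encodes direction,
not importance — and finally by pathway id so that ranking is total and
runs are byte-reproducible.

Per-pathway random streams derive from the global seed plus a CRC-32 hash
of the pathway's topology (nodes, classes, weights — not its id). Results
are therefore independent of processing order, and the same topology
analysed under two different ids receives identical statistics; any internal
parallelisation is required to produce output identical to serial execution.

## Enrichment

A knowledge-base record adds (miRNA → gene, β = −1) for validated
miRNA-target inhibition or (gene → miRNA, β = +1) for TF→miRNA activation,
with an optional per-record weight override as a hook for graded interaction
strengths. Only miRNAs with at least one partner already in the pathway are
added; enrichment never rewires the gene–gene subgraph and is idempotent.
Enrichment happens per pathway at analysis time rather than by mutating a
shared repository, because the decoy benchmark needs enriched and
unenriched variants of the same topology. TF→miRNA edges make miRNAs
ordinary intermediates: signal propagates through them like any other node.

Endpoints are re-marked after enrichment. Added miRNAs are never endpoints
— endpoints are phenotype-linked pathway *outputs*, and miRNAs are
regulators — and a former sink gene that gains a TF→miRNA edge stops being
one. Endpoint detection itself is sink-based (nodes from which no other
node can be reached, found by graph search); a curated id set reproduces a
manually screened endpoint list when one exists, and curated ids absent
from the graph are ignored with a warning.

## Decoy evaluation

A decoy keeps the full structure — edges, weights, edge classes, endpoint
positions — and substitutes every node id with one drawn without
replacement from a replacement universe, class-matched by default so decoys
remain enrichable. A `frozen_ids` set exempts nodes meant to survive
relabelling (complexes, abstract processes). One decoy is generated per
real pathway; replacements are drawn from the full gene universe, so
overlap with DE genes is allowed. The ranking statistic fed to the ROC is
the position in the ranked results, with identical (p, |Acc|) keys sharing
a mid-rank; the AUC equals the normalised Mann–Whitney U.

## Synthetic data

The generator emits connected signed DAGs (forward-oriented random edges,
which guarantees acyclicity and at least one sink), a random miRNA
interaction table over the pathways' genes, and planted expression inputs.
Defaults describe a desk-scale study: 10 pathways of 12–18 nodes, 15% edge
density, 25% inhibitory edges, 5 miRNAs with 2–4 targets, planted effects
of ~2 log2 units (|N(2, 0.5)|) against N(0, 0.25) background noise, ~30% of
nodes carrying signal, a DE magnitude threshold of 0.5, and 300 background
genes padding the assayed universe.

Planting is *coordinated*: each pathway gets one random orientation, and
each planted node's sign is chosen so that its effect, propagated through
the signed topology, pushes the pathway accumulator in that common
direction (the node's net downstream influence is read off one adjoint
solve of the propagation system). Endpoint fold changes are then set to the
perturbation each endpoint actually receives (plus noise), so with zero
noise the endpoint sign prediction is exact by construction. This emulates
the two couplings the benchmarks rely on — coordinated directional
deregulation within a pathway, and agreement between expression and wiring
— which identity-scrambled decoys destroy. Background genes model an
assayed transcriptome much larger than the pathway collection and serve as
the decoy replacement pool: decoys therefore draw mostly unremarkable
genes, exactly as in a real study.

What the generator does **not** emulate: RNA-Seq count distributions,
library-size normalisation, variance shrinkage of fold-change estimates,
correlated noise between samples, annotation errors in pathway topology, or
incomplete/false-positive miRNA interactions. Passing benchmarks on these
fixtures therefore demonstrates correctness and calibration of the scoring
machinery under its own assumptions, not performance on real tumour data.

The `antagonistic_kb` helper builds an adversarial knowledge base — one
inhibitory miRNA per endpoint whose expression is a multiple of the
endpoint's upstream perturbation — used to show that *wrongly signed* miRNA
information strictly degrades endpoint predictions (with strength 2 every
prediction flips), the converse of the benefit correct miRNA annotation
provides.

The null-calibration experiment uses one ~100-node pathway in a
1000-feature universe, 200 simulated inputs with 100 DE features each
(i.i.d. standard-normal fold changes on random DE labels, non-DE features
unchanged — under a global null only the DE calls carry signal, and this
makes the observed assignment exchangeable with the permutation null), and
1000 permutation repetitions per input. At these sizes the hypergeometric
term is smooth enough for the Kolmogorov–Smirnov check while the whole
experiment stays under a few seconds.

## Numerical choices and edge cases

* DE threshold on adjusted p-values: strictly below 0.01 by default.
* Probabilities are kept in (0, 1]: floors at 1e−16 before the
  inverse-normal transform, the permutation floor at 1/(n_reps+1).
* An endpoint with PF = 0 after masking counts as discordant (no
  prediction made); endpoints with zero recorded fold change are not
  scored, and a pathway with no scorable endpoint raises a distinct error
  rather than returning 0.
* KGML relation subtypes beyond activation/expression/inhibition/repression
  (phosphorylation, binding, indirect effect, …) default to β = 0 and are
  pruned; a user-supplied beta table can weight them. Group entries are
  flattened into member nodes, each inheriting the group's relations, since
  the propagation equation is defined over single nodes.
* A node whose outgoing effective weights sum to zero in absolute value
  simply propagates nothing (its column of M is zero).

## Problem sizes

The test suite and the acceptance script run the solver-oracle comparison
on 100 random DAGs of ≤ 15 nodes, the decoy benchmark on 10 pathways + 10
decoys at 2000 permutation repetitions (20 seeds for the zero-effect
control), and the calibration experiment at the sizes above; the full suite
completes in well under a minute on one CPU.

## Known limitations

* Endpoint auto-detection equates endpoints with sinks; genuine endpoint
  curation (phenotype association) must be supplied as a curated id file.
* The least-squares fallback for singular systems is this package's choice;
  other implementations of this family of methods may damp cycles or fail
  instead. `solver_info` flags every fallback.
* Identifier namespaces (`gene:`/`mirna:`) replace identifier-mapping
  services; inputs must arrive with consistent ids.
* No differential-expression calling, classifier, or cross-validation
  harness is included: inputs arrive pre-called, and exported endpoint and
  accumulator tables are the intended interface to external classifiers.
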