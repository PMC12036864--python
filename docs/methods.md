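# Methods

## Mixture model and anchored deconvolution

Bulk expression is modelled as a linear mixture in CPM space:
`X ≈ S·P`, where `X` is genes × samples (CPM), `S ≥ 0` is the gene × cell-type
signature matrix and `P` the cell-type × sample proportion matrix with each
column on the probability simplex. Mixing is additive in linear expression,
so deconvolution runs on CPM, never on log values.

Interpretation caveat: proportions recovered from expression are *relative
mRNA proportions*. They equal cell-number proportions only when all cell
types contribute the same total mRNA per cell. The synthetic generator
enforces this (signature columns share a common total mass); on real data the
usual per-cell-type mRNA-content distortion applies.

**Anchoring.** Prior marker genes pin component identity: for an anchor gene
`g` of type `k`, `S[g, j]` is fixed at zero for every `j ≠ k` throughout the
fit. Anchor sets must be disjoint; anchors absent from the matrix are dropped
with a warning (losing *all* anchors of a type is an error). Extra free
components (`k_free`) may be requested; they have no constraints and are
intended to absorb unannotated populations, with identity assigned post hoc
via enrichment.

**Fitting.** Alternating exact non-negative least squares:

* P-step, per sample: NNLS solve of `X[:, s]` on `S`, then Euclidean
  projection onto the simplex;
* S-step, per gene: NNLS solve of `X[g, :]` on `P` with anchored
  cross-loadings held at zero (anchored rows reduce to a 1-D non-negative
  solve).

Both steps first compute the unconstrained least-squares solution and fall
back to per-vector NNLS only where non-negativity is violated — numerically
identical and much faster. Because the per-component scale is indeterminate
(`S[:,k]·a`, `P[k,:]/a`), each signature column is renormalised to the data's
mean column sum between iterations; this is objective-neutral but keeps the
NNLS proportions summing near one, so the simplex projection is a small
correction rather than a distortion. The Frobenius objective is recorded
every iteration with a monotone safeguard: an iteration that would increase
it (possible in principle because the projection is applied after, not
inside, the non-negative solve) reverts to the previous iterate and stops.
Convergence is declared when the relative objective decrease falls below
`tol` (default 1e-6, `max_iter` 200).

Initialisation is deterministic for anchored components (column `k` is the
anchor-expression-weighted mean sample profile); free components draw from a
seeded exponential. Restarts (default 5) perturb only free components, so a
fully anchored model runs a single restart. Everything is a pure function of
the seed.

**Marker discovery.** specificity(g,k) = `S[g,k] / Σ_j S[g,j]`, computed for
genes whose top signature is at least `min_signature` (default 10 CPM-scale
units — suppresses ratio noise on silent genes); markers are genes with
specificity ≥ `spec_min` (default 0.7), sorted by specificity with
lexicographic tie-break.

For evaluation against planted truth, components are matched to truth by
Hungarian assignment on proportion correlation (free component order is not
identifiable).

## Differential expression

Welch's unequal-variance t-test (default) or Wilcoxon rank-sum on log2(CPM+1),
two-sided, with Benjamini–Hochberg step-up control across genes. A gene is
called up/down when `q < 0.05` and `|log2FC| ≥ 1` (both configurable). Genes
with zero variance in both groups get `p = 1` rather than an error. The BH
implementation is the package's own (it is also applied across enrichment
target sets) and is tested against an independent step-up oracle.

Cross-species conserved genes: an explicit orthology map (no case-convention
inference — human/mouse symbol casing is never guessed) joins two DE results;
pairs significant in both species with the same direction are retained,
one pair per concordant many-to-many mapping.

## Enrichment

Upper-tail hypergeometric `P(X ≥ k)` for overlap `k` between a query and a
target set within a universe, BH across the tested collection, odds ratio
from the 2×2 table with Haldane 0.5 correction when any cell is zero. The
universe should be the filtered (measured) gene background; queries are
intersected with it. Up- and down-regulated genes are tested separately —
direction carries the biology. Exactness is verified against complete subset
enumeration for all universes up to N = 12.

## Cell-graph structure learning

Variables are per-sample cell-type abundances. The score is the decomposable
linear-Gaussian BIC

```
score(G) = Σ_v [ −(n/2)·log(RSS_v/n) − (|pa(v)|+2)/2·log n ]
```

with `RSS_v` from an intercept-included least-squares regression of `v` on
its parents, an RSS floor of 1e-12 against exact collinearity, and variables
z-scored (ddof = 1) beforehand. Search is greedy hill-climbing from the empty
graph (plus whitelist) over single-edge additions, deletions and reversals,
accepting the best move with positive gain; near-ties (within 1e-12) break
lexicographically by (source, target, move kind), making the search
deterministic. Random restarts (default 10) perturb the start graph with
seeded whitelist-respecting additions. `max_indegree` defaults to 3 — real
designs have few samples, and larger families overfit. For three variables
the search provably-by-test matches exhaustive enumeration of all 25 DAGs.

**Bootstrap confidence.** Rows are resampled with replacement B times
(default 200 in the API; pipeline evaluations use 50–100 for runtime) and the
graph relearned per replicate (2 restarts — resampling already explores).
Skeleton confidence of a pair is the fraction of replicates containing it in
either direction; pairs at ≥ `conf_min` (default 0.5) are kept and oriented
by majority direction, lexicographic on ties. Orientation conflicts that
close a cycle are resolved by dropping the weakest edge on each cycle.
Observational Gaussian data only identifies graphs up to Markov equivalence,
so edges whose direction support is below 0.7 are flagged
"undirected-equivalent" rather than presented as causal.

**Compositional caveat.** Proportion vectors sum to one, so the K abundance
variables are *exactly* collinear: any node is near-deterministically
regressed on three others, the RSS floor engages, and learned families become
arbitrary. z-scoring does not remove this. The time-course pipeline therefore
learns the consensus graph on additive-log-ratio (ALR) coordinates,
`log(p_v / p_ref)`, with the least-variable cell type as the reference — the
standard log-ratio remedy for compositions, and the inverse of the
generator's softmax link up to the reference term. The cost is that the
reference cell cannot acquire edges; `transform="zscore"` is available for
data that are not strictly compositional (e.g. external abundance
estimates). Structure-recovery benchmarks run on the generator's latent SEM
abundances: the softmax closure genuinely couples all compositions, so the
planted DAG is only identifiable on the abundance scale.

## Communication networks

For each cell-graph edge `A → B`, the annotation is every database pair
(ligand, receptor) with the ligand among A's markers and the receptor among
B's markers. Pair score = `√(µ_l · µ_r)` with µ the mean CPM over the scored
samples — a geometric-mean mass-action convention; edge weight is the sum of
pair scores (a structural invariant checked everywhere). Optionally only
ligands called "up" by a DE result are eligible. Edges flagged
undirected-equivalent are tried in both orientations and emitted in the
orientation with stronger ligand–receptor support (stored orientation on
ties) — the LR database supplies the directional information the Gaussian
likelihood cannot.

**Gene-set activity.** Per gene, z-score across samples (zero-variance genes
skipped); per set and sample, the mean member z-score. Scores are centred
across samples by construction; for time courses they are aggregated to
timepoint means.

**Time-course gating.** One deconvolution on all samples, one ALR consensus
graph on all samples, then per timepoint `t`: a cell is *active* when the
one-sided Welch test of its proportions (t vs baseline) gives `p < 0.05` with
an increase (a per-timepoint screen, deliberately uncorrected); the network
at `t` keeps consensus edges whose endpoints are both active and which carry
at least one pair whose ligand is DE-up at `t`, scored on t's samples. The
baseline network is empty by construction. Per-day structure relearning was
rejected: per-day n is far too small for structure learning, so gating a
single consensus graph is both more stable and honest about what the data
support.

**Network comparison.** Edge-level diff over a shared node universe: gained,
lost, and retained edges, the latter flagged when the relative weight change
exceeds 10% (configurable). Swapping arguments exchanges gained and lost.

## Synthetic data generator

The generator emulates the mixture-of-cell-types structure the pipeline
inverts, with every quantity a pure function of the seed:

* **Signatures** — log-normal background (median 50, σ_log = 1); disjoint
  planted marker blocks whose off-type leakage is tied to ≤ 2% of the
  own-type value, guaranteeing specificity ≥ 0.9 even after columns are
  rescaled to a common total mass (the equal-mRNA-content convention that
  makes CPM mixtures exactly linear in the proportions).
* **Proportions** — linear-Gaussian SEM over a planted dependency DAG
  (roots N(0, root_sd), children = coefficient-weighted parent sum +
  N(0, noise_sd)), mapped to the simplex by softmax. Defaults: unit-variance
  roots and noise_sd 0.1 for generic fixtures.
* **Counts** — Poisson at library size 1e6 (or exact rounding for noiseless
  fixtures) of the column-normalised expected mixture.
* **Time course** — default 5 timepoints (days 0, 0.25, 1, 2, 3) × 5
  replicates, 5 cell types, 400 genes. Cells in their activity window have
  proportions doubled (then renormalised); planted ligands are additionally
  up-shifted 4× in bulk during the window, mimicking a cytokine surge. The
  two communicating cells share the early window; a third cell carries a
  late window so compositional variation keeps full rank and signatures stay
  identifiable. Latent scales root_sd = noise_sd = 0.12 give replicate
  proportion CVs around 15%, typical of bulk replicates; with much wider
  replicate scatter the prescribed activity screen (one-sided Welch, 2×
  boost) has no power at realistic replicate counts, and with a single
  shared window the proportion matrix becomes rank-deficient. The planted
  ligand/receptor are leading (anchor-grade) markers of their cells,
  mirroring canonical cytokines that double as anchors.

What the generator does **not** emulate: over-dispersion beyond Poisson,
batch effects, dropout, cell types with unequal mRNA content, markers shared
between types, or LR databases with wrong-direction annotations. Passing
recovery tests therefore demonstrate correctness of the inference machinery
under the stated model, not robustness to real-data artefacts.

## Problem sizes used in benchmarks

Deconvolution recovery: K=4, G=1000, n=60 (the generator defaults), 5
restarts. Structure recovery: 5 nodes, n=500, B=100 bootstrap replicates,
20 seeded runs. Time-course recovery: the time-course defaults above, B=50,
2 deconvolution restarts, 20 seeded runs. Oracle checks: all hypergeometric
instances with N ≤ 12; 1000 random p-vectors; 100 random 3-variable
datasets; 50 random LR fixtures.

## Known limitations

* Hard anchoring assumes anchors are truly exclusive; a mis-assigned anchor
  biases its component rather than being down-weighted.
* Proportions are relative mRNA shares (see above).
* Edge direction from observational data is Markov-equivalence-limited; the
  direction flag and LR-based orientation are mitigations, not solutions.
* The per-timepoint activity screen is uncorrected and one-sided by design;
  it is a gate for display, not an inference procedure.
* The ALR consensus cannot attach edges to the reference cell type.
* With co-activated cell types the signature split between them is
  ill-conditioned; anchor-backed markers remain reliable, discovered
  (non-anchor) markers of co-activated types less so.
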