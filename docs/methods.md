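# Methods

This note records the models behind each stage of `herbnet`, the
numerical conventions, the choices made where the methodology is
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Ingredient screening

The cascade retains a compound only when all seven criteria hold:
OB > 30 % and DL > 0.18 (strict, as these thresholds are conventionally
quoted), GI absorption equal to the token `high` (case-insensitive),
and the four Lipinski bounds taken inclusively (MW ≤ 500 g/mol,
Hdon ≤ 5, Hacc ≤ 10, iLOGP ≤ 5).  A compound missing any criterion
value is rejected: screening is deliberately conservative and only
fully characterised compounds pass.  Rows describing the same compound
under different herbs are merged into one record carrying the herb-set
union before anything else happens — without that merge the partition
into herb-shared (≥ 2 herbs) and herb-specific compounds would be
ill-defined.  Conflicting duplicate property values are an error, not
silently resolved.

## Single-cell differential expression

QC applies the gene filter first (detected in ≥ 10 cells), then the
cell filter once (≥ 200 detected genes **and** mitochondrial fraction
< 30 %).  The conjunction is intentional: a high-coverage cell that is
90 % mitochondrial is a damaged cell, and no sensible pipeline keeps
it.

Expression is normalised to 10 000 counts per cell followed by
`log1p`.  The rank-sum test runs on those log values (any strictly
monotone transform gives the identical p, a property the tests
verify); p-values use the tie-corrected normal approximation with
continuity correction, which stays within 0.02 of exhaustive
enumeration down to group sizes of ~6.  The fold change is computed on
the counts-per-10k scale, log₂((mean_d + 1)/(mean_c + 1)): computing it
on the doubly-compressed log1p values instead would shrink a true
four-fold change below common thresholds.  The base (2) and pseudocount
(1) are arguments.  The fraction-expressed gate passes a gene when
*either* group expresses it in ≥ 25 % of cells, so disease-silenced
genes are kept.  DE can run pooled (default) or per lineage with a
union over lineages, keeping each gene's most significant record.

## Networks

Gene symbols are uppercased and whitespace-stripped at ingestion; no
alias resolution is attempted.  The H-I-T-D network keeps an
ingredient only while it retains at least one edge into the
drug/disease intersection, and a herb only while one of its
ingredients survives; a single disease node connects to every target.
PPI edge lists are taken as given (no confidence re-filtering):
self-loops are dropped and reversed duplicates collapse into one
undirected edge.

## Centralities and the consensus core

Definitions: unnormalised Brandes betweenness with endpoints excluded;
closeness (n_c − 1)/Σd within a node's component; eigenvector
centrality as the non-negative L2-normalised limit of power iteration
on A + I from the uniform start — the +I shift makes bipartite spectra
converge, and the uniform start pins the vector down when the top
eigenvalue is degenerate (spectrally tied components); below 2 000
nodes that limit is computed exactly by projecting the ones vector onto
the top eigenspace of a dense eigendecomposition, above it by power
iteration to 1e-10.  LAC(v) is the mean degree of v's neighbours in the
subgraph they induce; the edge clustering coefficient is
triangles/min(deg−1, deg−1) (zero denominators contribute zero) and its
per-node sum is the "network" centrality; subgraph centrality is the
diagonal of exp(A) via eigendecomposition; information centrality
inverts (D − A + J) per connected component, so disconnected graphs are
handled without infinities (singleton components score 0).

The consensus rule marks a node core when it exceeds the median of
every measure.  Two deliberate refinements:

* **"Greater than" is strict** by default (configurable to ≥), with the
  even-count median taken as the midpoint of the central order
  statistics.
* **Constant measures are excluded from the consensus.**  On
  triangle-free graphs — and every layered herb–ingredient–target–
  disease network is triangle-free — LAC and the ECC-sum vanish
  identically, so a strict rule over all eight measures could never
  select any node and the notion of core ingredients would be vacuous.
  A measure with zero spread carries no ranking information; dropping
  it (and reporting it as degenerate) preserves the intended semantics.
  When *every* measure is constant, as on vertex-transitive graphs, the
  core is empty.  Comparisons use a 1e-9 relative tolerance so that
  numerically tied eigen-based values count as ties.

Core-ingredient selection runs the same rule on the H-I-T-D graph
treated as untyped, then filters the core to ingredient nodes.

## Over-representation analysis

Upper-tail hypergeometric p per set (overlap k, set size K, query n,
universe N), Benjamini–Hochberg adjustment across the tested sets, and
a Storey q-value with the single-λ estimator (λ = 0.5,
π₀ = #{p > λ}/((1−λ)m) capped into [1/m, 1]).  The BH-adjusted p is the
primary gate; both cutoffs must pass.  The background universe defaults
to the union of the collection's genes and can be overridden with a
measured-gene universe; query genes outside the universe are dropped
with a warning.

## Survival machinery

The Cox engine maximises the Efron partial likelihood by Newton–Raphson
with step-halving, declaring convergence at max|score| < 1e-9 within 50
iterations; covariates are centred internally for numerical stability.
Standard errors come from the observed information; hazard ratios carry
Wald 95 % CIs.  A monotone likelihood (perfect separation) is detected
by its numerical signature — a likelihood plateau whose standard error
dwarfs the attained coefficient (se > 100·(1+|β|)) or a diverging β —
and reported as non-convergence rather than an arbitrary large
estimate.  On tie-free two-group data the score test at β = 0 equals
the log-rank statistic; the tests verify the identity to 1e-8.

Stepwise model selection is backward elimination by AIC, with the null
model as a legal endpoint.  Risk scores are the linear predictor Σβx;
the median split assigns ties to the low group.  Kaplan–Meier and the
two-group log-rank test (hypergeometric variance at each event time)
are implemented directly and cross-checked against lifelines.

### ssGSEA

Within each sample, all genes are ranked by expression (average ranks
on ties).  Walking the genes in descending order, the running in-set
weight CDF (weights rank^τ, τ = 0.25, normalised over the in-set genes)
minus the uniform out-of-set CDF is accumulated over every position;
the sum is the sample's score.  Scores are rescaled across the cohort
by (max − min).  τ and the rescaling are arguments.  A set covering all
measured genes is an error (the out-of-set distribution is undefined);
a singleton overlap only warns.  Because per-sample rankings do not
depend on the gene set, the scorer precomputes them once, which makes
the subset search below cheap.

### ssGSEA-Cox search

A subset is *admissible* when the Cox Wald p of its median-split score
indicator is below α (default 0.05); the log-rank p of the same split
is always computed and reported alongside, since the two can be quoted
interchangeably in practice.  The search structure makes "the largest
significant subset" well defined: test the full candidate set; if
inadmissible, test leave-k-out subsets for k = 1, 2, … exhaustively
while C(n,k) ≤ 10 000, then fall back to greedy backward elimination
(repeatedly removing the gene whose removal minimises p) down to
subsets of three genes.  Equal-size admissible subsets are ordered by
smaller p, then lexicographic gene order.  Every tested subset is
recorded in the trace, so a reported optimum can be audited against
every larger rejected subset.  If nothing is admissible the result says
so explicitly.

## Synthetic data

The generators produce the statistical structure each stage assumes,
with planted truth, under `numpy`'s PCG64 so a seed reproduces outputs
bit-identically:

* **Ingredient tables** — each compound passes with probability
  `pass_fraction` (default 0.125 of 1 075 candidates, the scale of a
  seven-herb formula); failures violate 1–3 randomly chosen criteria,
  values drawn adjacent to each threshold so the cascade's boundaries
  are exercised.  A `shared_fraction` of compounds belongs to 2–3
  herbs.
* **Single-cell counts** — negative-binomial (gamma–Poisson) counts,
  dispersion 2, per-gene lognormal baseline means (meanlog 1, sdlog 1,
  chosen so a typical gene clears the fraction-expressed gate at 200
  cells per group); 50 planted DE genes shifted by |log₂ FC| = 2 with
  alternating sign; flagged mitochondrial genes; injected low-quality
  cells (≈ 50 detected genes, or mitochondria-dominated) at a stated
  rate to exercise QC.
* **Survival cohorts** — Gaussian log-scale expression; the planted
  signature behaves as a co-regulated module (a shared latent factor
  contributes half of each signature gene's variance, the way a
  transcriptional program co-varies in real cohorts — fully independent
  signature genes would make any set-level score of a 50-gene candidate
  list nearly blind to a 10-gene signal, which is not the regime a
  signature search addresses).  The latent risk is the standardized
  mean expression of the signature; survival is Weibull (shape 1.5,
  scale 5) with hazard multiplied by HR^z, HR = 3 per latent-score SD;
  censored samples keep a uniform fraction of their event time.
* **Spoiler cohorts** — 62 weakly informative genes plus one gene whose
  expression tracks the latent risk strongly in the opposite direction.
  Because the cancellation a single gene's rank swing can provide is
  bounded, both loadings are calibrated against the realised draw: the
  informative loading is bisected until the 62-gene score split reaches
  p ≈ 1e-3, and the spoiler loading is chosen to maximise the full
  63-gene set's p — i.e. the scenario is constructed, per cohort, to
  have its defining property (one gene's inclusion destroys
  significance).  Informative genes sit low in the expression range
  with small within-gene noise so their rank jitter stays small
  relative to the spoiler's swing.
* **Graphs** — Barabási–Albert networks with a planted clique placed by
  degree-weighted sampling, mirroring how disease modules occupy the
  connected core of an interactome rather than its periphery.

What the generators do **not** emulate: ambient RNA, doublets, batch
effects or library-size confounding in the single-cell model; gene–gene
correlation outside the planted module, non-proportional hazards or
informative censoring in the survival model; weighted or directed
interactions in the graphs.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under their stated
assumptions, not robustness to those real-data complications.

## Problem sizes in tests and the acceptance script

Oracle comparisons use 200 random graphs of ≤ 7 nodes (exhaustive
brute-force oracles remain cheap there), rank-sum enumeration up to
group sizes of 10 (≤ 20 000 assignments), 200 null replicates of n=500
for Cox calibration, n = 2 000 for hazard-ratio recovery, 20 replicates
of the 50-candidate signature search at n = 300, and one 63-candidate
spoiler cohort at n = 216.  These sizes were chosen so that every check
runs in seconds while keeping the statistical assertions (recovery
counts, KS calibration) comfortably away from their thresholds.

## Known limitations

* No proportional-hazards diagnostics, time-dependent covariates or
  penalised Cox variants.
* ORA ships no annotation content; the user supplies GMT collections,
  and enriched-term counts are inherently annotation-version dependent.
* The centrality definitions of LAC and the ECC-sum follow their
  published plugin descriptions; other tools' floating-point outputs
  are not reproduced bit-for-bit.
* The greedy phase of the ssGSEA-Cox search explores a path, not the
  full lattice; maximality is guaranteed only within the explored
  subsets (the trace records exactly which).
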