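# herbnet

Network-pharmacology analysis of multi-herb formulas, built around the
question of how a traditional multi-herb prescription acts on a complex
disease (the motivating case is an anti-fibrotic formula of seven herbs
acting on liver fibrosis and cirrhosis survival).  A formula contains
hundreds of candidate compounds; only a screened subset is plausibly
bioactive, each bioactive compound hits many protein targets, and the
therapeutic effect emerges from the network that herbs, compounds,
targets and disease genes form together.  `herbnet` implements that
analysis chain as a tested, reusable library with a thin CLI:

1. **Ingredient screening** (`herbnet.screening`) — candidate compounds
   pass a pharmacokinetic cascade: oral bioavailability OB > 30 %,
   gastrointestinal absorption class High, druglikeness DL > 0.18, and
   Lipinski's rule of five (MW ≤ 500 g/mol, H-bond donors ≤ 5,
   acceptors ≤ 10, iLOGP ≤ 5).  Survivors are partitioned into
   herb-shared and herb-specific compounds.
2. **Disease genes from single-cell data** (`herbnet.deg`) — QC
   filtering (genes in ≥ 10 cells; cells with ≥ 200 genes and < 30 %
   mitochondrial counts) followed by a per-gene two-sided Wilcoxon
   rank-sum test on log-normalised expression, gated on the fraction of
   expressing cells (≥ 0.25 in either group) and |log₂ fold-change|
   (≥ 0.7).
3. **Network construction** (`herbnet.networks`) — the bipartite
   ingredient–target network, the drug/disease target intersection, a
   PPI graph over the intersection, and the heterogeneous
   herb–ingredient–target–disease (H-I-T-D) network.
4. **Centrality-consensus core nodes** (`herbnet.centrality`) — eight
   node centralities (degree, betweenness, closeness, eigenvector,
   local average connectivity, edge-clustering-coefficient sum,
   subgraph, Stephenson–Zelen information); a node is *core* when it
   strictly exceeds the network-wide median on every informative
   measure.
5. **Over-representation analysis** (`herbnet.ora`) — hypergeometric
   upper-tail tests of a gene list against GMT gene sets, with
   Benjamini–Hochberg adjusted p and Storey q-values.
6. **Prognostic signature** (`herbnet.coxph`, `herbnet.signature`) — a
   Cox proportional-hazards engine (Efron ties, Newton–Raphson),
   Kaplan–Meier and log-rank tests, per-gene univariate screening,
   backward-AIC stepwise models with median risk-score splits, ssGSEA
   per-sample enrichment scores, and the **ssGSEA-Cox combinational
   search** for the largest gene subset whose enrichment-score median
   split is significantly associated with survival.
7. **Synthetic data** (`herbnet.simulate`) — seeded generators for
   every input above, each emitting planted ground truth, so the whole
   pipeline is testable without any external download.

## The core statistics

The Cox model relates covariates x to the hazard, h(t|x) = h₀(t)·exp(β′x);
β is estimated by Newton–Raphson on the Efron partial likelihood and a
covariate's effect is reported as the hazard ratio HR = exp(β) with a
Wald 95 % CI.  The ssGSEA score of a gene set S in one sample ranks all
genes by expression and accumulates, over the ranked list, the gap
between the weighted in-set cumulative distribution (weights rank^τ,
τ = 0.25) and the uniform out-of-set one; scores are rescaled across the
cohort by their range.  The ssGSEA-Cox search tests the full candidate
set first and then leave-k-out subsets (exhaustively while C(n,k) ≤
10 000, greedy backward beyond), returning the largest subset whose
median-split score indicator has Cox p < α.

## Worked example

```python
import herbnet as hn
from herbnet.simulate import SimulationConfig, gen_sc_counts, gen_survival_cohort

# disease genes from a synthetic two-group single-cell comparison
matrix, truth = gen_sc_counts(SimulationConfig(seed=1))
matrix = hn.qc_filter(matrix)
degs = hn.wilcoxon_deg(matrix, min_pct=0.25, min_abs_logfc=0.7)

# prognostic search on a synthetic 216-patient cohort
cohort, struth = gen_survival_cohort(SimulationConfig(seed=1))
screen = hn.univariate_screen(cohort, cohort.genes[:63])
res = hn.ssgsea_cox_search(cohort, cohort.genes[:63], alpha=0.05)
```

prints (via the fuller script in the docstrings):

```
DE genes: 50 (50/50 planted recovered, 0 false)
univariate Cox: 15 of 63 genes at P<0.05
ssGSEA-Cox optimal set: 63 genes (log-rank p = 3.94e-03); 10/10 planted signature genes included
```

The 50 planted genes (|log₂ FC| = 2) all clear the fraction-expressed
and fold-change gates while no null gene does; the univariate screen
flags the co-regulated signature genes plus the expected handful of
chance hits; and because the full 63-gene candidate set's enrichment
score is already significantly associated with survival, the search
returns it whole — including all ten genes that truly drive the planted
hazard.

The same stages are exposed as subcommands:

```
herbnet simulate ingredients --seed 3 --out sim
herbnet screen --in sim/candidates.tsv --out screened.tsv --report tally.json
herbnet deg --matrix counts.csv --meta cells.tsv --out deg.tsv
herbnet netbuild hitd --screened screened.tsv --targets targets.tsv \
    --disease-genes deg_genes.txt --out hitd.graphml
herbnet centrality --graph ppi.graphml --out profiles.tsv --core core.json
herbnet ora --genes core_up.txt --gmt reactome.gmt --adj-p 0.05 --q 0.05
herbnet signature --expr expr.csv --clin clin.tsv --genes candidates.txt --out sig.json
```

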