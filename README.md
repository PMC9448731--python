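# tissuewalk

Tissue- and cell-type-adjusted Markov diffusion on protein–protein
interaction (PPI) networks for disease-gene prioritization, with a synthetic
multi-omics cohort generator for validating recovery of planted gene modules.

## The problem

Complex neurodevelopmental disorders scatter weak genetic, epigenetic and
transcriptomic evidence across thousands of loci. Network propagation
aggregates these small effects: evidence placed on known risk genes is
diffused along PPI edges, so genes that are densely wired to many
weakly-implicated loci accumulate signal even when they carry no direct
evidence themselves. `tissuewalk` additionally makes the network
*tissue-aware*: every edge is re-weighted, per tissue or cell-type, by how
plausibly the two proteins actually meet there.

## The model

**Evidence matrix and signal vector.** For `G` genes and `L` omics layers
(curated risk-gene lists, differential methylation, differential expression,
differential splicing), the binary evidence matrix `E ∈ {0,1}^{G×L}` has
`E[i,j] = 1` when gene `i` is a significant hit in layer `j`. The initial
signal is the row sum `S_i = Σ_j E[i,j]`; a gene that is both differentially
expressed and differentially methylated starts at `S_i = 2`. Genes with
`S_i ≥ 1` are the seed set.

**Tissue-specific transition matrix.** For each edge `(u, v)` and tissue
`τ`, the raw weight is

```
W_τ(u,v) = max(Jaccard(D_u, D_v), floor) · sqrt(m(a_uτ) · m(a_vτ))
```

where `D_u` is the set of subcellular micro-domains annotated to `u` (32
labels by default), `a_uτ` is the ordinal protein abundance of `u` in tissue
`τ` (`not_detected < low < medium < high`) and `m` maps levels to positive
numbers (defaults 0.1 / 1 / 2 / 3). Row-normalizing `W_τ` (with unit
self-loops for isolated genes) yields a row-stochastic transition matrix
`P_τ`.

**Diffusion.** The signal is propagated as `S_t = S_{t-1} P_τ`, stopping
when the relative L1 change falls below `tol = 1e-3`. Mass is conserved at
every step. Setting `floor = 1` and a constant abundance mapping reduces
`P_τ` to the plain row-normalized adjacency — the all-edge-weights-1
ablation.

**Candidate selection.** After diffusing in every tissue column, a gene is a
*brain-high* candidate when its maximal intensity across tissues falls in a
brain column (ties that include a brain column count; all-zero rows never
do). Candidates split into *known* (seed) and *novel* genes; downstream
statistics cover micro-domain proportion maps with pooled two-proportion
z-tests, one-sided Fisher/hypergeometric marker-set enrichment, and
prenatal-vs-postnatal Welch t-tests per brain region with Benjamini–Hochberg
FDR control.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort with a planted brain-specific module (500 genes; module of 50 with 20
evidence-carrying seeds and 30 hidden members; 4 brain + 8 non-brain tissue
columns):

```
$ python analysis/01_simulate.py --seed 1
cohort: 500 genes, 3 edge sources, module of 50 (20 seeds, 30 hidden)
seed genes with evidence: 23; signal intensities 1..2
...
$ python analysis/02_build_network.py
merged 3407 raw records from 3 sources into 2642 unique interactions (765 duplicates/self-pairs removed)
built 12 row-stochastic transition matrices (500 x 500) ...
$ python analysis/03_diffuse.py
diffused 12 tissues; convergence times 45..55 steps (all converged: True)
$ python analysis/04_select_candidates.py
65 brain-high genes: 13 known seeds, 52 novel
hidden module genes among novel candidates: 16/30; background genes among novel: 36/450
hidden-gene recovery AUROC: weighted 0.953 vs all-weights-1 ablation 0.800
$ python analysis/05_downstream_stats.py
marker-set enrichment (one-sided Fisher):
  In_neurons: overlap 16, OR 2.9, p=1.77e-03
  Exc_neurons: overlap 15, OR 2.6, p=5.17e-03
  ...
developmental DE: 41/65 candidates (63%) DE in >= 1 of 16 regions
```

Reading the numbers: the deduplicated interactome keeps one canonical record
per unordered gene pair; diffusion conserves the initial signal mass of 25
in every tissue; hidden module genes — which carry zero direct evidence —
are ranked above background genes by brain-column intensity with AUROC
0.953, clearly better than the 0.800 achieved when all edge weights are set
to 1, which is the point of the tissue adjustment. The neuronal marker sets
(built to overlap the planted module) come out as the top Fisher hits, and
about two-thirds of candidates are developmentally differentially expressed
in at least one region, mirroring the planted prenatal→postnatal shifts.

Summary tables land in `results/`; bulky intermediates (transition matrices,
intensity matrix) in `scratch/pipeline/`. The same stages are available as
CLI subcommands (`tissuewalk simulate | build-network | diffuse | select |
enrich | devde | run-all`).

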