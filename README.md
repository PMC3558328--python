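# microdelim

Integrative DNA-barcode species delimitation and downstream evolutionary
analyses, built for datasets like the carychiid microsnails (*Carychium*,
*Zospeum*): morphologically conservative taxa whose shell-based
morphospecies hypotheses hide — or over-split — separately evolving
lineages.

The package is for systematists and phylogeographers who want to run the
whole delimitation-to-diversification workflow on aligned barcode
sequences and an ultrametric tree, and for methodologists who want every
stage verifiable on synthetic data with known truth.

## What it computes

**Five molecular delimitation methods**, all returning a `Partition` of
specimens into evolutionary lineages (ELs):

* fixed **K2P threshold** clustering (default 3.2%), with
  `d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]` under pairwise deletion;
* **automatic barcode gap discovery** (ABGD-style): recursive splitting
  at the first distance gap wider than `X · d` crossing a prior
  intraspecific limit, scanned over a geometric series of priors;
* **GMYC**, single- and multiple-threshold: the mixed model in which
  branching older than a threshold age follows a generalized Yule process
  (rate `lambda_d n^p_d`) and younger branching follows within-species
  coalescence (`lambda_c n^p_c` per group), with maximum-likelihood
  threshold placement and likelihood-ratio tests against the one-class
  null;
* **statistical parsimony** (TCS-style): haplotypes connected within the
  95% parsimony connection limit `j_max`; connected components are the
  entities.

A **conservative consensus** merges the method partitions by the
partition-lattice join (specimens are lumped whenever *any* method lumps
them), and a cross-validation report classifies each morphospecies as
`match`, `split`, `lumped` or `mixed` against the consensus ELs.

**Diversification analysis** on the delimited lineages: pureBirth, bd,
DDL, DDX and yule2rate fits by maximum likelihood, AIC model tables,
lineage-through-time data, a parametric-bootstrap test of rate constancy
(the delta-AIC statistic recomputed on pure-birth trees simulated at the
fitted rate), and a recent-history truncation experiment that slices off
the youngest fraction of the tree.

**Niche statistics** on habitat-suitability grids: Schoener's D, the
Hellinger-based I, relative rank concordance, and Levins' standardized
niche breadth.

**Synthetic data** for every stage: Yule / birth-death / two-rate trees,
species trees with coalescent tip clusters, K80 sequence evolution,
planted-barcode-gap alignments with hard distance guarantees,
morphospecies labels with controlled lumping/splitting, and Gaussian
suitability grids.

## Worked example

```python
from microdelim.simulate import make_planted_gap_dataset
from microdelim.distances import build_distance_matrix
from microdelim.threshold import threshold_partition
from microdelim.abgd import AbgdConfig, abgd_prior_scan
from microdelim.parsimony import sp_partition, parsimony_connection_limit
from microdelim.consensus import join_partitions

aln, truth = make_planted_gap_dataset(8, 5, intra_max=0.01,
                                      inter_min=0.06, length=607, seed=1)
dm = build_distance_matrix(aln, model="K2P")
thr = threshold_partition(dm, 0.032)
scan = abgd_prior_scan(dm, AbgdConfig(pmin=0.01, pmax=0.05, x=0.1, steps=50))
sp = sp_partition(aln)
consensus = join_partitions([thr, scan.runs[0][1], sp])
print(f"specimens: {aln.n_sequences}, alignment: {aln.length} bp")
print(f"threshold (3.2% K2P): {thr.n_blocks} lineages")
print(f"ABGD (50 priors):     {scan.modal_block_count} lineages, stable={scan.stable}")
print(f"parsimony (95%, j_max={parsimony_connection_limit(aln.length)}): {sp.n_blocks} lineages")
print(f"consensus join:       {consensus.n_blocks} lineages; matches truth: {consensus == truth}")
```

prints

```
specimens: 40, alignment: 607 bp
threshold (3.2% K2P): 8 lineages
ABGD (50 priors):     8 lineages, stable=True
parsimony (95%, j_max=9): 8 lineages
consensus join:       8 lineages; matches truth: True
```

Forty specimens from eight simulated species, with intraspecific K2P
distances held at or below 1% and interspecific distances at or above 6%,
are delimited identically by all three distance-based methods; the
conservative consensus equals the generating partition.  `j_max = 9` is
the 95% parsimony connection limit for a 607 bp barcode.

The same workflow is scriptable from the shell:

```
microdelim simulate gapdata --species 8 --tips-per-species 5 --seed 1 --out gap.fasta
microdelim delimit --alignment gap.fasta --methods threshold,abgd,sp \
    --pmin 0.01 --pmax 0.05 --out-prefix run
microdelim divtest --tree tree.nwk --nsims 500 --seed 42 --truncate 0.05
microdelim niche-overlap grid1.asc grid2.asc
```

`delimit` writes a per-specimen partition table (one column per method
plus the consensus) and a JSON summary; `divtest` writes a model table
with LH, parameter estimates, AIC and dAIC columns plus the bootstrap
p-value for rate constancy.

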