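# fcdecode

Resting-state functional-connectivity mapping with cluster-corrected group
inference, and transcriptomic decoding of the over-connected regions — an
end-to-end, fully synthetic-testable implementation of the analysis chain
used in mouse rsfMRI genetics studies: which brain regions are
over-connected in a mutant group, and which gene sets are preferentially
expressed in exactly those regions?

The package is aimed at researchers who want the complete chain — BOLD
preprocessing, connectivity statistics, permutation cluster inference,
expression-based decoding, gene-set overlap — as tested, composable library
code, with a synthetic-cohort generator that plants known effects so every
stage can be validated without any external data.

## The analysis

**Connectivity.** After preprocessing (trim the first 20 volumes, despike,
regress out mean ventricular signal and six motion traces, smooth at
FWHM 0.6 mm, band-pass 0.01–0.1 Hz at TR 1.2 s), each subject's *global
connectivity map* assigns voxel *v* the self-excluded average of its Pearson
correlations with all other brain voxels,

> r̄(v) = tanh( (1/(V−1)) Σ_{u≠v} atanh r(v,u) ),

averaged in Fisher-z space (an "r score"). Seed-based maps correlate each
voxel with a seed region's mean time course. Groups are compared voxelwise
with two-sample pooled-variance t tests on Fisher-z maps; family-wise error
over clusters is controlled by permuting group labels and comparing each
suprathreshold cluster's extent (|t| above the cluster-defining threshold,
6-connectivity) with the permutation distribution of the maximum cluster
extent.

**Decoding.** Given a genes × regions matrix of expression energies, each
gene's profile is normalized by its total over regions. For a focal region
pair, candidate genes are selected two ways: the intersection of the top
20% in both regions (tested per gene set with a hypergeometric tail), and a
ranking by the sum of normalized values in the pair (the L1 score), tested
with the flexible-threshold minimum-hypergeometric (mHG) statistic

> mHG = min over prefixes n of P[X ≥ b(n)], X ~ Hypergeom(N, B, n),

whose exact p-value is computed by dynamic programming over orderings.
Specificity comes from repeating the analysis on 10 random region pairs.
DEG/risk-list overlap uses Fisher's exact test with the sample odds ratio.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (6 + 6 subjects, 20×20×4 grid, 220 volumes at TR 1.2 s, planted
correlation 0.5 between regions 3 and 8 in group b):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_connectivity_mapping.py
python analysis/04_decode_expression.py
python analysis/05_gene_overlap.py
```

Script 01 verifies the planted effect is realized
(`realized_corr` 0.0075 for group a, 0.5049 for group b). Script 03 prints
the group inference:

```
df = 10, cluster-defining |t| = 2.228, 924 relabelings (exhaustive)
 cluster_id  extent_voxels    peak_t  sign  corrected_p  surviving
          1            145 19.038097    -1     0.002165       True
          2            113 21.317268    -1     0.054113      False
          ...
Top region by |group difference|: 3 (planted pair is 3 & 8)
Dice overlap of surviving clusters with the planted pair: 0.705
```

The surviving negative cluster (group b > group a) sits on the planted
regions, and the regional r-score contrast ranks a planted region first.
Script 04 decodes the focal pair transcriptomically:

```
  fixed mode best set: planted_set (q = 3.81e-54)
  mhg   mode best set: planted_set (q = 1.98e-64)
Significant sets: focal pair 1 vs control median 0.0
```

and script 05 reports the DEG/risk-list overlap on a synthetic table with
200 DEGs, a 100-gene risk list and 30 shared genes in a 2000-gene universe:
`Fisher's exact test: P = 7.59e-09, OR = 4.36`, i.e. risk genes are ~4-fold
over-represented among the DEGs.

Tables land in `results/`, volumes in `scratch/`. The same operations are
available as a CLI (`fcdecode simulate|preprocess|connectivity|decode|overlap`).

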