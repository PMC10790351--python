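# topodyn

Temporal 3D-genome dynamics on Hi-C timecourses: A/B compartment
trajectories, TAD boundary / domain / clique dynamics, chromatin-loop hubs,
loop-mediated gene communities, permutation and shuffle-null enrichment
statistics, and cross-sample concordance — together with a synthetic Hi-C
timecourse generator that plants every structure the analyses are meant to
recover.

## Who this is for

Developmental and regulatory genomics groups that profile chromatin
architecture at several stages of a differentiation timecourse (bulk Hi-C
plus RNA-seq) and want to ask: which genomic regions switch compartment, and
when? Which TAD boundaries are stably gained or lost? Where do chromatin
loops aggregate into hubs, and do those hubs drift toward the active
compartment? Do these topological changes track gene-expression changes?
The package implements each of these questions as a small, tested operation
over plain-text genomic formats (sparse-triplet contact matrices, bedGraph,
BED, BEDPE, TSV), so the same code runs on real binned data or on the
built-in simulator.

## The statistics at the core

- **Compartment score (PC1).** For each chromosome the observed/expected
  contact map (expected = mean over each diagonal) is averaged over 100 kb
  sliding windows stepped every 50 kb; PC1 of its Pearson correlation matrix
  is the compartment score, sign-oriented so that it correlates positively
  with gene density (A = positive).
- **Trajectory labels.** A bin with PC1 values x_1..x_T is `stable_A`/
  `stable_B` (no sign change), `stable_AtoB`/`stable_BtoA` (exactly one sign
  change), or `dynamic` (two or more). Exact zeros carry the previous sign.
- **Saddle strength.** Bins sorted by PC1 into 40 quantile groups; mean O/E
  per group pair; compartmentalization strength = mean of the 5x5 corner
  blocks (AA, BB, and the AB off-corners).
- **Differential compartments.** Per-bin Mahalanobis distance
  MD_i = sqrt((x_i - mu)' Sigma^-1 (x_i - mu)) of the multi-timepoint score
  vector, with mu and Sigma estimated genome-wide; bins with MD > 1 are
  flagged as changing.
- **Insulation and boundaries.** The insulation score at the gap between
  bins i and i+1 is the contact sum in a w-bin diamond straddling the gap;
  boundaries are prominent local minima, and boundary dynamics are labelled
  by presence across timepoints after single-linkage merging within ±20 kb.
- **Domain score.** Intra-TAD contact sum (diagonal excluded) over the sum
  of contacts between the focal TAD and all other TADs on the chromosome.
- **TAD cliques.** Cis TAD pairs whose inter-TAD contact sum exceeds the
  distance-decay expectation (one-sided Poisson test, BH-FDR 0.05) form a
  graph; cliques are its maximal cliques of size >= 3, compared against 100
  size-preserving member shuffles.
- **Loop hubs.** Loop-foot coverage in 30 kb windows stepped every 3 kb;
  windows with >= 5 feet are stitched (gaps up to 30 kb), merged across
  timepoints, and re-scored; hub dynamics (stable/gained/lost) and PC1
  trends (monotone increase/decrease) follow the presence and mean-PC1
  vectors.
- **Gene communities.** Connected components of the graph over gene bodies
  and loop feet (edges: body overlap, foot overlap, and the two feet of a
  loop), keeping components with more than one locus.
- **Permutation statistics.** Contact enrichment at a TSS is its cis row
  sum against 1000 random bins of the same chromosome, reported as the
  normalized rank (r+1)/(n+1) with significance at rank < 0.05; gene-set
  compartment enrichment and loop-annotation enrichment use genome-wide
  label shuffles and span-preserving loop shuffles.
- **Concordance.** SCC (stratum-adjusted correlation: per-diagonal Pearson
  correlations weighted by N_k sd(A_k) sd(B_k), per chromosome then
  averaged), sign-level compartment concordance, boundary recall within
  ±20 kb, and intra-TAD gene-pair recapture.

## Worked example

```python
from topodyn import SimulationSpec, simulate_timecourse
from topodyn.compartments import (
    call_compartments_bundle, classify_track_trajectories, switch_mass_summary,
)
from topodyn.loops_hubs import call_hubs, hub_dynamics_table

spec = SimulationSpec(seed=1)            # 2 x 20 Mb, 5 timepoints
bundle = simulate_timecourse(spec)

pc1 = {tp: call_compartments_bundle(bundle.matrices[tp], bundle.gene_density, 50_000)
       for tp in bundle.timepoints}
labels, switches, _ = classify_track_trajectories([pc1[tp] for tp in bundle.timepoints])
summary, hist = switch_mass_summary(labels, switches, 50_000)
print(summary.to_string(index=False))

hubs = call_hubs(bundle.loops, bundle.chromsizes)
hubs["dynamics"] = hub_dynamics_table(hubs, bundle.loop_timepoints)
print(hubs["dynamics"].value_counts().to_string())
```

prints

```
      label  n_bins    mb
   stable_A     288 14.40
   stable_B     288 14.40
stable_AtoB      78  3.90
stable_BtoA      85  4.25
    dynamic      59  2.95
dynamics
stable    4
gained    4
lost      4
```

The generator planted 80 A-to-B and 80 B-to-A switching 50 kb bins per
genome (8 megabase-scale blocks); the caller recovers 78 and 85 of them from
the Poisson-noised matrices (the excess/deficit sits at block edges where
the 100 kb window straddles two compartments). All 12 planted hubs are
recovered with their correct stable/gained/lost labels.

The same pipeline runs from the shell:

```sh
topodyn run-all --config cfg.yaml --seed 1 --out out/
```

which writes every stage's tables plus a `manifest.json` with content hashes
(re-running with the same config and seed reproduces the hashes exactly).

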