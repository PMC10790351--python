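# Methods

This note documents the models, parameter choices, and numerical decisions
behind `topodyn`, and what the synthetic-data tests do and do not establish
about real data.

## Scope and data model

The package analyses a *timecourse bundle*: per-timepoint binned cis contact
matrices (one per chromosome, fixed resolution), compartment-score tracks,
TAD/boundary intervals, chromatin loops (anchor pairs, "feet"), a gene
catalog with strand-aware TSS and biotype, and a replicate-level CPM
expression table. All coordinates are 0-based half-open; strand is used
only to place the TSS; every overlap operation is strand-blind. Loop
calling, read mapping, and matrix balancing are upstream of the package:
loops and matrices are inputs (or are simulated).

Timepoint labels are arbitrary ordered strings; the study design the
defaults mirror has five timepoints with loop calls at the first four, and
the code generalises to any counts >= 2.

## Compartment score

The caller aggregates the raw matrix to the score resolution (50 kb),
computes observed/expected with the expected value per diagonal equal to
the mean over that diagonal (bins with zero marginal excluded), averages
O/E over 100 kb sliding windows stepped every 50 kb (a 2x2 window mean in
bin units; the window value is assigned to its starting step), and takes
PC1 of the Pearson correlation matrix of the result, scaled by the square
root of its eigenvalue. Diagonals with no observed contacts carry no
information and are set to the neutral O/E of 1 before correlating.

Sign orientation is a convention, not an inference: PC1 is flipped, if
needed, so that it correlates positively with a reference track. We use
TSS density per 50 kb bin, under the standard observation that the active
A compartment is gene-dense. Flipping the reference flips the score
exactly; a constant matrix or a chromosome shorter than four windows yields
an all-missing track with a warning.

Known limitation: the score at the last bin of a compartment block mixes
two blocks (the window covers 100 kb), so single-bin errors concentrate at
block edges. The planted-recovery tests quantify this (precision and
recall of switching bins stay above 0.95 under default conditions).

## Trajectory classification and change detection

A bin's label is decided purely by the sign sequence of its per-timepoint
scores: zero changes = stable A or B, exactly one = stable switch with the
switch interval recorded, two or more = dynamic. Exact zeros carry the
previous sign (a total sign function is needed and zeros are measure-zero
in practice); leading zeros are dropped; any missing value withholds the
label and the bin is counted as unscored. Genomic mass per label is
bins x bin size.

Multi-sample change calling uses the Mahalanobis distance of each bin's
score vector against the genome-wide mean and covariance, with the
covariance diagonal regularised by `1e-8 * trace / dim` (numerical safety,
negligible bias); bins with MD > 1 are flagged. The distance is invariant
to affine rescaling of any single timepoint's track, which the tests assert
numerically.

## Saddle and compartmentalization strength

Each chromosome (treated as a single arm; the toy genome has no
centromeres) is distance-normalised, its scored bins sorted by PC1
ascending and cut into 40 equal groups, and the mean O/E per group pair
forms the saddle matrix; per-arm matrices are averaged unweighted. Strength
components are the means of the 5x5 corner blocks: BB at the low-PC1
corner, AA at the high-PC1 corner, AB the average of the two off-corners.
With ascending sort, a global PC1 sign flip exchanges AA and BB exactly.

## Insulation, boundaries, and boundary dynamics

The insulation score between bins i and i+1 sums the w x w diamond of
contacts spanning the gap (default w = 10 bins = 100 kb at 10 kb
resolution), optionally as log2 over the chromosome mean. Boundaries are
local minima of the log-normalised score with prominence >= 0.25 — a
deliberately simple, well-behaved stand-in for an HMM-based
directionality-index caller, with the prominence default chosen so that a
two-fold intra-TAD enrichment produces a comfortable margin over Poisson
noise at the default depth. TADs are the spans between consecutive
boundaries.

Boundary positions are points at bin scale, so all matching is
midpoint-to-midpoint with inclusive windows (±20 kb for dynamics and
recall, ±10 kb for boundary genes); midpoints avoid width artifacts.
Merging across timepoints is single-linkage in 1D (cluster while
consecutive gaps <= tolerance), which is order-independent; two
same-timepoint boundaries falling in one cluster are merged with a warning
and counted. Labels come from the presence vector: present everywhere =
stable; absent at the first timepoint then present from some timepoint
through the last = stably gained (mirror for stably lost); everything else
= other.

## Domain score, A/B TADs, cliques

The domain score divides intra-TAD contacts (upper triangle, diagonal
excluded — the self-bin signal is dominated by unligated fragments) by the
focal TAD's contacts with all other TADs on the chromosome; zero
inter-TAD contacts yields a missing score. TADs are labelled A or B by the
sign of the coverage-weighted mean PC1 over their span; an exact zero or an
unscored span leaves the TAD unassigned.

Significant TAD-TAD interactions use a one-sided Poisson upper-tail test:
the observed inter-TAD contact sum against the sum of the distance-decay
expectation (diagonal means) over the pair's bin rectangle, BH-corrected
per chromosome at FDR 0.05, keeping pairs with observed > expected. This
re-states a published non-central-hypergeometric enrichment test with the
same statistical target (inter-TAD enrichment over the decay background);
on distance-preserving shuffled matrices the significant-pair rate stays at
or below the nominal FDR (calibration test). The test runs per chromosome;
cliques are maximal cliques of size >= 3 in the significant-pair graph
(a 2-clique is merely a significant pair), enumerated exactly and verified
against exhaustive subset search on small graphs. Null cliques preserve the
multiset of clique sizes and redraw members uniformly without replacement
within a clique. With one observed value against n shuffles the rank-sum
comparison reduces to the empirical rank, reported as (r+1)/(n+1).
Cross-timepoint clique identity uses Jaccard >= 0.5 on members.

## Loops and hubs

Loops are cis anchor pairs in canonical order; merging across timepoints
matches loops whose two feet agree within one bin (transitively, via
connected components). Shuffled loops preserve foot widths and
foot-to-foot span and are placed uniformly on the same chromosome.

Hub calling counts loop-foot *occurrences* (a loop with both feet in one
window contributes 2) in 30 kb windows stepped every 3 kb, keeps windows
with >= 5 feet (inclusive), stitches kept windows across gaps up to 30 kb,
merges the stitched regions across timepoints by plain interval union, and
re-scores each merged region per timepoint; presence means >= 5 feet.
Dynamics labels (stable/gained/lost/other) follow the same presence-vector
rules as boundaries, evaluated over the timepoints that have loop data; the
PC1 trend uses all timepoints and requires the last mean strictly above
(below) the first with a monotone non-decreasing (non-increasing)
sequence.

## Gene communities

Communities are connected components of the graph whose nodes are gene
bodies and loop feet, with edges for >= 1 bp gene-gene body overlap,
gene-foot overlap, and the two feet of each loop (body overlap, not
TSS-only: the integration is of loci, not promoters). Components with at
least two loci are retained; components containing no genes stay in the
object model but are excluded from gene-count statistics. A gene spanning
two feet is a single node with two edges. Community ids are deterministic,
ordered by (chromosome, leftmost start).

## Permutation statistics

All null draws derive per-replicate generators from the master seed and a
replicate index, so results are independent of scheduling and exactly
reproducible. Normalized ranks are always (r+1)/(n+1) and never zero.

TSS contact enrichment compares a gene's cis row sum (diagonal excluded;
an optional ±k-bin window, default k = 0, since the upstream tool's window
is not published) against the same statistic at 1000 random bins of the
same chromosome; bins with zero marginal are excluded from the pool, as is
the focal bin (otherwise a strict maximum could not attain the minimal
rank); pools smaller than twice the permutation count are sampled with
replacement and flagged. No multiple-testing correction is applied to the
per-gene ranks (the threshold rank < 0.05 is reported raw; a BH option
exists). Raw counts are accepted as-is; balanced matrices may be supplied.

Loop-annotation enrichment annotates, for each loop with a foot in an
expressed gene body, the opposite foot by priority classes — promoter
(TSS ± 2 kb) over gene body over intergenic; exon/intron subdivision is
not derivable from a TSS-level catalog, so gene body stands in for both —
and reports log2 of the unique gene/class pair rate over its mean across
span-preserving loop shuffles. Gene-set compartment enrichment permutes
the bin-label vector genome-wide.

## Concordance

SCC computes the Pearson correlation per distance stratum k = 1..max
(default 5 Mb of bins, typical practice; the smoothing half-window defaults
to 0 because the reference tool's setting is unreported — both are recorded
in the result object) and combines them with weights N_k sd(A_k) sd(B_k),
skipping zero-variance strata; chromosomes are averaged unweighted.
Compartment concordance compares sign only, over pairwise-complete bins
(and per gene at the TSS bin). Boundary recall and intra-TAD gene-pair
recapture are as defined above; pair recapture is monotone non-decreasing
under query-TAD unions.

## Synthetic timecourse generator

The generator is the package's study-conditions module: its defaults are
fixed once and the acceptance tests run against them.

Genome: 2 chromosomes x 20 Mb, matrices at 10 kb (2000 bins), scores at
50 kb, five timepoints with loops at the first four. Expected counts are
`depth * (d+1)^-alpha` (depth 60 at the first off-diagonal, alpha = 1)
modulated by: compartment factor 1 ± 0.4 for same/opposite-sign bins on a
1 Mb alternating block layout; TAD factor 1 + 1.0 within domains; focal
factor 1 + 3.0 at loop pixels. Observed counts are Poisson draws of the
upper triangle, mirrored. Poisson (not negative binomial) is the simplest
noise with the right support; no published effect sizes exist for this
generative process, so the amplitudes are free parameters of the simulator,
documented here and held fixed.

Planted structure, per chromosome: 2 A-to-B, 2 B-to-A, and 1 dynamic
compartment block among the 18 interior blocks, each stable switch at a
random interior timepoint; TAD boundaries at every block edge plus one
interior split per block (40-60 bins), with 4 boundaries gained and 4 lost
at random timepoints, each >= 100 kb from other boundaries so the ±20 kb
matching is unambiguous — aligning domain boundaries with compartment block
edges mirrors real genomes, where compartment transitions coincide with
domain boundaries, and keeps compartment switches from masquerading as
boundary events; 6 loop hubs (2 stable, 2 gained, 2 lost) of 6 near feet
within 30 kb plus spread far feet; 150 background loops present per
timepoint with probability 0.7; and one 5-gene marker chain per switching
block connected by loops into a planted community. Marker log2 CPM follows
`beta * delta-PC1 + noise` (beta = 1, SD 0.25, two replicates); other genes
are pure noise around a fixed baseline, with 10% planted below the 1 CPM
expression cutoff. Gene placement is biased 3:1 toward stable-A blocks so
that gene density orients the compartment sign, as it does in real genomes.

Two construction rules keep the truth table exhaustive: background and
community feet are capped at 4 per 30 kb window (rejection sampling), and
background feet are excluded from the stitched footprint of planted hubs —
otherwise chance clusters would be genuine hubs the truth table does not
list, and a planted absence could be masked. Emitted PC1 tracks are the
planted block signs times amplitude 1.0 plus small sign-preserving jitter;
they are also recomputable from the matrices, and tests compare both paths.

What passing recovery tests shows — and does not. The simulator produces
clean block compartments, sharp domains, uncorrelated Poisson noise, no
translocations or copy-number effects, no balancing artifacts, no
cell-type mixture drift, and cis contacts only. Recovery at precision and
recall >= 0.9 under these conditions demonstrates that the operations
implement their definitions correctly and have the stated statistical
calibration; it does not by itself establish sensitivity on real tissue
Hi-C, where compartment transitions are gradual and depth varies along the
genome.

## Problem sizes and reproducibility

The default test and acceptance runs use the 2 x 20 Mb genome (five seeds
for recovery, twenty for calibration and shuffle nulls) and a 2100-bin
uniform matrix with 2000 genes and 1000 permutations for the type-I-error
check — sizes chosen so the whole suite completes in a few minutes on one
CPU while leaving the binomial confidence intervals tight enough for the
stated bounds. Every random draw in the library and the pipeline descends
from an explicit seed; the pipeline manifest records a SHA-256 hash per
output file, and re-running with the same config and seed reproduces the
hashes exactly.

## CLI

`topodyn simulate|compartments|tads|loops|hubs|communities|enrich|compare|run-all`
are thin wrappers over the stage functions in `topodyn.pipeline`; stages
after `simulate` read the bundle files a previous run wrote, so any stage
can be re-run standalone. Configuration is a single YAML file whose fields
all have the analysis' standard defaults; CLI flags override the file.
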