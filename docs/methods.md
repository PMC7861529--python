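# Methods

## The model in one paragraph

`coevotrace` detects pairs of protein sites that evolve concordantly or
discordantly on a phylogeny.  Its substrate is a *substitution history*: a
rooted tree with branch lengths plus a table of reconstructed amino-acid
substitutions, each located on a branch and an alignment column (at most
one event per branch and site, as ancestral reconstruction defines them).
Two substitutions at different sites are **consecutive** when one is
ancestral to the other along a line of descent and no other substitution
at either site lies between them.  For an ordered site pair (i → j) the
**epistatic statistic** is

    stat(i → j) = Σ over consecutive pairs  w_lead · w_trail · exp(−t / τ_j)

where t is the waiting time between the two events (branch-length units,
events placed at branch midpoints) and τ_j is the penalty scale.  A
significant excess of rapid consecutive pairs relative to a
margin-preserving null is concordant evolution; a deficit is discordant
evolution.

## Event geometry conventions

* Events are placed at the midpoint of their branch, for waiting times
  and for patristic distances alike; reconstructed substitution maps do not resolve
  positions within branches and the midpoint is unbiased for both uses.
* Two events on the same branch (order unobservable) count as one
  consecutive pair in each ordered direction with t = 0, and the
  same-branch partner pre-empts any strictly ancestral candidate
  (nearest-event rule).  `SubstitutionHistory(same_branch_pairs=False)`
  excludes same-branch pairs instead.
* τ defaults to the trailing site's expected waiting time, total tree
  length divided by that site's event count; a global constant can be set
  through `EpistatConfig.tau`.
* Sites with fewer than two events carry no pairwise signal and are
  excluded from analysis.

## The null model

The null preserves the number of substitutions at every site and on every
branch exactly and is sampled by curveball trades on the bipartite
site-by-branch incidence matrix (a pair of sites exchanges a random
subset of the branches unique to either; row and column sums are
invariant by construction — asserted in tests for every sample).  Between
retained samples the chain performs 5·S trades (S = number of analyzed
sites), with a 4× longer initial burn-in; curveball trades move many
entries at once, so this is comfortably past the mixing estimates in the
rewiring literature.  Amino-acid identities are not permuted; statistics
that depend on them (MAP) are simply not evaluated on rewired histories.

p-values use the add-one permutation form (r+1)/(n+1) so that ties count
toward both tails and no p-value is zero.  The z-score of an unordered
pair is computed from the null distribution of the *sum* of its two
ordered statistics on the same rewired ensemble.

**FDR.**  A separate batch of rewired replicates is treated as pseudo-data
and scored against the null ensemble exactly like the data, giving pseudo
p-values on the same discrete grid.  FDR(p) is the mean number of pseudo
findings at nominal level p divided by the number of data findings; the
reported threshold is the largest observed p with FDR below the target
(0.3 by default), and graph edges additionally require p below 0.05.
Using members of the null ensemble themselves as pseudo-data would make
the data's smallest attainable p-value unreachable by any pseudo-set and
manufacture FDR = 0 thresholds on pure noise; the disjoint-batch design
avoids this.

**Hemiplasy weighting.**  With bootstrap supports available, branches with
support > 95 are "well resolved"; removing them splits the tree into
poorly resolved subtrees, and a site reconstructed with n ≥ 2 events
inside one subtree has each event down-weighted to 1/n (events on
well-resolved branches, including terminal branches, keep weight 1).
When the weighting is enabled, every rewired replicate is re-weighted by
the same rule — the null is the full pipeline applied to rewired data.
Carrying the data's weights onto rewired placements instead deflates the
data relative to the null (weights correlate with the data's event
co-location) and was measured to produce large spurious discordant
excesses; it is not offered.

## From statistics to graphs

Pseudo-correlations are the unordered-pair z-scores divided by the global
maximum |z|, so both tails share one scale and values lie in [−1, 1].
Partial correlations shrink the pseudo-correlation matrix toward the
identity (λ = 0.9), invert, and rescale; because a pseudo-correlation
matrix need not be positive definite, λ is stepped toward 1 in halvings
of (1−λ) in the rare case the shrunk matrix is numerically singular.
The association statistic is the partial correlation clipped below at 0
for positively pseudo-correlated pairs and the pseudo-correlation itself
for negative ones.

The signed coevolution graph connects pairs whose direction-appropriate
p-value passes min(0.05, FDR threshold); positive edges are weighted by
the association statistic, negative ones by the pseudo-correlation.
Coevolving groups maximize signed modularity Q = Q_pos − Q_neg (each term
a configuration-model modularity of one sign's subgraph, equally
weighted) by Louvain-style greedy moves with node aggregation,
deterministic under a fixed seed, best of 10 restarts, ties broken toward
the lowest group id.  Singleton groups are retained.

## Clustering of non-consecutive substitutions and MAP

The clustering z-score compares the observed mean patristic distance
between non-consecutive cross-site events with the same margin-preserving
null (200 replicates by default), sign-inverted so positive means closer
than expected.  Together with the association statistic it separates
epistasis from additive episodic selection: episodes cluster all
substitutions, epistasis only consecutive ones.

The mutual allele preference (MAP) asks whether the derived allele at a
trailing site depends on the derived allele that most recently arose at
the leading site on its root path (strictly above; same-branch leading
events define no background because their order is unobservable).  For a
combination (background allele A, trailing ancestral b, trailing derived
B) the statistic is P(lead→A)·P(B | A, b) + P(lead→¬A)·P(¬B | ¬A, b),
averaged over the observed combinations that satisfy the positivity
constraints (both backgrounds and both outcomes present among trailing
substitutions from b).  Restricting the average to *observed* allele
combinations is what makes 1 the exact value for perfect association and
0.5 the value under independence; averaging over all marginally defined
combinations would score the symmetric perfect case 0.5.  An undefined
MAP (no admissible combination) is reported as missing, never as 0.

## Structure mapping and enrichment

Alignment columns map to residues by global affine alignment (BLOSUM62,
gap open −11 / extend −1) of the gap-stripped reference row against the
chain sequence, with a 90% identity floor as a wrong-chain guard.
Contacts are heavy-atom pairs closer than 4 Å.  Relative accessibility is
Shrake–Rupley SASA divided by the Tien et al. (2013) theoretical maximum
per residue type; buried means < 5% in the isolated subunit, contact
means any heavy atom within 4 Å of another chain, exposed non-contact
interface (ENC) means complex accessibility more than 0.1 percentage
point below the isolated value, the remainder is surface.  Buried
residues are excluded from the interface analysis; the contact-density
analysis keeps them by default (pass a contact graph restricted to
non-buried sites to apply the stricter behavior).

Contact-density p-values permute group labels over contact-graph nodes.
Interface enrichment is tested against random subgraphs of the contact
graph matched to the testing subset's vertex count and spatial
clustering: per connected component, a random connected subgraph of the
same size is grown (uniform frontier expansion) and rejected unless it
has at least as many edges, components are vertex-disjoint, a component
that fails 10000 trials triggers a one-step back-off, and a global budget
of 100 back-offs guarantees termination.  Group-level overlap is the
Jaccard index with upper/lower sample p-values; the table-level
chi-square uses sample-mean expected counts and the sampled chi-square
null.

## Episodic rate shifts and concordance

A pre-order traversal keeps a "current ancestor".  At each internal
branch the per-group substitution counts of the clade below it are
compared with the rest of the current ancestor's clade (groups without
events in that clade dropped) by Pearson chi-square, or by a Monte-Carlo
exact test (fixed-margin tables sampled with `scipy.stats.random_table`,
table-probability statistic, 1e5 draws by default) when any expected cell
is below 5.  Bonferroni correction uses the number of branches actually
tested; a significant branch becomes the new current ancestor; subtrees
with at most as many events as groups are not descended into.  The
cross-protein concordance test re-addresses each shift to its parental
branch, keeps branches testable in every protein, and permutes each
protein's shift count over parental branches with probability
proportional to the summed lengths of the two daughter branches, without
replacement (10000 permutations).

## Synthetic data: what it emulates and what it does not

Three generative regimes mirror the published validation experiments, and
a planted-history generator supports direct unit tests.

* **Pairwise epistasis** (`EpistasisSimConfig`): haploid Wright–Fisher,
  100 binary sites, 10 positive pairs (single mutants at fitness 0.9945,
  double restored to 1), 10 negative pairs (double mutant at 0.8), 60
  neutral sites; full scale N = 50000, 5000 generations, μ = 5e-4, 50
  genotypes sampled every 250 generations.  The desk preset shrinks N to
  2000 and scales μ and log-fitnesses up 25-fold, preserving N·μ = 25,
  N·s and the valley-suppression ratio s/μ; the sampling schedule and
  generation count stay at the printed values.
* **Clonal interference** (`CloneSimConfig`): one preferred amino acid
  per site (others at fitness 0.9), random unfit start, N = 10000, 566
  sites, μ = 2e-5 at full scale; desk preset N = 1000, 100 sites,
  μ = 2e-4 (N·μ preserved), 1500 generations, 2 genotypes every 40.
* **Fluctuating landscapes** (`LandscapeSimConfig`): per-site 20-allele
  lognormal (σ = 0.25) fitness vectors redrawn at Poisson change points
  (rate 0.5 per branch-length unit) independently along lineages, with
  origin–fixation substitution dynamics between change points
  (n_eff = 1e4 so each adaptive burst completes within a branch).  The
  desk tree is a 300-leaf Yule tree scaled to total length 40, giving the
  printed ~20 landscape changes per site *and* under one change per
  root-to-tip path — the regime of a broad species phylogeny.  A deep,
  narrow tree instead stacks several changes on single paths; the
  resulting same-site burst chains block cross-site consecutive pairs and
  fake a systematic discordance that a broad tree does not produce.

The Wright–Fisher simulators can return the **exact sample genealogy**
(lineage tracing with true mutation placements, branch lengths in
generations × μ).  The ground-truth test bed runs the statistics on these
exact genealogies.  What passing those tests shows: the statistic, null,
FDR and ranking machinery recover planted interactions and stay silent on
independent-site and hitchhiking histories *given a correct substitution
map*.  What they do not show: robustness to tree-reconstruction error.
A desk-scale reconstruction path is provided (FastTree with SH supports
rescaled to percent, or neighbor joining, plus Fitch parsimony and
optional hemiplasy weighting), but two-state desk-scale alignments are
mutationally saturated and approximate reconstruction co-locates parallel
changes, which at this scale measurably inflates the concordant tail of
the null calibration — a reconstruction artifact, not a property of the
statistic (hub pairs with z ≈ 6 on the reconstructed tree score z ≈ −2 on
the true genealogy).  The published full-scale analyses used RAxML trees
with MEGA ML ancestral states on 4350 taxa, a fidelity regime outside a
desk budget.

Known limitation, stated plainly: at desk data volumes the λ = 0.9
partial-correlation step separates direct from indirect positive pairs
only marginally.  Planted positive pairs occupy the top pseudo-correlation
ranks with z ≈ 10–13 against a noise ceiling of ≈ 3.9 (the expected
maximum of ~5000 null order statistics), but their partial correlations
(~0.02–0.08) sit near the noise pairs' (~0.02), so the association-
statistic top-8 is clean in some runs and diluted in others.  The margin
widens linearly with the data's z scale, which is ~10× larger at the full
published data volume.

## Numerical choices

* Problem sizes: pair analyses use 1000 null replicates plus 200
  pseudo-data replicates (published analysis: 10000 and 400); clustering
  z-scores 200; rate-shift Monte-Carlo 1e5 draws (smaller in unit tests);
  concordance 10000 permutations.  Ranking and zero-findings results were
  stable between 250 and 2000 replicates on the test bed.
* The all-ordered-pairs statistic is computed in one depth-first pass
  (per site, the most recent event on the current root path determines
  pairing and blocking); a numba kernel carries the load and the pure
  NumPy implementation is kept as the reference oracle, asserted equal.
* Degenerate inputs: empty pair lists are valid (statistic 0); a null
  with zero variance reports z = 0; clustering is undefined (raises)
  without non-consecutive pairs; MAP returns None when no combination is
  admissible; an edgeless coevolution graph yields singleton groups and an
  all-zero-weight graph a single flagged group.
* Determinism: one master seed; every stochastic component consumes an
  `numpy.random.default_rng` stream derived from it; partitioning ties
  break toward the lowest node id.
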