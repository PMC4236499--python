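# Methods

## The encoding and its identifiability limits

A genome is a set of chromosomes, each an ordered list of signed gene
identifiers; a chromosome is linear or circular. Adjacencies are
canonicalized under the reverse-strand identity (i, j) ≡ (−j, −i) by
picking the ordered representation whose first element is smaller under
the total order o < … < −2 < −1 < 1 < 2 < …; a right telomere (k, o) is
therefore stored as (o, −k). `build_encoding` produces one column per
distinct canonical adjacency/telomere observed in at least one genome
(in first-observation order, for deterministic bootstraps) followed by
one column per gene family in ascending id order.

Copy numbers are deliberately collapsed to presence/absence. With
duplicated genes the map from genomes to encodings is consequently not
one-to-one — e.g. the linear genomes [1,2,1] and [1,2,1,2,1] share an
encoding (this is asserted as a test). For duplication-free genomes the
adjacency set determines the genome up to chromosome order and
whole-chromosome flips; `decode_genome` implements that inverse and the
property is tested on simulator output.

## The transition model

One uniformly chosen DCJ on a genome with n genes and O(1) chromosomes
destroys a fixed present adjacency with probability 2/(n+O(1)) — on a
single linear chromosome exactly 2/(n+1), which the test suite verifies
by exhaustive enumeration of all (cut-pair, rejoin) outcomes — while a
fixed absent adjacency, one of up to binom(2n+2, 2) possibilities, is
created with probability 2/(2n²+O(n)). The package keeps only the
operative consequence, the loss/gain ratio r = 2n, and embeds it in a
two-state continuous-time chain; branch lengths absorb the event counts.
Concretely:

- gain rate q01 = (1+r)/(2r), loss rate q10 = r·q01 = (1+r)/2;
- stationary distribution π = (r/(1+r), 1/(1+r));
- normalization 2·π0·q01 = 1: one unit of branch length equals one
  expected change per character at stationarity;
- closed-form P(t): P01(t) = π1(1−e^(−(q01+q10)t)), etc.

Choices made where the design was open: no rate heterogeneity across
characters, and gene-family columns evolve under the same chain as
adjacency columns (no separate gain/loss value is available for genes).
The ratio r can be overridden per analysis but is never estimated from
data.

## Likelihood machinery and numerics

Felsenstein pruning runs vectorized over characters with per-node,
per-character rescaling of conditional likelihoods (log scales
accumulated separately), so underflow cannot occur even with hundreds of
characters and near-zero branches. The root prior is the stationary
distribution; the chain satisfies detailed balance, so the likelihood is
root-invariant (tested by rerooting, not assumed).

Branch lengths are optimized coordinate-wise. Each edge's 1-D objective
is assembled from the downward partial below the edge and the outward
partial above it, so one objective evaluation costs O(characters). The
natural time scale puts optima around 10⁻³–10⁻² while the likelihood
plateaus above ~0.5, so the bracketed minimization first runs on a log
scale over [10⁻⁹, t_max] and then refines linearly around the located
basin (tolerance 10⁻⁶ per branch by default, 10⁻⁸ for pairwise
distances). Pairwise ML distances saturate at a configurable cap
(default 5 expected changes); a pair is reported at the cap when the cap
is as likely as the located optimum to machine precision.

The topology search is NJ (on pairwise ML distances) followed by NNI
hill climbing: all neighbors of every internal edge are evaluated with a
short branch-optimization schedule (3 sweeps), the best strictly
improving neighbor is accepted and fully re-optimized, and the climb
stops when no neighbor improves. SPR/TBR moves are out of scope; on the
simulated study conditions NJ alone already recovers most topologies and
NNI corrects the remainder, which the recovery experiments quantify.
Ties are resolved deterministically by traversal order; the whole search
is deterministic given the input order and the recorded seed.

Neighbor joining itself and the majority-rule consensus utility are
delegated to scikit-bio and dendropy respectively (negative NJ branch
estimates are clamped to zero); Newick parsing is delegated to dendropy,
serialization is in-package with branch lengths at 10 significant
digits.

## Ancestral reconstruction

Marginal posteriors follow the standard marginal reconstruction scheme:
one downward pass (conditional likelihood of the data below each node)
and one outward pass (likelihood of everything outside the subtree,
including the root prior), multiplied and normalized per node and
character. The tree must be rooted for node identities; when the user
does not name a root the package roots at the midpoint of the longest
leaf-to-leaf path (the likelihood itself is root-invariant).

Gene content uses the strict >50% rule: a family is present iff its
posterior exceeds the threshold strictly (0.50 itself is absent).
Candidate adjacencies touching an absent gene are dropped (logged) so
the TSP matching invariant holds.

The assembly instance has two vertices (head, tail) per present gene
plus 2L caps, where L = max(1, round(Σ telomere posteriors / 2)).
Candidate adjacency edges weigh −ln(max(p, ε)) with ε = 10⁻⁶ by default;
non-candidate extremity pairs weigh −ln ε; cap–cap edges are free; each
gene's head–tail edge carries a reward −B with B exceeding the sum of
all other edge magnitudes, so every optimal tour keeps all genes intact.
Cutting the optimal tour at caps yields linear chromosomes, with entry
extremity fixing each gene's sign. Instances of up to 18 vertices are
solved exactly by Held–Karp dynamic programming; larger ones by
nearest-neighbor construction from a seeded start plus 2-opt restricted
to moves that never remove a mandatory edge. The heuristic never beats
the exact optimum (tested) and retains every mandatory edge by
construction of the NN start.

Known restrictions: ancestral chromosomes are always linear (the cap
construction cannot close circles), duplicated families contribute a
single copy to assembled ancestors (the presence encoding carries no
copy counts), and the candidate adjacency universe is limited to the
encoding's observed columns — unseen adjacencies enter only through the
ε penalty.

## The simulator and what the experiments show

The generator evolves the identity genome (1..n on the configured
chromosomes) down a tree. Defaults define the study conditions: 12 taxa,
100 genes on one linear chromosome, a fixed 10/3 events per branch (the
fractional part applied as a Bernoulli extra so the mean is exact), of
which 90% are DCJs and the rest split evenly among deletions, insertions
and duplications; segment lengths are geometric with p = 0.5 (short
indels dominate real data); inserted genes always receive fresh family
ids to avoid spurious homology. DCJ cut sites are chosen uniformly over
the genome's current adjacencies and telomeres, matching the model's
uniformity assumption; cut-site pairs admit exactly two rejoinings, so
inversions, translocations, fusions, fissions, excisions and
reintegrations all arise. Every event is logged and replayable; replay
identity is property-tested.

A fixed (rather than Poisson) per-branch event count is used for the
study conditions because a Poisson draw leaves an appreciable fraction
of internal branches with zero events, making exact topology recovery
impossible for any method on those replicates; the fixed count makes
"events per branch" mean what it says. Branch-length-proportional
Poisson counts remain available via `rate_scale` for users who want
clocklike data.

What passing experiments do and do not show: the simulator realizes the
same uniform-DCJ assumption the model is derived from, so recovery rates
here are a best case. Real gene orders feature hotspots, length-biased
inversions, lineage rate variation and orthology assignment errors, none
of which are emulated; the measured ~97% ancestral adjacency recall and
high topology recovery should be read as internal consistency of the
pipeline at moderate divergence, not as field accuracy guarantees. The
bootstrap's character-independence premise — an adjacency once broken is
essentially never re-formed — is measured on simulations (the observed
re-formation fraction is far below 5%) rather than assumed.

## Problem sizes

Default experiment sizes were chosen so the whole suite runs comfortably
on a single CPU: recovery experiments use 20 replicates of 12 taxa x 100
genes; oracle comparisons use 4-6-leaf trees (where exhaustive
enumeration over internal states is exact and fast), 50-character
matrices, and 100 random TSP instances of up to 8 vertices (where all
tours can be enumerated). The exact TSP path is exercised up to its
18-vertex Held-Karp limit.
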