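# Methods

This note documents the models, decision rules, defaults, and numerical
choices behind `exomertrace`, and what the synthetic benchmarks do and do
not establish about real data.

## Gene-family simulator

Gene lineages descend a rooted species tree whose branch lengths are in
expected substitutions/site. Along a branch of length *t*, each lineage
experiences duplication and loss events as a Poisson process with rates
`dup_rate·t` and `loss_rate·t`, realized by exponential waiting times;
a duplication copies the current sequence state, a loss prunes the
lineage. Substitutions follow an equal-exchangeability 20-letter model:
per site, the number of substitution events is Poisson with mean equal to
the elapsed branch length, and each event redraws the residue from the
stationary frequencies (uniform by default, configurable). Model realism
beyond this is deliberately omitted — the downstream divergence statistic
is an uncorrected p-distance, so a multiple-hit-corrected generator would
add parameters without changing what is being tested. No indels are
simulated, so the true alignment of a simulated family is the identity
and the aligner is never a confounder in benchmarks.

The neofunctionalization scenario plants exactly one duplication on the
stem edge of a designated clade; the two daughter copies are labelled
`.bb` and `.bc`, and every lineage descending from the `.bc` copy has its
branch lengths multiplied by `neo_multiplier` (default 2.0, the smallest
acceleration the divergence battery is expected to resolve on deep
trees). Decoy sequences are drawn i.i.d. from the stationary frequencies,
20 per taxon by default, with lengths 0.8–1.2× the family length — the
regime in which the margin rule has non-trivial work to do.

The packaged 12-taxon species tree has three 4-taxon clades (the
duplication-bearing clade A, sister clade B, outgroup clade C) with a
root-to-tip depth of ~0.26 substitutions/site at scale 1.0. Orthology
benchmarks run at this depth (where RBH should be near-perfect);
divergence benchmarks scale branch lengths ×2 (depth ~0.52), where rate
asymmetry is resolvable but identity has not saturated. Ancestral
sequence length defaults to 200 residues, typical of a single structured
domain. All stochastic draws flow from one integer seed; an extinct
family (all lineages lost) is returned flagged, not raised.

If every simulated taxon is its own genus — as with the default tree —
genus balancing keeps exactly the reference taxon's sequences in each
duplicated clade, which is the intended single-genus contrast.

## Search and RBH classification

The built-in pairwise engine is full-matrix affine-gap Smith–Waterman
(BLOSUM62; a gap of length *k* costs `gap_open + k·gap_extend`, defaults
11/1). There is no heuristic seeding: at desk scale the exact quadratic
DP is fast enough, and exactness makes the engine testable against an
independent oracle. E-values come from fitting a right Gumbel
(extreme-value) distribution to the scores of the query against shuffled
database sequences (`null_shuffles` ≥ 100, cycling over the database) and
setting `E(S) = N·P(score ≥ S)` for a database of size N. This is the
same distributional family local-alignment statistics assume; the fit is
per query, so composition effects are absorbed. A degenerate null (all
shuffle scores equal) is an error, not a silent fallback.

Classification follows the bidirectional rules: a forward hit at or below
the family cutoff (inclusive 0.05 for the paralogous family; stringent
1e-40 for the core protein, which has many spurious low-complexity
partial matches in real proteomes) becomes positive only if a reverse
search into at least one reference database returns an established
orthologue-set member as top hit AND the margin rule holds: the top hit's
E-value times 10^`margin_orders` (default 2) must not exceed the E-value
of the best *non-redundant* non-member — a hit that is neither in the set
nor an identical-sequence duplicate of a member. E-values are floored at
1e-180 before taking orders of magnitude, so reported-zero E-values from
external tools remain comparable. With no non-member hit the margin is
+∞. Candidates whose reverse top hit is a robustly annotated non-member
are negative; everything else unresolved is ambiguous, kept distinct from
negative throughout. Ties in rankings break by descending score then
lexical target id, making every classification order-invariant and
reproducible. An optional filter demotes positives lacking a required
domain annotation supplied as an external TSV; the domain scan itself is
out of scope.

## Profile HMMs and the enrichment loop

`build_hmm` uses the textbook plan: alignment columns with gap fraction
strictly below 0.5 become match states; emissions are
`(counts + w·background)/(n + w)` with pseudocount weight *w* (default
1.0); transitions are Laplace-smoothed counts of the observed per-row
M/I/D state paths. Insert states emit the background, so the forward
log-odds score — `log2 P(seq|model)/P(seq|background)`, computed in
log space — charges inserts only their transition costs. The model is
global over its match states (sequences much longer or shorter than the
profile pay insert/delete penalties), which matches the simulator's
indel-free families; a local-envelope mode is a known limitation for
real proteomes with long extensions. The forward DP is vectorized over
model states per residue; delete chains are resolved by an exact
sequential scan within each position.

The iterative loop: build → search all proteomes → reverse-validate each
new hit (its top pairwise hit in the reference proteome must already be
accepted) → insert validated hits into the alignment along their Viterbi
path (match states take the residue, deletions a gap, insert residues are
dropped) → rebuild. Viterbi projection instead of full re-alignment each
round keeps the loop deterministic and cheap; re-running an external
aligner every round is an acceptable alternative backend but is not what
the tests pin down. The loop stops when an iteration validates nothing,
or flags non-convergence at `max_iterations` (default 10). The accepted
set only grows. The default bit threshold is calibrated per run as the
99th percentile of scores on shuffled sequences (decoy acceptance ≤1%);
no universal threshold is claimed.

## Divergence statistics

Distances are uncorrected p-distances with pairwise deletion — on an
untrimmed alignment, complete deletion would discard most columns, so
pairwise deletion is the recorded convention. Percent identity is
(1 − p)×100. Set comparisons exclude identical-id pairs and use the
sample (n−1) SD; a single-pair comparison reports its SD as missing. The
"diverged" verdict requires non-overlapping ±1 SD intervals — an
intentionally conservative, assumption-free criterion rather than a
formal test.

Genus balancing drops members of a *duplicated* clade whose genus differs
from the kept genus, while preduplicate members are always retained:
congeneric sequences are near-identical data points that would otherwise
weight the mean toward one genus. The packaged fungal set definitions
(`taxon_sets.py`) encode this: the balanced BB8 set is the preduplicate
BB8 members plus Bud7/Bch1 of *S. cerevisiae* only, and likewise for BC8.
Ambiguously placed paralogues (the *C. glabrata* case) are assigned to
the preduplicate sets in that packaged config. The tetramer-variant count
is the number of unordered pairs with repetition, n(n+1)/2.

## Trees and Dollo mapping

Neighbor joining is the Saitou–Nei algorithm with deterministic lexical
tie-breaking on the Q-criterion; negative branch-length estimates are
clamped to zero and flagged, and zero-length internal edges are collapsed
into polytomies (so an uninformative matrix yields a star, not an
arbitrary resolution). On additive matrices NJ provably returns the
generating topology, which the tests exploit as an exact oracle.
Bootstrap support is the percentage of column-resampled replicates
containing each internal bipartition; bipartitions are canonicalized by
the side not containing the alphabetically first taxon, so supports are
rooting-invariant, and they are attached to edges of the point-estimate
tree. Full Bayesian/ML inference is out of scope; NJ+bootstrap is the
desk-scale stand-in for monophyly and duplication-order checks, and
duplication order itself is a pure containment rule: for a monophyletic
paralogue clade, the species present in both daughters of its founding
node diverged after the duplication.

Dollo mapping assumes one gain and unlimited losses: the gain sits at the
MRCA of the present tips, losses on every maximal absent subtree below
it. This placement is provably loss-minimal among single-gain histories
(verified against brute force over all gain placements in the tests). A
component forced into ≥5 losses is flagged, since such patterns may
instead indicate multiple gains, which the model excludes by assumption.
Group-level presence uses a k-of-group rule (default: at least 2 member
taxa) with single-representative cases reported separately rather than
silently merged.

## Pipeline and reproducibility

The pipeline runs simulate → search → hmm-iterate → divergence → tree →
dollo, writing TSV/FASTA/Newick artifacts plus a JSON manifest of
per-stage SHA-256 checksums. Dot-plot cells are three-state internally
(present / not identified / not assessed) and collapse to booleans only
on export — absence of evidence stays distinct from evidence of absence.
No artifact contains a timestamp, and all randomness is seeded from the
config, so identical configs produce byte-identical outputs; `resume`
reruns a stage only if its outputs are missing or an upstream stage
reran.

## What the benchmarks show, and don't

The synthetic benchmarks use families with no indels, i.i.d. decoys, a
single planted duplication, and uniform residue frequencies. They
establish that the decision rules and statistics are implemented
correctly and behave as intended under the model's assumptions (near-
perfect RBH recovery at shallow depth; the balanced divergence contrast
resolving a 2× acceleration in ≥90% of deep-tree replicates). They do not
establish performance on real proteomes, where domain shuffling,
low-complexity regions, compositional bias, and alignment error all
degrade both search statistics and p-distances. Reproducing the published
fungal percent-identity values additionally requires the original
sequence sets and aligner, which are external inputs to this package.
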