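# Methods

`cladeprimer` implements a classical group-specific PCR primer-design
workflow for the 16S rRNA gene, together with the downstream clone-library
computations used to validate such primers, and a synthetic-data generator
that makes every stage testable without external databases.

## Consensus construction

The design starts from a multiple alignment of the target clade.  Each
column is summarised by the relative frequencies of the four canonical
bases among its non-gap residues; indels are excluded from the denominator
rather than counted as a fifth state.  Ambiguity codes in input rows
contribute fractionally (1/|base set|) to each of their bases; a config
switch (`ambiguous="drop"`) excludes them from the column count instead.

The threshold consensus (default t = 0.90) encodes, per column, the
minimal-cardinality base subset whose cumulative frequency reaches t, as a
single IUPAC code.  Ties between subsets are broken by higher cumulative
frequency (rounded to 9 decimals so summation order cannot flip an exact
tie), then by lexicographically smaller symbol, making builds
deterministic.  An alternative "inclusion" encoding — every base whose own
frequency is at least 1 − t — is available behind a config switch; the
minimal-set form is the default because it yields the least degenerate
primer alphabet.

Columns that are entirely gaps are always dropped; columns whose gap
fraction exceeds `max_gap_fraction` (default 0.5) are treated as alignment
artifacts and dropped too.  The profile records a consensus-index →
alignment-column map so primer coordinates remain traceable.

## Window extraction and candidate enumeration

A sliding window of 15 nt marks every consensus position that opens a
stretch with at most 2 degenerate positions ("fewer than three").
Overlapping or abutting valid windows are merged into maximal domains, and
every domain substring of 20–30 nt is emitted as a candidate primer,
re-filtered for at most 2 degeneracies — a long substring can straddle two
valid windows yet collect too many ambiguity codes.  Reverse-orientation
candidates are emitted as the reverse complement of the consensus
substring, so both candidate lists hold synthesizable 5'→3' oligos.
Deduplication is by (sequence, consensus start): identical oligos at
different loci are kept for coordinate reporting.

## Mismatch-tolerant scanning

A primer position matches a template position iff their IUPAC base sets
intersect — symmetric semantics, so ambiguity codes in templates (e.g. N)
count as matches.  Matching is ungapped: the scanner minimises the
degenerate-aware Hamming distance over all offsets of the template (both
strands), implemented as a 4-bit base-mask AND over sliding windows.
Equal-mismatch placements resolve to the leftmost plus-strand position.
The scan covers full-length sequences, not just an expected gene region.

A primer *pair* recognises a sequence at allowance k if the forward primer
binds the plus strand entirely upstream of the reverse primer's binding
site with the implied product length inside the pair's bounds (default
50–2000 nt).  The mismatch allowance applies per primer (each within k) by
default; a `summed` mode bounds the total across both primers instead.
Failures carry a reason code (`no_fwd`, `no_rev`, `orientation`,
`length`).

Coverage of a taxon at allowance k is 100 × (recognised sequences)/n over
the taxon's database records, reported at k = 0, 1, 2 (optionally 3);
values are exact internally and rounded to one decimal only in reports.

## Pair selection

Candidate pairs are pruned by consensus coordinates (forward upstream of
reverse; implied product length within bounds) and scored

    score = coverage_in(mm_sel) − λ · coverage_out(mm_spec)

with mm_sel = 1, mm_spec = 2, λ = 1 by default — an explicit stand-in for
the informal goal of wide in-group coverage with high specificity.  Equal
scores break toward (1) higher in-group coverage at 0 mismatches, (2)
fewer total degeneracies, (3) shorter combined length, (4) leftmost
coordinates.  The zero-mismatch key is deliberate: primers that match
every target exactly amplify more reliably than primers leaning on the
mismatch allowance, and in simulations it is what separates a truly
conserved signature from regions that reach the same score only at k ≥ 1.
A single-primer prefilter (top 40 per orientation by in-group coverage,
ties preferring upstream forward / downstream reverse loci) keeps the pair
search tractable; `top_n=0` disables it for an exhaustive search.

## In-silico and nested PCR

Amplicons are reported for every orientation- and length-valid
(forward site, reverse site) combination: 1-based inclusive span from the
forward primer's first base to the last base of the reverse site, with
`length = end − start + 1`.  Product termini carry the primer sequences
verbatim (as in a real PCR product, IUPAC codes preserved); a config
option resolves degenerate positions to the template base where they
match.  The packaged pair's reference coordinates (326–350 / 758–785)
give the worked product length 785 − 326 + 1 = 460 bp.  Nested PCR applies
the inner pair to each outer product, retaining provenance.

## Clone-library analysis

Pairwise similarity is computed by optimal global alignment (biopython's
`PairwiseAligner`) with match +1, mismatch −1, gap open −2 (first gapped
column), gap extend −1.  Percent identity counts identical columns over
the span between the first and last column where both sequences have a
residue — terminal gaps are excluded so partial-length clones are not
penalised.  Caveat: under this definition a sequence and a strict prefix
of it score 100%.

Database searches (`top_hits`, `classify`) additionally make terminal
gaps free during alignment (overlap alignment): with penalised end gaps,
the optimal *global* alignment of a 460 nt amplicon against a 1.2 kb
reference scatters the clone across the full reference and the identity
becomes meaningless.  Queries are orientation-normalised by aligning both
strands and keeping the higher-*scoring* one — score, not identity,
because a near-empty overlap can reach a vacuous 100% identity.  Hits
must also cover at least half the query.  Up to k = 20 hits at ≥ 80%
identity are retained, ordered by identity then reference id.

Consensus taxonomy descends from 99% in 1-point steps until some hits
reach the working threshold, restricts to those hits, and assigns the
deepest rank (Domain > Phylum > Class > Order > Family > Genus) on which
all of them agree; lineages shallower than a rank block agreement at it.
Queries with no hit at ≥ 80% are unassigned.  Degenerate edge: if
retained hits agree at no rank at all (not even domain), the query is
reported unassigned at that threshold.

OTUs are built by agglomerative average linkage on the distance
100 − identity, cut where the next merge exceeds 100 − cutoff (default
97%).  Cluster–cluster distances follow the exact Lance–Williams update;
equal-distance merges pick the pair whose combined sorted member-id tuple
is lexicographically smallest, so partitions are deterministic.  The
implementation is in-package because this tie-break is part of the
contract; scipy's average linkage serves as an independent cross-check in
the tests.

Rarefaction uses the hypergeometric closed form
E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n)) with exact integer binomials (the
all-singleton case is exactly E[S_n] = n), or seeded Monte-Carlo
subsampling without replacement, which reports the standard error of its
mean.

## Synthetic data

The generator emulates a SILVA-style hierarchical database: a random root
radiates into phyla, genera and strains with i.i.d. substitutions at
per-level rates (defaults 0.15 / 0.08 / 0.01 — roughly the 16S divergence
of between-phylum, between-genus and within-genus comparisons; no indels,
matching the ungapped scanner).  One phylum carries a two-site primer
signature planted exactly in every member: by default the packaged pair's
sites at their reference coordinates (forward at 326; reverse site ending
at 785, so the true product is 460 bp), with the reverse primer's
degenerate position instantiated as C.  Every out-group sequence carries
both sites with exactly `decay` (default 4) substitutions, injected at
evenly spaced interior positions — placed so that any sub-window of
≥ 20 nt of either site contains at least decay − 1 of them, which makes
out-group exclusion at ≤ 2 mismatches a property of the construction, not
of the random draw.  A truth table (site coordinates, decay counts,
lineages) accompanies every database so tests never re-derive ground
truth from FASTA.

Clone libraries sample templates from weighted taxa, trim them to the
primer pair's first predicted product when a pair is given, add per-clone
substitutions, and optionally trim ends.  All generators are
bit-reproducible under a fixed seed.

What the generator does **not** emulate: indel evolution, rRNA secondary
structure and covariation, chimeras, compositional bias, and the extreme
taxon-size imbalance of real reference databases.  Passing tests
therefore demonstrate algorithmic correctness and recoverability of a
planted signal under substitution noise — not primer performance against
real 16S diversity.

## Problem sizes and numerics

Shipped analyses run at desk scale: planted databases of 3 phyla × 4
genera × 10 strains × 1.2 kb, clone libraries of ~40–50 members, oracle
sweeps of a few hundred random instances.  Frequency/threshold
comparisons carry a 1e-9 tolerance; coverage values are exact fractions of
integer counts.  The annealing-temperature helper (Wallace rule, mean
over degenerate expansions) is an unvalidated convenience, provided
because primer reports conventionally carry a Tm column.

## Known limitations

* Ungapped scanning cannot model primer sites containing indels.
* Identity under terminal-gap stripping is not a metric; prefix/extension
  pairs score 100%.
* The pair-selection prefilter is heuristic; exhaustive search is
  available but quadratic in the candidate count.
* Average-linkage clustering is O(n³) in the worst case — fine for clone
  libraries of hundreds, not for amplicon surveys of millions.
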