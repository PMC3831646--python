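"""Clone-library analysis: similarity search, consensus taxonomy, OTUs, rarefaction.

Clone sequences from a group-specific PCR are characterised in four steps:

1. global (Needleman-Wunsch) alignment of each clone against every
   reference, keeping the top hits above a similarity cutoff (default 20
   hits at >=80% identity);
2. step-wise consensus taxonomy: starting at 99% and descending one
   percentage point at a time to 80%, stop at the first threshold with
   hits and assign the deepest rank on which *all* retained hits agree;
3. average-linkage agglomerative clustering of the clones into OTUs at a
   similarity cutoff (97% by default, sweepable 85-100%);
4. rarefaction of the OTU partition — the expected number of OTUs in a
   random subsample of n clones, analytically (hypergeometric closed
   form) or by seeded Monte-Carlo subsampling.

Percent identity is computed over alignment columns after stripping
terminal-gap columns, so partial-length clones are not penalised for
missing ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from Bio import Align

from .database import RANKS, ReferenceDatabase
from .iupac import reverse_complement
from .scan import _as_seq


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine global-alignment scoring (match/mismatch, gap open/extend).

    With ``free_end_gaps`` terminal gaps cost nothing (overlap alignment)
    — the right mode when comparing partial-length clones against
    full-length references; the database search uses it by default.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0  # cost of the first gapped column
    gap_extend: float = -1.0
    free_end_gaps: bool = False


#: Overlap-alignment scoring used for clone-vs-reference searches.
SEARCH_SCORING = AlignmentScoring(free_end_gaps=True)


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if scoring.free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # biopython < 1.88 attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class GlobalAlignmentResult:
    aligned_a: str
    aligned_b: str
    identity_pct: float
    score: float


def global_similarity(
    a, b, scoring: AlignmentScoring = AlignmentScoring()
) -> GlobalAlignmentResult:
    """Optimal global alignment and percent identity of two sequences.

    Identity = 100 x (identical columns) / (columns between the first and
    last column where both sequences have a residue) — terminal gaps are
    excluded from the denominator.
    """
    _, sa = _as_seq(a)
    _, sb = _as_seq(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    aln = aligner.align(sa, sb)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    first = 0
    last = len(row_a) - 1
    while first <= last and (row_a[first] == "-" or row_b[first] == "-"):
        first += 1
    while last >= first and (row_a[last] == "-" or row_b[last] == "-"):
        last -= 1
    span = last - first + 1
    if span <= 0:  # degenerate: alignments of nonempty seqs always overlap somewhere
        return GlobalAlignmentResult(row_a, row_b, 0.0, float(aln.score))
    ident = sum(
        1 for i in range(first, last + 1) if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    return GlobalAlignmentResult(row_a, row_b, 100.0 * ident / span, float(aln.score))


@dataclass(frozen=True)
class Hit:
    ref_id: str
    lineage: tuple[str, ...]
    identity_pct: float


@dataclass(frozen=True)
class HitList:
    query_id: str
    hits: tuple[Hit, ...]


def _aligned_span(res: GlobalAlignmentResult) -> int:
    sa, sb = res.aligned_a, res.aligned_b
    first, last = 0, len(sa) - 1
    while first <= last and (sa[first] == "-" or sb[first] == "-"):
        first += 1
    while last >= first and (sa[last] == "-" or sb[last] == "-"):
        last -= 1
    return last - first + 1


def top_hits(
    query,
    refdb: ReferenceDatabase,
    k: int = 20,
    cutoff_pct: float = 80.0,
    *,
    orient: bool = True,
    scoring: AlignmentScoring = SEARCH_SCORING,
    min_overlap_frac: float = 0.5,
) -> HitList:
    """Up to k references at or above the similarity cutoff, best first.

    Queries are orientation-normalised when ``orient`` is set: both the
    query and its reverse complement are aligned and the higher-*scoring*
    strand kept (score, not identity — with free end gaps a near-empty
    overlap can reach a meaningless 100% identity).  Hits must also cover
    at least ``min_overlap_frac`` of the query.  Equal identities are
    ordered by reference id for determinism.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    qid, qseq = _as_seq(query)
    rc = reverse_complement(qseq) if orient else None
    min_span = min_overlap_frac * len(qseq)
    scored: list[Hit] = []
    for rec in refdb:
        res = global_similarity(qseq, rec.sequence.residues, scoring)
        if rc is not None:
            res_rc = global_similarity(rc, rec.sequence.residues, scoring)
            if res_rc.score > res.score:
                res = res_rc
        if _aligned_span(res) < min_span:
            continue
        if res.identity_pct + 1e-9 >= cutoff_pct:
            scored.append(Hit(rec.id, rec.lineage, res.identity_pct))
    scored.sort(key=lambda h: (-h.identity_pct, h.ref_id))
    return HitList(qid, tuple(scored[:k]))


@dataclass(frozen=True)
class TaxonomyAssignment:
    query_id: str
    assigned_rank: str | None
    assigned_name: str | None
    threshold_used: float | None
    status: str  # "assigned" | "unassigned"
    best_identity: float | None = None


def consensus_taxonomy(
    hits: HitList, start_pct: float = 99.0, floor_pct: float = 80.0, step: float = 1.0
) -> TaxonomyAssignment:
    """Step-wise consensus taxonomy over a hit list.

    Descend from ``start_pct`` in steps of ``step`` until some hits reach
    the working threshold; restrict to those hits and assign the deepest
    rank at which they all agree (lineages shallower than a rank block
    agreement at it).  No hit at or above ``floor_pct`` leaves the query
    unassigned.
    """
    best = max((h.identity_pct for h in hits.hits), default=None)
    if best is None or best + 1e-9 < floor_pct:
        return TaxonomyAssignment(hits.query_id, None, None, None, "unassigned", best)
    t = start_pct
    while t - 1e-9 > best:
        t -= step
    t = max(t, floor_pct)
    sel = [h for h in hits.hits if h.identity_pct + 1e-9 >= t]
    for depth in range(len(RANKS) - 1, -1, -1):
        if any(len(h.lineage) <= depth for h in sel):
            continue
        names = {h.lineage[depth] for h in sel}
        if len(names) == 1:
            return TaxonomyAssignment(
                hits.query_id, RANKS[depth], names.pop(), t, "assigned", best
            )
    # Hits exist above threshold but agree at no rank at all.
    return TaxonomyAssignment(hits.query_id, None, None, t, "unassigned", best)


def classify(
    queries,
    refdb: ReferenceDatabase,
    k: int = 20,
    cutoff_pct: float = 80.0,
    start_pct: float = 99.0,
    floor_pct: float = 80.0,
    step: float = 1.0,
    *,
    orient: bool = True,
) -> list[TaxonomyAssignment]:
    """Hit retrieval + consensus taxonomy for a batch of query sequences."""
    out = []
    for q in queries:
        hl = top_hits(q, refdb, k=k, cutoff_pct=cutoff_pct, orient=orient)
        out.append(consensus_taxonomy(hl, start_pct, floor_pct, step))
    return out


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OTUPartition:
    cutoff_pct: float
    clusters: tuple[tuple[str, ...], ...]  # each sorted; largest first
    linkage: str = "average"

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.clusters)


def average_linkage_partition(
    dist: np.ndarray, ids: list[str], max_dist: float
) -> tuple[tuple[str, ...], ...]:
    """Agglomerative average linkage, cut where the merge distance exceeds max_dist.

    Cluster-cluster distances follow the exact Lance-Williams update for
    average linkage.  Equal-distance merges pick the pair whose combined,
    sorted member-id tuple is lexicographically smallest, so dendrograms
    (and partitions) are deterministic.
    """
    n = len(ids)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    members: list[tuple[str, ...] | None] = [(i,) for i in ids]
    sizes = [1] * n
    d = dist.astype(float).copy()
    active = set(range(n))
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                merged = tuple(sorted(members[i] + members[j]))
                key = (d[i, j], merged)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dij, _), i, j = best
        if dij > max_dist + 1e-9:
            break
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        members[i] = tuple(sorted(members[i] + members[j]))
        sizes[i] = ni + nj
        members[j] = None
        active.remove(j)
    clusters = [members[i] for i in sorted(active)]
    clusters.sort(key=lambda c: (-len(c), c))
    return tuple(clusters)


def pairwise_identity_matrix(
    seqs, scoring: AlignmentScoring = AlignmentScoring()
) -> tuple[list[str], np.ndarray]:
    """Symmetric percent-identity matrix over (id, sequence) pairs."""
    pairs = [_as_seq(s) for s in seqs]
    ids = [p[0] for p in pairs]
    n = len(pairs)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = global_similarity(pairs[i][1], pairs[j][1], scoring).identity_pct
            ident[i, j] = ident[j, i] = v
    return ids, ident


def cluster_otus(
    seqs, cutoff_pct: float = 97.0, scoring: AlignmentScoring = AlignmentScoring()
) -> OTUPartition:
    """Average-linkage OTUs at a similarity cutoff (distance = 100 - identity)."""
    pairs = [_as_seq(s) for s in seqs]
    if not pairs:
        raise ValueError("no sequences to cluster")
    if len(pairs) == 1:
        return OTUPartition(cutoff_pct, ((pairs[0][0],),))
    ids, ident = pairwise_identity_matrix(seqs, scoring)
    clusters = average_linkage_partition(100.0 - ident, ids, 100.0 - cutoff_pct)
    return OTUPartition(cutoff_pct, clusters)


def cluster_from_distances(
    dist: np.ndarray, ids: list[str], cutoff_pct: float = 97.0
) -> OTUPartition:
    """OTU partition from a precomputed percent-distance matrix."""
    clusters = average_linkage_partition(dist, ids, 100.0 - cutoff_pct)
    return OTUPartition(cutoff_pct, clusters)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RarefactionCurve:
    sample_sizes: tuple[int, ...]
    expected_otu_counts: tuple[float, ...]
    method: str  # "analytic" | "monte_carlo"
    replicates: int | None = None
    seed: int | None = None
    std_errors: tuple[float, ...] | None = None


def rarefaction(
    partition: OTUPartition,
    sizes,
    method: str = "analytic",
    replicates: int = 1000,
    seed: int | None = None,
) -> RarefactionCurve:
    """Expected OTU richness in random subsamples of the clone library.

    Analytic: E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)) with exact
    integer binomials (so the all-singleton case gives exactly n).
    Monte-Carlo: mean OTU count over seeded subsamples drawn without
    replacement, with the standard error of that mean attached.
    """
    counts = list(partition.sizes)
    N = sum(counts)
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s < 0 or s > N:
            raise ValueError(f"subsample size {s} outside [0, {N}]")
    if method == "analytic":
        expected = []
        for n in sizes:
            denom = math.comb(N, n)
            e = sum(1 - Fraction(math.comb(N - Ni, n), denom) for Ni in counts)
            expected.append(float(e))
        return RarefactionCurve(tuple(sizes), tuple(expected), "analytic")
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(counts)), counts)
        means, ses = [], []
        for n in sizes:
            obs = np.empty(replicates)
            for r in range(replicates):
                sub = rng.choice(labels, size=n, replace=False)
                obs[r] = np.unique(sub).size
            means.append(float(obs.mean()))
            ses.append(float(obs.std(ddof=1) / math.sqrt(replicates)) if replicates > 1 else 0.0)
        return RarefactionCurve(
            tuple(sizes), tuple(means), "monte_carlo", replicates, seed, tuple(ses)
        )
    raise ValueError(f"unknown rarefaction method {method!r}")
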