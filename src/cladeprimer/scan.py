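"""Mismatch-tolerant primer scanning, coverage tables, and in-silico PCR.

The scanner slides a degenerate primer along every ungapped offset of a
template and counts mismatches, where a primer position matches a
template position iff their IUPAC base sets intersect.  On top of that
primitive sit:

* per-sequence recognition of a primer *pair* (forward binds the plus
  strand upstream of the reverse-primer site, product length within
  bounds), with a configurable mismatch-allocation mode — ``per-primer``
  (each primer within k mismatches; default) or ``summed`` (total across
  both primers within k);
* taxon-by-taxon coverage tables at several mismatch allowances (the
  coverage/specificity report);
* exhaustive scoring and ranking of candidate primer pairs against a
  labelled database (wide in-group coverage, low out-group coverage);
* amplicon prediction and nested (two-round) PCR simulation.

Sequences are encoded as 4-bit base masks so the per-offset mismatch
profile is a vectorised AND + popcount-style reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import CandidatePrimer
from .database import NucleotideSequence, ReferenceDatabase
from .iupac import (
    DegeneratePrimer,
    IUPAC_TO_BASES,
    InvalidAlphabetError,
    reverse_complement,
)

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_TO_BASES.items()
}

_LUT = np.zeros(256, dtype=np.uint8)
for _sym, _mask in _CODE_MASK.items():
    _LUT[ord(_sym)] = _mask
    _LUT[ord(_sym.lower())] = _mask
_LUT[ord("U")] = _BASE_BIT["T"]
_LUT[ord("u")] = _BASE_BIT["T"]


def seq_to_mask(sequence: str) -> np.ndarray:
    """Encode an IUPAC string as a uint8 array of 4-bit base-set masks."""
    try:
        raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise InvalidAlphabetError(sequence[exc.start], exc.start) from None
    masks = _LUT[raw]
    bad = np.flatnonzero(masks == 0)
    if bad.size:
        i = int(bad[0])
        raise InvalidAlphabetError(sequence[i], i)
    return masks


def mismatch_profile(primer_mask: np.ndarray, template_mask: np.ndarray) -> np.ndarray:
    """Mismatch count at every ungapped offset (empty if primer is longer)."""
    lp = primer_mask.size
    if lp > template_mask.size:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, lp)
    return ((windows & primer_mask) == 0).sum(axis=1)


def _as_seq(template) -> tuple[str, str]:
    """Accept NucleotideSequence or (id, residues) or bare string."""
    if isinstance(template, NucleotideSequence):
        return template.id, template.residues
    if isinstance(template, tuple):
        return template[0], template[1]
    return "", template


def _primer_seq(primer) -> str:
    if isinstance(primer, (DegeneratePrimer, CandidatePrimer)):
        return primer.sequence
    return primer


@dataclass(frozen=True)
class RecognitionResult:
    """Best placement of a primer on one strand of a template."""

    sequence_id: str
    min_mismatches: float  # int, or math.inf when no placement exists
    best_position: int | None  # 0-based start of the site on the plus strand
    strand: str  # "plus" | "minus"


def min_mismatches(primer, template, strand: str = "plus") -> RecognitionResult:
    """Minimum degenerate-aware Hamming distance over all ungapped offsets.

    For ``strand="minus"`` the primer is compared against the reverse
    complement; the reported position is still the site's 0-based start on
    the plus strand.  Equal-mismatch ties resolve to the smallest
    plus-strand position.  A primer longer than the template yields
    ``min_mismatches = inf`` with no position.
    """
    if strand not in ("plus", "minus"):
        raise ValueError(f"bad strand {strand!r}")
    sid, residues = _as_seq(template)
    pseq = _primer_seq(primer)
    scanned = residues if strand == "plus" else reverse_complement(residues)
    prof = mismatch_profile(seq_to_mask(pseq), seq_to_mask(scanned))
    if prof.size == 0:
        return RecognitionResult(sid, math.inf, None, strand)
    m = int(prof.min())
    offs = np.flatnonzero(prof == m)
    if strand == "plus":
        pos = int(offs[0])
    else:  # smallest plus-strand start = largest offset on the rc
        pos = len(residues) - (int(offs[-1]) + len(pseq))
    return RecognitionResult(sid, m, pos, strand)


def find_placements(scan_seq: str, template_mask: np.ndarray, max_mm: int):
    """(position, mismatches) pairs with mismatches <= max_mm, ascending position."""
    prof = mismatch_profile(seq_to_mask(scan_seq), template_mask)
    pos = np.flatnonzero(prof <= max_mm)
    return [(int(p), int(prof[p])) for p in pos]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with admissible product-length bounds."""

    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    min_amplicon: int = 50
    max_amplicon: int = 2000

    def __post_init__(self):
        if self.min_amplicon <= 0 or self.min_amplicon > self.max_amplicon:
            raise ValueError("amplicon bounds must be positive with min <= max")

    @property
    def total_degeneracy(self) -> int:
        return self.forward.degeneracy_count + self.reverse.degeneracy_count


def _pair_level(fwd_sites, rev_sites, len_f, len_r, bounds, mode) -> float:
    """Best mismatch level over all orientation- and length-valid site combos.

    ``per-primer`` returns min over combos of max(mf, mr); ``summed``
    returns min of mf + mr.  inf when no valid combination exists.
    """
    lo, hi = bounds
    best = math.inf
    for pf, mf in fwd_sites:
        for pr, mr in rev_sites:
            if pf + len_f > pr:
                continue
            length = pr + len_r - pf
            if not lo <= length <= hi:
                continue
            level = max(mf, mr) if mode == "per-primer" else mf + mr
            if level < best:
                best = level
    return best


@dataclass(frozen=True)
class PairRecognition:
    recognized: bool
    reason: str | None  # None | no_fwd | no_rev | orientation | length
    level: float  # best mismatch level, inf if unrecognized
    fwd_sites: tuple
    rev_sites: tuple


def pair_recognizes(
    pair: PrimerPair, template, max_mm: int, mode: str = "per-primer"
) -> PairRecognition:
    """Does the pair amplify this template within ``max_mm`` mismatches?

    Requires a forward site on the plus strand entirely upstream of a
    reverse-primer site (scanned as the reverse complement of the reverse
    primer on the plus strand), with product length inside the pair's
    bounds.  On failure the reason codes are ``no_fwd``, ``no_rev``,
    ``orientation`` (sites in the wrong order) or ``length``.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if mode not in ("per-primer", "summed"):
        raise ValueError(f"bad mismatch mode {mode!r}")
    _, residues = _as_seq(template)
    tmask = seq_to_mask(residues)
    fwd_sites = find_placements(pair.forward.sequence, tmask, max_mm)
    rev_sites = find_placements(reverse_complement(pair.reverse.sequence), tmask, max_mm)
    if not fwd_sites:
        return PairRecognition(False, "no_fwd", math.inf, (), tuple(rev_sites))
    if not rev_sites:
        return PairRecognition(False, "no_rev", math.inf, tuple(fwd_sites), ())
    len_f, len_r = len(pair.forward), len(pair.reverse)
    level = _pair_level(
        fwd_sites, rev_sites, len_f, len_r, (pair.min_amplicon, pair.max_amplicon), mode
    )
    if level <= max_mm:
        return PairRecognition(True, None, level, tuple(fwd_sites), tuple(rev_sites))
    # Distinguish why no combination worked.
    any_oriented = any(
        pf + len_f <= pr for pf, _ in fwd_sites for pr, _ in rev_sites
    )
    reason = "length" if any_oriented else "orientation"
    return PairRecognition(False, reason, math.inf, tuple(fwd_sites), tuple(rev_sites))


@dataclass
class CoverageTable:
    """Per-taxon recognition percentages at each mismatch allowance."""

    data: pd.DataFrame  # columns: taxon, n, cov@<k> for each level (full precision)
    rank: str
    mm_levels: tuple[int, ...]
    mode: str = "per-primer"

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        """Display copy with coverage rounded; internal values stay exact."""
        out = self.data.copy()
        for k in self.mm_levels:
            out[f"cov@{k}"] = out[f"cov@{k}"].round(decimals)
        return out


def _record_levels(
    pair: PrimerPair, records, max_mm: int, mode: str
) -> dict[str, float]:
    """Best pair mismatch level per record id (inf = not recognized at max_mm)."""
    len_f, len_r = len(pair.forward), len(pair.reverse)
    rev_scan = reverse_complement(pair.reverse.sequence)
    bounds = (pair.min_amplicon, pair.max_amplicon)
    levels = {}
    for rec in records:
        tmask = seq_to_mask(rec.sequence.residues)
        per_site = max_mm if mode == "per-primer" else max_mm
        fwd = find_placements(pair.forward.sequence, tmask, per_site)
        rev = find_placements(rev_scan, tmask, per_site) if fwd else []
        levels[rec.id] = (
            _pair_level(fwd, rev, len_f, len_r, bounds, mode) if fwd and rev else math.inf
        )
    return levels


def coverage_table(
    pair: PrimerPair,
    db: ReferenceDatabase,
    rank: str = "phylum",
    mm_levels=(0, 1, 2),
    mode: str = "per-primer",
) -> CoverageTable:
    """Coverage of every taxon at ``rank`` for each mismatch allowance.

    Coverage at k is 100 x (sequences recognized within k mismatches) / n;
    it is non-decreasing in k by construction.  Taxa with no sequences at
    the rank are omitted.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    levels = sorted(mm_levels)
    per_record = _record_levels(pair, db.records, max(levels), mode)
    rows = []
    for taxon, recs in db.group_by(rank).items():
        n = len(recs)
        row = {"taxon": taxon, "n": n}
        for k in levels:
            hit = sum(1 for r in recs if per_record[r.id] <= k)
            row[f"cov@{k}"] = 100.0 * hit / n
        rows.append(row)
    return CoverageTable(pd.DataFrame(rows), rank, tuple(levels), mode)


# ---------------------------------------------------------------------------
# Primer-pair selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairSelectionParams:
    """Knobs for the pair search.

    score = coverage_in(mm_sel) - lam * coverage_out(mm_spec), both in
    percent.  ``top_n`` caps how many forward/reverse candidates survive
    the single-primer prefilter (0 disables pruning).
    """

    mm_sel: int = 1
    mm_spec: int = 2
    lam: float = 1.0
    mode: str = "per-primer"
    min_amplicon: int = 50
    max_amplicon: int = 2000
    top_n: int = 40


@dataclass(frozen=True)
class ScoredPair:
    pair: PrimerPair
    score: float
    coverage_in: dict[int, float]
    coverage_out: dict[int, float]
    n_in: int
    n_out: int
    fwd_candidate: CandidatePrimer | None = None
    rev_candidate: CandidatePrimer | None = None


def _single_coverage(placements_by_seq: list[list], max_mm: int) -> float:
    hit = sum(1 for pl in placements_by_seq if any(m <= max_mm for _, m in pl))
    return 100.0 * hit / len(placements_by_seq) if placements_by_seq else 0.0


def select_primer_pairs(
    forward_cands: list[CandidatePrimer],
    reverse_cands: list[CandidatePrimer],
    db: ReferenceDatabase,
    target_taxon: str,
    params: PairSelectionParams = PairSelectionParams(),
) -> list[ScoredPair]:
    """Score and rank candidate primer pairs against a labelled database.

    Pairs are pruned by consensus coordinates first (forward upstream of
    reverse, implied product length within bounds), then scored as
    in-group coverage at ``mm_sel`` minus ``lam`` times out-group coverage
    at ``mm_spec``.  Ties prefer fewer total degeneracies, then shorter
    total primer length, then leftmost coordinates.  A single-primer
    in-group-coverage prefilter keeps the search tractable; set
    ``top_n=0`` for the exhaustive search.
    """
    if not forward_cands or not reverse_cands:
        raise ValueError("candidate lists must be nonempty")
    in_recs, out_recs = db.partition(target_taxon)
    kmax = max(params.mm_sel, params.mm_spec)
    in_masks = [seq_to_mask(r.sequence.residues) for r in in_recs]
    out_masks = [seq_to_mask(r.sequence.residues) for r in out_recs]

    # Placement cache keyed by the plus-strand string actually scanned.
    cache_in: dict[str, list[list]] = {}
    cache_out: dict[str, list[list]] = {}

    def placements(scan_seq: str):
        if scan_seq not in cache_in:
            cache_in[scan_seq] = [find_placements(scan_seq, m, kmax) for m in in_masks]
            cache_out[scan_seq] = [find_placements(scan_seq, m, kmax) for m in out_masks]
        return cache_in[scan_seq], cache_out[scan_seq]

    def prefilter(cands: list[CandidatePrimer], role: str) -> list[CandidatePrimer]:
        if params.top_n <= 0 or len(cands) <= params.top_n:
            return list(cands)
        scored = []
        for c in cands:
            scan_seq = c.sequence if role == "fwd" else reverse_complement(c.sequence)
            pl_in, pl_out = placements(scan_seq)
            # Equal-quality ties prefer upstream forward / downstream reverse
            # candidates, so the retained sets remain pairable.
            locus = c.consensus_start if role == "fwd" else -c.consensus_start
            scored.append(
                (
                    -_single_coverage(pl_in, params.mm_sel),
                    _single_coverage(pl_out, params.mm_spec),
                    c.degeneracy_count,
                    len(c),
                    locus,
                    c,
                )
            )
        scored.sort(key=lambda t: t[:5])
        return [t[-1] for t in scored[: params.top_n]]

    fwds = prefilter(forward_cands, "fwd")
    revs = prefilter(reverse_cands, "rev")
    bounds = (params.min_amplicon, params.max_amplicon)
    results: list[ScoredPair] = []
    for f in fwds:
        pl_f_in, pl_f_out = placements(f.sequence)
        for r in revs:
            # Consensus-coordinate pruning: forward upstream, plausible length.
            if f.consensus_end > r.consensus_start:
                continue
            implied = r.consensus_end - f.consensus_start
            if not bounds[0] <= implied <= bounds[1]:
                continue
            pl_r_in, pl_r_out = placements(reverse_complement(r.sequence))
            len_f, len_r = len(f), len(r)
            cov_in: dict[int, float] = {}
            cov_out: dict[int, float] = {}
            lv_in = [
                _pair_level(a, b, len_f, len_r, bounds, params.mode)
                for a, b in zip(pl_f_in, pl_r_in)
            ]
            lv_out = [
                _pair_level(a, b, len_f, len_r, bounds, params.mode)
                for a, b in zip(pl_f_out, pl_r_out)
            ]
            for k in sorted({0, params.mm_sel, params.mm_spec}):
                cov_in[k] = 100.0 * sum(1 for v in lv_in if v <= k) / len(lv_in)
                cov_out[k] = (
                    100.0 * sum(1 for v in lv_out if v <= k) / len(lv_out)
                    if lv_out
                    else 0.0
                )
            score = cov_in[params.mm_sel] - params.lam * cov_out[params.mm_spec]
            pair = PrimerPair(
                DegeneratePrimer(f"fwd_{f.consensus_start}_{len_f}", f.sequence),
                DegeneratePrimer(f"rev_{r.consensus_start}_{len_r}", r.sequence),
                params.min_amplicon,
                params.max_amplicon,
            )
            results.append(
                ScoredPair(pair, score, cov_in, cov_out, len(in_recs), len(out_recs), f, r)
            )
    # Equal scores break first toward higher zero-mismatch in-group coverage
    # (primers that match every target exactly amplify more reliably than
    # ones leaning on the mismatch allowance), then toward fewer
    # degeneracies, shorter oligos and leftmost coordinates.
    results.sort(
        key=lambda s: (
            -s.score,
            -s.coverage_in[0],
            s.pair.total_degeneracy,
            len(s.pair.forward) + len(s.pair.reverse),
            s.fwd_candidate.consensus_start,
            s.rev_candidate.consensus_start,
        )
    )
    return results


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted PCR product.

    ``start``/``end`` are 1-based inclusive on the template, from the
    forward primer's first base to the last base of the reverse-primer
    binding site; ``length = end - start + 1``.  Product termini carry the
    primer sequences (as in a real PCR product), IUPAC codes verbatim
    unless resolved against the template.
    """

    sequence_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int
    product: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _resolve_against(primer_seq: str, template_seg: str) -> str:
    out = []
    for p, t in zip(primer_seq, template_seg):
        out.append(t if t in IUPAC_TO_BASES.get(p, ()) else p)
    return "".join(out)


def predict_amplicons(
    pair: PrimerPair, template, max_mm: int = 3, *, resolve_termini: bool = False
) -> list[AmpliconPrediction]:
    """Every orientation- and length-valid product of the pair on one template."""
    sid, residues = _as_seq(template)
    tmask = seq_to_mask(residues)
    fwd_sites = find_placements(pair.forward.sequence, tmask, max_mm)
    rev_scan = reverse_complement(pair.reverse.sequence)
    rev_sites = find_placements(rev_scan, tmask, max_mm)
    len_f, len_r = len(pair.forward), len(pair.reverse)
    out = []
    for pf, mf in fwd_sites:
        for pr, mr in rev_sites:
            if pf + len_f > pr:
                continue
            length = pr + len_r - pf
            if not pair.min_amplicon <= length <= pair.max_amplicon:
                continue
            head, tail = pair.forward.sequence, rev_scan
            if resolve_termini:
                head = _resolve_against(head, residues[pf : pf + len_f])
                tail = _resolve_against(tail, residues[pr : pr + len_r])
            product = head + residues[pf + len_f : pr] + tail
            out.append(
                AmpliconPrediction(
                    sequence_id=sid,
                    start=pf + 1,
                    end=pr + len_r,
                    fwd_mismatches=mf,
                    rev_mismatches=mr,
                    product=product,
                )
            )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def nested_pcr(
    outer: PrimerPair,
    inner: PrimerPair,
    template,
    max_mm_outer: int = 3,
    max_mm_inner: int = 3,
) -> list[tuple[int, AmpliconPrediction]]:
    """Two-round PCR: inner-pair prediction on each outer product.

    Returns (outer_product_index, inner_prediction) pairs so provenance is
    retained.  Empty when either round yields nothing.
    """
    sid, residues = _as_seq(template)
    results = []
    for i, prod in enumerate(predict_amplicons(outer, (sid, residues), max_mm_outer)):
        inner_id = f"{sid}|outer{i}" if sid else f"outer{i}"
        for pred in predict_amplicons(inner, (inner_id, prod.product), max_mm_inner):
            results.append((i, pred))
    return results
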