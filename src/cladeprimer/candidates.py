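"""Candidate primer enumeration from a degenerate consensus.

A sliding window (default 15 nt) marks every consensus position opening a
low-degeneracy stretch (at most 2 ambiguity codes per window).  Valid
windows that overlap or abut are merged into maximal *domains*, and every
domain substring of primer length (default 20-30 nt) that itself passes
the degeneracy filter becomes a candidate primer.  Reverse-orientation
candidates are emitted as the reverse complement of the consensus
substring, so both lists hold 5'->3' oligos ready for scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ConsensusProfile
from .iupac import degeneracy_count, reverse_complement


@dataclass(frozen=True)
class WindowSpec:
    window_length: int = 15
    max_degeneracies: int = 2  # "fewer than three" degenerate positions

    def __post_init__(self):
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if self.max_degeneracies < 0:
            raise ValueError("max_degeneracies must be >= 0")


@dataclass(frozen=True)
class Domain:
    """A maximal low-degeneracy consensus region, 0-based half-open."""

    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end - self.start != len(self.sequence):
            raise ValueError("domain span and sequence length disagree")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidatePrimer:
    """A primer candidate cut from a domain.

    Coordinates are 0-based half-open on the consensus.  For
    ``orientation="reverse"`` the stored sequence is the reverse
    complement of the consensus substring (the oligo as synthesised).
    """

    sequence: str
    consensus_start: int
    consensus_end: int
    orientation: str = "forward"
    degeneracy_count: int = field(init=False)

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        object.__setattr__(self, "degeneracy_count", degeneracy_count(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def find_valid_windows(consensus: str, spec: WindowSpec = WindowSpec()) -> list[int]:
    """Ascending start positions of windows with at most the allowed degeneracies.

    A consensus shorter than the window yields an empty list.
    """
    w = spec.window_length
    if len(consensus) < w:
        return []
    # Rolling count of degenerate positions across the consensus.
    degen = [1 if degeneracy_count(c) else 0 for c in consensus]
    run = sum(degen[:w])
    starts = []
    if run <= spec.max_degeneracies:
        starts.append(0)
    for s in range(1, len(consensus) - w + 1):
        run += degen[s + w - 1] - degen[s - 1]
        if run <= spec.max_degeneracies:
            starts.append(s)
    return starts


def merge_windows(
    consensus: str, starts: list[int], spec: WindowSpec = WindowSpec()
) -> list[Domain]:
    """Union overlapping-or-abutting valid windows into maximal domains."""
    if not starts:
        return []
    w = spec.window_length
    domains: list[tuple[int, int]] = []
    cur_start, cur_end = starts[0], starts[0] + w
    for s in starts[1:]:
        if s <= cur_end:  # overlap or abut
            cur_end = max(cur_end, s + w)
        else:
            domains.append((cur_start, cur_end))
            cur_start, cur_end = s, s + w
    domains.append((cur_start, cur_end))
    return [Domain(a, b, consensus[a:b]) for a, b in domains]


def enumerate_primers(
    domains: list[Domain],
    min_len: int = 20,
    max_len: int = 30,
    max_degen: int = 2,
    orientation: str = "forward",
) -> list[CandidatePrimer]:
    """All domain substrings within the length bounds that pass the degeneracy filter.

    The degeneracy filter is re-applied per candidate: a long substring
    can straddle two valid windows and still carry too many ambiguity
    codes.  Candidates are deduplicated by (sequence, consensus_start) —
    the same oligo at a different locus is kept for coordinate reporting.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    seen: set[tuple[str, int]] = set()
    out: list[CandidatePrimer] = []
    for dom in domains:
        n = len(dom)
        for off in range(n - min_len + 1):
            for length in range(min_len, min(max_len, n - off) + 1):
                sub = dom.sequence[off : off + length]
                if degeneracy_count(sub) > max_degen:
                    continue
                seq = sub if orientation == "forward" else reverse_complement(sub)
                key = (seq, dom.start + off)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    CandidatePrimer(
                        sequence=seq,
                        consensus_start=dom.start + off,
                        consensus_end=dom.start + off + length,
                        orientation=orientation,
                    )
                )
    return out


def candidates_from_consensus(
    profile: ConsensusProfile,
    spec: WindowSpec = WindowSpec(),
    min_len: int = 20,
    max_len: int = 30,
    max_degen: int = 2,
) -> tuple[list[CandidatePrimer], list[CandidatePrimer]]:
    """Window, merge and enumerate in both orientations from a consensus profile."""
    starts = find_valid_windows(profile.consensus, spec)
    domains = merge_windows(profile.consensus, starts, spec)
    fwd = enumerate_primers(domains, min_len, max_len, max_degen, "forward")
    rev = enumerate_primers(domains, min_len, max_len, max_degen, "reverse")
    return fwd, rev
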