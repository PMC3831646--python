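"""Degenerate-nucleotide algebra over the 15-letter IUPAC alphabet.

Every primer-design step in this package (consensus encoding, degeneracy
filtering, mismatch-tolerant scanning) reduces to operations on IUPAC
ambiguity codes, each of which names a nonempty subset of the canonical
bases {A, C, G, T}.  This module is the single source of truth for that
algebra: expansion/encoding between symbols and base sets, degenerate
matching (two codes match iff their base sets intersect), degeneracy
counting, and reverse complementation.

Input is case-insensitive; ``U`` is accepted and normalised to ``T``.
Gap characters are never valid here — gapped columns are handled by the
consensus builder before any of these functions see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidAlphabetError(ValueError):
    """A character outside the 15-letter IUPAC nucleotide alphabet."""

    def __init__(self, char: str, position: int | None = None):
        self.char = char
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"invalid IUPAC nucleotide code {char!r}{where}")


#: The defining bijection: IUPAC symbol -> base set.
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Symbol-level complement, e.g. R={A,G} -> Y={C,T}.
IUPAC_COMPLEMENT: dict[str, str] = {
    sym: BASES_TO_IUPAC[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for sym, bases in IUPAC_TO_BASES.items()
}


def normalize(sequence: str, *, allow_gaps: bool = False) -> str:
    """Uppercase a sequence, map U->T and '.'->'-', and validate the alphabet.

    Raises :class:`InvalidAlphabetError` naming the first offending
    character and its 0-based position.
    """
    out = sequence.upper().replace("U", "T")
    if allow_gaps:
        out = out.replace(".", "-")
    for i, ch in enumerate(out):
        if ch in IUPAC_TO_BASES:
            continue
        if allow_gaps and ch == "-":
            continue
        raise InvalidAlphabetError(ch, i)
    return out


def expand_code(symbol: str) -> frozenset[str]:
    """Return the base set named by one IUPAC symbol (e.g. Y -> {C, T})."""
    sym = symbol.upper().replace("U", "T")
    try:
        return IUPAC_TO_BASES[sym]
    except KeyError:
        raise InvalidAlphabetError(symbol, 0) from None


def encode_set(bases) -> str:
    """Return the unique IUPAC symbol for a nonempty subset of {A,C,G,T}.

    Inverse of :func:`expand_code`.
    """
    key = frozenset(b.upper() for b in bases)
    if not key:
        raise ValueError("cannot encode an empty base set")
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        bad = sorted(key - frozenset("ACGT"))
        raise InvalidAlphabetError(bad[0] if bad else "".join(sorted(key))) from None


def codes_match(primer_symbol: str, template_symbol: str) -> bool:
    """True iff the two codes' base sets intersect.

    This is the match semantics used throughout the mismatch scanner: a
    degenerate primer position matches a (possibly ambiguous) template
    position whenever at least one concrete base is shared.  The relation
    is symmetric; N matches everything.
    """
    return bool(expand_code(primer_symbol) & expand_code(template_symbol))


def degeneracy_count(sequence: str) -> int:
    """Number of positions whose code expands to more than one base."""
    n = 0
    for i, ch in enumerate(sequence.upper().replace("U", "T")):
        try:
            bases = IUPAC_TO_BASES[ch]
        except KeyError:
            raise InvalidAlphabetError(sequence[i], i) from None
        if len(bases) > 1:
            n += 1
    return n


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an IUPAC string (degeneracy-preserving involution)."""
    out = []
    seq = sequence.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        try:
            out.append(IUPAC_COMPLEMENT[ch])
        except KeyError:
            raise InvalidAlphabetError(sequence[i], i) from None
    return "".join(reversed(out))


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-alphabet oligonucleotide, written 5'->3'.

    ``ref_start``/``ref_end`` are optional 1-based inclusive coordinates of
    the primer's binding site on a reference sequence (plus-strand span,
    also for reverse primers — the convention of names like "f-326-350").
    """

    name: str
    sequence: str
    ref_start: int | None = None
    ref_end: int | None = None
    degeneracy_count: int = field(init=False)

    def __post_init__(self):
        seq = normalize(self.sequence)
        if not seq:
            raise ValueError(f"primer {self.name!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "degeneracy_count", degeneracy_count(seq))
        if (self.ref_start is None) != (self.ref_end is None):
            raise ValueError(f"primer {self.name!r}: give both coordinates or neither")
        if self.ref_start is not None:
            span = self.ref_end - self.ref_start + 1
            if span != len(seq):
                raise ValueError(
                    f"primer {self.name!r}: coordinate span {span} != length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def wallace_tm(sequence: str) -> float:
    """Wallace-rule annealing-temperature estimate, 2(A+T) + 4(G+C) in deg C.

    A rough convenience only — short-oligo rule of thumb with no salt or
    concentration correction, and no validated accuracy claim.  Degenerate
    positions contribute the mean over their base set.
    """
    seq = normalize(sequence)
    t = 0.0
    for ch in seq:
        bases = IUPAC_TO_BASES[ch]
        t += sum(4.0 if b in "GC" else 2.0 for b in bases) / len(bases)
    return t
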