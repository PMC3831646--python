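"""Threshold-encoded IUPAC consensus from a multiple sequence alignment.

The design pipeline starts from an alignment of the target clade and
summarises it as a single degenerate string: per column, the smallest set
of bases whose cumulative non-gap frequency reaches the consensus
threshold (default 90%), written as one IUPAC code.  Indels are ignored
when counting — gaps are simply excluded from a column's denominator —
and columns that are mostly or entirely gaps are dropped, with the
surviving-column mapping recorded so consensus coordinates can be traced
back to alignment columns.

Two encodings are available:

``minimal-set`` (default)
    the minimal-cardinality base subset with cumulative frequency >=
    threshold; ties broken by higher cumulative frequency, then by
    lexicographically smaller IUPAC symbol.
``inclusion``
    every base whose own frequency is >= (1 - threshold); the majority
    base is always included.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .iupac import IUPAC_TO_BASES, encode_set, normalize

_EPS = 1e-9

#: All 15 nonempty subsets of {A,C,G,T}.
ALL_BASE_SUBSETS: tuple[frozenset[str], ...] = tuple(
    frozenset(c)
    for k in (1, 2, 3, 4)
    for c in combinations("ACGT", k)
)


@dataclass
class MultipleAlignment:
    """Rows of equal length over the IUPAC alphabet plus '-' gaps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        norm = []
        width = None
        for sid, row in zip(self.ids, self.rows):
            r = normalize(row, allow_gaps=True)
            if width is None:
                width = len(r)
            elif len(r) != width:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(r)}, expected {width}"
                )
            norm.append(r)
        self.rows = norm

    @property
    def num_rows(self) -> int:
        return len(self.rows)

    @property
    def num_columns(self) -> int:
        return len(self.rows[0])

    def column(self, index: int) -> list[str]:
        if not 0 <= index < self.num_columns:
            raise IndexError(f"column {index} out of range [0, {self.num_columns})")
        return [row[index] for row in self.rows]


@dataclass
class ConsensusProfile:
    """A threshold consensus plus the per-column frequencies behind it.

    ``column_map[i]`` is the 1-based alignment column that produced
    consensus position ``i`` (dropped columns leave holes in the map).
    """

    consensus: str
    column_freqs: list[dict[str, float]]
    threshold: float
    column_map: list[int]
    method: str = "minimal-set"

    def __len__(self) -> int:
        return len(self.consensus)


def column_frequencies(
    alignment: MultipleAlignment, column: int, *, ambiguous: str = "fractional"
) -> dict[str, float]:
    """Relative base frequencies of one column, gaps excluded.

    Ambiguity codes in the rows either contribute ``1/|base_set|`` to each
    of their bases (``ambiguous="fractional"``, default) or are dropped
    from the column count (``ambiguous="drop"``).
    """
    if ambiguous not in ("fractional", "drop"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    weights: dict[str, float] = {}
    total = 0.0
    for ch in alignment.column(column):
        if ch == "-":
            continue
        bases = IUPAC_TO_BASES[ch]
        if len(bases) > 1 and ambiguous == "drop":
            continue
        total += 1.0
        w = 1.0 / len(bases)
        for b in bases:
            weights[b] = weights.get(b, 0.0) + w
    if total == 0.0:
        raise ValueError(f"column {column} has no usable (non-gap) residues")
    return {b: w / total for b, w in sorted(weights.items())}


def consensus_code(freqs: dict[str, float], threshold: float) -> str:
    """IUPAC code of the minimal base subset reaching the threshold.

    Among subsets of equal cardinality the one with the highest cumulative
    frequency wins, then the lexicographically smallest symbol — so builds
    are deterministic.
    """
    if not freqs:
        raise ValueError("empty frequency map")
    if not 0.5 < threshold <= 1.0 + _EPS:
        raise ValueError(f"threshold must be in (0.5, 1.0], got {threshold}")
    best_key = None
    best_sym = None
    for subset in ALL_BASE_SUBSETS:
        cum = sum(freqs.get(b, 0.0) for b in subset)
        if cum + _EPS >= threshold:
            sym = encode_set(subset)
            # cum rounded so summation order cannot flip an exact tie
            key = (len(subset), -round(cum, 9), sym)
            if best_key is None or key < best_key:
                best_key, best_sym = key, sym
    if best_sym is None:
        # Frequencies failed to sum to ~1 — even N cannot reach the threshold.
        raise ValueError(f"frequency map sums to {sum(freqs.values()):.6f} < threshold")
    return best_sym


def _inclusion_code(freqs: dict[str, float], threshold: float) -> str:
    floor = 1.0 - threshold
    bases = {b for b, f in freqs.items() if f + _EPS >= floor}
    bases.add(max(freqs, key=lambda b: (freqs[b], b)))  # majority base always in
    return encode_set(bases)


def build_consensus(
    alignment: MultipleAlignment,
    threshold: float = 0.90,
    *,
    max_gap_fraction: float = 0.5,
    method: str = "minimal-set",
    ambiguous: str = "fractional",
) -> ConsensusProfile:
    """Build the threshold consensus, dropping gap-dominated columns.

    All-gap columns are always dropped; columns whose gap fraction exceeds
    ``max_gap_fraction`` are treated as alignment artifacts and dropped
    too.  ``column_map`` records the surviving columns (1-based).
    """
    if method not in ("minimal-set", "inclusion"):
        raise ValueError(f"unknown consensus method {method!r}")
    chars: list[str] = []
    freqs_out: list[dict[str, float]] = []
    col_map: list[int] = []
    n = alignment.num_rows
    for col in range(alignment.num_columns):
        column = alignment.column(col)
        gap_frac = sum(1 for ch in column if ch == "-") / n
        if gap_frac >= 1.0 or gap_frac > max_gap_fraction:
            continue
        freqs = column_frequencies(alignment, col, ambiguous=ambiguous)
        if method == "minimal-set":
            chars.append(consensus_code(freqs, threshold))
        else:
            chars.append(_inclusion_code(freqs, threshold))
        freqs_out.append(freqs)
        col_map.append(col + 1)
    return ConsensusProfile(
        consensus="".join(chars),
        column_freqs=freqs_out,
        threshold=threshold,
        column_map=col_map,
        method=method,
    )
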