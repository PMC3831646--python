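"""Seeded synthetic databases and clone libraries with planted primer signatures.

The generator emulates a SILVA-style hierarchical 16S database: a random
root sequence radiates into phyla, genera and strains, each level adding
i.i.d. substitutions at its own rate.  One phylum is the *target clade*
and carries a conserved two-site primer signature (a forward site and the
plus-strand binding site of a reverse primer, a fixed distance apart)
planted exactly in every member.  All other sequences carry decayed
homologs of the same sites: a fixed number of substitutions per site,
injected at evenly spaced interior positions so that *every* sub-window
of at least 20 nt contains at least ``decay - 1`` of them — out-group
exclusion at low mismatch allowances holds by construction, not by luck.

Clone libraries are sampled from the database by taxon weights,
optionally trimmed to a primer pair's amplicon, and noised with per-clone
substitutions.  Every generator is bit-reproducible under a fixed seed
and returns a truth table so tests never re-derive ground truth from the
generated FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .database import DbRecord, NucleotideSequence, ReferenceDatabase
from .iupac import normalize, reverse_complement
from .scan import PrimerPair, predict_amplicons

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default signature: the packaged Deinococcus-Thermus primer sites at their
# reference coordinates (forward 326-350; reverse site 758-785 => 460 bp
# product).  The reverse primer's one degenerate position is instantiated
# as C so the planted site is IUPAC-free.
_DEFAULT_FWD_SITE = "CGGGAGGCAGCAGTTAGGAATCTTC"
_DEFAULT_REV_SITE = "GTTTAGGGCGTGGACTACCCGGGTATCT"


@dataclass(frozen=True)
class SyntheticDbSpec:
    """Parameters of one synthetic database draw.

    Rates are per-site substitution probabilities applied on the branch
    into each level's ancestor (phylum, genus) or leaf (strain).
    ``decay_substitutions`` is the number of substitutions injected into
    each signature site outside the target clade.
    """

    seed: int = 0
    n_phyla: int = 3
    genera_per_phylum: int = 4
    seqs_per_genus: int = 10
    seq_length: int = 1200
    phylum_rate: float = 0.15
    genus_rate: float = 0.08
    strain_rate: float = 0.01
    target_phylum: int = 0
    fwd_site: str = _DEFAULT_FWD_SITE
    rev_site: str = _DEFAULT_REV_SITE  # reverse primer 5'->3'; planted as its rc
    fwd_position: int = 325  # 0-based; 1-based 326
    site_gap: int = 407  # bases between fwd site end and rev site start
    decay_substitutions: int = 4
    ingroup_site_rate: float = 0.0

    def __post_init__(self):
        for name in ("phylum_rate", "genus_rate", "strain_rate", "ingroup_site_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if min(self.n_phyla, self.genera_per_phylum, self.seqs_per_genus) < 1:
            raise ValueError("taxon counts must be >= 1")
        if not 0 <= self.target_phylum < self.n_phyla:
            raise ValueError("target_phylum out of range")
        object.__setattr__(self, "fwd_site", normalize(self.fwd_site))
        object.__setattr__(self, "rev_site", normalize(self.rev_site))
        if self.rev_start + len(self.rev_site) > self.seq_length:
            raise ValueError("signature sites do not fit in seq_length")
        if self.fwd_position < 0 or self.site_gap < 0:
            raise ValueError("fwd_position and site_gap must be >= 0")

    @property
    def rev_start(self) -> int:
        """0-based plus-strand start of the reverse-primer binding site."""
        return self.fwd_position + len(self.fwd_site) + self.site_gap

    @property
    def product_length(self) -> int:
        return self.rev_start + len(self.rev_site) - self.fwd_position


@dataclass(frozen=True)
class CloneLibrarySpec:
    """Parameters of a synthetic clone library draw.

    ``taxon_weights`` maps taxon names (any rank) to sampling weights that
    must sum to 1; clones are noised at ``substitution_rate`` and each end
    trimmed by a uniform number of bases from ``trim_range``.
    """

    seed: int = 0
    n_clones: int = 50
    taxon_weights: dict = field(default_factory=dict)
    substitution_rate: float = 0.0
    trim_range: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.taxon_weights:
            total = sum(self.taxon_weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"taxon weights sum to {total}, expected 1")
        lo, hi = self.trim_range
        if lo < 0 or hi < lo:
            raise ValueError("trim_range must be 0 <= lo <= hi")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_array(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = arr.copy()
    if rate <= 0.0:
        return out
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def mutate_sequence(seq: str, rate: float, seed: int | None = None) -> str:
    """i.i.d. per-position substitution to a uniformly chosen different base."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(normalize(seq).encode("ascii"), dtype=np.uint8)
    return _mutate_array(arr, rate, rng).tobytes().decode("ascii")


def _decay_positions(site_len: int, n_subs: int) -> list[int]:
    """Evenly spaced interior positions for out-group signature decay.

    Centres of ``n_subs`` equal bins: any window of >= 20 nt over a
    ~25-28 nt site covers at least n_subs - 1 of them.
    """
    return sorted({int(round((i + 0.5) * site_len / n_subs)) for i in range(n_subs)})


def _plant(
    arr: np.ndarray,
    site: str,
    pos: int,
    decay: int,
    rng: np.random.Generator,
) -> None:
    s = np.frombuffer(site.encode("ascii"), dtype=np.uint8).copy()
    if decay > 0:
        for p in _decay_positions(len(site), decay):
            p = min(p, len(site) - 1)
            choices = _BASES[_BASES != s[p]]
            s[p] = rng.choice(choices)
    arr[pos : pos + len(site)] = s


def generate_database(spec: SyntheticDbSpec) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Simulate a hierarchical database with a planted clade signature.

    Returns the database and a truth table (one row per sequence) with
    the planted site coordinates (0-based) and per-site decay counts.
    """
    rng = np.random.default_rng(spec.seed)
    root = _random_sequence(rng, spec.seq_length)
    rc_rev_site = reverse_complement(spec.rev_site)
    records: list[DbRecord] = []
    truth_rows = []
    for p in range(spec.n_phyla):
        anc_p = _mutate_array(root, spec.phylum_rate, rng)
        in_group = p == spec.target_phylum
        for g in range(spec.genera_per_phylum):
            anc_g = _mutate_array(anc_p, spec.genus_rate, rng)
            for s in range(spec.seqs_per_genus):
                arr = _mutate_array(anc_g, spec.strain_rate, rng)
                decay = 0 if in_group else spec.decay_substitutions
                _plant(arr, spec.fwd_site, spec.fwd_position, decay, rng)
                _plant(arr, rc_rev_site, spec.rev_start, decay, rng)
                if in_group and spec.ingroup_site_rate > 0.0:
                    for pos, ln in (
                        (spec.fwd_position, len(spec.fwd_site)),
                        (spec.rev_start, len(rc_rev_site)),
                    ):
                        arr[pos : pos + ln] = _mutate_array(
                            arr[pos : pos + ln], spec.ingroup_site_rate, rng
                        )
                sid = f"P{p}G{g}S{s}"
                lineage = (
                    "Bacteria",
                    f"Phylum_{p}",
                    f"Class_{p}",
                    f"Order_{p}",
                    f"Family_{p}",
                    f"Genus_{p}_{g}",
                )
                records.append(
                    DbRecord(NucleotideSequence(sid, arr.tobytes().decode("ascii")), lineage)
                )
                truth_rows.append(
                    {
                        "seq_id": sid,
                        "lineage": ";".join(lineage),
                        "in_target_clade": in_group,
                        "fwd_site_start": spec.fwd_position,
                        "rev_site_start": spec.rev_start,
                        "decay_substitutions_per_site": decay,
                    }
                )
    return ReferenceDatabase(records), pd.DataFrame(truth_rows)


def target_clade_alignment(db: ReferenceDatabase, spec: SyntheticDbSpec):
    """The target clade's rows as a gap-free multiple alignment.

    The substitution-only model keeps all sequences positionally
    homologous, so the in-group sequences *are* their own alignment.
    """
    from .consensus import MultipleAlignment

    taxon = f"Phylum_{spec.target_phylum}"
    ins, _ = db.partition(taxon)
    return MultipleAlignment([r.id for r in ins], [r.sequence.residues for r in ins])


def generate_clone_library(
    db: ReferenceDatabase,
    spec: CloneLibrarySpec,
    pair: PrimerPair | None = None,
    max_mm: int = 3,
) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """Sample noisy clones from weighted taxa, optionally amplicon-trimmed.

    With a primer pair supplied, each clone is the pair's first predicted
    product on its template (templates with no product are rejected and
    redrawn from the same taxon's candidates).  Truth labels (source
    sequence and lineage) are returned alongside.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    rng = np.random.default_rng(spec.seed)
    weights = spec.taxon_weights or {db.records[0].lineage[1]: 1.0}
    pools = {}
    for taxon in weights:
        recs = [r for r in db.records if r.in_taxon(taxon)]
        if not recs:
            raise ValueError(f"taxon {taxon!r} has no sequences in the database")
        pools[taxon] = recs
    taxa = sorted(weights)
    probs = np.array([weights[t] for t in taxa])
    probs = probs / probs.sum()
    clones: list[NucleotideSequence] = []
    truth_rows = []
    for i in range(spec.n_clones):
        taxon = taxa[rng.choice(len(taxa), p=probs)]
        rec = pools[taxon][rng.integers(len(pools[taxon]))]
        template = rec.sequence.residues
        if pair is not None:
            preds = predict_amplicons(pair, (rec.id, template), max_mm)
            if not preds:
                candidates = [
                    r
                    for r in pools[taxon]
                    if predict_amplicons(pair, (r.id, r.sequence.residues), max_mm)
                ]
                if not candidates:
                    raise ValueError(
                        f"no template in taxon {taxon!r} yields a product for the pair"
                    )
                rec = candidates[rng.integers(len(candidates))]
                preds = predict_amplicons(pair, (rec.id, rec.sequence.residues), max_mm)
            template = preds[0].product
        arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
        arr = _mutate_array(arr, spec.substitution_rate, rng)
        seq = arr.tobytes().decode("ascii")
        lo, hi = spec.trim_range
        if hi > 0:
            left = int(rng.integers(lo, hi + 1))
            right = int(rng.integers(lo, hi + 1))
            if left + right < len(seq):
                seq = seq[left : len(seq) - right if right else len(seq)]
        cid = f"clone_{i:04d}"
        clones.append(NucleotideSequence(cid, seq))
        truth_rows.append(
            {
                "clone_id": cid,
                "source_id": rec.id,
                "lineage": ";".join(rec.lineage),
                "taxon_drawn": taxon,
            }
        )
    return clones, pd.DataFrame(truth_rows)
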