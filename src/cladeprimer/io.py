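"""File formats and report writers.

Sequence I/O is plain FASTA (via Bio.SeqIO); lineages travel as a
two-column TSV ``sequence_id <TAB> Domain;Phylum;...;Genus``.  All report
coordinates are 1-based inclusive (the convention of primer names like
"f-326-350"); the 0-based half-open internal convention never leaks into
files.  Coverage percentages are rounded to one decimal for display only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .candidates import CandidatePrimer
from .community import OTUPartition, RarefactionCurve, TaxonomyAssignment
from .consensus import MultipleAlignment
from .database import RANKS, NucleotideSequence, ReferenceDatabase
from .iupac import normalize
from .scan import AmpliconPrediction, CoverageTable, ScoredPair

logger = logging.getLogger("cladeprimer")


class FormatError(ValueError):
    """A malformed input file (exit code 3 at the CLI)."""


def _parse_fasta(path):
    try:
        return list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: not valid FASTA ({exc})") from exc


def read_fasta(path) -> list[NucleotideSequence]:
    """Read unaligned FASTA; wrapping and mixed case tolerated, gaps stripped."""
    records = _parse_fasta(path)
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out = []
    dropped_gaps = 0
    for rec in records:
        seq = str(rec.seq)
        clean = seq.replace("-", "").replace(".", "")
        if len(clean) != len(seq):
            dropped_gaps += 1
        if not clean:
            raise FormatError(f"{path}: record {rec.id!r} is empty")
        out.append(NucleotideSequence(rec.id, normalize(clean)))
    if dropped_gaps:
        logger.warning("%s: stripped gap characters from %d records", path, dropped_gaps)
    return out


def read_alignment(path) -> MultipleAlignment:
    """Read aligned FASTA ('-' gaps; '.' normalised to '-'); rows must align."""
    records = _parse_fasta(path)
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        expected = len(rows[0])
        for rid, row in zip(ids, rows):
            if len(row) != expected:
                raise FormatError(
                    f"{path}: ragged alignment — record {rid!r} has length "
                    f"{len(row)}, expected {expected}"
                )
    try:
        return MultipleAlignment(ids, rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(path, seqs, width: int = 70) -> None:
    records = []
    for s in seqs:
        sid, residues = (s.id, s.residues) if isinstance(s, NucleotideSequence) else s
        records.append(SeqRecord(Seq(residues), id=sid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_lineages(path) -> dict[str, tuple[str, ...]]:
    """Parse the id -> semicolon-delimited-lineage TSV."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, lineage_str = parts
            if sid in out:
                raise FormatError(f"{path}:{lineno}: duplicate sequence id {sid!r}")
            ranks = tuple(x.strip() for x in lineage_str.split(";") if x.strip())
            if not ranks:
                raise FormatError(f"{path}:{lineno}: empty lineage for {sid!r}")
            if len(ranks) > len(RANKS):
                raise FormatError(
                    f"{path}:{lineno}: lineage deeper than {len(RANKS)} ranks"
                )
            out[sid] = ranks
    if not out:
        raise FormatError(f"{path}: no lineage rows")
    return out


def write_lineages(path, lineages: dict[str, tuple[str, ...]]) -> None:
    with open(path, "w") as fh:
        for sid, lineage in lineages.items():
            fh.write(f"{sid}\t{';'.join(lineage)}\n")


def load_database(fasta_path, lineage_path) -> ReferenceDatabase:
    """Assemble a labelled database; sequences without a lineage are dropped (logged)."""
    seqs = read_fasta(fasta_path)
    lineages = read_lineages(lineage_path)
    kept, dropped = [], 0
    for s in seqs:
        if s.id in lineages:
            kept.append((s.id, s.residues))
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "%s: dropped %d of %d sequences with no lineage entry",
            fasta_path,
            dropped,
            len(seqs),
        )
    if not kept:
        raise FormatError(f"{fasta_path}: no sequence has a lineage in {lineage_path}")
    return ReferenceDatabase.from_pairs(kept, lineages)


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def write_coverage_table(
    path, table: CoverageTable, target_taxon: str | None = None, decimals: int = 1
) -> None:
    """Coverage TSV: taxon, n, cov@<k>...; target taxon's rows listed first."""
    df = table.rounded(decimals)
    if target_taxon is not None and target_taxon in set(df["taxon"]):
        first = df[df["taxon"] == target_taxon]
        rest = df[df["taxon"] != target_taxon]
        df = pd.concat([first, rest], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def write_candidates_fasta(path, cands: list[CandidatePrimer]) -> None:
    seqs = [
        (f"cand_{c.consensus_start}_{len(c)}_{c.orientation}", c.sequence) for c in cands
    ]
    write_fasta(path, seqs)


def write_candidates_tsv(path, cands: list[CandidatePrimer]) -> None:
    rows = [
        {
            "id": f"cand_{c.consensus_start}_{len(c)}_{c.orientation}",
            "sequence": c.sequence,
            "consensus_start": c.consensus_start + 1,  # 1-based inclusive
            "consensus_end": c.consensus_end,
            "length": len(c),
            "degeneracy": c.degeneracy_count,
            "orientation": c.orientation,
        }
        for c in cands
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ranked_pairs(path, scored: list[ScoredPair], decimals: int = 1) -> None:
    rows = []
    for rank, s in enumerate(scored, 1):
        row = {
            "rank": rank,
            "forward": s.pair.forward.sequence,
            "reverse": s.pair.reverse.sequence,
            "fwd_start": (
                s.fwd_candidate.consensus_start + 1 if s.fwd_candidate else ""
            ),
            "rev_start": (
                s.rev_candidate.consensus_start + 1 if s.rev_candidate else ""
            ),
            "total_degeneracy": s.pair.total_degeneracy,
            "score": round(s.score, decimals),
        }
        for k, v in sorted(s.coverage_in.items()):
            row[f"cov_in@{k}"] = round(v, decimals)
        for k, v in sorted(s.coverage_out.items()):
            row[f"cov_out@{k}"] = round(v, decimals)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_amplicons(fasta_path, tsv_path, preds: list[AmpliconPrediction]) -> None:
    seqs, rows = [], []
    for i, p in enumerate(preds):
        pid = f"{p.sequence_id}|amplicon{i}_{p.start}-{p.end}"
        seqs.append((pid, p.product))
        rows.append(
            {
                "id": pid,
                "template": p.sequence_id,
                "start": p.start,
                "end": p.end,
                "length": p.length,
                "fwd_mismatches": p.fwd_mismatches,
                "rev_mismatches": p.rev_mismatches,
            }
        )
    if seqs:
        write_fasta(fasta_path, seqs)
    else:
        Path(fasta_path).write_text("")
    pd.DataFrame(
        rows,
        columns=[
            "id",
            "template",
            "start",
            "end",
            "length",
            "fwd_mismatches",
            "rev_mismatches",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)


def write_assignments(path, assignments: list[TaxonomyAssignment], decimals: int = 1):
    rows = [
        {
            "query": a.query_id,
            "status": a.status,
            "rank": a.assigned_rank or "",
            "name": a.assigned_name or "",
            "threshold_pct": "" if a.threshold_used is None else a.threshold_used,
            "best_identity_pct": (
                "" if a.best_identity is None else round(a.best_identity, decimals)
            ),
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows, columns=["query", "status", "rank", "name", "threshold_pct", "best_identity_pct"]
    ).to_csv(path, sep="\t", index=False)


def write_otus(path, partition: OTUPartition, seqs=None) -> None:
    """OTU TSV: otu_id, size, members; representative = longest member if seqs given."""
    lengths = {}
    if seqs is not None:
        for s in seqs:
            sid, residues = (s.id, s.residues) if isinstance(s, NucleotideSequence) else s
            lengths[sid] = len(residues)
    rows = []
    for i, members in enumerate(partition.clusters, 1):
        rep = max(members, key=lambda m: (lengths.get(m, 0), m)) if lengths else members[0]
        rows.append(
            {
                "otu_id": f"OTU_{i}",
                "size": len(members),
                "representative": rep,
                "members": ",".join(members),
            }
        )
    pd.DataFrame(rows, columns=["otu_id", "size", "representative", "members"]).to_csv(
        path, sep="\t", index=False
    )


def write_rarefaction(path, curve: RarefactionCurve) -> None:
    rows = []
    for i, (n, e) in enumerate(zip(curve.sample_sizes, curve.expected_otu_counts)):
        row = {"sample_size": n, "expected_otus": round(e, 4), "method": curve.method}
        if curve.std_errors is not None:
            row["std_error"] = round(curve.std_errors[i], 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path, config: dict, seeds: dict | None = None) -> None:
    """Run manifest: serialized config, its hash, and the seeds used.

    No timestamps, so identical configurations write identical manifests.
    """
    from . import __version__

    payload = {
        "package": "cladeprimer",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "seeds": seeds or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
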