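# cladeprimer

Group-specific degenerate PCR primer design on the 16S rRNA gene, with
mismatch-tolerant in-silico PCR and clone-library analysis.

Microbial ecologists who want to survey one clade (a phylum, an order, a
genus) inside a complex community need primers that amplify essentially
all of that clade and nothing else.  `cladeprimer` implements the whole
desk workflow:

1. **Consensus** — from a multiple alignment of the target clade, build a
   threshold IUPAC consensus: per column, the smallest base set whose
   cumulative non-gap frequency reaches *t* (default 90%), written as one
   ambiguity code.
2. **Candidates** — slide a 15-nt window over the consensus, keep windows
   with < 3 degeneracies, merge overlapping windows into domains, and
   enumerate every 20–30 nt domain substring with < 3 degeneracies, in
   both orientations.
3. **Scan** — test each candidate pair against a taxonomically labelled
   reference database, counting degenerate-aware mismatches at every
   ungapped offset on both strands.  A sequence is *covered* at allowance
   *k* if both primers bind in the correct orientation within *k*
   mismatches each and the implied product length is plausible.  Pairs are
   ranked by `coverage_in(1 mm) − λ·coverage_out(2 mm)`.
4. **Amplify** — predict amplicons (and nested two-round PCR products)
   for any pair against any FASTA.
5. **Analyse clones** — Needleman–Wunsch similarity search (top 20 hits at
   ≥ 80%), step-wise 99→80% consensus taxonomy, average-linkage OTU
   clustering at 97%, and analytic or Monte-Carlo rarefaction.

A seeded synthetic-data module generates hierarchical databases
(phyla → genera → strains) with a planted clade-specific primer signature
and matching truth tables, so the full pipeline is testable offline.
The package ships the Deinococcus-Thermus pair
Deino-f-326-350 (`CGGGAGGCAGCAGTTAGGAATCTTC`) and Deino-r-758-785
(`GTTTAGGGYGTGGACTACCCGGGTATCT`) as fixtures; their reference coordinates
imply the worked 460 bp product (785 − 326 + 1).

See `docs/methods.md` for the model, scoring conventions and limitations.

## Worked example

```sh
# 1. simulate a labelled database (3 phyla x 4 genera x 10 strains) with a
#    planted signature in Phylum_0, plus 20 amplicon clones
cladeprimer simulate --seed 7 --clones 20 --outdir demo

# 2. design primers for the target clade
cladeprimer design --alignment demo/target_alignment.fasta \
    --db-fasta demo/database.fasta --db-lineages demo/lineages.tsv \
    --target-taxon Phylum_0 --outdir demo/design
```

which prints

```
wrote synthetic database (120 sequences) to demo
933 forward / 933 reverse candidates; 567 feasible pairs ranked -> demo/design
```

and the top of `demo/design/ranked_pairs.tsv` reads

```
rank  forward               reverse               fwd_start  rev_start  total_degeneracy  score  cov_in@0  cov_in@1  cov_in@2  cov_out@0  cov_out@1  cov_out@2
1     TCGGGAGGCAGCAGTTAGGA  CGTGGACTACCCGGGTATCT  325        758        0                 100.0  100.0     100.0     100.0     0.0        0.0        0.0
```

The top-ranked pair sits on the planted signature: the forward candidate
starts one conserved base upstream of the planted forward site (326) and
the reverse candidate is a 20-mer of the planted reverse site at 758,
matching the fixture primers' name coordinates.  It covers 100% of the 40
target-clade sequences with zero mismatches and none of the 80 out-group
sequences within two — the design goal of wide coverage with high
specificity.  Scanning and PCR use the packaged pair by
default:

```sh
cladeprimer scan --db-fasta demo/database.fasta \
    --db-lineages demo/lineages.tsv --target-taxon Phylum_0 \
    --out demo/coverage.tsv
cladeprimer pcr --fasta demo/database.fasta --outdir demo/pcr   # 460 bp products
cladeprimer classify --queries demo/clones.fasta \
    --db-fasta demo/database.fasta --db-lineages demo/lineages.tsv \
    --out demo/assignments.tsv
cladeprimer otu --queries demo/clones.fasta --rarefy --outdir demo/otu
```

`demo/coverage.tsv` mirrors the standard coverage-table layout (taxon, n,
cov@0/1/2, target clade first); `classify` assigns each clone a consensus
taxonomy with the threshold at which it was reached; `otu` writes the
97% average-linkage partition and its rarefaction curve.

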