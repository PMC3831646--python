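"""Mismatch scanner, pair recognition, coverage tables, in-silico and nested PCR."""

import math

import pytest

from cladeprimer.database import DbRecord, NucleotideSequence, ReferenceDatabase
from cladeprimer.iupac import DegeneratePrimer, IUPAC_TO_BASES, reverse_complement
from cladeprimer.primers import DEINO_F_326_350, DEINO_PAIR, DEINO_R_758_785
from cladeprimer.scan import (
    PairSelectionParams,
    PrimerPair,
    coverage_table,
    min_mismatches,
    nested_pcr,
    pair_recognizes,
    predict_amplicons,
    select_primer_pairs,
)


def brute_min_mismatches(primer: str, template: str):
    """Reference implementation: explicit double loop over offsets and positions."""
    best = math.inf
    best_pos = None
    for off in range(len(template) - len(primer) + 1):
        mm = sum(
            1
            for p, t in zip(primer, template[off : off + len(primer)])
            if not (IUPAC_TO_BASES[p] & IUPAC_TO_BASES[t])
        )
        if mm < best:
            best, best_pos = mm, off
    return best, best_pos


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMinMismatches:
    def test_exact_substring_hit(self, rng):
        t = _rand_seq(rng, 300)
        primer = t[100:125]
        r = min_mismatches(primer, ("t", t))
        assert r.min_mismatches == 0

    def test_two_planted_substitutions(self, rng):
        t = _rand_seq(rng, 400)
        site = list(t[200:225])
        site[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[3]]
        site[17] = {"A": "G", "C": "T", "G": "A", "T": "C"}[site[17]]
        primer = "".join(site)
        got = min_mismatches(primer, ("t", t))
        brute, _ = brute_min_mismatches(primer, t)
        assert got.min_mismatches == brute <= 2

    def test_degenerate_primer_position_matches(self):
        r = min_mismatches("AYA", ("t", "GGACAGG"))
        assert r.min_mismatches == 0 and r.best_position == 2

    def test_primer_longer_than_template_is_flagged(self):
        r = min_mismatches("ACGTACGT", ("t", "ACG"))
        assert r.min_mismatches == math.inf and r.best_position is None

    def test_leftmost_tie_breaking(self):
        r = min_mismatches("AAAA", ("t", "GGAAAACCAAAA"))
        assert r.best_position == 2

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(40):
            t = _rand_seq(rng, int(rng.integers(40, 400)))
            L = int(rng.integers(18, 29))
            primer = _rand_seq(rng, L)
            got = min_mismatches(primer, ("t", t))
            brute, pos = brute_min_mismatches(primer, t)
            assert got.min_mismatches == brute
            assert got.best_position == pos

    def test_strand_symmetry(self, rng):
        t = _rand_seq(rng, 200)
        primer = _rand_seq(rng, 20)
        plus = min_mismatches(primer, ("t", t), "plus")
        minus_on_rc = min_mismatches(primer, ("t", reverse_complement(t)), "minus")
        # The minus-strand scan of the reverse complement sees the original
        # plus strand again: same mismatch minimum, mirrored coordinates.
        assert minus_on_rc.min_mismatches == plus.min_mismatches
        assert minus_on_rc.best_position == len(t) - (plus.best_position + len(primer))


def _template_with_sites(rng, fwd, rev_site_rc, fwd_pos, rev_pos, length=900):
    t = list(_rand_seq(rng, length))
    t[fwd_pos : fwd_pos + len(fwd)] = fwd
    t[rev_pos : rev_pos + len(rev_site_rc)] = rev_site_rc
    return "".join(t)


@pytest.fixture()
def perfect_template(rng):
    fwd = DEINO_F_326_350.sequence
    rev_rc = reverse_complement(DEINO_R_758_785.sequence).replace("R", "G")
    return _template_with_sites(rng, fwd, rev_rc, 100, 400)


class TestPairRecognition:
    def test_perfect_sites_recognized(self, perfect_template):
        rec = pair_recognizes(DEINO_PAIR, ("t", perfect_template), 0)
        assert rec.recognized and rec.level == 0

    def test_reverse_site_upstream_fails_with_orientation(self, rng):
        fwd = DEINO_F_326_350.sequence
        rev_rc = reverse_complement(DEINO_R_758_785.sequence).replace("R", "G")
        t = _template_with_sites(rng, fwd, rev_rc, 500, 100)
        rec = pair_recognizes(DEINO_PAIR, ("t", t), 1)
        assert not rec.recognized and rec.reason == "orientation"

    def test_four_mismatch_reverse_site_not_recognized_at_three(self, rng):
        fwd = DEINO_F_326_350.sequence
        rev_rc = list(reverse_complement(DEINO_R_758_785.sequence).replace("R", "G"))
        for i in (2, 9, 16, 23):  # avoid the degenerate-Y column
            rev_rc[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[rev_rc[i]]
        t = _template_with_sites(rng, fwd, "".join(rev_rc), 100, 400)
        assert brute_min_mismatches(
            reverse_complement(DEINO_R_758_785.sequence), t
        )[0] == 4
        rec = pair_recognizes(DEINO_PAIR, ("t", t), 3)
        assert not rec.recognized and rec.reason == "no_rev"

    def test_recognition_monotone_in_allowance(self, rng):
        for _ in range(5):
            t = _rand_seq(rng, 600)
            pair = PrimerPair(
                DegeneratePrimer("f", t[50:72]),
                DegeneratePrimer("r", reverse_complement(t[300:324])),
            )
            for k in range(3):
                if pair_recognizes(pair, ("t", t), k).recognized:
                    assert pair_recognizes(pair, ("t", t), k + 1).recognized

    def test_product_length_bound_reason(self, rng):
        t = _rand_seq(rng, 600)
        pair = PrimerPair(
            DegeneratePrimer("f", t[50:72]),
            DegeneratePrimer("r", reverse_complement(t[500:524])),
            min_amplicon=50,
            max_amplicon=100,  # true product is ~474 nt
        )
        rec = pair_recognizes(pair, ("t", t), 0)
        assert not rec.recognized and rec.reason == "length"


def _toy_db(rng, n_in=4, n_out=4, fwd_mm_for=None):
    """In-group with planted perfect (or mutated) sites; out-group random."""
    fwd = DEINO_F_326_350.sequence
    rev_rc = reverse_complement(DEINO_R_758_785.sequence).replace("R", "G")
    records = []
    for i in range(n_in):
        t = list(_template_with_sites(rng, fwd, rev_rc, 100, 400))
        if fwd_mm_for is not None and i in fwd_mm_for:
            for j in range(fwd_mm_for[i]):
                pos = 100 + 3 * j
                t[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[pos]]
        records.append(
            DbRecord(
                NucleotideSequence(f"in{i}", "".join(t)),
                ("Bacteria", "TargetPhylum", "C", "O", "F", f"G{i % 2}"),
            )
        )
    for i in range(n_out):
        records.append(
            DbRecord(
                NucleotideSequence(f"out{i}", _rand_seq(rng, 900)),
                ("Bacteria", "OtherPhylum", "C", "O", "F", "G9"),
            )
        )
    return ReferenceDatabase(records)


class TestCoverageTable:
    def test_perfect_in_group_and_siteless_out_group(self, rng):
        db = _toy_db(rng)
        table = coverage_table(DEINO_PAIR, db, "phylum", (0, 1, 2))
        rows = table.data.set_index("taxon")
        assert rows.loc["TargetPhylum", ["cov@0", "cov@1", "cov@2"]].tolist() == [100, 100, 100]
        assert rows.loc["OtherPhylum", ["cov@0", "cov@1", "cov@2"]].tolist() == [0, 0, 0]

    def test_single_one_mismatch_sequence_moves_between_levels(self, rng):
        db = _toy_db(rng, fwd_mm_for={0: 1})
        table = coverage_table(DEINO_PAIR, db, "phylum", (0, 1))
        row = table.data.set_index("taxon").loc["TargetPhylum"]
        assert row["cov@0"] == pytest.approx(75.0)
        assert row["cov@1"] == pytest.approx(100.0)

    def test_coverage_monotone_in_allowance(self, rng):
        db = _toy_db(rng, fwd_mm_for={0: 2, 1: 1})
        table = coverage_table(DEINO_PAIR, db, "genus", (0, 1, 2, 3))
        for _, row in table.data.iterrows():
            covs = [row[f"cov@{k}"] for k in (0, 1, 2, 3)]
            assert covs == sorted(covs)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            coverage_table(DEINO_PAIR, ReferenceDatabase([]), "phylum")


class TestSelectPrimerPairs:
    def test_lambda_zero_scores_equal_in_coverage(self, small_db, small_spec):
        from cladeprimer.candidates import candidates_from_consensus
        from cladeprimer.consensus import build_consensus
        from cladeprimer.simulate import target_clade_alignment

        db, _ = small_db
        spec_params = PairSelectionParams(lam=0.0, top_n=10)
        prof = build_consensus(target_clade_alignment(db, small_spec))
        fwd, rev = candidates_from_consensus(prof)
        ranked = select_primer_pairs(fwd, rev, db, "Phylum_0", spec_params)
        assert ranked
        for s in ranked:
            assert s.score == pytest.approx(s.coverage_in[spec_params.mm_sel])

    def test_swapping_group_labels_inverts_specificity(self, rng):
        # Two "phyla", each with its own perfect signature: the best pair for
        # one group must have zero coverage of the other, in both directions.
        from cladeprimer.candidates import CandidatePrimer

        fwd_a = "CGGGAGGCAGCAGTTAGGAATCTTC"
        rev_a_rc = "AGATACCCGGGTAGTCCACGCCCTAAAC"
        fwd_b = "TTACCGAGTCTCGGAAGCTTAACCT"
        rev_b_rc = "ACCTTGAGCGATTCGGAAGGTTCCTTAG"
        records = []
        for i in range(3):
            ta = _template_with_sites(rng, fwd_a, rev_a_rc, 100, 400)
            tb = _template_with_sites(rng, fwd_b, rev_b_rc, 100, 400)
            records.append(DbRecord(NucleotideSequence(f"a{i}", ta), ("Bacteria", "PhyA")))
            records.append(DbRecord(NucleotideSequence(f"b{i}", tb), ("Bacteria", "PhyB")))
        db = ReferenceDatabase(records)
        cands_a = (
            [CandidatePrimer(fwd_a[:22], 100, 122)],
            [CandidatePrimer(reverse_complement(rev_a_rc)[:22], 406, 428, "reverse")],
        )
        cands_b = (
            [CandidatePrimer(fwd_b[:22], 100, 122)],
            [CandidatePrimer(reverse_complement(rev_b_rc)[:22], 406, 428, "reverse")],
        )
        params = PairSelectionParams(top_n=0)
        for target, cands, other in (("PhyA", cands_a, cands_b), ("PhyB", cands_b, cands_a)):
            own = select_primer_pairs(cands[0], cands[1], db, target, params)[0]
            assert own.coverage_in[1] == 100.0 and own.coverage_out[2] == 0.0
            cross = select_primer_pairs(other[0], other[1], db, target, params)[0]
            assert cross.coverage_in[1] == 0.0 and cross.coverage_out[2] == 100.0

    def test_empty_candidate_lists_rejected(self, rng):
        db = _toy_db(rng)
        with pytest.raises(ValueError):
            select_primer_pairs([], [], db, "TargetPhylum")


class TestPredictAmplicons:
    def test_sites_at_published_coordinates_give_460bp(self, rng):
        fwd = DEINO_F_326_350.sequence
        rev_rc = reverse_complement(DEINO_R_758_785.sequence).replace("R", "G")
        t = _template_with_sites(rng, fwd, rev_rc, 325, 757)  # 1-based 326 / 758
        preds = predict_amplicons(DEINO_PAIR, ("t", t), 0)
        assert len(preds) == 1
        p = preds[0]
        assert (p.start, p.end) == (326, 785)
        assert p.length == 460 == len(p.product)

    def test_two_reverse_sites_give_two_products(self, rng):
        fwd = DEINO_F_326_350.sequence
        rev_rc = reverse_complement(DEINO_R_758_785.sequence).replace("R", "G")
        t = list(_template_with_sites(rng, fwd, rev_rc, 50, 300, length=1000))
        t[600 : 600 + len(rev_rc)] = rev_rc
        preds = predict_amplicons(DEINO_PAIR, ("t", "".join(t)), 0)
        assert len(preds) == 2
        assert preds[0].length < preds[1].length

    def test_product_termini_carry_primer_sequences(self, perfect_template):
        (p,) = predict_amplicons(DEINO_PAIR, ("t", perfect_template), 0)
        assert p.product.startswith(DEINO_F_326_350.sequence)
        assert p.product.endswith(reverse_complement(DEINO_R_758_785.sequence))

    def test_resolve_termini_substitutes_template_bases(self, perfect_template):
        (p,) = predict_amplicons(DEINO_PAIR, ("t", perfect_template), 0, resolve_termini=True)
        assert "Y" not in p.product and "R" not in p.product

    def test_length_equals_span(self, rng, perfect_template):
        for p in predict_amplicons(DEINO_PAIR, ("t", perfect_template), 3):
            assert p.length == p.end - p.start + 1
            assert DEINO_PAIR.min_amplicon <= p.length <= DEINO_PAIR.max_amplicon


class TestNestedPcr:
    @pytest.fixture()
    def outer_pair(self, rng):
        t = _rand_seq(rng, 1100)
        outer = PrimerPair(
            DegeneratePrimer("of", t[20:42]),
            DegeneratePrimer("or", reverse_complement(t[900:922])),
        )
        return outer, t

    def test_inner_product_matches_direct_amplification(self, rng, outer_pair):
        outer, t = outer_pair
        inner = PrimerPair(
            DegeneratePrimer("if", t[100:122]),
            DegeneratePrimer("ir", reverse_complement(t[700:722])),
        )
        nested = nested_pcr(outer, inner, ("t", t), 0, 0)
        assert len(nested) == 1
        direct = predict_amplicons(inner, ("t", t), 0)
        assert nested[0][1].product == direct[0].product

    def test_inner_site_outside_outer_product_yields_nothing(self, rng, outer_pair):
        outer, t = outer_pair
        inner = PrimerPair(
            DegeneratePrimer("if", t[950:972]),  # downstream of the outer product
            DegeneratePrimer("ir", reverse_complement(t[1050:1072])),
        )
        assert nested_pcr(outer, inner, ("t", t), 0, 0) == []

    def test_outer_mismatch_allowance_gates_the_nest(self, rng):
        t = list(_rand_seq(rng, 1100))
        outer_f = "".join(t[20:42])
        t[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[t[25]]  # 1 mm outer fwd site
        t = "".join(t)
        outer = PrimerPair(
            DegeneratePrimer("of", outer_f),
            DegeneratePrimer("or", reverse_complement(t[900:922])),
        )
        inner = PrimerPair(
            DegeneratePrimer("if", t[100:122]),
            DegeneratePrimer("ir", reverse_complement(t[700:722])),
        )
        assert nested_pcr(outer, inner, ("t", t), 0, 0) == []
        assert nested_pcr(outer, inner, ("t", t), 1, 0)
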