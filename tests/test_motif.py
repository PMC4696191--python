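"""Promoter scanning: identity metric, windows, strands, PWM, gaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regulonscan as rs
from regulonscan.motif import _round_half_up, pwm_score

from conftest import TABLE_ROWS

DNA22 = st.text(alphabet="ACGT", min_size=22, max_size=22)


def brute_force_identity(query, consensus):
    """Independent per-position loop skipping 1-based positions 10-13."""
    n = 0
    for p in range(22):
        if p + 1 in (10, 11, 12, 13):
            continue
        if query[p] == consensus[p]:
            n += 1
    return n


class TestIdentityScore:
    @pytest.mark.parametrize("gene_id,motif,n_exp,pct_exp", TABLE_ROWS)
    def test_published_rows(self, consensus, gene_id, motif, n_exp, pct_exp):
        n, pct = rs.identity_score(motif, consensus)
        assert (n, pct) == (n_exp, pct_exp)

    def test_self_identity(self, consensus):
        assert rs.identity_score(consensus.sequence, consensus) == (18, 100.0)

    def test_excluded_positions_never_matter(self, consensus):
        seq = list(consensus.sequence)
        for pos in (10, 11, 12, 13):
            mutated = seq.copy()
            mutated[pos - 1] = "A" if mutated[pos - 1] != "A" else "C"
            assert rs.identity_score("".join(mutated), consensus) == (18, 100.0)

    @pytest.mark.parametrize("k", range(1, 19))
    def test_each_mismatch_is_one_step(self, consensus, k):
        seq = list(consensus.sequence)
        for idx in consensus.scored_indices[:k]:
            seq[idx] = "A" if seq[idx] != "A" else "C"
        n, pct = rs.identity_score("".join(seq), consensus)
        assert n == 18 - k
        assert pct == _round_half_up(100.0 * (18 - k) / 18)

    @settings(derandomize=True, max_examples=200)
    @given(DNA22)
    def test_matches_brute_force_loop(self, query):
        consensus = rs.ConsensusMotif()
        n, pct = rs.identity_score(query, consensus)
        n_bf = brute_force_identity(query, consensus.sequence)
        assert n == n_bf
        assert pct == _round_half_up(100.0 * n_bf / 18)

    def test_full_denominator_option(self, consensus):
        n, pct = rs.identity_score(consensus.sequence, consensus, denominator="full")
        assert n == 18
        assert pct == _round_half_up(100.0 * 18 / 22)

    def test_length_mismatch_rejected(self, consensus):
        with pytest.raises(ValueError):
            rs.identity_score("ACGT", consensus)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), (rs.ROSR_BOX, "CGAAATCCACCCCTAGATTCCG")],
    )
    def test_known_values(self, seq, expected):
        assert rs.reverse_complement(seq) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_involution(self, seq):
        assert rs.reverse_complement(rs.reverse_complement(seq)) == seq

    def test_rejects_ambiguous(self):
        with pytest.raises(ValueError):
            rs.reverse_complement("ACGN")


class TestPromoterWindow:
    def test_plus_strand_default_window(self):
        contig = "ACGT" * 500
        genome = rs.GenomeAnnotation(
            {"c1": contig}, [rs.GeneRecord("g", "c1", "+", 1000, 1500)]
        )
        seq, offset = rs.extract_promoter_window(genome, "g")
        assert len(seq) == 450
        assert offset == -300
        # contig positions 700..1149 (1-based)
        assert seq == contig[699:1149]

    def test_truncation_at_contig_start(self):
        genome = rs.GenomeAnnotation(
            {"c1": "ACGT" * 500}, [rs.GeneRecord("g", "c1", "+", 50, 500)]
        )
        seq, offset = rs.extract_promoter_window(genome, "g")
        assert offset == -49
        assert len(seq) == 49 + 150

    def test_minus_strand_mirrors_plus_slice(self, tiny_genome):
        # minus gene with translation start at contig position 400
        seq, offset = rs.extract_promoter_window(tiny_genome, "minus_gene")
        contig = tiny_genome.contigs["c1"]
        # gene-local -300..149 maps to plus-strand slice 251..700, RC'd
        assert offset == -300
        assert seq == rs.reverse_complement(contig[250:700])

    def test_minus_strand_marker_recovery(self):
        marker = "GGGGCCCCAAAA"
        contig = list("ACGT" * 500)
        # plant RC(marker) so the gene-oriented window shows marker at -50
        gene = rs.GeneRecord("g", "c1", "-", 601, 1200)
        ts = 1200
        lo = ts + 50 - len(marker) + 1  # marker occupies local -50..-39
        rc = rs.reverse_complement(marker)
        contig[lo - 1 : lo - 1 + len(marker)] = list(rc)
        genome = rs.GenomeAnnotation({"c1": "".join(contig)}, [gene])
        seq, offset = rs.extract_promoter_window(genome, "g")
        assert seq[(-50 - offset) : (-50 - offset) + len(marker)] == marker

    def test_unknown_gene(self, tiny_genome):
        with pytest.raises(KeyError):
            rs.extract_promoter_window(tiny_genome, "nope")


class TestScanGene:
    def test_planted_exact_match(self, consensus):
        rng = np.random.default_rng(5)
        window = "".join(rng.choice(list("AT"), 450))
        window = window[:200] + consensus.sequence + window[222:]
        # offset -300: planted frame index 200 -> distance -100
        hits = rs.scan_gene(window, -300, consensus, min_identity_pct=90.0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.identity_pct, h.distance_nt, h.match_strand) == (100.0, -100, "+")
        assert h.matched_sequence == consensus.sequence

    def test_planted_reverse_complement(self, consensus):
        rng = np.random.default_rng(5)
        window = "".join(rng.choice(list("AT"), 450))
        rc = rs.reverse_complement(consensus.sequence)
        window = window[:200] + rc + window[222:]
        hits = rs.scan_gene(window, -300, consensus, min_identity_pct=90.0)
        assert len(hits) == 1
        assert hits[0].match_strand == "-"
        assert hits[0].distance_nt == -100

    def test_poly_a_window_no_perfect_hit(self, consensus):
        assert rs.scan_gene("A" * 100, 0, consensus, min_identity_pct=100.0) == []

    def test_bad_threshold(self, consensus):
        with pytest.raises(ValueError):
            rs.scan_gene("A" * 100, 0, consensus, min_identity_pct=101.0)

    def test_hits_are_self_consistent(self, consensus):
        rng = np.random.default_rng(11)
        window = "".join(rng.choice(list("ACGT"), 300))
        for h in rs.scan_gene(window, -150, consensus, min_identity_pct=0.0):
            n, pct = rs.identity_score(h.matched_sequence, consensus)
            assert (n, pct) == (h.n_matches, h.identity_pct)


class TestScanGenome:
    @pytest.fixture()
    def five_gene_genome(self):
        genome = rs.generate_genome(1, 5, 600, 900, gc=0.5, seed=3)
        return genome

    def test_planted_truth_recovery(self, five_gene_genome, consensus):
        genome = rs.plant_motif(five_gene_genome, "g1_1", consensus.sequence, -120, "+")
        genome = rs.plant_motif(genome, "g1_4", consensus.sequence, 30, "-")
        hits = rs.scan_genome(genome, min_identity_pct=90.0)
        assert set(hits.gene_id) == {"g1_1", "g1_4"}
        by_gene = hits.set_index("gene_id")
        assert by_gene.loc["g1_1", "distance_nt"] == -120
        assert by_gene.loc["g1_4", "distance_nt"] == 30
        assert by_gene.loc["g1_4", "match_strand"] == "-"

    def test_zero_threshold_reports_every_gene(self, five_gene_genome):
        hits = rs.scan_genome(five_gene_genome, min_identity_pct=0.0)
        assert set(hits.gene_id) == {g.gene_id for g in five_gene_genome.genes}

    def test_motif_outside_window_not_reported(self, five_gene_genome, consensus):
        genome = rs.plant_motif(five_gene_genome, "g1_2", consensus.sequence, 200, "+")
        hits = rs.scan_genome(genome, min_identity_pct=90.0)
        assert "g1_2" not in set(hits.gene_id)

    def test_strand_symmetry(self, consensus):
        """Reverse-complementing a contig and flipping strands is a no-op."""
        genome = rs.generate_genome(1, 4, 600, 900, gc=0.5, seed=9)
        genome = rs.plant_motif(genome, "g1_2", consensus.sequence, -77, "+")
        n = len(genome.contigs["contig_1"])
        flipped = rs.GenomeAnnotation(
            {"contig_1": rs.reverse_complement(genome.contigs["contig_1"])},
            [
                rs.GeneRecord(
                    g.gene_id,
                    g.contig_id,
                    "-" if g.strand == "+" else "+",
                    n - g.cds_end + 1,
                    n - g.cds_start + 1,
                )
                for g in genome.genes
            ],
        )
        h1 = rs.scan_genome(genome, min_identity_pct=60.0)
        h2 = rs.scan_genome(flipped, min_identity_pct=60.0)
        cols = ["gene_id", "match_strand", "distance_nt", "matched_sequence",
                "identity_pct"]
        assert h1[cols].to_dict("records") == h2[cols].to_dict("records")


class TestPwm:
    def test_closed_form_cells(self, consensus):
        pwm = rs.build_pwm(consensus)
        expected_hit = np.log2((1.25 / 2.0) / 0.25)
        expected_miss = np.log2((0.25 / 2.0) / 0.25)
        for p, base in enumerate(consensus.sequence):
            for b, letter in enumerate("ACGT"):
                exp = expected_hit if letter == base else expected_miss
                assert pwm[p, b] == pytest.approx(exp)

    def test_consensus_score_closed_form(self, consensus):
        assert pwm_score(consensus.sequence, consensus) == pytest.approx(
            18 * np.log2(2.5)
        )

    def test_any_scored_mismatch_lowers_score(self, consensus):
        base_score = pwm_score(consensus.sequence, consensus)
        for idx in consensus.scored_indices:
            seq = list(consensus.sequence)
            seq[idx] = "A" if seq[idx] != "A" else "C"
            assert pwm_score("".join(seq), consensus) < base_score


class TestGappedIdentity:
    def test_single_deletion_restored(self, consensus):
        query = consensus.sequence[:4] + consensus.sequence[5:]  # drop position 5
        (aq, ac), n, pct = rs.gapped_identity(query, consensus)
        # positions 4 and 5 are an AA run, so the restored gap can sit at
        # either column; the score and identity are identical
        assert aq.count("-") == 1 and aq.index("-") in (3, 4)
        assert ac == consensus.sequence
        assert (n, pct) == (17, 94.4)

    def test_no_indel_reduces_to_identity_score(self, consensus):
        rng = np.random.default_rng(2)
        for _ in range(20):
            q = "".join(rng.choice(list("ACGT"), 22))
            (_, _), n, pct = rs.gapped_identity(q, consensus)
            assert (n, pct) == rs.identity_score(q, consensus)

    def test_matches_exhaustive_gap_enumeration(self, consensus):
        """Best alignment equals a brute-force search over all single-gap
        placements under the same scoring."""
        rng = np.random.default_rng(4)
        cons = consensus.sequence
        for _ in range(30):
            q = "".join(rng.choice(list("ACGT"), 21))
            best = -99
            for c in range(22):
                aq = q[:c] + "-" + q[c:]
                score = sum(1 for a, b in zip(aq, cons) if a == b) - 1
                best = max(best, score)
            (aq, ac), _, _ = rs.gapped_identity(q, consensus)
            got = sum(1 for a, b in zip(aq, ac) if a == b and a != "-") - 1
            assert got == best

    def test_insertion_gap_in_consensus(self, consensus):
        query = consensus.sequence[:7] + "A" + consensus.sequence[7:]
        (aq, ac), n, pct = rs.gapped_identity(query, consensus)
        assert "-" in ac
        assert (n, pct) == (18, 100.0)

    def test_length_difference_limit(self, consensus):
        with pytest.raises(ValueError):
            rs.gapped_identity("ACGT" * 5, consensus, max_indels=1)
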