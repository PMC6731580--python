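"""Alignment, percent identity and similarity matrices."""

import itertools
import random

import pytest
from Bio import Align

from conftest import exhaustive_align_score
from modeldiscovery.errors import InvalidInputError, NotFoundError
from modeldiscovery.seqsim import (
    ProteinRecord,
    Scoring,
    SequenceSource,
    global_align,
    parse_percent_identity_matrix,
    percent_identity,
    read_fasta,
    similarity_matrix,
    write_fasta,
)


class TestGlobalAlign:
    def test_identity_alignment_has_no_gaps(self):
        aln = global_align("ACDE", "ACDE")
        assert aln.aligned_a == aln.aligned_b == "ACDE"
        assert aln.score == 4

    def test_single_mismatch_column(self):
        aln = global_align("A", "G")
        assert (aln.aligned_a, aln.aligned_b) == ("A", "G")
        assert aln.score == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            global_align("", "ACD")

    def test_gaps_strip_back_to_inputs(self):
        aln = global_align("ACDACD", "ACD")
        assert aln.aligned_a.replace("-", "") == "ACDACD"
        assert aln.aligned_b.replace("-", "") == "ACD"
        assert len(aln.aligned_a) == len(aln.aligned_b)

    def test_score_matches_exhaustive_enumeration(self):
        """DP optimum equals brute-force recursion over all alignments,
        sampled across lengths ≤ 6 on the {A,C,D} alphabet."""
        rng = random.Random(13)
        pool = [
            "".join(rng.choice("ACD") for _ in range(rng.randint(1, 6)))
            for _ in range(40)
        ]
        pairs = [(rng.choice(pool), rng.choice(pool)) for _ in range(150)]
        pairs += [("A", "A"), ("ACDACD", "DCA"), ("AAA", "CCC"), ("ACD", "ACD")]
        for a, b in pairs:
            assert global_align(a, b).score == pytest.approx(
                exhaustive_align_score(a, b)
            )

    def test_score_matches_biopython_aligner(self):
        """Independent cross-check against Biopython's global aligner."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        rng = random.Random(29)
        for _ in range(30):
            a = "".join(rng.choice("ACDEFGHIK") for _ in range(rng.randint(3, 12)))
            b = "".join(rng.choice("ACDEFGHIK") for _ in range(rng.randint(3, 12)))
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))


class TestPercentIdentity:
    def test_identical_sequences_are_100(self):
        for seq in ("A", "ACDE", "ACDEFGHIKLMNPQRSTVWY"):
            assert percent_identity(global_align(seq, seq)) == 100.00

    def test_three_of_four_identical_is_75(self):
        assert percent_identity(global_align("ACDE", "ACDF")) == 75.00

    def test_disjoint_alphabets_give_zero(self):
        assert percent_identity(global_align("AAAA", "CCCC")) == 0.00

    def test_rounding_is_half_up_to_two_decimals(self):
        # 1/3 identical -> 33.333... -> 33.33 ; 2/3 -> 66.666... -> 66.67
        assert percent_identity(global_align("ACC", "ADD")) == 33.33
        assert percent_identity(global_align("ACD", "ACC")) == 66.67

    def test_gap_only_overlap_is_undefined(self):
        from modeldiscovery.seqsim import Alignment

        with pytest.raises(InvalidInputError):
            percent_identity(Alignment("A-", "-C", 0.0))


class TestSimilarityMatrix:
    def test_identical_records(self):
        recs = [ProteinRecord("A1", "ACDE"), ProteinRecord("A2", "ACDE")]
        m = similarity_matrix(recs)
        assert m.values == ((100.0, 100.0), (100.0, 100.0))

    def test_symmetric_unit_diagonal_bounded(self, workspace):
        generated, _ = workspace
        recs = sorted(generated.records.values(), key=lambda r: r.accession)[:5]
        m = similarity_matrix(recs)
        arr = m.as_array()
        assert (arr == arr.T).all()
        assert (arr.diagonal() == 100.0).all()
        assert ((arr >= 0) & (arr <= 100)).all()

    def test_invariant_under_record_reordering(self):
        rng = random.Random(17)
        recs = [
            ProteinRecord(f"R{i}", "".join(rng.choice("ACDEFG") for _ in range(30)))
            for i in range(4)
        ]
        m1 = similarity_matrix(recs)
        m2 = similarity_matrix(recs[::-1])
        for a, b in itertools.combinations([r.accession for r in recs], 2):
            assert m1.get(a, b) == m2.get(a, b)

    def test_duplicate_accessions_rejected(self):
        recs = [ProteinRecord("X", "ACDE"), ProteinRecord("X", "ACDF")]
        with pytest.raises(InvalidInputError):
            similarity_matrix(recs)

    def test_planted_identities_recovered_within_two_points(self, workspace):
        generated, _ = workspace
        ref = generated.records["FIXREF"]
        targets = {"FIX090": 90.0, "FIX050": 50.0, "FIX020": 20.0}
        recs = [ref] + [generated.records[a] for a in sorted(targets)]
        m = similarity_matrix(recs)
        row = m.row("FIXREF")
        for acc, planted in targets.items():
            assert abs(row[acc] - planted) <= 2.0, (acc, row[acc])


class TestSequenceSource:
    def test_local_fasta_served_verbatim(self, workspace, tmp_path):
        generated, out = workspace
        source = SequenceSource(fasta_path=out / "proteins.fasta")
        rec = source.fetch("FIXREF")
        assert rec.sequence == generated.records["FIXREF"].sequence

    def test_unknown_accession_not_found(self, workspace):
        _, out = workspace
        source = SequenceSource(fasta_path=out / "proteins.fasta")
        with pytest.raises(NotFoundError):
            source.fetch("NOPE999")

    def test_second_fetch_served_from_cache(self, workspace):
        generated, out = workspace
        source = SequenceSource(fasta_path=out / "proteins.fasta")
        accs = sorted(generated.records)
        first = [source.fetch(a).sequence for a in accs]
        calls = source.fetch_calls
        second = [source.fetch(a).sequence for a in accs]
        assert first == second
        assert source.fetch_calls == calls

    def test_fasta_round_trip(self, tmp_path):
        recs = [ProteinRecord("B2", "ACDEF" * 30), ProteinRecord("A1", "GHIKL")]
        path = tmp_path / "x.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert {a: r.sequence for a, r in back.items()} == {
            "A1": "GHIKL", "B2": "ACDEF" * 30
        }


def test_percent_identity_matrix_text_parses():
    """Clustal-style percent-identity matrix text (synthetic values)."""
    text = (
        "#\n"
        "# Percent Identity  Matrix - created by Clustal2.1\n"
        "#\n"
        "  1: P26433  100.00   89.49   21.86   18.20\n"
        "  2: P48764   89.49  100.00   21.50   17.90\n"
        "  3: Q9ET37   21.86   21.50  100.00   19.00\n"
        "  4: P06685   18.20   17.90   19.00  100.00\n"
    )
    m = parse_percent_identity_matrix(text)
    assert m.accessions == ("P26433", "P48764", "Q9ET37", "P06685")
    assert m.row("P26433") == {
        "P26433": 100.00, "P48764": 89.49, "Q9ET37": 21.86, "P06685": 18.20
    }
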