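import random

import pytest
from hypothesis import given, settings, strategies as st

import oniscamp as o
from oniscamp.seqio_core import (
    FastaParseError,
    FRAMES,
    NucleotideRecord,
    global_nucleotide_identity,
)
from oracles import six_frame_orfs


def write(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record(self, tmp_path):
        recs = o.read_fasta(write(tmp_path, ">a\nACGT\n"), "dna")
        assert len(recs) == 1 and recs[0].id == "a" and recs[0].seq == "ACGT"

    def test_case_and_u_normalization(self, tmp_path):
        recs = o.read_fasta(write(tmp_path, ">a\nacgu\n"), "dna")
        assert recs[0].seq == "ACGT"

    def test_wrapped_and_multirecord_order(self, tmp_path):
        recs = o.read_fasta(write(tmp_path, ">a desc\nAC\nGT\n>b\nGG\n"), "dna")
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].seq == "ACGT"

    def test_sequence_before_header_names_line(self, tmp_path):
        with pytest.raises(FastaParseError, match="line 1"):
            o.read_fasta(write(tmp_path, "ACGT\n>a\nACGT\n"), "dna")

    def test_duplicate_id_rejected(self, tmp_path):
        with pytest.raises(FastaParseError, match="duplicate"):
            o.read_fasta(write(tmp_path, ">a\nAC\n>a\nGT\n"), "dna")

    def test_packaged_fixture_has_18_mature_peptides(self, matures):
        assert len(matures) == 18
        ids = [r.id for r in matures]
        assert "A_vulgare_H" in ids and "A_vulgare_Q" in ids
        # 17 organisms: the two A. vulgare variants share one organism
        organisms = {i.removesuffix("_H").removesuffix("_Q") for i in ids}
        assert len(organisms) == 17


class TestFindOrfs:
    def test_forced_forward_orf(self):
        orfs = o.find_orfs(NucleotideRecord("x", "ATGGGTTAA"), min_aa=2)
        assert (1, "MG") in [(orf.frame, orf.peptide) for orf in orfs]

    def test_reverse_complement_recovers_same_peptide(self):
        fwd = "ATGGGTCGTTTCTAA"
        rc = "TTAGAAACGACCCAT"
        peps_fwd = {(orf.frame > 0, orf.peptide) for orf in o.find_orfs(NucleotideRecord("f", fwd), 4)}
        peps_rev = {(orf.frame > 0, orf.peptide) for orf in o.find_orfs(NucleotideRecord("r", rc), 4)}
        assert (True, "MGRF") in peps_fwd
        assert (False, "MGRF") in peps_rev

    def test_short_sequence_gives_empty(self):
        assert o.find_orfs(NucleotideRecord("x", "AC"), 1) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_six_frame_scan(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        got = {
            (orf.frame, orf.start, orf.end, orf.peptide)
            for orf in o.find_orfs(NucleotideRecord("x", seq), 5)
        }
        assert got == six_frame_orfs(seq, 5)


class TestLongestOrf:
    def test_selection_matches_oracle_over_random_sequences(self):
        rng = random.Random(17)
        rank = {f: k for k, f in enumerate(FRAMES)}
        for _ in range(10):
            seq = "".join(rng.choice("ACGT") for _ in range(400))
            orfs = six_frame_orfs(seq, 1)
            expected = sorted(
                orfs, key=lambda t: (-len(t[3]), rank[t[0]], t[1])
            )[0]
            pep = o.longest_orf_peptide(NucleotideRecord("x", seq))
            assert pep.seq == expected[3]
            assert (pep.source.frame, pep.source.start) == expected[:2]

    def test_frame_tiebreak_prefers_plus_one(self):
        # two 2-codon ORFs: frame +1 (ATGGGT) and frame +2 (embedded);
        # equal length -> frame order decides
        rec = NucleotideRecord("x", "TAAATGGGTTAAAATGGGTTAAC")
        orfs = o.find_orfs(rec, 1)
        best = o.longest_orf_peptide(rec)
        top_len = len(best.seq)
        tied = [orf for orf in orfs if len(orf.peptide) == top_len]
        ranks = [FRAMES.index(orf.frame) for orf in tied]
        assert FRAMES.index(best.source.frame) == min(ranks)

    def test_no_orf_returns_none(self):
        assert o.longest_orf_peptide(NucleotideRecord("x", "TA")) is None

    def test_longest_is_at_least_every_other_orf(self):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        rec = NucleotideRecord("x", seq)
        best = o.longest_orf_peptide(rec)
        assert all(len(best.seq) >= len(orf.peptide) for orf in o.find_orfs(rec, 1))


def mutate_dna(seq, rate, rng):
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in "ACGT" if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


class TestCollapse:
    def test_identical_records_collapse(self):
        recs = [NucleotideRecord("a", "ACGT" * 30), NucleotideRecord("b", "ACGT" * 30)]
        clusters = o.collapse_redundant(recs)
        assert len(clusters) == 1 and sorted(clusters[0].member_ids) == ["a", "b"]

    def test_ten_percent_divergence_stays_apart(self):
        rng = random.Random(0)
        base = "".join(rng.choice("ACGT") for _ in range(200))
        div = mutate_dna(base, 0.10, rng)
        clusters = o.collapse_redundant(
            [NucleotideRecord("a", base), NucleotideRecord("b", div)], 0.95
        )
        assert len(clusters) == 2

    def test_clustering_equals_greedy_replay_on_identity_matrix(self):
        # 20 copies of one template at 2% mutation: replay the greedy
        # rule directly from the all-pairs identity matrix and require
        # the same clusters
        rng = random.Random(1)
        template = "".join(rng.choice("ACGT") for _ in range(300))
        recs = [
            NucleotideRecord(f"m{i}", mutate_dna(template, 0.02, rng))
            for i in range(20)
        ]
        ident = {
            (a.id, b.id): global_nucleotide_identity(a.seq, b.seq)
            for a in recs
            for b in recs
        }
        expected: list[tuple[str, list[str]]] = []
        for rec in sorted(recs, key=lambda r: -len(r.seq)):
            for rep, members in expected:
                if ident[(rep, rec.id)] >= 0.95:
                    members.append(rec.id)
                    break
            else:
                expected.append((rec.id, [rec.id]))
        clusters = o.collapse_redundant(recs, 0.95)
        assert [(c.representative_id, c.member_ids) for c in clusters] == expected

    def test_membership_partitions_input(self):
        rng = random.Random(2)
        recs = [
            NucleotideRecord(
                f"r{i}", "".join(rng.choice("ACGT") for _ in range(rng.randint(40, 120)))
            )
            for i in range(15)
        ]
        clusters = o.collapse_redundant(recs)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.id for r in recs)
        for c in clusters:
            assert c.representative_id in c.member_ids

    def test_empty_input(self):
        assert o.collapse_redundant([]) == []


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet="ACGT", min_size=3, max_size=120), st.integers(1, 10))
def test_orf_scan_agrees_with_enumeration(seq, min_aa):
    got = {
        (orf.frame, orf.start, orf.end, orf.peptide)
        for orf in o.find_orfs(NucleotideRecord("x", seq), min_aa)
    }
    assert got == six_frame_orfs(seq, min_aa)
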