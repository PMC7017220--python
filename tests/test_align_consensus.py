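import random

import pytest

import oniscamp as o
from oniscamp.align_consensus import MultipleAlignment, pairwise_identity
from oniscamp.seqio_core import PeptideRecord
from oracles import affine_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self, scheme):
        msa = o.global_align("GGGF", "GGGF", scheme)
        assert msa.rows == ["GGGF", "GGGF"]

    def test_length_difference_forces_one_gap_column(self, scheme):
        msa = o.global_align("GGGF", "GGF", scheme)
        assert msa.column_count == 4
        assert msa.rows[1].count("-") == 1 and msa.rows[0].count("-") == 0

    def test_score_matches_bruteforce_dp(self, scheme):
        rng = random.Random(12)
        matrix = scheme.matrix
        aligner = scheme.make_aligner("global")
        for _ in range(30):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(15, 25)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(15, 25)))
            assert int(round(aligner.score(a, b))) == affine_global_score(
                a, b, matrix, scheme.gap_open, scheme.gap_extend
            )

    def test_ungapping_recovers_inputs(self, scheme):
        msa = o.global_align("ACDEFGHIK", "ACDFGHK", scheme)
        assert msa.ungapped(0) == "ACDEFGHIK"
        assert msa.ungapped(1) == "ACDFGHK"


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self, scheme):
        seqs = [PeptideRecord(f"s{i}", "ACDEFGHIKLMNP") for i in range(4)]
        msa = o.progressive_msa(seqs, scheme)
        assert all("-" not in row for row in msa.rows)

    def test_single_sequence(self, scheme):
        msa = o.progressive_msa([PeptideRecord("s", "ACDEF")], scheme)
        assert msa.rows == ["ACDEF"]

    def test_rows_ungap_to_inputs_and_column_count(self, armadillidiidae, scheme):
        msa = o.progressive_msa(armadillidiidae, scheme)
        by_id = {r.id: r.seq for r in armadillidiidae}
        for rid, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == by_id[rid]
        assert msa.column_count >= max(len(r.seq) for r in armadillidiidae)


class TestTrimBlocks:
    def test_gap_free_alignment_unchanged(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEFGHIK", "ACDEFGHIR"])
        out = o.trim_blocks(msa)
        assert out.rows == msa.rows

    def test_gappy_column_inside_long_block_removed(self):
        rows = ["ACDEF-GHIKLM", "ACDEFWGHIKLM", "ACDEF-GHIKLM"]
        out = o.trim_blocks(MultipleAlignment(["a", "b", "c"], rows), 0.5, 5)
        assert out.column_count == 11
        assert out.rows[1] == "ACDEFGHIKLM"

    def test_matches_columnwise_filter_oracle(self):
        rng = random.Random(13)
        nrow, ncol = 6, 60
        rows = [
            "".join(
                "-" if rng.random() < 0.3 else rng.choice(AA) for _ in range(ncol)
            )
            for _ in range(nrow)
        ]
        msa = MultipleAlignment([f"r{i}" for i in range(nrow)], rows)
        out = o.trim_blocks(msa, 0.5, 5)
        # oracle: apply the two rules directly
        keep = [sum(r[j] == "-" for r in rows) / nrow <= 0.5 for j in range(ncol)]
        runs, j = [], 0
        while j < ncol:
            if keep[j]:
                k = j
                while k < ncol and keep[k]:
                    k += 1
                runs.append((j, k))
                j = k
            else:
                j += 1
        cols = [c for s, e in runs if e - s >= 5 for c in range(s, e)]
        expected = ["".join(r[c] for c in cols) for r in rows]
        assert out.rows == expected

    def test_idempotent(self):
        rng = random.Random(14)
        rows = [
            "".join("-" if rng.random() < 0.4 else rng.choice(AA) for _ in range(50))
            for _ in range(5)
        ]
        msa = MultipleAlignment([f"r{i}" for i in range(5)], rows)
        once = o.trim_blocks(msa)
        twice = o.trim_blocks(once)
        assert once.rows == twice.rows

    def test_all_columns_dropped_warns(self):
        msa = MultipleAlignment(["a", "b"], ["A---", "-CDE"])
        with pytest.warns(UserWarning):
            out = o.trim_blocks(msa, 0.4, 5)
        assert out.column_count == 0


class TestColumnConsensus:
    def test_identical_rows_reproduce_sequence(self):
        msa = MultipleAlignment(["a", "b"], ["GGGF", "GGGF"])
        res = o.column_consensus(msa)
        assert res.consensus == "GGGF"
        assert res.column_conservation == [1.0] * 4

    def test_disjoint_rows_give_all_gaps(self):
        msa = MultipleAlignment(["a", "b"], ["GGGG", "PPPP"])
        assert o.column_consensus(msa, 0.70).consensus == "----"

    def test_class_level_conservation_emits_modal_residue(self):
        # column of L/I/V/L: no residue at 70% but class {AVLIM} is 100%
        msa = MultipleAlignment(list("abcd"), ["L", "I", "V", "L"])
        res = o.column_consensus(msa, 0.70)
        assert res.consensus == "L"

    def test_letter_emitted_iff_conserved(self, armadillidiidae, scheme):
        msa = o.progressive_msa(armadillidiidae, scheme)
        res = o.column_consensus(msa, 0.70)
        for sym, cons in zip(res.consensus, res.column_conservation):
            assert (sym != "-") == (cons >= 0.70)

    def test_consensus_fixed_point(self, armadillidiidae, scheme):
        res = o.column_consensus(o.progressive_msa(armadillidiidae, scheme), 0.70)
        copies = MultipleAlignment(["a", "b", "c"], [res.consensus] * 3)
        assert o.column_consensus(copies, 0.70).consensus == res.consensus


class TestArmadillidiidaeConsensus:
    """The family consensus of the eight Armadillidiidae armadillidins."""

    def test_contains_conserved_motif_block(self, armadillidiidae, scheme):
        res = o.column_consensus(o.progressive_msa(armadillidiidae, scheme), 0.70)
        assert "RPYIGGGG" in res.consensus
        assert res.consensus.count("GGGF") >= 3

    def test_robust_to_input_order(self, armadillidiidae, scheme):
        rng = random.Random(15)
        for _ in range(3):
            perm = list(armadillidiidae)
            rng.shuffle(perm)
            res = o.column_consensus(o.progressive_msa(perm, scheme), 0.70)
            assert "RPYIGGGG" in res.consensus
            assert res.consensus.count("GGGF") >= 3

    def test_independent_aligner_supports_same_motifs(self, armadillidiidae, tmp_path):
        """Cross-check with mafft: the motif content of the consensus is a
        property of the sequences, not of this package's aligner."""
        import subprocess

        fa = tmp_path / "in.fasta"
        o.write_fasta(armadillidiidae, fa)
        proc = subprocess.run(
            ["mafft", "--auto", str(fa)], capture_output=True, text=True, check=True
        )
        ids, rows, cur = [], [], []
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            else:
                cur.append(line.upper())
        rows.append("".join(cur))
        res = o.column_consensus(MultipleAlignment(ids, rows), 0.70)
        assert "RPYIGGGG" in res.consensus
        assert res.consensus.count("GGGF") >= 3


def test_pairwise_identity_bounds(scheme):
    assert pairwise_identity("ACDEF", "ACDEF", scheme) == 1.0
    assert pairwise_identity("AAAA", "CCCC", scheme) == 0.0
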