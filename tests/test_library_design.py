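import itertools

import numpy as np
import pytest

from dnahyb import library_design as ld
from dnahyb import seqops, thermo
from _oracles import lcs_bruteforce


class TestLcsLength:
    def test_identical_strings(self):
        assert ld.lcs_length("ACGT", "ACGT") == 4

    def test_disjoint_alphabets(self):
        assert ld.lcs_length("AAAA", "CCCC") == 0

    def test_random_pairs_match_bruteforce(self, rng):
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), rng.integers(1, 25)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(1, 25)))
            assert ld.lcs_length(a, b) == lcs_bruteforce(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ld.lcs_length("", "ACGT")


class TestDedup:
    def test_symmetric_and_self_pairs_removed(self):
        raw = {("seq10", "seq20"), ("seq20", "seq10"), ("seq7", "seq7")}
        assert ld.dedup_pairs(raw) == frozenset({("seq10", "seq20")})

    def test_idempotent(self, rng):
        names = [f"s{i}" for i in range(20)]
        raw = {(rng.choice(names), rng.choice(names)) for _ in range(100)}
        once = ld.dedup_pairs(raw)
        assert ld.dedup_pairs(once) == once


class TestCandidatePairs:
    def _random_library(self, n, rng, length=20):
        return {f"seq{i}": seqops.random_sequence(length, rng)
                for i in range(n)}

    def test_equals_bruteforce_filter_on_100_random_20mers(self):
        gen = np.random.default_rng(33)
        seqs = self._random_library(100, gen)
        result = ld.candidate_pairs(seqs, ld.LCSParams(k=5))
        expected = set()
        for a, b in itertools.combinations(sorted(seqs), 2):
            if lcs_bruteforce(seqs[a],
                              seqops.reverse_complement(seqs[b])) >= 5:
                expected.add((a, b))
        assert result.pairs == frozenset(expected)
        assert len(result) <= 100 * 99 // 2

    def test_kmer_join_equivalence_exhaustive_small(self, rng):
        # many random small libraries, short sequences, several thresholds
        for trial in range(40):
            n = int(rng.integers(2, 9))
            seqs = {f"s{i}": "".join(rng.choice(list("ACGT"),
                                                rng.integers(5, 11)))
                    for i in range(n)}
            for k in (2, 3, 5):
                got = ld.candidate_pairs(seqs, ld.LCSParams(k=k)).pairs
                want = {tuple(sorted((a, b)))
                        for a, b in itertools.combinations(sorted(seqs), 2)
                        if lcs_bruteforce(
                            seqs[a],
                            seqops.reverse_complement(seqs[b])) >= k}
                assert got == want

    def test_direct_mode_flag(self):
        seqs = {"a": "ACGTACGTACGTACGTACGT", "b": "ACGTACGTACGTACGTACGT"}
        direct = ld.candidate_pairs(
            seqs, ld.LCSParams(k=5, against_revcomp=False))
        assert ("a", "b") in direct.pairs

    def test_degenerate_threshold_k1(self):
        # every pair shares at least one complementary base here
        seqs = {"x": "ACGTACGTACGTACGTACGT",
                "y": "TGCATGCATGCATGCATGCA",
                "z": "GGAAGGAAGGAAGGAAGGAA"}
        result = ld.candidate_pairs(seqs, ld.LCSParams(k=1))
        assert result.pairs == frozenset({("x", "y"), ("x", "z"), ("y", "z")})

    def test_no_self_pairs_even_for_self_complementary(self):
        seqs = {"p": "CCATGGAGGCGCGCCTTT", "q": "ACACACACACACACACAC"}
        result = ld.candidate_pairs(seqs, ld.LCSParams(k=4))
        for a, b in result.pairs:
            assert a != b


class TestMMseqs2:
    def test_command_construction_matches_protocol(self):
        cmds = ld.build_mmseqs_commands("lib.fa", "/tmp/w", min_lcs=5)
        createdb, search, convert = cmds
        assert createdb[:2] == ["mmseqs", "createdb"]
        assert "--dbtype" in createdb
        flags = " ".join(search)
        for fragment in ("-s 7.5", "-k 5", "--max-seqs 10000",
                         "--exact-kmer-matching 1", "--spaced-kmer-mode 0",
                         "--min-seq-id 0.25", "--alignment-mode 4",
                         "-e inf", "--min-aln-len 5", "--strand 0",
                         "--search-type 3"):
            assert fragment in flags
        assert convert[1] == "convertalis"

    def test_missing_binary_raises(self, tmp_path, monkeypatch):
        fasta = tmp_path / "lib.fa"
        seqops.write_fasta({"a": "ACGTACGTACGTACGTACGT"}, fasta)
        monkeypatch.setattr(ld.shutil, "which", lambda _: None)
        with pytest.raises(ld.MMseqs2NotFoundError):
            ld.mmseqs2_candidates(fasta, tmp_path)

    def test_empty_fasta_rejected(self, tmp_path):
        fasta = tmp_path / "empty.fa"
        fasta.write_text("")
        with pytest.raises(ValueError, match="empty"):
            ld.mmseqs2_candidates(fasta, tmp_path)


class _OraclePredictor:
    def predict(self, pairs, batch_size=512):
        return np.array([thermo.builtin_yield(a, b).yield_fraction
                         for a, b in pairs])


class TestDesignReport:
    def test_no_candidates_all_conflict_free(self):
        empty = ld.CandidatePairSet(pairs=frozenset(), min_lcs=5,
                                    source="builtin_kmer")
        seqs = {"a": "ACGTACGTACGTACGTACGT"}
        report = ld.design_report(empty, _OraclePredictor(), seqs)
        assert report.conflict_free == frozenset({"a"})
        assert len(report.pair_table) == 0

    def test_revcomp_pair_flagged_and_removed(self, rng):
        s = seqops.random_sequence(20, rng)
        seqs = {"fwd": s, "rev": seqops.reverse_complement(s),
                "other": "ACACACACACACACACACAC"}
        candidates = ld.candidate_pairs(seqs, ld.LCSParams(k=5))
        assert ("fwd", "rev") in candidates.pairs
        report = ld.design_report(candidates, _OraclePredictor(), seqs)
        row = report.pair_table.set_index(["id_a", "id_b"]).loc[("fwd", "rev")]
        assert bool(row["conflict"])
        # the greedy subset drops one of the two conflicting strands
        assert not {"fwd", "rev"} <= report.conflict_free

    def test_conflict_free_subset_has_no_flagged_pair(self, rng):
        seqs = {f"s{i}": seqops.random_sequence(20, rng) for i in range(30)}
        candidates = ld.candidate_pairs(seqs, ld.LCSParams(k=4))
        report = ld.design_report(candidates, _OraclePredictor(), seqs,
                                  threshold=0.2)
        flagged = {(a, b) for a, b, c in zip(report.pair_table["id_a"],
                                             report.pair_table["id_b"],
                                             report.pair_table["conflict"])
                   if c}
        for a, b in flagged:
            assert not {a, b} <= report.conflict_free

    def test_missing_sequence_rejected(self):
        candidates = ld.CandidatePairSet(pairs=frozenset({("a", "b")}),
                                         min_lcs=5, source="builtin_kmer")
        with pytest.raises(KeyError):
            ld.design_report(candidates, _OraclePredictor(),
                             {"a": "ACGTACGTACGTACGTACGT"})

    def test_tsv_output(self, tmp_path, rng):
        seqs = {f"s{i}": seqops.random_sequence(20, rng) for i in range(10)}
        candidates = ld.candidate_pairs(seqs, ld.LCSParams(k=4))
        report = ld.design_report(candidates, _OraclePredictor(), seqs)
        out = tmp_path / "pairs.tsv"
        report.write_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == ["id_a", "id_b", "lcs", "predicted_yield",
                          "conflict"]
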