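import itertools

import pytest
from hypothesis import given, settings, strategies as st

from amphipep.seqio import (
    PeptideCandidate,
    ProteinRecord,
    ValidationError,
    cluster_peptides,
    enumerate_peptides,
    mature_sequence,
    read_fasta,
    read_signal_table,
    similarity,
    write_fasta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=1, max_size=100)


class TestReadFasta:
    def test_two_entries(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">p1 desc\n" + "A" * 10 + "\n>p2\n" + "G" * 20 + "\n")
        records = read_fasta(p)
        assert [len(r) for r in records] == [10, 20]
        assert records[0].id == "p1"

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">p1\ngikg\nii\n")
        assert read_fasta(p)[0].sequence == "GIKGII"

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fasta(p) == []
        assert "no FASTA records" in caplog.text

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nAAA\n>x\nCCC\n")
        with pytest.raises(ValidationError, match="x"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            read_fasta(tmp_path / "nope.fasta")

    def test_roundtrip(self, tmp_path):
        records = [ProteinRecord(id="a", sequence="ACDEFG" * 15)]
        out = tmp_path / "out.fasta"
        write_fasta(records, out)
        back = read_fasta(out)
        assert back[0].sequence == records[0].sequence


class TestMaturation:
    def test_prefix_removed(self):
        rec = ProteinRecord(id="p", sequence="MKKLLAGIKGII", signal_end=4)
        assert mature_sequence(rec).sequence == "LAGIKGII"
        assert mature_sequence(rec).signal_end is None

    def test_no_signal_is_identity(self):
        rec = ProteinRecord(id="p", sequence="MKKLLAGIKGII")
        assert mature_sequence(rec) is rec

    def test_whole_sequence_signal_rejected(self):
        rec = ProteinRecord(id="p", sequence="MKKLLAGIKGII", signal_end=12)
        with pytest.raises(ValidationError):
            mature_sequence(rec)

    def test_signal_table(self, tmp_path):
        p = tmp_path / "sig.tsv"
        p.write_text("# comment\np1\t4\np2\t21\n")
        assert read_signal_table(p) == {"p1": 4, "p2": 21}


class TestEnumeration:
    def test_below_minimum_yields_nothing(self):
        assert enumerate_peptides(ProteinRecord(id="p", sequence="A" * 6)) == []

    def test_exactly_minimum(self):
        cands = enumerate_peptides(ProteinRecord(id="p", sequence="ACDEFGH"))
        assert len(cands) == 1
        assert cands[0].sequence == "ACDEFGH"
        assert (cands[0].start, cands[0].end) == (1, 7)

    def test_length_30_gives_300(self):
        # sum over window lengths 7..30 of (31 - len) = 1 + 2 + ... + 24
        cands = enumerate_peptides(ProteinRecord(id="p", sequence="ACDEFGHIKL" * 3))
        assert len(cands) == 300

    @given(L=st.integers(min_value=1, max_value=100))
    @settings(max_examples=40, deadline=None)
    def test_count_matches_closed_form_and_brute_force(self, L):
        rec = ProteinRecord(id="p", sequence="A" * L)
        cands = enumerate_peptides(rec)
        closed = sum(L - w + 1 for w in range(7, min(30, L) + 1))
        brute = sum(
            1
            for start in range(L)
            for end in range(start + 6, min(start + 30, L))
        )
        assert len(cands) == closed == brute

    def test_duplicate_free(self):
        cands = enumerate_peptides(ProteinRecord(id="p", sequence="ACDEFGHIKLMNPQRS"))
        keys = [c.key() for c in cands]
        assert len(keys) == len(set(keys))

    def test_subsequence_invariant(self):
        rec = ProteinRecord(id="p", sequence="ACDEFGHIKLMNPQRS")
        for c in enumerate_peptides(rec):
            assert c.sequence == rec.sequence[c.start - 1 : c.end]
            assert c.length == c.end - c.start + 1

    def test_noncanonical_windows_skipped(self, caplog):
        rec = ProteinRecord(id="p", sequence="ACDEFGH" + "X" + "IKLMNPQ")
        with caplog.at_level("WARNING"):
            cands = enumerate_peptides(rec)
        assert all("X" not in c.sequence for c in cands)
        assert "non-canonical" in caplog.text


class TestSimilarity:
    def test_identical(self):
        assert similarity("AAAAAAA", "AAAAAAA") == 1.0

    def test_zero_identity(self):
        assert similarity("AAAAAAA", "RRRRRRR") == 0.0

    def test_embedded_is_one(self):
        assert similarity("EALKRFAKLLSD", "KKPVSKDSPETYEEALKRFAKLLSDRKKL") == 1.0

    def test_symmetric(self):
        assert similarity("ACDEFGH", "CDEFGHIKL") == similarity("CDEFGHIKL", "ACDEFGH")


class TestClustering:
    def _cand(self, seq, pid="p", start=1):
        return PeptideCandidate(pid, start, start + len(seq) - 1, seq)

    def test_identical_pair_one_cluster(self):
        c1 = self._cand("LNIQFNI", "a")
        c2 = self._cand("LNIQFNI", "b")
        clusters = cluster_peptides([c1, c2])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 2

    def test_embedded_reference_peptides_cluster_together(self):
        # one published cluster: the shorter peptide is embedded in the longer
        short = self._cand("DSPETYEEALKRFAKLLSD", "pat")
        long_ = self._cand("KKPVSKDSPETYEEALKRFAKLLSDRKKL", "pat", 5)
        clusters = cluster_peptides([short, long_])
        assert len(clusters) == 1

    def test_dissimilar_singletons(self):
        clusters = cluster_peptides([self._cand("AAAAAAA"), self._cand("RRRRRRR", "q")])
        assert len(clusters) == 2
        assert all(len(c.members) == 1 for c in clusters)

    def test_representative_highest_score_then_longest(self):
        a = self._cand("LNIQFNI", "a")
        b = self._cand("LNIQFNIPT", "b")
        clusters = cluster_peptides([a, b], score_of=lambda p: 1.0)
        assert clusters[0].representative.sequence == "LNIQFNIPT"
        clusters = cluster_peptides([a, b], score_of=lambda p: 2.0 if p.sequence == "LNIQFNI" else 1.0)
        assert clusters[0].representative.sequence == "LNIQFNI"

    @given(st.lists(st.text(alphabet="AR", min_size=7, max_size=12), min_size=0, max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_order_invariance(self, seqs):
        cands = [PeptideCandidate(f"p{i}", 1, len(s), s) for i, s in enumerate(seqs)]
        parts = lambda cs: sorted(
            tuple(sorted(m.key() for m in c.members)) for c in cs
        )
        forward = parts(cluster_peptides(cands))
        backward = parts(cluster_peptides(list(reversed(cands))))
        assert forward == backward

    def test_matches_naive_pairwise_oracle(self):
        import numpy as np

        rng = np.random.default_rng(42)
        letters = np.array(list(AA))
        cands = []
        for i in range(40):
            w = int(rng.integers(7, 18))
            cands.append(PeptideCandidate(f"p{i}", 1, w, "".join(rng.choice(letters, w))))
        cands.append(self._cand("EALKRFAKLLSD", "x"))
        cands.append(self._cand("DSPETYEEALKRFAKLLSD", "y"))

        parent = list(range(len(cands)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(cands)), 2):
            if similarity(cands[i].sequence, cands[j].sequence) > 0.70:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
        naive = {}
        for i in range(len(cands)):
            naive.setdefault(find(i), set()).add(cands[i].key())
        expected = sorted(tuple(sorted(g)) for g in naive.values())
        got = sorted(
            tuple(sorted(m.key() for m in c.members)) for c in cluster_peptides(cands)
        )
        assert got == expected
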