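import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from lgtscreen.homology import (
    NUCLEOTIDE_SCHEME,
    PROTEIN_SCHEME,
    AlignmentHit,
    bit_score,
    e_value,
    external_engine_adapter,
    search,
    smith_waterman,
    sw_score,
    write_hit_table,
)
from lgtscreen.seqio import Scaffold, revcomp

AA = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local(a: str, b: str, scheme=PROTEIN_SCHEME) -> float:
    """Independent Gotoh local-alignment DP, no acceleration tricks.

    A gap of length g costs gap_open + g * gap_extend.
    """
    go, ge = scheme.gap_open, scheme.gap_extend

    def sub(x, y):
        if scheme.matrix is not None:
            return float(_B62[x][y])
        return float(scheme.match if x == y else scheme.mismatch)

    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - go - ge, E[i - 1][j] - ge)
            F[i][j] = max(H[i][j - 1] - go - ge, F[i][j - 1] - ge)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_hand_computed_identity_score(self):
        # 4 x BLOSUM62(A,A) = 16
        assert sw_score("AAAA", "AAAA") == 16

    def test_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=10))
            b = "".join(rng.choice(list(AA), size=12))
            assert sw_score(a, b) == sw_score(b, a)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            assert sw_score(a, b) == pytest.approx(brute_force_local(a, b))

    def test_nucleotide_oracle(self, rng):
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 15)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(4, 15)))
            assert sw_score(a, b, NUCLEOTIDE_SCHEME) == pytest.approx(
                brute_force_local(a, b, NUCLEOTIDE_SCHEME))

    def test_extension_never_decreases_score(self, rng):
        # local alignment score is monotone under sequence extension
        for _ in range(30):
            a = "".join(rng.choice(list(AA), size=15))
            b = "".join(rng.choice(list(AA), size=15))
            s0 = sw_score(a, b)
            assert sw_score(a + "W", b) >= s0
            assert sw_score(a, "W" + b) >= s0

    def test_intervals_and_identity(self):
        raw, a_iv, b_iv, ident, alen = smith_waterman("XXMKVLWXX", "MKVLW")
        assert a_iv == (3, 7) and b_iv == (1, 5)
        assert ident == 1.0 and alen == 5

    def test_alphabet_mismatch(self):
        with pytest.raises(TypeError):
            smith_waterman("MKVLW", "MKVLW", NUCLEOTIDE_SCHEME)


class TestScoreStatistics:
    def test_bit_score_closed_form(self):
        # (0.267*40 - ln 0.041) / ln 2
        assert bit_score(40, PROTEIN_SCHEME) == pytest.approx(20.02, abs=0.01)

    def test_e_value_limits_and_linearity(self):
        assert e_value(1e6, 100, 1000) == pytest.approx(0.0, abs=1e-200)
        e1 = e_value(30, 100, 1000)
        assert e_value(30, 100, 2000) == pytest.approx(2 * e1)

    def test_bits_to_e_strictly_decreasing(self):
        es = [e_value(b, 50, 500) for b in np.linspace(1, 60, 40)]
        assert all(x > y for x, y in zip(es, es[1:]))
        assert es[0] <= 50 * 500


class TestSearch:
    @pytest.fixture()
    def db(self, rng):
        return [Scaffold(id=f"p{i}", sequence="".join(rng.choice(list(AA), size=60)))
                for i in range(20)]

    def test_self_hit_is_top(self, db):
        hits = search([db[3]], db, mode="prot-prot", bits_min=25.0)
        assert hits[0].subject_id == "p3"
        assert hits[0].percent_identity == 100.0

    def test_translated_query_strand_symmetry(self, db, rng):
        from lgtscreen.synthetic_data import reverse_translate

        cds = reverse_translate(db[5].sequence, rng, 0.4)
        fwd = search([Scaffold(id="q", sequence=cds)], db,
                     mode="translated-query", bits_min=40.0)
        rev = search([Scaffold(id="q", sequence=revcomp(cds))], db,
                     mode="translated-query", bits_min=40.0)
        assert fwd[0].subject_id == rev[0].subject_id == "p5"
        assert fwd[0].bit_score == pytest.approx(rev[0].bit_score)

    def test_matches_exhaustive_all_pairs_oracle(self, rng):
        queries = [Scaffold(id=f"q{i}", sequence="".join(rng.choice(list(AA), size=30)))
                   for i in range(15)]
        db = [Scaffold(id=f"d{i}", sequence="".join(rng.choice(list(AA), size=30)))
              for i in range(15)]
        threshold_bits = 18.0
        hits = search(queries, db, mode="prot-prot", bits_min=threshold_bits)
        got = {(h.query_id, h.subject_id) for h in hits}
        expected = set()
        for q in queries:
            for d in db:
                if bit_score(brute_force_local(q.sequence, d.sequence),
                             PROTEIN_SCHEME) >= threshold_bits:
                    expected.add((q.id, d.id))
        assert got == expected

    def test_threshold_monotonicity(self, db, rng):
        queries = [Scaffold(id=f"q{i}", sequence="".join(rng.choice(list(AA), size=40)))
                   for i in range(10)]
        loose = {(h.query_id, h.subject_id)
                 for h in search(queries, db, mode="prot-prot", bits_min=12.0)}
        tight = {(h.query_id, h.subject_id)
                 for h in search(queries, db, mode="prot-prot", bits_min=20.0)}
        assert tight <= loose

    def test_empty_database(self):
        assert search([Scaffold(id="q", sequence="MKV")], [], mode="prot-prot") == []

    def test_nt_search_finds_reverse_strand(self, rng):
        subject = Scaffold(id="s", sequence="".join(rng.choice(list("ACGT"), size=400)))
        query = Scaffold(id="q", sequence=revcomp(subject.sequence[100:300]))
        hits = search([query], [subject], mode="nt-nt", bits_min=55.0)
        assert hits and hits[0].frame == -1
        assert hits[0].s_start >= 95 and hits[0].s_end <= 305


class TestExternalAdapter:
    def test_round_trip(self, tmp_path):
        hits = [AlignmentHit("q1", "s1", "bact", 97.5, 100, 1, 100, 5, 104,
                             200.0, 80.25, 1e-20)]
        p = tmp_path / "hits.tsv"
        write_hit_table(hits, p)
        back = external_engine_adapter(p)
        assert len(back) == 1
        h = back[0]
        assert (h.query_id, h.subject_id, h.subject_db) == ("q1", "s1", "bact")
        assert h.bit_score == pytest.approx(80.25)

    def test_comments_skipped_and_column_check(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("# comment\n" + "\t".join(map(str, [
            "q", "s", 99.0, 50, 1, 50, 1, 50, 100, 45.1, 1e-9, 0])) + "\n")
        assert len(external_engine_adapter(p)) == 1
        bad = tmp_path / "bad.tsv"
        bad.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="line 1"):
            external_engine_adapter(bad)
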