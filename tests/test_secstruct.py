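"""Normalized ungapped similarity, fragment matching and the vote profile."""

import math
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepkit.errors import PepkitError
from pepkit.secstruct import (
    MatchHit,
    ReferenceDB,
    ReferenceEntry,
    load_reference_db,
    match_query,
    natural_query,
    predict_secstruct,
    similarity_score,
)
from pepkit.sequence import build_sequence

SEQUENCES = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12)


class TestSimilarityScore:
    def test_identity_normalizes_to_one(self, blosum62):
        assert similarity_score("ACDEFGH", "ACDEFGH", blosum62) == \
            pytest.approx(1.0)

    def test_hand_computed_blosum62_case(self, blosum62):
        # score_AB = 4*s(A,G) = 0; score_AA = 4*4; score_BB = 4*6
        assert similarity_score("AAAA", "GGGG", blosum62) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self, blosum62):
        with pytest.raises(PepkitError):
            similarity_score("AA", "AAA", blosum62)

    @given(a=SEQUENCES)
    @settings(max_examples=100, deadline=None)
    def test_self_score_is_exactly_one(self, a):
        assert similarity_score(a, a) == 1.0

    @given(ab=st.tuples(st.integers(1, 10), st.data()))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, ab):
        n, data = ab
        a = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY",
                              min_size=n, max_size=n))
        b = data.draw(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY",
                              min_size=n, max_size=n))
        s_ab = similarity_score(a, b)
        assert s_ab == pytest.approx(similarity_score(b, a))
        assert abs(s_ab) <= 1.0 + 1e-9


def brute_force_hits(query, db, matrix, threshold):
    """Independent oracle: exhaustive double-loop window enumeration."""
    hits = []
    for e_idx, entry in enumerate(db.entries):
        shorter_is_query = len(query) <= len(entry.sequence)
        if shorter_is_query:
            windows = [
                (0, len(query), start, start + len(query))
                for start in range(len(entry.sequence) - len(query) + 1)
            ]
        else:
            windows = [
                (start, start + len(entry.sequence), 0, len(entry.sequence))
                for start in range(len(query) - len(entry.sequence) + 1)
            ]
        for q0, q1, d0, d1 in windows:
            a, b = query[q0:q1], entry.sequence[d0:d1]
            score_ab = sum(matrix[x][y] for x, y in zip(a, b))
            score_aa = sum(matrix[x][x] for x in a)
            score_bb = sum(matrix[y][y] for y in b)
            s = score_ab / math.sqrt(score_aa * score_bb)
            if s >= threshold:
                hits.append(((q0, q1), e_idx, (d0, d1), round(s, 9)))
    return sorted(hits)


class TestMatchQuery:
    def test_identity_windows(self, blosum62):
        db = ReferenceDB([ReferenceEntry("AAAAA", "HHHHH")])
        hits = match_query("AAA", db, blosum62)
        assert len(hits) == 3
        assert all(h.s_ab == pytest.approx(1.0) for h in hits)
        assert all(h.ss_fragment == "HHH" for h in hits)

    def test_exact_entry_full_cover(self, blosum62):
        db = ReferenceDB([ReferenceEntry("ACDEFG", "HHHHEE")])
        hits = match_query("ACDEFG", db, blosum62, threshold=0.99)
        assert any(h.query_span == (0, 6) and h.s_ab == pytest.approx(1.0)
                   for h in hits)

    def test_impossible_threshold_yields_no_hits(self, blosum62):
        db = ReferenceDB([ReferenceEntry("WWWWW", "EEEEE")])
        assert match_query("AAAAA", db, blosum62, threshold=1.0) == []

    def test_empty_db(self, blosum62):
        assert match_query("AAA", ReferenceDB([]), blosum62) == []

    def test_monotone_in_threshold(self, blosum62, reference_db):
        query = reference_db.entries[0].sequence[:8]
        counts = [
            len(match_query(query, reference_db, blosum62, t))
            for t in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("query", ["AAA", "GLVKT", "WYWYWYWYWYWY"])
    def test_brute_force_oracle_equivalence(self, blosum62, query,
                                            reference_db):
        small = ReferenceDB(reference_db.entries[:10])
        got = sorted(
            (h.query_span, h.db_entry, h.db_span, round(h.s_ab, 9))
            for h in match_query(query, small, blosum62, 0.55)
        )
        assert got == brute_force_hits(query, small, blosum62, 0.55)


class TestPredict:
    def test_self_retrieval_single_entry(self, blosum62):
        db = ReferenceDB([ReferenceEntry("ACDEFGH", "HHHHHHH")])
        got = predict_secstruct("ACDEFGH", db, blosum62, 0.65)
        assert got.categories == "HHHHHHH"

    def test_no_hits_gives_all_unassigned(self, blosum62):
        db = ReferenceDB([ReferenceEntry("WWWWWWW", "EEEEEEE")])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = predict_secstruct("AAA", db, blosum62, 0.99)
        assert got.categories == "---"

    def test_self_retrieval_whole_fixture_db(self, blosum62, reference_db):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for entry in reference_db.entries:
                got = predict_secstruct(entry.sequence, reference_db,
                                        blosum62, 0.65)
                assert got.categories == entry.ss

    def test_empty_query_rejected(self, blosum62, reference_db):
        with pytest.raises(PepkitError):
            predict_secstruct("", reference_db, blosum62)

    def test_length_warning_outside_recommended_range(self, blosum62):
        db = ReferenceDB([ReferenceEntry("AAAA", "HHHH")])
        with pytest.warns(UserWarning, match="recommended"):
            predict_secstruct("AAAA", db, blosum62)

    def test_nnaa_query_maps_to_analogs(self, library):
        seq = build_sequence("N-Iva-F-D-I-meT-N-A-L-W-Y-Aib-K", library)
        mapped = natural_query(seq)
        assert len(mapped) == 13
        assert mapped[1] == "A" and mapped[5] == "T" and mapped[11] == "A"

    def test_nnaa_peptide_predicted_helical_on_helix_db(self, library,
                                                        blosum62):
        # a helix-rich reference containing the mapped sequence context
        seq = build_sequence("N-Iva-F-D-I-meT-N-A-L-W-Y-Aib-K", library)
        mapped = natural_query(seq)
        db = ReferenceDB([
            ReferenceEntry(mapped, "H" * len(mapped)),
            ReferenceEntry("KELAKEGLAKLKA", "HHHHHHHHHHHHH"),
        ])
        got = predict_secstruct(seq, db, blosum62, 0.65)
        assert got.categories.count("H") > len(mapped) / 2


class TestLoadReferenceDB:
    def test_valid_records(self):
        db = load_reference_db("AAAAA\tHHHHH\nGGGGG\t-----\nWLKVA\tEEEE-\n")
        assert len(db) == 3
        assert db.max_len == 5

    def test_duplicate_keeps_first_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            db = load_reference_db("AAAAA\tHHHHH\nAAAAA\t-----\n")
        assert len(db) == 1
        assert db.entries[0].ss == "HHHHH"

    def test_length_mismatch_names_record(self):
        with pytest.raises(PepkitError, match="record 1"):
            load_reference_db("AAAAA\tHHHHH\nGGG\tHHHH\n")

    def test_fasta_dialect(self):
        db = load_reference_db(">a ss=HHHHH\nAAAAA\n>b ss=EEE--\nWLKVA\n")
        assert len(db) == 2
        assert db.entries[1].ss == "EEE--"
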