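"""Inclusion rules: pairwise alignment scores, thresholds, trimming,
orthology clustering, and reference coordinate mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import codonsel as cs
from codonsel.curation import (
    EXCL_IDENTITY,
    EXCL_NONE,
    EXCL_SIMILARITY,
    CurationRecord,
    _scoring_matrix,
    apply_inclusion_filter,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent affine-gap oracle (Gotoh), with a brute-force check of itself


def gotoh_score(a: str, b: str, matrix, open_=10.0, ext=0.5) -> float:
    """Plain dynamic-programming global alignment score with affine end
    gaps penalized; first gap residue costs `open_`, later ones `ext`."""
    neg = -1e30
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (moving along a)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_ - ext * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -open_ - ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - ext, Iy[i - 1, j] - open_)
            Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - ext, Ix[i, j - 1] - open_)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def enumerate_score(a: str, b: str, matrix, open_=10.0, ext=0.5) -> float:
    """Exhaustive recursion over all global alignments (tiny inputs only)."""

    best = [-1e30]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            pen = ext if last == "x" else open_
            rec(i + 1, j, score - pen, "x")
        if j < len(b):
            pen = ext if last == "y" else open_
            rec(i, j + 1, score - pen, "y")

    rec(0, 0, 0.0, "m")
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences_score_100(self, rng):
        seq = "".join(rng.choice(list(AAS), size=100))
        rec = cs.ProteinRecord("a", seq)
        res = cs.global_align(rec, cs.ProteinRecord("b", seq))
        assert res.percent_identity == 100.0
        assert res.percent_similarity == 100.0

    def test_two_of_three_identical(self):
        res = cs.global_align(cs.ProteinRecord("q", "ACD"), cs.ProteinRecord("r", "ACE"))
        assert res.percent_identity == pytest.approx(200 / 3, abs=0.05)
        # D vs E is a positively scoring (similar) pair under BLOSUM62
        assert res.percent_similarity == pytest.approx(100.0)

    def test_oracle_agrees_with_itself_at_tiny_size(self):
        matrix = _scoring_matrix(cs.ScoringConfig())
        rng = np.random.default_rng(99)
        for _ in range(6):
            a = "".join(rng.choice(list(AAS), size=4))
            b = "".join(rng.choice(list(AAS), size=5))
            assert gotoh_score(a, b, matrix) == pytest.approx(enumerate_score(a, b, matrix))

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_dp_oracle_at_length_12(self, seed):
        matrix = _scoring_matrix(cs.ScoringConfig())
        rng = np.random.default_rng(3500 + seed)
        a = "".join(rng.choice(list(AAS), size=12))
        b = "".join(rng.choice(list(AAS), size=12))
        res = cs.global_align(cs.ProteinRecord("a", a), cs.ProteinRecord("b", b))
        assert res.score == pytest.approx(gotoh_score(a, b, matrix))

    def test_fixed_twelve_residue_pair_oracle(self):
        a, b = "MKTAYIAKQRQW", "MKTAYIAKQRQI"
        matrix = _scoring_matrix(cs.ScoringConfig())
        res = cs.global_align(cs.ProteinRecord("a", a), cs.ProteinRecord("b", b))
        assert res.score == pytest.approx(gotoh_score(a, b, matrix))

    def test_degapping_recovers_inputs(self, rng):
        a = "".join(rng.choice(list(AAS), size=30))
        b = a[:10] + a[14:]  # force an internal gap
        res = cs.global_align(cs.ProteinRecord("a", a), cs.ProteinRecord("b", b))
        assert res.aligned_query.replace("-", "") == a
        assert res.aligned_reference.replace("-", "") == b
        assert len(res.aligned_query) == len(res.aligned_reference)

    def test_identity_similarity_are_symmetric(self, rng):
        a = "".join(rng.choice(list(AAS), size=40))
        b = "".join(rng.choice(list(AAS), size=37))
        r1 = cs.global_align(cs.ProteinRecord("a", a), cs.ProteinRecord("b", b))
        r2 = cs.global_align(cs.ProteinRecord("b", b), cs.ProteinRecord("a", a))
        assert r1.percent_identity == pytest.approx(r2.percent_identity)
        assert r1.percent_similarity == pytest.approx(r2.percent_similarity)

    def test_identity_never_exceeds_similarity_without_x(self, rng):
        a = "".join(rng.choice(list(AAS), size=25))
        b = "".join(rng.choice(list(AAS), size=25))
        r = cs.global_align(cs.ProteinRecord("a", a), cs.ProteinRecord("b", b))
        assert 0 <= r.percent_identity <= r.percent_similarity <= 100

    def test_x_scores_zero_and_is_never_identical(self):
        r = cs.global_align(cs.ProteinRecord("a", "MAXAM"), cs.ProteinRecord("b", "MAXAM"))
        assert r.percent_identity == pytest.approx(80.0)  # the X column does not count

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'J'"):
            cs.ProteinRecord("bad", "MAJ")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs.ProteinRecord("bad", "")


class TestInclusionFilter:
    def _rec(self, ident, sim):
        return CurationRecord("t", ident, sim, included=False)

    def test_boundary_is_inclusive(self):
        out = apply_inclusion_filter([self._rec(50.0, 60.0)])
        assert out[0].included and out[0].exclusion_reason == EXCL_NONE

    def test_identity_checked_first(self):
        out = apply_inclusion_filter([self._rec(49.9, 95.0), self._rec(49.0, 59.0)])
        assert not out[0].included and out[0].exclusion_reason == EXCL_IDENTITY
        assert out[1].exclusion_reason == EXCL_IDENTITY

    def test_similarity_violation(self):
        out = apply_inclusion_filter([self._rec(80.0, 59.0)])
        assert not out[0].included and out[0].exclusion_reason == EXCL_SIMILARITY

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_inclusion_filter([self._rec(50, 60)], identity_min=-1)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            max_size=8,
        )
    )
    def test_idempotent_and_order_independent(self, vals):
        recs = [CurationRecord(f"t{i}", a, b, False) for i, (a, b) in enumerate(vals)]
        once = apply_inclusion_filter(recs)
        twice = apply_inclusion_filter(once)
        assert once == twice
        rev = apply_inclusion_filter(recs[::-1])
        assert rev == once[::-1]


class TestTrimming:
    def test_artificial_extension_removed(self, rng):
        ref = "M" + "".join(rng.choice(list(AAS), size=59))
        ext = "".join(rng.choice(list(AAS), size=20))
        cds = "".join("GCT" for _ in range(80)) + "TAA"
        query = cs.ProteinRecord("q", ext + ref)
        trimmed, offset = cs.trim_to_canonical_start(query, cs.ProteinRecord("r", ref))
        assert offset == 20
        assert trimmed.sequence == ref

    def test_no_extension_is_noop(self, rng):
        ref = "M" + "".join(rng.choice(list(AAS), size=40))
        q = cs.ProteinRecord("q", ref)
        trimmed, offset = cs.trim_to_canonical_start(q, cs.ProteinRecord("r", ref))
        assert offset == 0 and trimmed.sequence == ref

    def test_seven_residue_extension_with_substitutions(self):
        ref = "MKTAYIAKQRQWISFNDAGHKLMERTVVWY"
        q = list("PPPPPPP" + ref)
        q[10], q[17], q[25] = "A", "G", "S"  # three internal substitutions
        query = cs.ProteinRecord("q", "".join(q))
        trimmed, offset = cs.trim_to_canonical_start(query, cs.ProteinRecord("r", ref))
        assert offset == 7
        assert trimmed.sequence == "".join(q)[7:]

    def test_cds_trimmed_in_register(self):
        ref = "MKTAYIAKQR"
        ext = "GG"
        prot = ext + ref
        cds = "".join({"G": "GGT", "M": "ATG", "K": "AAA", "T": "ACT", "A": "GCT",
                       "Y": "TAT", "I": "ATT", "Q": "CAA", "R": "CGT"}[a] for a in prot)
        query = cs.ProteinRecord("q", prot, cds)
        trimmed, offset = cs.trim_to_canonical_start(query, cs.ProteinRecord("r", ref))
        assert offset == 2
        assert trimmed.source_cds == cds[6:]

    def test_idempotent_on_own_output(self, rng):
        ref = "M" + "".join(rng.choice(list(AAS), size=50))
        query = cs.ProteinRecord("q", "WWWWW" + ref)
        t1, o1 = cs.trim_to_canonical_start(query, cs.ProteinRecord("r", ref))
        t2, o2 = cs.trim_to_canonical_start(t1, cs.ProteinRecord("r", ref))
        assert o1 == 5 and o2 == 0 and t2.sequence == t1.sequence

    def test_non_met_start_warns_but_keeps(self, rng):
        ref = "M" + "".join(rng.choice(list(AAS), size=30))
        query = cs.ProteinRecord("q", "PP" + "K" + ref[1:])
        with pytest.warns(UserWarning, match="not Met"):
            trimmed, offset = cs.trim_to_canonical_start(query, cs.ProteinRecord("r", ref))
        assert offset == 2 and trimmed.sequence.startswith("K")


class TestOrthology:
    def _mutate(self, seq, positions, rng):
        s = list(seq)
        for p in positions:
            choices = [a for a in AAS if a != s[p]]
            s[p] = str(rng.choice(choices))
        return "".join(s)

    def test_near_identical_member_wins(self, rng):
        base = "".join(rng.choice(list(AAS), size=60))
        famA = self._mutate(base, range(0, 12), rng)
        famB = self._mutate(base, range(30, 42), rng)
        panel = [
            ("famA", cs.ProteinRecord("pa1", famA)),
            ("famA", cs.ProteinRecord("pa2", self._mutate(famA, [55], rng))),
            ("famB", cs.ProteinRecord("pb1", famB)),
            ("famB", cs.ProteinRecord("pb2", self._mutate(famB, [56], rng))),
        ]
        query = cs.ProteinRecord("q", self._mutate(famA, [57], rng))
        assert cs.assign_ortholog_group(query, panel) == "famA"

    def test_symmetric_query_is_ambiguous(self, rng):
        base = "".join(rng.choice(list(AAS), size=40))
        famA = self._mutate(base, range(0, 8), rng)
        famB = self._mutate(base, range(20, 28), rng)
        panel = [
            ("A", cs.ProteinRecord("a1", famA)),
            ("A", cs.ProteinRecord("a2", famA)),
            ("B", cs.ProteinRecord("b1", famB)),
            ("B", cs.ProteinRecord("b2", famB)),
        ]
        # the query sits exactly between the two families
        assert cs.assign_ortholog_group(cs.ProteinRecord("q", base), panel) is None

    def test_planted_query_in_ten_member_panel(self, rng):
        base = "".join(rng.choice(list(AAS), size=80))
        families = {}
        panel = []
        for fi, fam in enumerate(["famA", "famC", "famD", "famB", "famE"]):
            fam_seq = self._mutate(base, range(fi * 14, fi * 14 + 10), rng)
            families[fam] = fam_seq
            for m in range(2):
                panel.append(
                    (fam, cs.ProteinRecord(f"{fam}_m{m}", self._mutate(fam_seq, [79 - m], rng)))
                )
        query = cs.ProteinRecord("q", self._mutate(families["famD"], [70], rng))
        assert cs.assign_ortholog_group(query, panel) == "famD"

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            cs.assign_ortholog_group(
                cs.ProteinRecord("q", "MA"), [("A", cs.ProteinRecord("p", "MA"))]
            )


class TestReferenceMap:
    def test_gapless_reference_gives_identity_map(self):
        seqs = ["ATGGCTGCT" * 5, "ATGGCAGCG" * 5]
        aln = cs.CodonAlignment(["hs", "mm"], seqs, reference="hs")
        m = cs.map_alignment_to_reference(aln)
        assert m.reference_length == 15
        assert m.column_to_ref == {i: i + 1 for i in range(15)}

    def test_reference_gap_columns_unmapped(self):
        aln = cs.CodonAlignment(
            ["hs", "mm"], ["ATG---GCT", "ATGAAAGCT"], reference="hs"
        )
        m = cs.map_alignment_to_reference(aln)
        assert m.column_to_ref == {0: 1, 2: 2}
        assert m.reference_length == 2

    def test_reference_only_alignment(self):
        aln = cs.CodonAlignment(["hs"], ["ATGGCTAGA"], reference="hs")
        m = cs.map_alignment_to_reference(aln)
        assert m.reference_length == 3

    def test_all_gap_reference_rejected(self):
        aln = cs.CodonAlignment(["hs", "mm"], ["---------", "ATGAAAGCT"], reference="hs")
        with pytest.raises(ValueError, match="all gaps"):
            cs.map_alignment_to_reference(aln)

    def test_map_inverse_is_identity(self):
        aln = cs.CodonAlignment(
            ["hs", "mm"], ["ATG---GCTTGG", "ATGAAAGCTTGG"], reference="hs"
        )
        m = cs.map_alignment_to_reference(aln)
        for col, ref in m.column_to_ref.items():
            assert m.ref_to_column[ref] == col
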