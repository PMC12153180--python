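import math
import random

import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from divmine import io as dio
from divmine.pairalign import (
    ScoringScheme,
    Thresholds,
    bit_score,
    compute_evalue,
    filter_hits,
    hits_to_table,
    local_align,
    protein_scheme,
    search_all,
)
from divmine.records import SequenceRecord

from _oracles import brute_force_local_score
from conftest import make_records, random_protein


def reduced_scheme():
    """Small-alphabet scheme for exhaustive-enumeration checks."""
    mat = substitution_matrices.Array(alphabet="ACDE", dims=2)
    scores = {
        ("A", "A"): 4, ("C", "C"): 5, ("D", "D"): 4, ("E", "E"): 3,
        ("A", "C"): -2, ("A", "D"): -1, ("A", "E"): -2,
        ("C", "D"): -3, ("C", "E"): -3, ("D", "E"): 1,
    }
    for (a, b), v in scores.items():
        mat[a, b] = v
        mat[b, a] = v
    return ScoringScheme(matrix=mat, gap_open=3, gap_extend=1, lam=0.3, K=0.1)


def oracle_matrix(scheme):
    alpha = scheme.matrix.alphabet
    return {(a, b): float(scheme.matrix[a, b]) for a in alpha for b in alpha}


def test_identical_sequences_full_length_hit(rng):
    seq = random_protein(rng, 50)
    a = SequenceRecord("a", seq, source="seed")
    b = SequenceRecord("b", seq)
    hit = local_align(a, b)
    assert hit.identity_pct == 100.0
    assert hit.q_interval == (1, 50) and hit.s_interval == (1, 50)
    assert hit.mismatch == 0 and hit.gapopen == 0


def test_no_positive_scoring_pair_returns_none():
    scheme = reduced_scheme()
    a = SequenceRecord("a", "AAAA")
    b = SequenceRecord("b", "CCCC")  # A:C scores -2 everywhere
    assert local_align(a, b, scheme) is None


def test_alphabet_mismatch_is_an_error():
    a = SequenceRecord("a", "MKT", alphabet="aa")
    b = SequenceRecord("b", "ACGT", alphabet="nt")
    with pytest.raises(ValueError, match="alphabet"):
        local_align(a, b)


def test_local_align_matches_exhaustive_enumeration():
    """Raw local-alignment scores equal brute-force enumeration of every
    affine-gap alignment for short reduced-alphabet sequences."""
    scheme = reduced_scheme()
    mat = oracle_matrix(scheme)
    rng = random.Random(7)
    checked_hits = 0
    for _ in range(150):
        q = "".join(rng.choice("ACDE") for _ in range(rng.randint(1, 8)))
        s = "".join(rng.choice("ACDE") for _ in range(rng.randint(1, 8)))
        expected = brute_force_local_score(q, s, mat, scheme.gap_open, scheme.gap_extend)
        hit = local_align(SequenceRecord("q", q), SequenceRecord("s", s), scheme)
        if expected <= 0:
            assert hit is None
        else:
            assert hit is not None and hit.score == pytest.approx(expected)
            checked_hits += 1
    assert checked_hits > 50  # the sample genuinely exercised alignments


def test_score_symmetry(rng):
    """Scores are direction-symmetric under a symmetric matrix; identity is
    too whenever the optimum is unique (checked on strongly related pairs,
    where co-optimal tracebacks do not arise)."""
    from conftest import mutate

    scheme = protein_scheme()
    for _ in range(5):
        a = SequenceRecord("a", random_protein(rng, 40))
        b = SequenceRecord("b", random_protein(rng, 45))
        ha = local_align(a, b, scheme)
        hb = local_align(b, a, scheme)
        assert (ha is None) == (hb is None)
        if ha is not None:
            assert ha.score == pytest.approx(hb.score)
    for _ in range(5):
        seq = random_protein(rng, 60)
        a = SequenceRecord("a", seq)
        b = SequenceRecord("b", mutate(rng, seq, 0.1))
        ha, hb = local_align(a, b, scheme), local_align(b, a, scheme)
        assert ha.identity_pct == pytest.approx(hb.identity_pct)


class TestEvalue:
    def test_closed_form(self):
        got = compute_evalue(50.0, 300, 10**6, protein_scheme())
        expected = 0.041 * 300 * 10**6 * math.exp(-0.267 * 50.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_database_size(self):
        scheme = protein_scheme()
        assert compute_evalue(40, 100, 2 * 10**5, scheme) == pytest.approx(
            2 * compute_evalue(40, 100, 10**5, scheme)
        )

    def test_strictly_decreasing_in_score(self):
        scheme = protein_scheme()
        evals = [compute_evalue(s, 100, 10**5, scheme) for s in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(evals, evals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_evalue(10, 0, 100, protein_scheme())
        with pytest.raises(ValueError):
            compute_evalue(-1, 100, 100, protein_scheme())

    def test_retained_hits_have_score_above_evalue_threshold(self, rng):
        """E <= 1e-5 implies the raw score clears the closed-form bound."""
        scheme = protein_scheme()
        seq = random_protein(rng, 80)
        a, b = SequenceRecord("a", seq), SequenceRecord("b", seq)
        hit = local_align(a, b, scheme, db_residues=10**6)
        assert hit.evalue <= 1e-5
        s_min = math.log(scheme.K * 80 * 10**6 / 1e-5) / scheme.lam
        assert hit.score > s_min


def make_hit_row(qseqid="q", sseqid="s", pident=50.0, evalue=1e-10,
                 qstart=1, qend=100, sstart=1, send=100, qlen=100, slen=100):
    return {
        "qseqid": qseqid, "sseqid": sseqid, "pident": pident,
        "length": qend - qstart + 1, "mismatch": 0, "gapopen": 0,
        "qstart": qstart, "qend": qend, "sstart": sstart, "send": send,
        "evalue": evalue, "bitscore": 100.0, "qlen": qlen, "slen": slen,
    }


class TestFilterHits:
    def test_identity_threshold_edge(self):
        hits = pd.DataFrame([make_hit_row(pident=29.99), make_hit_row(pident=30.0)])
        kept = filter_hits(hits)
        assert list(kept["pident"]) == [30.0]

    def test_mutual_means_both_sides(self):
        # 80% on query but 79% on subject -> removed
        row = make_hit_row(qstart=1, qend=80, sstart=1, send=79, qlen=100, slen=100)
        assert filter_hits(pd.DataFrame([row])).empty
        row = make_hit_row(qstart=1, qend=80, sstart=1, send=80)
        assert len(filter_hits(pd.DataFrame([row]))) == 1

    def test_six_row_hand_fixture(self):
        rows = [
            make_hit_row(qseqid="keep1"),                            # passes all
            make_hit_row(qseqid="badE", evalue=2e-5),                # E too big
            make_hit_row(qseqid="badI", pident=10.0),                # identity low
            make_hit_row(qseqid="badQ", qend=70),                    # query cov 70%
            make_hit_row(qseqid="badS", send=60),                    # subject cov 60%
            make_hit_row(qseqid="keep2", pident=30.0, evalue=1e-5),  # edges inclusive
        ]
        kept = filter_hits(pd.DataFrame(rows))
        assert list(kept["qseqid"]) == ["keep1", "keep2"]

    def test_idempotent_and_order_preserving(self):
        rows = [make_hit_row(qseqid=f"q{i}", pident=25 + 5 * i) for i in range(6)]
        once = filter_hits(pd.DataFrame(rows))
        twice = filter_hits(once)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once["pident"]) == sorted(once["pident"])  # original order kept

    def test_missing_lengths_error(self):
        hits = pd.DataFrame([make_hit_row()]).drop(columns=["qlen"])
        with pytest.raises(ValueError, match="qlen"):
            filter_hits(hits)


class TestSearchAll:
    def test_self_hit_excluded(self, rng):
        rec = make_records([random_protein(rng, 60)], prefix="only")
        assert search_all(rec, rec).empty

    def test_empty_database(self, rng):
        rec = make_records([random_protein(rng, 60)])
        assert search_all(rec, []).empty

    def test_planted_identical_pair(self, rng):
        seq = random_protein(rng, 80)
        records = make_records([seq] + [random_protein(rng, 80) for _ in range(3)])
        twin = SequenceRecord("twin", seq)
        hits = search_all([twin], records)
        assert list(hits["sseqid"]) == ["s1"]
        assert hits.iloc[0]["pident"] == 100.0

    def test_matches_looped_local_align_plus_filter(self, rng):
        """search_all equals its compositional definition on a 10x10 fixture."""
        from conftest import mutate

        bases = [random_protein(rng, rng.randint(40, 60)) for _ in range(4)]
        seqs = bases + [mutate(rng, b, 0.15) for b in bases] + [
            random_protein(rng, 50) for _ in range(2)
        ]
        records = make_records(seqs)
        scheme, th = protein_scheme(), Thresholds()
        got = search_all(records, records, scheme, th, backend="builtin")
        db_residues = sum(r.length for r in records)
        manual = []
        for q in records:
            for s in records:
                if q.id == s.id:
                    continue
                hit = local_align(q, s, scheme, db_residues=db_residues)
                if hit is not None:
                    manual.append(hit)
        expected = filter_hits(
            hits_to_table(manual), th.max_evalue, th.min_identity_pct, th.min_mutual_coverage
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected)

    def test_blast_backend_finds_planted_pair(self, rng):
        seq = random_protein(rng, 80)
        records = make_records([seq, seq[:79] + "W"] + [random_protein(rng, 80) for _ in range(3)])
        hits = search_all(records, records, backend="blast")
        pairs = set(map(tuple, hits[["qseqid", "sseqid"]].values))
        assert ("s1", "s2") in pairs and ("s2", "s1") in pairs
        assert not any(q == s for q, s in pairs)
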