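import random

import numpy as np
import pandas as pd
import pytest

from divmine.annotate import (
    assign_cluster_taxonomy,
    best_reference_similarity,
    classify_viral,
    cross_domain_baseline,
    detect_paralogy,
    label_divergent,
    length_concordance,
    merge_lineages,
    parse_lineage,
)
from divmine.records import SimilarityLabel

from test_pairalign import make_hit_row


class TestBestReferenceSimilarity:
    def test_identical_full_length_pair_scores_100(self):
        hits = pd.DataFrame([make_hit_row(pident=100.0)])
        labels = best_reference_similarity(hits)
        assert labels["q"].best_similarity == pytest.approx(100.0)

    def test_half_coverage_half_identity(self):
        # identity 50%, alignment covering half the shorter sequence -> 25
        row = make_hit_row(pident=50.0, qstart=1, qend=50, sstart=1, send=50,
                           qlen=100, slen=120)
        labels = best_reference_similarity(pd.DataFrame([row]))
        assert labels["q"].best_similarity == pytest.approx(25.0)
        assert labels["q"].best_identity == pytest.approx(50.0)

    def test_similarity_never_exceeds_identity(self):
        rng = random.Random(3)
        rows = []
        for i in range(30):
            qlen = rng.randint(50, 150)
            qend = rng.randint(10, qlen)
            rows.append(make_hit_row(qseqid=f"q{i}", pident=rng.uniform(20, 100),
                                     qstart=1, qend=qend, qlen=qlen, slen=rng.randint(40, 150)))
        labels = best_reference_similarity(pd.DataFrame(rows))
        for lab in labels.values():
            assert lab.best_similarity <= lab.best_identity + 1e-9 <= 100 + 1e-9

    def test_maximum_over_competing_hits_matches_exhaustive_scan(self):
        rng = random.Random(5)
        rows = []
        for _ in range(5):
            qlen, slen = rng.randint(80, 120), rng.randint(80, 120)
            span = rng.randint(30, min(qlen, slen))
            rows.append(make_hit_row(qseqid="q", sseqid=f"r{rng.random()}",
                                     pident=rng.uniform(20, 95), qstart=1, qend=span,
                                     sstart=1, send=span, qlen=qlen, slen=slen))
        hits = pd.DataFrame(rows)
        labels = best_reference_similarity(hits)
        sims = hits["pident"] * (hits["length"] / hits[["qlen", "slen"]].min(axis=1)).clip(upper=1)
        assert labels["q"].best_similarity == pytest.approx(sims.max())

    def test_no_hit_gives_undefined(self):
        labels = best_reference_similarity(pd.DataFrame(), sequence_ids=["lonely"])
        assert labels["lonely"].best_similarity is None


class TestCrossDomainBaseline:
    def test_all_identical_cross_pairs(self):
        dom = {"a1": "Archaea", "b1": "Bacteria"}
        hits = pd.DataFrame([make_hit_row(qseqid="a1", sseqid="b1", pident=100.0)])
        assert cross_domain_baseline(dom, hits) == pytest.approx(100.0)

    def test_symmetric_two_sequence_family(self):
        dom = {"a1": "Archaea", "b1": "Bacteria"}
        hits = pd.DataFrame([
            make_hit_row(qseqid="a1", sseqid="b1", pident=34.9),
            make_hit_row(qseqid="b1", sseqid="a1", pident=34.9),
        ])
        assert cross_domain_baseline(dom, hits) == pytest.approx(34.9)

    def test_known_pairwise_identities_hand_mean(self):
        dom = {"a1": "Archaea", "a2": "Archaea", "b1": "Bacteria", "b2": "Bacteria",
               "e1": "Eukaryota"}
        rows = [
            make_hit_row(qseqid="a1", sseqid="b1", pident=40.0),
            make_hit_row(qseqid="a1", sseqid="b2", pident=30.0),
            make_hit_row(qseqid="a2", sseqid="b1", pident=20.0),
            make_hit_row(qseqid="b1", sseqid="a1", pident=40.0),
            make_hit_row(qseqid="b2", sseqid="a1", pident=30.0),
            make_hit_row(qseqid="b1", sseqid="a2", pident=20.0),
            make_hit_row(qseqid="a1", sseqid="e1", pident=99.0),  # not Archaea<->Bacteria
        ]
        got = cross_domain_baseline(dom, pd.DataFrame(rows))
        # closest cross-Domain identities: a1->40, a2->20, b1->40, b2->30
        assert got == pytest.approx((40 + 20 + 40 + 30) / 4)

    def test_single_domain_family_is_error(self):
        dom = {"a1": "Archaea", "a2": "Archaea"}
        hits = pd.DataFrame([make_hit_row(qseqid="a1", sseqid="a2")])
        with pytest.raises(ValueError, match="cross-Domain"):
            cross_domain_baseline(dom, hits)


class TestLabelDivergent:
    def test_threshold_edge_is_strict(self):
        labels = {"x": SimilarityLabel("x", 30.0, 34.9)}
        label_divergent(labels, 34.9)
        assert labels["x"].divergent is False

    def test_no_reference_hit_is_divergent(self):
        labels = {"x": SimilarityLabel("x")}
        label_divergent(labels, 34.9)
        assert labels["x"].divergent is True

    def test_divergent_fraction_matches_manual_count(self):
        rng = random.Random(10)
        labels = {}
        for i in range(100):
            ident = rng.uniform(5, 95) if rng.random() < 0.9 else None
            labels[f"s{i}"] = SimilarityLabel(f"s{i}", ident, ident)
        label_divergent(labels, 34.9)
        manual = sum(1 for l in labels.values() if l.best_identity is None or l.best_identity < 34.9)
        assert sum(l.divergent for l in labels.values()) == manual

    def test_extreme_thresholds(self):
        labels = {
            "hit": SimilarityLabel("hit", 50.0, 50.0),
            "nohit": SimilarityLabel("nohit"),
        }
        label_divergent(labels, 0.001)
        assert labels["hit"].divergent is False and labels["nohit"].divergent is True
        label_divergent(labels, 99.999)
        assert labels["hit"].divergent is True


class TestTaxonomy:
    def test_merge_keeps_deeper_lineage(self):
        v1 = parse_lineage("Bacteria")
        v2 = parse_lineage("Bacteria;Actinobacteria;Actinomycetes")
        assert merge_lineages(v1, v2) == v2
        assert merge_lineages(v2, v1) == v2

    def test_merge_tie_keeps_first(self):
        v1 = parse_lineage("Bacteria;Firmicutes")
        v2 = parse_lineage("Bacteria;Actinobacteria")
        assert merge_lineages(v1, v2) == v1

    def test_merge_with_empty(self):
        v2 = parse_lineage("Archaea;Euryarchaeota")
        assert merge_lineages((), v2) == v2

    def test_lineage_truncates_at_first_gap(self):
        assert parse_lineage("Bacteria;;Actinomycetes") == ("Bacteria",)

    def test_unanimous_species(self):
        lin = parse_lineage("Bacteria;P;C;O;F;G;S")
        assert assign_cluster_taxonomy([lin] * 5) == ("species", "S")

    def test_majority_at_genus_level(self):
        # 6/10 genus G (all family F); 4/10 spread over other families
        g = parse_lineage("Bacteria;P;C;O;F;G")
        others = [parse_lineage(f"Bacteria;P;C;O;F{i}") for i in range(4)]
        got = assign_cluster_taxonomy([g] * 6 + others)
        assert got == ("genus", "G")
        # recount: the returned value really occurs in > 50% of members
        members = [g] * 6 + others
        count = sum(1 for l in members if len(l) > 5 and l[5] == "G")
        assert count * 2 > len(members)

    def test_even_split_is_unannotated(self):
        a = parse_lineage("Bacteria;P1;C1")
        b = parse_lineage("Archaea;P2;C2")
        assert assign_cluster_taxonomy([a] * 5 + [b] * 5) is None

    def test_empty_lineages_count_in_denominator(self):
        lin = parse_lineage("Bacteria")
        assert assign_cluster_taxonomy([lin] * 5 + [()] * 5) is None
        assert assign_cluster_taxonomy([lin] * 6 + [()] * 4) == ("domain", "Bacteria")


def viral_row(qid, pident, slen, evalue=1e-10, qcov=1.0, qlen=100):
    qend = int(qcov * qlen)
    return make_hit_row(qseqid=qid, pident=pident, evalue=evalue,
                        qstart=1, qend=qend, sstart=1, send=qend,
                        qlen=qlen, slen=slen)


class TestClassifyViral:
    def test_two_tiers_and_contig_filter(self):
        hits = pd.DataFrame([
            viral_row("direct", 96.0, 8000),
            viral_row("homolog", 70.0, 8000),
            viral_row("short_contig", 99.0, 4000),
            viral_row("low_cov", 99.0, 8000, qcov=0.5),
        ])
        ids = ["direct", "homolog", "short_contig", "low_cov", "nohit"]
        status = classify_viral(ids, hits)
        assert status["direct"].status == "direct"
        assert status["homolog"].status == "homologous"
        assert status["short_contig"].status == "none"
        assert status["low_cov"].status == "none"
        assert status["nohit"].status == "none"
        # statuses partition the input set
        assert sorted(status) == sorted(ids)

    def test_direct_implies_high_identity(self):
        hits = pd.DataFrame([viral_row("x", 95.0, 10000)])
        status = classify_viral(["x"], hits)
        assert status["x"].status == "direct" and status["x"].best_nt_identity >= 95


def genome_row(qid, genome, contig, sstart, send, pident=95.0, cov=1.0, qlen=100):
    row = make_hit_row(qseqid=qid, pident=pident, qstart=1, qend=int(cov * qlen),
                       sstart=sstart, send=send, qlen=qlen, slen=10**5)
    row["genome"], row["contig"] = genome, contig
    return row


class TestDetectParalogy:
    def test_ten_genomes_distinct_contigs_is_a_pair(self):
        rows = []
        for g in range(10):
            rows.append(genome_row("a1", f"g{g}", "c1", 100, 400))
            rows.append(genome_row("b1", f"g{g}", "c2", 100, 400))
        call = detect_paralogy(["a1"], ["b1"], pd.DataFrame(rows))
        assert call.supporting_genomes == 10 and call.is_paralogy_pair

    def test_same_locus_overlap_excluded(self):
        rows = []
        for g in range(12):
            rows.append(genome_row("a1", f"g{g}", "c1", 100, 400))
            rows.append(genome_row("b1", f"g{g}", "c1", 300, 600))  # shares bases
        call = detect_paralogy(["a1"], ["b1"], pd.DataFrame(rows))
        assert call.supporting_genomes == 0 and not call.is_paralogy_pair

    def test_mixed_fixture_matches_exhaustive_evaluation(self):
        rng = random.Random(21)
        rows, truth = [], 0
        for g in range(15):
            kind = rng.choice(["diff_contig", "same_overlap", "same_separate",
                               "weak_identity", "a_only"])
            if kind == "diff_contig":
                rows += [genome_row("a1", f"g{g}", "c1", 1, 300),
                         genome_row("b1", f"g{g}", "c2", 1, 300)]
                truth += 1
            elif kind == "same_overlap":
                rows += [genome_row("a1", f"g{g}", "c1", 1, 300),
                         genome_row("b1", f"g{g}", "c1", 300, 600)]
            elif kind == "same_separate":
                rows += [genome_row("a1", f"g{g}", "c1", 1, 300),
                         genome_row("b1", f"g{g}", "c1", 301, 600)]
                truth += 1
            elif kind == "weak_identity":
                rows += [genome_row("a1", f"g{g}", "c1", 1, 300, pident=80.0),
                         genome_row("b1", f"g{g}", "c2", 1, 300)]
            else:
                rows += [genome_row("a1", f"g{g}", "c1", 1, 300)]
        call = detect_paralogy(["a1"], ["b1"], pd.DataFrame(rows))
        assert call.supporting_genomes == truth
        assert call.is_paralogy_pair == (truth >= 10)


class TestLengthConcordance:
    def test_equal_means(self):
        seed = [300.0, 250.0, 400.0]
        r, p, rel = length_concordance(seed, seed)
        assert r == pytest.approx(1.0) and rel == pytest.approx(0.0)

    def test_affine_four_percent_shorter(self):
        seed = np.array([300.0, 250.0, 400.0, 320.0])
        r, p, rel = length_concordance(seed, 0.96 * seed)
        assert r == pytest.approx(1.0)
        assert rel == pytest.approx(-0.04)

    def test_matches_textbook_formula(self):
        rng = random.Random(2)
        seed = [rng.uniform(200, 500) for _ in range(10)]
        env = [s * rng.uniform(0.9, 1.1) for s in seed]
        r, p, rel = length_concordance(seed, env)
        x, y = np.asarray(seed), np.asarray(env)
        xm, ym = x - x.mean(), y - y.mean()
        expected_r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(expected_r)
        assert rel == pytest.approx(np.mean((y - x) / x))

    def test_too_few_families_is_error(self):
        with pytest.raises(ValueError):
            length_concordance([300.0, 200.0], [290.0, 195.0])
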