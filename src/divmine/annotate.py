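"""Similarity-to-reference scoring, divergence labelling, taxonomy, viral
classification, paralogy detection and length-concordance QC.

The central quantity is the similarity of an environmental sequence to its
closest published relative: identity in the aligned region times alignment
coverage on the shorter of the two sequences. Sequences whose best-hit
identity falls below the cross-Domain baseline (the mean archaeal-bacterial
identity within the seed families, 34.9% in the original ocean survey) are
labelled "highly divergent" — more distant from anything published than the
two prokaryotic Domains are from each other in these families.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import ParalogyCall, SimilarityLabel, ViralStatus

logger = logging.getLogger("divmine.annotate")

LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


# ---------------------------------------------------------------------------
# Closest published relative

def best_reference_similarity(hits: pd.DataFrame, sequence_ids: Optional[Iterable[str]] = None) -> Dict[str, SimilarityLabel]:
    """Best closest-published-relative similarity per query sequence.

    Per hit, ``similarity = pident * min(1, length / min(qlen, slen))``; per
    sequence the maximum-similarity hit is kept and its raw identity
    recorded. Sequences without any hit get undefined (None) values.
    Hits are assumed E-value prefiltered.
    """
    labels: Dict[str, SimilarityLabel] = {}
    if not hits.empty:
        for col in ("qlen", "slen"):
            if col not in hits.columns:
                raise ValueError("hit table must carry qlen and slen")
        shortest = hits[["qlen", "slen"]].min(axis=1)
        coverage = (hits["length"] / shortest).clip(upper=1.0)
        sim = hits["pident"] * coverage
        df = hits.assign(_sim=sim)
        best = df.sort_values(["_sim", "pident"], ascending=False, kind="mergesort").drop_duplicates("qseqid")
        for _, row in best.iterrows():
            labels[str(row["qseqid"])] = SimilarityLabel(
                sequence_id=str(row["qseqid"]),
                best_similarity=float(row["_sim"]),
                best_identity=float(row["pident"]),
            )
    if sequence_ids is not None:
        for sid in sequence_ids:
            labels.setdefault(sid, SimilarityLabel(sequence_id=sid))
    return labels


def cross_domain_baseline(domain_of: Dict[str, str], hits: pd.DataFrame) -> float:
    """Mean identity of each bacterial seed to its closest archaeal family
    member, and vice versa, over all seeds with a defined value.

    ``hits`` holds within-family pairwise alignments; only Archaea<->Bacteria
    pairs contribute. Raises ``ValueError`` when no cross-Domain pair exists.
    """
    if hits.empty:
        raise ValueError("no hits supplied")
    qdom = hits["qseqid"].map(domain_of)
    sdom = hits["sseqid"].map(domain_of)
    cross = hits[
        ((qdom == "Archaea") & (sdom == "Bacteria")) | ((qdom == "Bacteria") & (sdom == "Archaea"))
    ]
    if cross.empty:
        raise ValueError("no cross-Domain (Archaea/Bacteria) pairs in hit table")
    best = cross.groupby("qseqid")["pident"].max()
    # symmetrise: a pair seen only in one direction still gives the other
    # member its closest cross-Domain identity
    best_rev = cross.groupby("sseqid")["pident"].max()
    per_seed = pd.concat([best, best_rev]).groupby(level=0).max()
    return float(per_seed.mean())


def label_divergent(labels: Dict[str, SimilarityLabel], threshold: float = 34.9) -> Dict[str, SimilarityLabel]:
    """Set the ``divergent`` flag: best identity strictly below ``threshold``,
    or no published relative at all."""
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    for lab in labels.values():
        lab.divergent = lab.best_identity is None or lab.best_identity < threshold
    n_div = sum(l.divergent for l in labels.values())
    logger.info("divergence labelling at %.1f%%: %d/%d divergent", threshold, n_div, len(labels))
    return labels


def labels_to_frame(labels: Dict[str, SimilarityLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": l.sequence_id,
                "best_similarity": l.best_similarity,
                "best_identity": l.best_identity,
                "divergent": l.divergent,
            }
            for l in sorted(labels.values(), key=lambda l: l.sequence_id)
        ],
        columns=["sequence_id", "best_similarity", "best_identity", "divergent"],
    )


# ---------------------------------------------------------------------------
# Taxonomy

def parse_lineage(text: str) -> Tuple[str, ...]:
    """Parse a semicolon-joined lineage into a rank tuple (root -> leaf),
    truncated at the first empty rank and capped at 7 ranks."""
    if not text:
        return ()
    parts = [p.strip() for p in text.split(";")]
    out = []
    for p in parts[: len(LINEAGE_RANKS)]:
        if not p:
            break
        out.append(p)
    return tuple(out)


def merge_lineages(lineage_v1: Tuple[str, ...], lineage_v2: Tuple[str, ...]) -> Tuple[str, ...]:
    """Keep the lineage with the better taxonomic resolution (more defined
    ranks); ties favour the first argument."""
    return lineage_v2 if len(lineage_v2) > len(lineage_v1) else lineage_v1


def assign_cluster_taxonomy(lineages: Sequence[Tuple[str, ...]]) -> Optional[Tuple[str, str]]:
    """Deepest-rank majority annotation of a cluster.

    Scanning ranks leaf -> root, returns ``(rank_name, value)`` for the first
    rank at which one value is shared by strictly more than half of ALL
    members (empty lineages count in the denominator); ``None`` if no rank
    reaches a majority.
    """
    n = len(lineages)
    if n == 0:
        return None
    max_depth = max((len(l) for l in lineages), default=0)
    for depth in range(min(max_depth, len(LINEAGE_RANKS)) - 1, -1, -1):
        counts: Dict[str, int] = {}
        for lin in lineages:
            if len(lin) > depth:
                counts[lin[depth]] = counts.get(lin[depth], 0) + 1
        if counts:
            value, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            if count * 2 > n:
                return (LINEAGE_RANKS[depth], value)
    return None


# ---------------------------------------------------------------------------
# Viral classification

def classify_viral(
    sequence_ids: Iterable[str],
    viral_hits: pd.DataFrame,
    min_contig_len: int = 5000,
    max_evalue: float = 1e-5,
    min_identity_pct: float = 30.0,
    min_query_coverage: float = 0.8,
    direct_identity: float = 95.0,
) -> Dict[str, ViralStatus]:
    """Two-tier viral classification from nucleotide hits to viral contigs.

    Hits to contigs of length <= ``min_contig_len`` are dropped; survivors
    must pass E-value, identity and QUERY coverage thresholds. A sequence
    whose best remaining identity is >= ``direct_identity`` is ``direct``
    (encoded in a viral genome); any other remaining hit makes it
    ``homologous``; otherwise ``none``. Statuses partition the input set.
    """
    status = {sid: ViralStatus(sequence_id=sid) for sid in sequence_ids}
    if viral_hits.empty:
        return status
    h = viral_hits
    qcov = (h["qend"] - h["qstart"] + 1) / h["qlen"]
    keep = (
        (h["slen"] > min_contig_len)
        & (h["evalue"] <= max_evalue)
        & (h["pident"] >= min_identity_pct)
        & (qcov >= min_query_coverage)
    )
    for qid, group in h.loc[keep].groupby("qseqid"):
        if str(qid) not in status:
            continue
        best = float(group["pident"].max())
        status[str(qid)] = ViralStatus(
            sequence_id=str(qid),
            status="direct" if best >= direct_identity else "homologous",
            best_nt_identity=best,
        )
    return status


# ---------------------------------------------------------------------------
# Paralogy

def _encoded_loci(
    genome_hits: pd.DataFrame,
    member_ids: set,
    min_identity: float,
    min_coverage: float,
) -> pd.DataFrame:
    h = genome_hits[genome_hits["qseqid"].isin(member_ids)]
    if h.empty:
        return h
    cov = (h["qend"] - h["qstart"] + 1) / h["qlen"]
    return h[(h["pident"] >= min_identity) & (cov >= min_coverage)]


def detect_paralogy(
    cluster_a: Iterable[str],
    cluster_b: Iterable[str],
    genome_hits: pd.DataFrame,
    min_identity: float = 90.0,
    min_coverage: float = 0.95,
    min_genomes: int = 10,
) -> ParalogyCall:
    """Co-occurrence test for divergent paralogy between two clusters.

    ``genome_hits`` maps sequences onto single-cell genome contigs and must
    carry ``genome`` and ``contig`` columns plus subject coordinates. A
    sequence is encoded in a genome iff some hit reaches ``min_identity``
    and covers ``min_coverage`` of the sequence. A genome supports the pair
    iff it encodes a member of each cluster on different contigs or on
    non-overlapping regions (no shared base) of the same contig.
    """
    for col in ("genome", "contig"):
        if col not in genome_hits.columns:
            raise ValueError(f"genome hit table must carry a {col!r} column")
    a_ids, b_ids = set(cluster_a), set(cluster_b)
    loci_a = _encoded_loci(genome_hits, a_ids, min_identity, min_coverage)
    loci_b = _encoded_loci(genome_hits, b_ids, min_identity, min_coverage)
    supporting = 0
    genomes = set(loci_a["genome"]) & set(loci_b["genome"]) if not (loci_a.empty or loci_b.empty) else set()
    for genome in sorted(genomes):
        ga = loci_a[loci_a["genome"] == genome]
        gb = loci_b[loci_b["genome"] == genome]
        found = False
        for _, ra in ga.iterrows():
            for _, rb in gb.iterrows():
                if ra["contig"] != rb["contig"]:
                    found = True
                    break
                a_lo, a_hi = sorted((int(ra["sstart"]), int(ra["send"])))
                b_lo, b_hi = sorted((int(rb["sstart"]), int(rb["send"])))
                if min(a_hi, b_hi) < max(a_lo, b_lo):  # no shared base
                    found = True
                    break
            if found:
                break
        supporting += found
    return ParalogyCall(
        cluster_pair=(str(sorted(a_ids)[0]) if a_ids else "", str(sorted(b_ids)[0]) if b_ids else ""),
        supporting_genomes=supporting,
        is_paralogy_pair=supporting >= min_genomes,
    )


# ---------------------------------------------------------------------------
# Length concordance QC

def length_concordance(
    seed_means: Sequence[float], env_means: Sequence[float]
) -> Tuple[float, float, float]:
    """Per-family length concordance between seed and retrieved sequences.

    Returns ``(pearson_r, p_value, mean_relative_difference)`` where the
    relative difference of a family is ``(env - seed) / seed``; a value of
    -0.04 means retrieved sequences are 4% shorter on average.
    """
    seed_means = np.asarray(seed_means, dtype=float)
    env_means = np.asarray(env_means, dtype=float)
    if len(seed_means) != len(env_means) or len(seed_means) < 3:
        raise ValueError("need mean lengths for at least 3 families")
    r, p = stats.pearsonr(seed_means, env_means)
    rel = float(np.mean((env_means - seed_means) / seed_means))
    return float(r), float(p), rel
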