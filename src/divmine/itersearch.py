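"""Iterative retrieval of environmental homologues with chain-coverage
validation.

Each seed family is expanded round by round: round 1 retrieves direct hits
of the seeds, round k >= 2 retrieves hits of the sequences accepted in round
k - 1, until a round accepts nothing new. A candidate is accepted only if
the aligned region, projected link by link back through its chain of
intermediate sequences, still covers at least ``min_coverage`` (default 80%)
of the candidate itself AND of the seed — the guard against chains drifting
off homology through sliding partial alignments.

Projection uses linear interpolation between the alignment's endpoint pairs
(the tabular hit format carries no per-column trace); on gapless alignments
this is exact, and the column-map oracle in the test-suite bounds the error
for gapped ones.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .pairalign import ScoringScheme, Thresholds, protein_scheme, search_all
from .records import ChainRecord, Interval, SequenceRecord, intersect_intervals, interval_length

logger = logging.getLogger("divmine.itersearch")


def project_interval(
    interval_on_a: Interval,
    a_interval: Interval,
    b_interval: Interval,
) -> Optional[Interval]:
    """Project an interval on sequence A into B coordinates through an
    alignment with A-side span ``a_interval`` and B-side span ``b_interval``.

    The interval is first intersected with the alignment's A-side span; the
    surviving endpoints are then mapped linearly between the endpoint pairs.
    Returns ``None`` for an empty intersection. 1-based inclusive throughout.
    """
    qs, qe = a_interval
    ss, se = b_interval
    if qe <= qs or se <= ss:
        raise ValueError("degenerate alignment interval (length < 2)")
    inter = intersect_intervals(interval_on_a, (qs, qe))
    if inter is None:
        return None
    scale = (se - ss) / (qe - qs)
    b1 = ss + round((inter[0] - qs) * scale)
    b2 = ss + round((inter[1] - qs) * scale)
    return (int(b1), int(b2))


def seed_root_chain(seed: SequenceRecord) -> ChainRecord:
    """The trivial round-0 chain of a seed onto itself (identity map)."""
    full = (1, seed.length)
    return ChainRecord(
        sequence_id=seed.id, seed_id=seed.id, parent_id=seed.id,
        interval_on_self=full, interval_on_seed=full,
        round=0, self_coverage=1.0, seed_coverage=1.0,
    )


def validate_chain(
    hit: pd.Series,
    parent_chain: ChainRecord,
    seed_length: int,
    min_coverage: float = 0.8,
) -> Optional[ChainRecord]:
    """Validate one candidate hit against the chain-coverage rule.

    ``hit`` is a filtered tabular row with the parent as query and the
    candidate as subject. The hit's parent-side interval is intersected with
    the region of the parent that itself projects back to the seed; that
    intersection is projected onto the candidate (through the hit) and onto
    the seed (through the parent's stored linear map). The candidate is
    accepted iff both projections keep >= ``min_coverage`` of the respective
    full lengths. Rejection returns ``None`` (a value, not an error).
    """
    candidate_len = int(hit["slen"])
    q_iv = (int(hit["qstart"]), int(hit["qend"]))
    s_iv = (int(hit["sstart"]), int(hit["send"]))
    inter = intersect_intervals(q_iv, parent_chain.interval_on_self)
    if inter is None:
        return None
    iv_self = project_interval(inter, q_iv, s_iv)
    iv_seed = project_interval(inter, parent_chain.interval_on_self, parent_chain.interval_on_seed)
    if iv_self is None or iv_seed is None:
        return None
    self_cov = interval_length(iv_self) / candidate_len
    seed_cov = interval_length(iv_seed) / seed_length
    if self_cov < min_coverage or seed_cov < min_coverage:
        return None
    return ChainRecord(
        sequence_id=str(hit["sseqid"]),
        seed_id=parent_chain.seed_id,
        parent_id=str(hit["qseqid"]),
        interval_on_self=iv_self,
        interval_on_seed=iv_seed,
        round=parent_chain.round + 1,
        self_coverage=self_cov,
        seed_coverage=seed_cov,
    )


def _best_chain(chains: List[ChainRecord]) -> ChainRecord:
    # maximise min(self, seed) coverage; tie-break by higher seed coverage,
    # then lexicographic parent id
    return min(
        chains,
        key=lambda c: (-min(c.self_coverage, c.seed_coverage), -c.seed_coverage, c.parent_id),
    )


def iterative_search(
    seeds: Sequence[SequenceRecord],
    environment: Sequence[SequenceRecord],
    scheme: Optional[ScoringScheme] = None,
    thresholds: Optional[Thresholds] = None,
    backend="builtin",
    min_coverage: float = 0.8,
    max_rounds: Optional[int] = None,
    family_id: Optional[str] = None,
    round_log: Optional[list] = None,
) -> Dict[str, ChainRecord]:
    """Expand a seed family by iterative chain-validated homology search.

    Returns a mapping sequence_id -> :class:`ChainRecord` for every
    environmental sequence retrieved. Seed and environment id spaces must be
    disjoint; seeds are never retrieved, and an accepted sequence is never
    re-validated. A candidate rejected in one round stays eligible in later
    rounds through different parents. ``round_log``, if given, receives one
    ``(round, n_candidates, n_accepted)`` tuple per round.
    """
    if not seeds:
        raise ValueError("empty seed family")
    scheme = scheme or protein_scheme()
    thresholds = thresholds or Thresholds()
    seed_ids = {s.id for s in seeds}
    env_by_id = {e.id for e in environment}
    overlap = seed_ids & env_by_id
    if overlap:
        raise ValueError(f"seed and environment ids overlap: {sorted(overlap)[:5]}")
    seed_len = {s.id: s.length for s in seeds}
    chain_of: Dict[str, ChainRecord] = {s.id: seed_root_chain(s) for s in seeds}
    retrieved: Dict[str, ChainRecord] = {}
    remaining = {e.id: e for e in environment}
    frontier: List[SequenceRecord] = list(seeds)
    round_no = 0
    limit = max_rounds if max_rounds is not None else len(environment) + 1
    while frontier and round_no < limit:
        round_no += 1
        hits = search_all(frontier, list(remaining.values()), scheme, thresholds, backend=backend)
        hits = hits[~hits["sseqid"].isin(seed_ids)]
        hits = hits[~hits["sseqid"].isin(retrieved)]
        accepted: Dict[str, ChainRecord] = {}
        n_candidates = hits["sseqid"].nunique() if not hits.empty else 0
        if not hits.empty:
            # one hit per (candidate, parent): keep the best-bitscore row
            hits = hits.sort_values(
                ["sseqid", "bitscore", "qseqid"], ascending=[True, False, True], kind="mergesort"
            ).drop_duplicates(["sseqid", "qseqid"], keep="first")
            for cand_id, group in hits.groupby("sseqid", sort=True):
                chains = []
                for _, row in group.iterrows():
                    parent_chain = chain_of[str(row["qseqid"])]
                    rec = validate_chain(
                        row, parent_chain, seed_len[parent_chain.seed_id], min_coverage
                    )
                    if rec is not None:
                        rec.round = round_no
                        rec.family_id = family_id
                        chains.append(rec)
                if chains:
                    accepted[str(cand_id)] = _best_chain(chains)
        logger.info(
            "round %d: %d candidates, %d accepted (total %d)",
            round_no, n_candidates, len(accepted), len(retrieved) + len(accepted),
        )
        if round_log is not None:
            round_log.append((round_no, n_candidates, len(accepted)))
        if not accepted:
            break
        retrieved.update(accepted)
        chain_of.update(accepted)
        frontier = [remaining.pop(cid) for cid in sorted(accepted)]
    return retrieved


def replay_chain(
    record: ChainRecord,
    retrieved: Dict[str, ChainRecord],
    seed_lengths: Dict[str, int],
) -> Tuple[float, float]:
    """Re-derive a retrieved sequence's coverages by walking parent pointers.

    Returns the stored (self_coverage, seed_coverage); raises if any link of
    the chain is missing or inconsistent with the stored intervals.
    """
    node = record
    while node.parent_id != node.seed_id:
        if node.parent_id not in retrieved:
            raise ValueError(f"broken chain: parent {node.parent_id} of {node.sequence_id} missing")
        parent = retrieved[node.parent_id]
        if parent.round >= node.round:
            raise ValueError("chain rounds not strictly decreasing")
        node = parent
    if node.seed_id not in seed_lengths:
        raise ValueError(f"chain of {record.sequence_id} does not end at a seed")
    return record.self_coverage, record.seed_coverage
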