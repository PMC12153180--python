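"""Built-in pairwise local alignment backend and hit filtering.

Provides the same contract as an external aligner (single best affine-gap
Smith-Waterman HSP per pair, Karlin-Altschul E-values, BLAST ``outfmt 6``
rows) so the whole pipeline runs self-contained. NCBI ``blastp`` can be
substituted as a faster backend for large all-against-all searches and
produces the identical tabular dialect.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(BLAST convention; defaults 11/1 with BLOSUM62).
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import io as dio
from .records import AlignmentHit, SequenceRecord

LN2 = math.log(2.0)


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul parameters.

    ``lam`` and ``K`` are the gapped Karlin-Altschul parameters used for the
    E-value closed form ``E = K * m * n * exp(-lam * S)``.
    """

    matrix: object
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs are positive magnitudes")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


def protein_scheme() -> ScoringScheme:
    """Default protein scoring: BLOSUM62, gaps 11/1, gapped lambda/K."""
    return ScoringScheme(matrix=substitution_matrices.load("BLOSUM62"))


def nucleotide_scheme() -> ScoringScheme:
    """Nucleotide scoring: match +2 / mismatch -3, gaps 5/2 (blastn defaults)."""
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = 2.0 if (a == b and a != "N") else -3.0
    return ScoringScheme(matrix=mat, gap_open=5, gap_extend=2, lam=0.625, K=0.41, alphabet="nt")


@dataclass
class Thresholds:
    """Hit retention thresholds (inclusive, as printed in Methods)."""

    max_evalue: float = 1e-5
    min_identity_pct: float = 30.0
    min_mutual_coverage: float = 0.8


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each further one; shift to the BLAST convention.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def compute_evalue(score: float, query_len: int, db_residues: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query_len and db_residues must be positive")
    if score <= 0:
        raise ValueError("score must be positive")
    return scheme.K * query_len * db_residues * math.exp(-scheme.lam * score)


def bit_score(score: float, scheme: ScoringScheme) -> float:
    """Normalised (bit) score ``(lambda * S - ln K) / ln 2``."""
    return (scheme.lam * score - math.log(scheme.K)) / LN2


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: Optional[ScoringScheme] = None,
    db_residues: Optional[int] = None,
) -> Optional[AlignmentHit]:
    """Best local alignment between two sequences, or ``None`` if no
    alignment scores above zero.

    A single maximal-scoring HSP is reported (ties broken by Biopython's
    deterministic traceback order). ``db_residues`` sets the search-space
    size for the E-value; it defaults to the subject length.
    """
    scheme = scheme or protein_scheme()
    if query.alphabet != subject.alphabet:
        raise ValueError(
            f"alphabet mismatch: {query.id} is {query.alphabet}, {subject.id} is {subject.alphabet}"
        )
    aligner = _make_aligner(scheme)
    score = aligner.score(query.residues, subject.residues)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(query.residues, subject.residues)))
    qblocks, sblocks = alignment.aligned
    matches = 0
    mismatches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        qseg = query.residues[qs:qe]
        sseg = subject.residues[ss:se]
        columns += len(qseg)
        matches += sum(a == b for a, b in zip(qseg, sseg))
    mismatches = columns - matches
    # gap opens and gapped columns between consecutive aligned blocks
    gapopen = 0
    for i in range(1, len(qblocks)):
        qgap = qblocks[i][0] - qblocks[i - 1][1]
        sgap = sblocks[i][0] - sblocks[i - 1][1]
        if qgap:
            gapopen += 1
            columns += qgap
        if sgap:
            gapopen += 1
            columns += sgap
    n = db_residues if db_residues is not None else subject.length
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        identity_pct=100.0 * matches / (columns if columns else 1),
        aligned_length=columns,
        mismatch=mismatches,
        gapopen=gapopen,
        q_start=int(qblocks[0][0]) + 1,
        q_end=int(qblocks[-1][1]),
        s_start=int(sblocks[0][0]) + 1,
        s_end=int(sblocks[-1][1]),
        evalue=compute_evalue(score, query.length, n, scheme),
        bitscore=round(bit_score(score, scheme), 1),
        qlen=query.length,
        slen=subject.length,
        score=float(score),
    )


def hit_to_row(hit: AlignmentHit) -> dict:
    return {
        "qseqid": hit.query_id, "sseqid": hit.subject_id,
        "pident": round(hit.identity_pct, 2), "length": hit.aligned_length,
        "mismatch": hit.mismatch, "gapopen": hit.gapopen,
        "qstart": hit.q_start, "qend": hit.q_end,
        "sstart": hit.s_start, "send": hit.s_end,
        "evalue": hit.evalue, "bitscore": hit.bitscore,
        "qlen": hit.qlen, "slen": hit.slen,
    }


def hits_to_table(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    rows = [hit_to_row(h) for h in hits]
    if not rows:
        return dio.empty_hit_table()
    return pd.DataFrame(rows, columns=dio.HIT_COLUMNS + dio.HIT_EXTRA_COLUMNS)


def filter_hits(
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_identity_pct: float = 30.0,
    min_mutual_coverage: float = 0.8,
) -> pd.DataFrame:
    """Retain hits with ``evalue <= max_evalue``, ``pident >= min_identity``
    and the aligned interval covering at least ``min_mutual_coverage`` of
    BOTH sequences' full lengths. Order-preserving and idempotent."""
    if hits.empty:
        return hits
    for col in ("qlen", "slen"):
        if col not in hits.columns or hits[col].isna().any():
            raise ValueError("filter_hits requires qlen and slen on every row")
    qcov = (hits["qend"] - hits["qstart"] + 1) / hits["qlen"]
    scov = (hits["send"] - hits["sstart"] + 1) / hits["slen"]
    keep = (
        (hits["evalue"] <= max_evalue)
        & (hits["pident"] >= min_identity_pct)
        & (qcov >= min_mutual_coverage)
        & (scov >= min_mutual_coverage)
    )
    return hits.loc[keep].copy()


# ---------------------------------------------------------------------------
# Search backends

def _builtin_search(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    thresholds: Thresholds,
) -> pd.DataFrame:
    db_residues = sum(s.length for s in database)
    # Skip the full traceback for pairs that cannot reach the E-value
    # threshold: the closed form gives the minimal qualifying raw score.
    hits: List[AlignmentHit] = []
    aligner = _make_aligner(scheme)
    for q in queries:
        min_score = (
            math.log(scheme.K * q.length * db_residues / thresholds.max_evalue) / scheme.lam
            if db_residues
            else float("inf")
        )
        for s in database:
            if q.id == s.id:
                continue
            if aligner.score(q.residues, s.residues) < min_score:
                continue
            hit = local_align(q, s, scheme, db_residues=db_residues)
            if hit is not None:
                hits.append(hit)
    return filter_hits(
        hits_to_table(hits),
        thresholds.max_evalue,
        thresholds.min_identity_pct,
        thresholds.min_mutual_coverage,
    )


def _blast_search(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    scheme: ScoringScheme,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """All-against-all search through NCBI BLAST+ (same tabular dialect)."""
    from . import io as dio_  # local alias for FASTA helpers

    prog = "blastp" if scheme.alphabet == "aa" else "blastn"
    if shutil.which(prog) is None or shutil.which("makeblastdb") is None:
        raise RuntimeError(f"BLAST+ ({prog}/makeblastdb) not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qpath, dbpath = tmp / "q.faa", tmp / "db.faa"
        dio_.write_fasta(queries, qpath)
        dio_.write_fasta(database, dbpath)
        dbtype = "prot" if scheme.alphabet == "aa" else "nucl"
        subprocess.run(
            ["makeblastdb", "-in", str(dbpath), "-dbtype", dbtype, "-out", str(tmp / "db")],
            check=True, capture_output=True,
        )
        out = tmp / "hits.tsv"
        cmd = [
            prog, "-query", str(qpath), "-db", str(tmp / "db"),
            "-outfmt", "6 std qlen slen",
            "-evalue", str(thresholds.max_evalue),
            "-max_hsps", "1",
            "-max_target_seqs", str(max(len(database), 500)),
            "-num_threads", "1",
            "-out", str(out),
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        hits = dio_.read_hit_table(out)
    hits = hits[hits["qseqid"] != hits["sseqid"]]
    return filter_hits(
        hits,
        thresholds.max_evalue,
        thresholds.min_identity_pct,
        thresholds.min_mutual_coverage,
    ).reset_index(drop=True)


def search_all(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    scheme: Optional[ScoringScheme] = None,
    thresholds: Optional[Thresholds] = None,
    backend: Union[str, Callable] = "builtin",
) -> pd.DataFrame:
    """Filtered all-against-all hit table between two sequence collections.

    Self-hits (equal ids) are excluded. ``backend`` is ``"builtin"`` (exact
    Smith-Waterman), ``"blast"`` (NCBI BLAST+), or a callable with the same
    signature returning an (unfiltered or filtered) hit table; hit files from
    an external aligner can be injected via :func:`precomputed_backend`.
    """
    scheme = scheme or protein_scheme()
    thresholds = thresholds or Thresholds()
    if not database:
        return dio.empty_hit_table()
    if callable(backend):
        hits = backend(queries, database, scheme, thresholds)
        return filter_hits(hits, thresholds.max_evalue, thresholds.min_identity_pct,
                           thresholds.min_mutual_coverage).reset_index(drop=True)
    if backend == "builtin":
        return _builtin_search(queries, database, scheme, thresholds).reset_index(drop=True)
    if backend == "blast":
        return _blast_search(queries, database, scheme, thresholds)
    raise ValueError(f"unknown backend {backend!r}")


def precomputed_backend(hit_table: pd.DataFrame) -> Callable:
    """Backend serving rows of an externally produced hit table."""

    def _backend(queries, database, scheme, thresholds):
        qids = {q.id for q in queries}
        dids = {d.id for d in database}
        sub = hit_table[hit_table["qseqid"].isin(qids) & hit_table["sseqid"].isin(dids)]
        return sub[sub["qseqid"] != sub["sseqid"]]

    return _backend
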