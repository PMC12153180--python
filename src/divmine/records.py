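"""Core domain types shared across the package.

Interval convention: all intervals are 1-based and inclusive at both ends,
following the 12-column tabular alignment dialect (BLAST ``outfmt 6``).
Conversion to other conventions is centralised here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

# Amino-acid alphabet plus ambiguity codes accepted on input.  X (and the
# rarer B/Z/J/U/O) occur in metagenomic catalogues and are kept verbatim.
AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
AA_AMBIGUOUS = set("XBZJUO*")
NT_LETTERS = set("ACGT")
NT_AMBIGUOUS = set("NRYSWKMBDHV")

DEPTH_LAYERS = ("SRF", "DCM/MIX", "MES")
DOMAIN_LABELS = ("Archaea", "Bacteria", "Eukaryota", "Virus", "Plasmid")

Interval = Tuple[int, int]


def interval_length(iv: Optional[Interval]) -> int:
    """Length of a 1-based inclusive interval; ``None`` (empty) has length 0."""
    if iv is None:
        return 0
    return iv[1] - iv[0] + 1


def intersect_intervals(a: Optional[Interval], b: Optional[Interval]) -> Optional[Interval]:
    """Intersection of two 1-based inclusive intervals, ``None`` if disjoint."""
    if a is None or b is None:
        return None
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if lo > hi:
        return None
    return (lo, hi)


@dataclass
class SequenceRecord:
    """One amino-acid or nucleotide sequence with provenance attributes.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token before the first whitespace).
    residues : str
        Upper-case residue string; never empty.
    source : str
        ``"seed"`` for reference-family members, ``"environmental"`` for
        catalogue sequences.
    alphabet : str
        ``"aa"`` (default) or ``"nt"``.
    domain_label : str, optional
        Domain of life (one of :data:`DOMAIN_LABELS`).
    sample_id : str, optional
        Identifier linking the sequence to sampling metadata.
    """

    id: str
    residues: str
    source: str = "environmental"
    alphabet: str = "aa"
    domain_label: Optional[str] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        if self.source not in ("seed", "environmental"):
            raise ValueError(f"invalid source {self.source!r} for {self.id!r}")
        if self.alphabet not in ("aa", "nt"):
            raise ValueError(f"invalid alphabet {self.alphabet!r}")
        allowed = (AA_LETTERS | AA_AMBIGUOUS) if self.alphabet == "aa" else (NT_LETTERS | NT_AMBIGUOUS)
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {sorted(bad)}"
            )
        if self.domain_label is not None and self.domain_label not in DOMAIN_LABELS:
            raise ValueError(f"unknown Domain label {self.domain_label!r}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentHit:
    """One local alignment between two sequences (single best HSP).

    Intervals are 1-based inclusive; ``identity_pct`` is
    ``100 * matches / aligned columns``.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    aligned_length: int
    mismatch: int
    gapopen: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    qlen: Optional[int] = None
    slen: Optional[int] = None
    score: Optional[float] = None  # raw alignment score

    @property
    def q_interval(self) -> Interval:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> Interval:
        return (self.s_start, self.s_end)

    @property
    def query_coverage(self) -> float:
        if self.qlen is None:
            raise ValueError("qlen missing; cannot compute query coverage")
        return interval_length(self.q_interval) / self.qlen

    @property
    def subject_coverage(self) -> float:
        if self.slen is None:
            raise ValueError("slen missing; cannot compute subject coverage")
        return interval_length(self.s_interval) / self.slen


@dataclass
class ChainRecord:
    """Provenance of one retrieved environmental sequence.

    ``interval_on_self`` is the region of the sequence that survives
    link-by-link projection back to the seed; ``interval_on_seed`` is its
    image on the seed. Round-1 records have ``parent_id == seed_id``.
    """

    sequence_id: str
    seed_id: str
    parent_id: str
    interval_on_self: Interval
    interval_on_seed: Interval
    round: int
    self_coverage: float
    seed_coverage: float
    family_id: Optional[str] = None


@dataclass
class Cluster:
    """A community of an SSN with selection statistics."""

    cluster_id: str
    member_ids: frozenset
    env_fraction: Optional[float] = None
    mean_closest_published_similarity: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class SimilarityLabel:
    """Closest-published-relative scores for one environmental sequence.

    ``best_similarity`` is identity x coverage-on-shortest for the best hit;
    ``best_identity`` is the raw identity of that same hit. Both are ``None``
    when the sequence has no reference hit.
    """

    sequence_id: str
    best_similarity: Optional[float] = None
    best_identity: Optional[float] = None
    divergent: Optional[bool] = None


@dataclass
class ViralStatus:
    """Two-tier viral classification of one environmental sequence."""

    sequence_id: str
    status: str = "none"  # direct | homologous | none
    best_nt_identity: Optional[float] = None


@dataclass
class ParalogyCall:
    """Co-occurrence evidence that two clusters are divergent paralogues."""

    cluster_pair: Tuple[str, str]
    supporting_genomes: int
    is_paralogy_pair: bool


@dataclass
class RetrievalScore:
    """Precision/recall of one simulated-family retrieval.

    ``precision`` is ``None`` (undefined) when nothing was retrieved.
    """

    factor: float
    depth: int
    replicate: int
    precision: Optional[float]
    recall: float
    n_retrieved: int = 0
    n_false: int = 0
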