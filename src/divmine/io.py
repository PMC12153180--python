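"""Readers and writers for all interchange formats.

Formats: FASTA (sequences), 12(+2)-column tabular hits (BLAST ``outfmt 6``
dialect: qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore [qlen slen]), TSV sample metadata, edge lists, cluster and
chain assignments, and JSON/YAML configuration.

Every tabular output starts with a ``#`` comment line naming the producing
tool version and the configuration hash; all tabular readers skip ``#``
lines, so write-then-read is the identity. FASTA has no comment syntax and
carries no such header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import DEPTH_LAYERS, SequenceRecord

__version__ = "0.1.0"

logger = logging.getLogger("divmine")

#: Canonical column order of the tabular hit dialect.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
HIT_EXTRA_COLUMNS = ["qlen", "slen"]

_NUMERIC_HIT_COLS = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float, "qlen": int, "slen": int,
}


def config_hash(config: Optional[dict]) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def output_header(config: Optional[dict] = None) -> str:
    return f"# divmine v{__version__} config={config_hash(config)}"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministically split a top-level seed into a per-stage seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "aa", source: str = "environmental") -> List[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    The id is the header token before the first whitespace. Duplicate ids,
    empty sequences and characters outside the alphabet (other than
    X/ambiguity codes) raise ``ValueError``.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(SequenceRecord(id=entry.id, residues=str(entry.seq), source=source, alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA with ``width``-column wrapped sequence lines."""
    bio = [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Hit tables

def read_hit_table(path) -> pd.DataFrame:
    """Read a 12(+2)-column tabular hit file.

    Raises ``ValueError`` naming the (1-based) line number for rows with a
    wrong column count or unparseable numeric fields.
    """
    path = Path(path)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 14):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated columns, got {len(fields)}"
                )
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            cols = HIT_COLUMNS + (HIT_EXTRA_COLUMNS if len(fields) == 14 else [])
            row = {}
            for name, value in zip(cols, fields):
                caster = _NUMERIC_HIT_COLS.get(name, str)
                try:
                    row[name] = caster(value)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad value {value!r} for column {name}") from exc
            rows.append(row)
    cols = HIT_COLUMNS + (HIT_EXTRA_COLUMNS if ncols == 14 else [])
    return pd.DataFrame(rows, columns=cols)


def write_hit_table(hits: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    cols = [c for c in HIT_COLUMNS + HIT_EXTRA_COLUMNS if c in hits.columns]
    with open(path, "w") as fh:
        fh.write(output_header(config) + "\n")
        hits.to_csv(fh, sep="\t", header=False, index=False, columns=cols, float_format="%.6g")


def empty_hit_table(with_lengths: bool = True) -> pd.DataFrame:
    cols = HIT_COLUMNS + (HIT_EXTRA_COLUMNS if with_lengths else [])
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# Generic headered TSV

def _read_tsv(path, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _write_tsv(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sequence sample metadata (sequence_id, station, depth_layer,
    region[, size_fraction]); validates the three-layer depth vocabulary."""
    df = _read_tsv(path, columns=["sequence_id", "station", "depth_layer", "region"])
    bad = set(df["depth_layer"]) - set(DEPTH_LAYERS)
    if bad:
        raise ValueError(f"{path}: unknown depth layers {sorted(bad)}; expected {DEPTH_LAYERS}")
    return df


def write_metadata(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    _write_tsv(df, path, config)


def read_edge_list(path) -> pd.DataFrame:
    return _read_tsv(path, columns=["node_a", "node_b"])


def write_edge_list(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    _write_tsv(df, path, config)


def read_node_attributes(path) -> pd.DataFrame:
    """Node attribute TSV: id, domain."""
    return _read_tsv(path, columns=["id", "domain"])


def read_clusters(path) -> pd.DataFrame:
    return _read_tsv(path, columns=["sequence_id", "family_id", "cluster_id"])


def write_clusters(df: pd.DataFrame, path, config: Optional[dict] = None) -> None:
    _write_tsv(df, path, config)


CHAIN_COLUMNS = [
    "sequence_id", "family_id", "seed_id", "parent_id", "round",
    "self_start", "self_end", "seed_start", "seed_end", "self_cov", "seed_cov",
]


def read_chains(path) -> pd.DataFrame:
    return _read_tsv(path, columns=CHAIN_COLUMNS)


def write_chains(chains, path, family_id: str = "", config: Optional[dict] = None) -> None:
    """Write chain records (mapping id -> ChainRecord, or an iterable)."""
    if isinstance(chains, dict):
        chains = chains.values()
    rows = [
        {
            "sequence_id": c.sequence_id,
            "family_id": c.family_id or family_id,
            "seed_id": c.seed_id,
            "parent_id": c.parent_id,
            "round": c.round,
            "self_start": c.interval_on_self[0],
            "self_end": c.interval_on_self[1],
            "seed_start": c.interval_on_seed[0],
            "seed_end": c.interval_on_seed[1],
            "self_cov": round(c.self_coverage, 6),
            "seed_cov": round(c.seed_coverage, 6),
        }
        for c in sorted(chains, key=lambda c: c.sequence_id)
    ]
    _write_tsv(pd.DataFrame(rows, columns=CHAIN_COLUMNS), path, config)


def read_lineages(path) -> Dict[str, str]:
    """Lineage TSV (sequence_id, semicolon-joined lineage) -> mapping."""
    df = _read_tsv(path, columns=["sequence_id", "lineage"])
    return dict(zip(df["sequence_id"], df["lineage"].fillna("")))


# ---------------------------------------------------------------------------
# Configuration

def load_config(path) -> dict:
    """Load a JSON or YAML configuration file by extension."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            config = yaml.safe_load(fh)
        else:
            config = json.load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
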