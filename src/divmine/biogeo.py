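"""Biogeography of highly divergent variants: per-sample fold-changes and
exact binomial enrichment/depletion tests.

A sample is one (station, depth layer) combination. Its fold-change is the
local fraction of divergent variants over the global fraction among all
retrieved homologues; enrichment or depletion is tested with a one-sided
exact binomial test in the observed direction, Bonferroni-corrected over the
samples with non-zero sequence count. The same machinery runs on the two
margins (stations pooled over depths, depths pooled over stations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger("divmine.biogeo")

#: Adjusted-p-value ranges rendered as significance stars.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class EnrichmentResult:
    station: Optional[str]
    depth_layer: Optional[str]
    n_total: int
    n_divergent: int
    fold_change: float
    direction: str  # enriched | depleted
    p_raw: float
    p_adjusted: float
    significant: bool
    stars: str = ""


def tabulate_samples(
    sequence_ids: Iterable[str],
    divergent_of: Dict[str, bool],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Count total and divergent sequences per (station, depth_layer).

    Sequences absent from the metadata are excluded and logged; the sum of
    ``n_total`` over samples equals the number of assigned sequences.
    """
    meta = metadata.set_index("sequence_id")
    rows = []
    unassigned = 0
    for sid in sequence_ids:
        if sid not in meta.index:
            unassigned += 1
            continue
        rows.append(
            {
                "station": meta.at[sid, "station"],
                "depth_layer": meta.at[sid, "depth_layer"],
                "divergent": bool(divergent_of.get(sid, False)),
            }
        )
    if unassigned:
        logger.info("tabulate_samples: %d sequences without metadata excluded", unassigned)
    if not rows:
        return pd.DataFrame(columns=["station", "depth_layer", "n_total", "n_divergent"])
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["station", "depth_layer"], sort=True)
        .agg(n_total=("divergent", "size"), n_divergent=("divergent", "sum"))
        .reset_index()
    )
    counts["n_divergent"] = counts["n_divergent"].astype(int)
    return counts


def global_divergent_fraction(divergent_of: Dict[str, bool]) -> float:
    """Fraction of divergent sequences over the full retrieved set (before
    any metadata-assignment losses)."""
    if not divergent_of:
        raise ValueError("empty label set")
    return sum(divergent_of.values()) / len(divergent_of)


def fold_change(n_divergent: int, n_total: int, global_fraction: float) -> float:
    """Local divergent fraction over the global fraction."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 < global_fraction < 1:
        raise ValueError("global_fraction must be in (0, 1)")
    return (n_divergent / n_total) / global_fraction


def _stars(p_adjusted: float) -> str:
    for cut, mark in STAR_LEVELS:
        if p_adjusted < cut:
            return mark
    return ""


def binomial_enrichment(
    counts: pd.DataFrame,
    global_fraction: float,
    n_tests: Optional[int] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided exact binomial tests per sample, Bonferroni-corrected.

    For each sample with ``n_total > 0``, the tail in the observed direction
    is computed (upper tail when the local fraction >= global, lower tail
    otherwise); ``p_adjusted = min(1, N * p_raw)`` with N defaulting to the
    number of tested samples. Returns one row per sample with fold change,
    direction, p-values, significance at ``alpha`` and stars.
    """
    rows = counts[counts["n_total"] > 0]
    n = n_tests if n_tests is not None else len(rows)
    if n < 1:
        raise ValueError("N_tests must be >= 1")
    out = []
    for _, row in rows.iterrows():
        k, m = int(row["n_divergent"]), int(row["n_total"])
        local = k / m
        if local >= global_fraction:
            direction = "enriched"
            p_raw = float(stats.binom.sf(k - 1, m, global_fraction))
        else:
            direction = "depleted"
            p_raw = float(stats.binom.cdf(k, m, global_fraction))
        p_adj = min(1.0, n * p_raw)
        out.append(
            {
                "station": row.get("station"),
                "depth_layer": row.get("depth_layer"),
                "n_total": m,
                "n_divergent": k,
                "fold_change": fold_change(k, m, global_fraction),
                "direction": direction,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
                "stars": _stars(p_adj),
            }
        )
    return pd.DataFrame(out)


def margin_counts(counts: pd.DataFrame, by: str) -> pd.DataFrame:
    """Collapse sample counts onto one margin (``"station"`` or
    ``"depth_layer"``) for the margin-wise tests (N = margin size)."""
    agg = counts.groupby(by, sort=True)[["n_total", "n_divergent"]].sum().reset_index()
    other = "depth_layer" if by == "station" else "station"
    agg[other] = None
    return agg[["station", "depth_layer", "n_total", "n_divergent"]]


def fold_change_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Station x depth-layer fold-change matrix for heatmap export."""
    return enrichment.pivot(index="station", columns="depth_layer", values="fold_change")
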