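"""Simulated protein-family benchmark for the iterative retrieval protocol.

Families of related protein sequences are generated along balanced binary
trees in which every branch between the root and one chosen target node is
elongated by a factor, creating a fast-evolving root-side subtree (the one
containing the target) and a slow-evolving one. The slow leaves of each
family serve as seeds to retrieve their own fast leaves from the pooled
sequences of ALL families; precision and recall of the retrieval are scored
per elongation factor and per depth of the target node.

Sequences evolve site-independently under a continuous-time Markov model
(LG exchangeabilities by default) with the root drawn from the stationary
frequencies; no indels are simulated, so all family members share the root
length. The full design is 64 leaves x 9 factors x 3 replicates over all
126 non-root target nodes (3402 families); a scaled-down design (16 leaves,
factors 1/2/4/8, 2 replicates, 150 residues) exercises the same machinery
at desk scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._lg_data import AA_ORDER, LG_EXCH_LOWER, LG_FREQS
from .io import derive_seed
from .itersearch import iterative_search
from .pairalign import ScoringScheme, Thresholds, precomputed_backend, protein_scheme, search_all
from .records import RetrievalScore, SequenceRecord

logger = logging.getLogger("divmine.simbench")

#: Elongation factors of the full design (1 is the null case).
FULL_FACTORS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 6.0, 8.0)
#: Scaled-down design for routine runs.
SCALED_FACTORS = (1.0, 2.0, 4.0, 8.0)
SCALED_N_LEAVES = 16
SCALED_REPLICATES = 2
SCALED_ROOT_LENGTH = 150

#: Branch length of the full 64-leaf design (expected substitutions/site per
#: edge), calibrated so that the slow-side mean pairwise identity lands near
#: the 42.7% observed for the real seed families (see
#: calibrate_branch_length).
DEFAULT_BRANCH_LENGTH = 0.1223


def default_branch_length(n_leaves: int) -> float:
    """Branch length for an ``n_leaves`` design, preserving the tree height
    (root-to-leaf distance in expected substitutions) of the calibrated
    64-leaf design.

    Height is what the elongation factor acts on, so keeping it constant
    keeps the seed-to-target divergence each factor creates — the
    independent variable of the benchmark — comparable across tree sizes.
    """
    return DEFAULT_BRANCH_LENGTH * 6.0 / math.log2(n_leaves)


# ---------------------------------------------------------------------------
# Substitution models

def build_rate_matrix(model: str = "lg") -> Tuple[np.ndarray, np.ndarray]:
    """Return ``(Q, freqs)`` for a 20-state substitution model, with Q
    normalised to one expected substitution per site per unit time.

    ``"lg"`` uses the LG exchangeabilities and frequencies; ``"poisson"``
    uses uniform exchangeabilities and uniform frequencies (fast tests).
    """
    if model == "lg":
        freqs = LG_FREQS / LG_FREQS.sum()  # renormalise printed precision
        s = np.zeros((20, 20))
        idx = np.tril_indices(20, k=-1)
        # column-major strict lower triangle
        order = np.lexsort((idx[0], idx[1]))
        s[idx[0][order], idx[1][order]] = LG_EXCH_LOWER
        s = s + s.T
    elif model == "poisson":
        freqs = np.full(20, 0.05)
        s = np.ones((20, 20))
        np.fill_diagonal(s, 0.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    q = s * freqs[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.sum(freqs * np.diag(q))
    return q / rate, freqs


# ---------------------------------------------------------------------------
# Trees

@dataclass
class SimTree:
    """Rooted balanced binary tree stored in level order.

    Node 0 is the root; node i has children 2i+1 and 2i+2; leaves are the
    last ``n_leaves`` ids. ``branch_length[i]`` is the length of the edge
    above node i (index 0 unused).
    """

    n_leaves: int
    branch_length: np.ndarray

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def leaves(self) -> range:
        return range(self.n_leaves - 1, 2 * self.n_leaves - 1)

    @staticmethod
    def parent(node: int) -> int:
        return (node - 1) // 2

    @staticmethod
    def depth(node: int) -> int:
        return int(math.floor(math.log2(node + 1)))

    def path_to_root(self, node: int) -> List[int]:
        """Nodes on the path from ``node`` up to (excluding) the root."""
        path = []
        while node != 0:
            path.append(node)
            node = self.parent(node)
        return path

    def root_distance(self, node: int) -> float:
        return float(sum(self.branch_length[n] for n in self.path_to_root(node)))


def balanced_tree(n_leaves: int, branch_length: float) -> SimTree:
    """Balanced binary tree with uniform branch lengths.

    ``n_leaves`` must be a power of two >= 2; the tree then has
    ``2 * n_leaves - 2`` non-root nodes and all leaves at depth
    ``log2(n_leaves)``.
    """
    if n_leaves < 2 or (n_leaves & (n_leaves - 1)) != 0:
        raise ValueError("n_leaves must be a power of two >= 2")
    if branch_length <= 0:
        raise ValueError("branch_length must be positive")
    lengths = np.full(2 * n_leaves - 1, float(branch_length))
    lengths[0] = 0.0
    return SimTree(n_leaves=n_leaves, branch_length=lengths)


def elongate_root_path(tree: SimTree, target_node: int, factor: float) -> SimTree:
    """Multiply the length of every branch on the root -> target path by
    ``factor``; all other branches are unchanged."""
    if target_node == 0:
        raise ValueError("target node must not be the root")
    if not 0 < target_node < tree.n_nodes:
        raise ValueError(f"target node {target_node} outside tree")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    lengths = tree.branch_length.copy()
    for node in tree.path_to_root(target_node):
        lengths[node] *= factor
    return SimTree(n_leaves=tree.n_leaves, branch_length=lengths)


def root_child_of(tree: SimTree, node: int) -> int:
    """The root child (1 or 2) whose subtree contains ``node``."""
    path = tree.path_to_root(node)
    return path[-1]


# ---------------------------------------------------------------------------
# Sequence evolution

_EXPM_CACHE: Dict[Tuple[str, float], np.ndarray] = {}


def _transition_matrix(q: np.ndarray, t: float, model_key: str) -> np.ndarray:
    key = (model_key, round(float(t), 12))
    if key not in _EXPM_CACHE:
        _EXPM_CACHE[key] = expm(q * t)
    return _EXPM_CACHE[key]


def evolve_along_tree(
    tree: SimTree,
    root_length: int = 300,
    model: str = "lg",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Dict[int, str]:
    """Evolve a random root sequence along the tree; returns leaf sequences.

    The root is drawn from the model's stationary frequencies; along each
    branch of length t every site evolves independently with transition
    matrix ``exp(Q t)``. Deterministic given the seed/rng.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    q, freqs = build_rate_matrix(model)
    states = np.empty((tree.n_nodes, root_length), dtype=np.int8)
    states[0] = rng.choice(20, size=root_length, p=freqs)
    for node in range(1, tree.n_nodes):
        t = float(tree.branch_length[node])
        if t == 0.0:
            states[node] = states[tree.parent(node)]
            continue
        p = _transition_matrix(q, t, model)
        cum = np.cumsum(p, axis=1)
        u = rng.random(root_length)
        rows = cum[states[tree.parent(node)]]
        states[node] = np.minimum((rows < u[:, None]).sum(axis=1), 19)
    aa = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
    return {leaf: aa[states[leaf]].tobytes().decode() for leaf in tree.leaves}


# ---------------------------------------------------------------------------
# Design

@dataclass
class SimFamily:
    """One simulated family: a tree instance, its target node and replicate.

    ``sequences`` (leaf id -> residues) is filled lazily by
    :func:`realize_family`; ``depth`` is the target node's depth (1 = child
    of the root). Fast leaves sit in the root-child subtree containing the
    target; the other leaves are slow.
    """

    family_id: str
    tree: SimTree
    target_node: int
    factor: float
    replicate: int
    depth: int
    fast_leaves: Tuple[int, ...]
    slow_leaves: Tuple[int, ...]
    root_length: int = 300
    sequences: Optional[Dict[int, str]] = None

    def sequence_id(self, leaf: int) -> str:
        return f"{self.family_id}.L{leaf}"

    def records(self, leaves: Iterable[int], source: str) -> List[SequenceRecord]:
        if self.sequences is None:
            raise ValueError(f"family {self.family_id} has no sequences; call realize_family")
        return [
            SequenceRecord(id=self.sequence_id(l), residues=self.sequences[l], source=source)
            for l in leaves
        ]

    def slow_records(self) -> List[SequenceRecord]:
        return self.records(self.slow_leaves, "seed")

    def fast_records(self) -> List[SequenceRecord]:
        return self.records(self.fast_leaves, "environmental")

    @property
    def fast_ids(self) -> frozenset:
        return frozenset(self.sequence_id(l) for l in self.fast_leaves)

    @property
    def slow_ids(self) -> frozenset:
        return frozenset(self.sequence_id(l) for l in self.slow_leaves)


def generate_design(
    n_leaves: int = 64,
    factors: Sequence[float] = FULL_FACTORS,
    replicates: int = 3,
    base_branch_length: Optional[float] = None,
    root_length: int = 300,
) -> List[SimFamily]:
    """Enumerate the full factorial design of simulated families.

    One family per (non-root target node, elongation factor, replicate):
    ``(2 * n_leaves - 2) * len(factors) * replicates`` families over
    ``(2 * n_leaves - 2) * len(factors)`` (non-unique) tree instances.
    ``base_branch_length`` defaults to the height-preserving value for
    ``n_leaves`` (see :func:`default_branch_length`). Sequences are not
    generated here (see :func:`realize_family`).
    """
    if base_branch_length is None:
        base_branch_length = default_branch_length(n_leaves)
    base = balanced_tree(n_leaves, base_branch_length)
    families = []
    for target in range(1, base.n_nodes):
        depth = SimTree.depth(target)
        fast_root = root_child_of(base, target)
        fast = tuple(l for l in base.leaves if root_child_of(base, l) == fast_root)
        slow = tuple(l for l in base.leaves if root_child_of(base, l) != fast_root)
        for factor in factors:
            tree = elongate_root_path(base, target, factor)
            for rep in range(1, replicates + 1):
                fam_id = f"N{target:03d}F{factor:g}R{rep}"
                families.append(
                    SimFamily(
                        family_id=fam_id,
                        tree=tree,
                        target_node=target,
                        factor=float(factor),
                        replicate=rep,
                        depth=depth,
                        fast_leaves=fast,
                        slow_leaves=slow,
                        root_length=root_length,
                    )
                )
    return families


def count_tree_instances(families: Sequence[SimFamily]) -> int:
    return len({(f.target_node, f.factor) for f in families})


def realize_family(family: SimFamily, model: str = "lg", master_seed: int = 0) -> SimFamily:
    """Generate the family's leaf sequences (deterministic per family id)."""
    rng = np.random.default_rng(derive_seed(master_seed, family.family_id))
    family.sequences = evolve_along_tree(
        family.tree, root_length=family.root_length, model=model, rng=rng
    )
    return family


def realize_all(families: Sequence[SimFamily], model: str = "lg", master_seed: int = 0) -> List[SimFamily]:
    for fam in families:
        realize_family(fam, model=model, master_seed=master_seed)
    return families


def pool_records(families: Sequence[SimFamily]) -> List[SequenceRecord]:
    """All sequences of all families with globally unique ids."""
    records = []
    for fam in families:
        records.extend(fam.slow_records())
        records.extend(fam.fast_records())
    return records


def truth_frame(families: Sequence[SimFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        for leaf in list(fam.slow_leaves) + list(fam.fast_leaves):
            rows.append(
                {
                    "sequence_id": fam.sequence_id(leaf),
                    "family": fam.family_id,
                    "side": "fast" if leaf in fam.fast_leaves else "slow",
                    "factor": fam.factor,
                    "depth": fam.depth,
                    "replicate": fam.replicate,
                }
            )
    return pd.DataFrame(rows, columns=["sequence_id", "family", "side", "factor", "depth", "replicate"])


# ---------------------------------------------------------------------------
# Benchmark

def score_retrieval(retrieved_ids: Iterable[str], family: SimFamily) -> RetrievalScore:
    """Precision and recall of one family's retrieval.

    Recall is true fast members retrieved over the fast-side size; precision
    is true fast members retrieved over everything retrieved, undefined
    (``None``) when nothing was retrieved. Seeds must not be in the set.
    """
    retrieved = set(retrieved_ids)
    if retrieved & set(family.slow_ids):
        raise ValueError("retrieved set contains seed sequences")
    true_pos = retrieved & set(family.fast_ids)
    recall = len(true_pos) / len(family.fast_leaves)
    precision = (len(true_pos) / len(retrieved)) if retrieved else None
    return RetrievalScore(
        factor=family.factor,
        depth=family.depth,
        replicate=family.replicate,
        precision=precision,
        recall=recall,
        n_retrieved=len(retrieved),
        n_false=len(retrieved) - len(true_pos),
    )


def run_benchmark(
    families: Sequence[SimFamily],
    scheme: Optional[ScoringScheme] = None,
    thresholds: Optional[Thresholds] = None,
    backend: str = "blast",
    pool_hits: Optional[pd.DataFrame] = None,
) -> Tuple[List[RetrievalScore], pd.DataFrame]:
    """Run the retrieval benchmark over realised families.

    The pooled all-against-all hit table is computed once (with the given
    backend) and served to every family's iterative search; each family's
    slow side seeds a search against the pool minus those seeds. Returns the
    per-family scores and the pooled hit table (reusable across calls).
    """
    scheme = scheme or protein_scheme()
    thresholds = thresholds or Thresholds()
    records = pool_records(families)
    if pool_hits is None:
        logger.info("benchmark: all-against-all over %d pooled sequences", len(records))
        pool_hits = search_all(records, records, scheme, thresholds, backend=backend)
    provider = precomputed_backend(pool_hits)
    scores = []
    for fam in families:
        seeds = fam.slow_records()
        slow = set(fam.slow_ids)
        env = [r for r in records if r.id not in slow]
        retrieved = iterative_search(
            seeds, env, scheme, thresholds, backend=provider, family_id=fam.family_id
        )
        scores.append(score_retrieval(retrieved.keys(), fam))
    return scores, pool_hits


def scores_frame(scores: Sequence[RetrievalScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": s.factor,
                "depth": s.depth,
                "replicate": s.replicate,
                "precision": s.precision,
                "recall": s.recall,
                "n_retrieved": s.n_retrieved,
                "n_false": s.n_false,
            }
            for s in scores
        ]
    )


def summarize_scores(scores: Sequence[RetrievalScore]) -> pd.DataFrame:
    """Median recall and pooled precision per (factor, depth)."""
    df = scores_frame(scores)
    return (
        df.groupby(["factor", "depth"])
        .agg(
            median_recall=("recall", "median"),
            mean_recall=("recall", "mean"),
            n_false=("n_false", "sum"),
            n_families=("recall", "size"),
        )
        .reset_index()
    )


def scaled_design() -> List[SimFamily]:
    """The scaled-down benchmark design for routine runs: 16 leaves,
    factors 1/2/4/8, 2 replicates, 150-residue sequences."""
    return generate_design(
        n_leaves=SCALED_N_LEAVES,
        factors=SCALED_FACTORS,
        replicates=SCALED_REPLICATES,
        root_length=SCALED_ROOT_LENGTH,
    )


def run_scaled_benchmark(
    master_seed: int,
    backend: str = "blast",
    model: str = "lg",
) -> Tuple[List[RetrievalScore], pd.DataFrame]:
    """Realise the scaled design at ``master_seed`` and run the benchmark;
    returns the per-family scores and their tabular form."""
    families = realize_all(scaled_design(), model=model, master_seed=master_seed)
    scores, _ = run_benchmark(families, backend=backend)
    return scores, scores_frame(scores)


# ---------------------------------------------------------------------------
# Calibration

def mean_pairwise_identity(sequences: Sequence[str]) -> float:
    """Mean pairwise identity (%) over all sequence pairs (equal lengths)."""
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in sequences]
    total, n = 0.0, 0
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            total += float(np.mean(arrs[i] == arrs[j]))
            n += 1
    return 100.0 * total / n


def calibrate_branch_length(
    target_identity: float = 42.7,
    n_leaves: int = 64,
    root_length: int = 300,
    model: str = "lg",
    n_replicates: int = 3,
    seed: int = 12345,
    lo: float = 0.02,
    hi: float = 0.5,
    tol: float = 0.2,
) -> float:
    """Bisect the uniform branch length so the slow-side mean pairwise
    identity of an unelongated family matches ``target_identity`` percent.

    The slow side of any family is one root-child subtree; identity is
    averaged over its leaves across ``n_replicates`` simulated trees.
    """

    def slow_identity(b: float) -> float:
        tree = balanced_tree(n_leaves, b)
        half = [l for l in tree.leaves if root_child_of(tree, l) == 1]
        vals = []
        for rep in range(n_replicates):
            leaves = evolve_along_tree(tree, root_length, model, seed=seed + rep)
            vals.append(mean_pairwise_identity([leaves[l] for l in half]))
        return float(np.mean(vals))

    for _ in range(25):
        mid = math.sqrt(lo * hi)
        ident = slow_identity(mid)
        if abs(ident - target_identity) < tol:
            return mid
        if ident > target_identity:  # too similar -> lengthen branches
            lo = mid
        else:
            hi = mid
    return mid
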