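"""Clustering of active compound profiles and annotation-term enrichment.

Active, annotated compound profiles are clustered agglomeratively with
cosine distance and single linkage; every internal node of the
dendrogram (n leaves -> n - 1 nodes) is a candidate cluster.  Each
(cluster, term) pair with at least one in-cluster occurrence of the term
is scored by a uniform-permutation null: the fraction of random
same-size subsets of the universe (active AND annotated compounds)
containing at least as many term carriers.  The matching hypergeometric
upper tail P(X >= m) is computed alongside as the exact limit of the
permutation fraction, and records are ranked by permutation fraction
(the fractions order clusters; they are not corrected or interpreted as
p-values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "node_id", "term", "k", "m", "M", "N",
    "perm_fraction", "exact_tail", "n_permutations", "seed",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterCandidate:
    """One non-leaf subtree: its node id and the compounds beneath it."""

    node_id: int
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Dendrogram:
    """Single-linkage tree over compound profiles.

    ``linkage`` is the (n-1, 4) SciPy linkage matrix; leaf i carries
    ``leaves[i]`` and internal node j (j >= n) is row j - n.
    """

    leaves: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if self.linkage.shape != (n - 1, 4):
            raise EnrichmentError(
                f"linkage shape {self.linkage.shape} inconsistent with {n} leaves"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def subtrees(self) -> list[ClusterCandidate]:
        """All internal nodes with their leaf sets (n - 1 candidates)."""
        n = len(self.leaves)
        members: list[frozenset[str]] = [frozenset([c]) for c in self.leaves]
        out: list[ClusterCandidate] = []
        for i, (a, b, _h, _c) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members.append(merged)
            out.append(ClusterCandidate(node_id=n + i, members=merged))
        return out

    def to_newick(self) -> str:
        """Newick string with merge heights encoded as branch lengths."""
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for i, (a, b, h, _c) in enumerate(self.linkage):
            height[n + i] = float(h)
            children[n + i] = (int(a), int(b))

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{self.leaves[node]}:{bl:.10g}"
            a, b = children[node]
            h = height[node]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        root = n + len(self.linkage) - 1
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"


def cosine_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distances 1 - u.v/(|u||v|) between profile rows.

    ``profiles`` is indexed by compound id with feature columns.  A
    zero-norm profile has no direction and is rejected by name.
    """
    X = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        names = [str(profiles.index[i]) for i in bad]
        raise EnrichmentError(f"zero-norm profile(s): {names}")
    D = squareform(pdist(X, metric="cosine"))
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


def cluster_profiles(distances: pd.DataFrame) -> Dendrogram:
    """Single-linkage agglomerative clustering of a distance matrix."""
    n = len(distances)
    if n < 2:
        raise EnrichmentError(f"clustering needs >=2 profiles, got {n}")
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    Z = linkage(condensed, method="single")
    return Dendrogram(leaves=[str(i) for i in distances.index], linkage=Z)


def enumerate_clusters(tree: Dendrogram) -> list[ClusterCandidate]:
    """Candidate clusters: one per non-leaf subtree of the dendrogram."""
    return tree.subtrees()


def sample_uniform_clusters(
    n_universe: int, k: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_permutations, k) index array of uniform size-k subsets, drawn
    without replacement within each subset."""
    if not (1 <= k <= n_universe):
        raise EnrichmentError(f"cluster size {k} outside [1, {n_universe}]")
    if k == n_universe:
        return np.tile(np.arange(n_universe), (n_permutations, 1))
    X = rng.random((n_permutations, n_universe))
    return np.argpartition(X, k - 1, axis=1)[:, :k]


def score_enrichment(
    clusters: list[ClusterCandidate],
    annotations: pd.DataFrame,
    universe: list[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation + exact enrichment of every observed (cluster, term) pair.

    For a cluster of size k containing m >= 1 carriers of a term carried
    by M of the N universe compounds, ``perm_fraction`` is the fraction
    of ``n_permutations`` uniform size-k subsets of the universe with at
    least m carriers, and ``exact_tail`` the hypergeometric upper tail
    P(X >= m | N, M, k).  Terms with no carrier in the universe are
    skipped with a warning; pairs with m = 0 are not scored.  Subset
    draws are shared across terms for a given cluster size and seeded
    per (seed, k), so results do not depend on cluster order.
    """
    universe = list(universe)
    N = len(universe)
    if N == 0:
        raise EnrichmentError("empty universe")
    index = {cid: i for i, cid in enumerate(universe)}
    ann = annotations.loc[annotations["compound_id"].isin(index)]
    skipped = sorted(set(annotations["term"]) - set(ann["term"]))
    if skipped:
        logger.warning(
            "%d term(s) have no carrier in the universe and are skipped: %s",
            len(skipped), skipped[:10],
        )
    term_members: dict[str, np.ndarray] = {}
    for term, grp in ann.groupby("term"):
        mask = np.zeros(N, dtype=bool)
        mask[[index[c] for c in grp["compound_id"]]] = True
        term_members[term] = mask

    subsets_by_k: dict[int, np.ndarray] = {}
    counts_cache: dict[tuple[int, str], np.ndarray] = {}
    rows = []
    for cand in clusters:
        extra = cand.members - set(universe)
        if extra:
            raise EnrichmentError(
                f"cluster node {cand.node_id} contains compounds outside the "
                f"universe: {sorted(extra)[:5]}"
            )
        k = cand.size
        member_idx = np.zeros(N, dtype=bool)
        member_idx[[index[c] for c in cand.members]] = True
        if k not in subsets_by_k:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
            subsets_by_k[k] = sample_uniform_clusters(N, k, n_permutations, rng)
        subsets = subsets_by_k[k]
        for term in sorted(term_members):
            mask = term_members[term]
            m = int((mask & member_idx).sum())
            if m == 0:
                continue
            key = (k, term)
            if key not in counts_cache:
                counts_cache[key] = mask[subsets].sum(axis=1)
            counts = counts_cache[key]
            M = int(mask.sum())
            rows.append(
                {
                    "node_id": cand.node_id,
                    "term": term,
                    "k": k,
                    "m": m,
                    "M": M,
                    "N": N,
                    "perm_fraction": float((counts >= m).mean()),
                    "exact_tail": float(hypergeom.sf(m - 1, N, M, k)),
                    "n_permutations": n_permutations,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def rank_clusters(records: pd.DataFrame) -> pd.DataFrame:
    """Rank ascending by permutation fraction; deterministic tie-breaks.

    Ties are broken by larger in-cluster count m, then smaller exact
    tail, then node id and term.  No multiple-testing correction is
    applied: the fractions serve only to order the clusters.
    """
    if records.empty:
        raise EnrichmentError("no enrichment records to rank")
    out = records.sort_values(
        by=["perm_fraction", "m", "exact_tail", "node_id", "term"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
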