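"""Rarefaction, alpha diversity (Shannon, Faith PD), weighted UniFrac, PCoA.

Conventions: Shannon entropy is reported in nats; Faith's phylogenetic
diversity includes the path to the tree root by default; weighted UniFrac is
the raw (non-normalised) variant unless ``normalized=True``; PCoA reports
negative eigenvalues but embeds only the positive ones, with no Cailliez or
Lingoes correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io_formats import CountTable, check_taxa_in_tree
from .stratified_permanova import gower_center

DEFAULT_RAREFACTION_DEPTH = 10_000


def _branch_table(tree: TreeNode, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and taxon-descendancy indicators for every non-root edge.

    Returns ``(lengths, membership)`` where ``membership[t, b]`` is True when
    taxon ``t`` descends from branch ``b``. Computed in a single postorder
    pass; any tree shape (including multifurcations and star trees) is
    accepted as long as every taxon maps to exactly one leaf.
    """
    check_taxa_in_tree(list(taxa), tree)
    pos = {t: i for i, t in enumerate(taxa)}
    lengths: list[float] = []
    columns: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            ind = np.zeros(len(taxa), dtype=bool)
            if node.name in pos:
                ind[pos[node.name]] = True
        else:
            ind = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                ind |= below[id(child)]
        below[id(node)] = ind
        if node.parent is not None:
            lengths.append(float(node.length or 0.0))
            columns.append(ind)
    return np.asarray(lengths), np.asarray(columns).T


def rarefy(
    table: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0
) -> tuple[CountTable, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` counts.

    Samples whose total is below ``depth`` are excluded and returned in the
    second element; exclusion is a reported outcome, not an error. A single
    draw is taken per sample (no averaging over draws), deterministic under
    ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept_ids, kept_rows, excluded = [], [], []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            excluded.append(sid)
            continue
        row = table.counts[i]
        if totals[i] == depth:
            kept_rows.append(row.copy())
        else:
            kept_rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    counts = (
        np.array(kept_rows, dtype=np.int64)
        if kept_rows
        else np.zeros((0, table.n_taxa), dtype=np.int64)
    )
    return CountTable(kept_ids, list(table.taxon_ids), counts), excluded


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats, over taxa with p_i > 0."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("shannon expects a single-sample 1-D count vector")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has undefined Shannon entropy")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def faith_pd(present_taxa, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a taxon set.

    Sum of branch lengths of the union of root-to-leaf paths over the
    present taxa. With ``include_root=False`` the path from the root down to
    the lowest common ancestor of the set is excluded (the minimal spanning
    subtree of the leaves).
    """
    present = list(dict.fromkeys(present_taxa))
    if not present:
        raise ValueError("present_taxa must be non-empty")
    lengths, membership = _branch_table(tree, present)
    n_desc = membership.sum(axis=0)
    support = n_desc > 0
    if not include_root:
        # branches above the LCA of the set have every present taxon below them
        support &= n_desc < len(present)
    return float(lengths[support].sum())


def weighted_unifrac(
    a: np.ndarray,
    b: np.ndarray,
    taxa: list[str],
    tree: TreeNode,
    normalized: bool = False,
) -> float:
    """Weighted UniFrac between two count vectors over the same taxon list.

    d = sum over branches of l_b * |p_a(b) - p_b(b)|, where p_x(b) is the
    fraction of sample x's counts descending from branch b. Raw by default;
    ``normalized=True`` divides by the abundance-weighted maximum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) != len(taxa):
        raise ValueError("count vectors must be 1-D and aligned with taxa")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("weighted UniFrac is undefined for an empty sample")
    lengths, membership = _branch_table(tree, list(taxa))
    pa = (a / a.sum()) @ membership
    pb = (b / b.sum()) @ membership
    d = float(lengths @ np.abs(pa - pb))
    if normalized:
        denom = float(lengths @ (pa + pb))
        return d / denom if denom > 0 else 0.0
    return d


def pairwise_weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """All-pairs weighted UniFrac distance matrix for a (rarefied) table."""
    if table.n_samples == 0:
        raise ValueError("empty count table")
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    lengths, membership = _branch_table(tree, list(table.taxon_ids))
    P = (table.counts / totals[:, None]) @ membership  # samples x branches
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(P[i + 1 :] - P[i]) @ lengths
        if normalized:
            denom = (P[i + 1 :] + P[i]) @ lengths
            diff = np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(d, ids=list(table.sample_ids))


def alpha_diversity_table(table: CountTable, tree: TreeNode) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Faith PD for a (rarefied) count table."""
    lengths, membership = _branch_table(tree, list(table.taxon_ids))
    rows = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        support = (counts > 0) @ membership > 0
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon(counts),
                "faith_pd": float(lengths[support].sum()),
            }
        )
    return pd.DataFrame(rows)


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=True)))


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) output.

    ``eigenvalues`` holds the full descending spectrum (negative values
    reported, not embedded); ``coordinates`` and ``proportion_explained``
    cover the positive axes only, with proportions relative to the sum of
    positive eigenvalues.
    """

    sample_ids: list[str]
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    proportion_explained: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        axes = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        coords = pd.DataFrame(self.coordinates, index=self.sample_ids, columns=axes)
        coords.index.name = "sample_id"
        eig = pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "proportion_explained": np.concatenate(
                    [
                        self.proportion_explained,
                        np.full(len(self.eigenvalues) - len(self.proportion_explained), np.nan),
                    ]
                ),
            }
        )
        return eig, coords


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by eigendecomposition of -1/2 J D^2 J."""
    n = dm.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    G = gower_center(dm)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum()
    return OrdinationResult(
        sample_ids=list(dm.ids),
        eigenvalues=eigvals,
        coordinates=coords,
        proportion_explained=prop,
    )
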