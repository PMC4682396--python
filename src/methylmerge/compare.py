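"""Multi-sample comparison: block binning, rank-correlation distances,
hierarchical clustering, Newick export.

Samples (each a set of integrated or single-mapper calls) are binned into
fixed-size genomic blocks (10 kb by default); each block's level is the
unweighted mean of its covered cytosines of one context class.  Pairwise
sample distance is 1 − Spearman ρ over blocks present in both samples, and
the resulting matrix is clustered agglomeratively (UPGMA by default).
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from methylmerge.errors import UsageError
from methylmerge.evaluate import calls_to_level_frame

LINKAGES = ("single", "complete", "average")


def bin_methylation(
    calls,
    block_size: int = 10_000,
    context: str = "CG",
    method: str = "wave",
    min_depth: int = 1,
) -> pd.Series:
    """One sample's column: mean level per (chrom, block) bin.

    Bins tile each chromosome in 1-based inclusive coordinates: positions
    1..block_size fall in bin 0, block_size+1..2·block_size in bin 1, and
    so on.  Bins with no covered cytosine of the context are absent (they
    become missing when columns are aligned across samples).
    """
    if block_size < 1:
        raise UsageError("block_size must be >= 1")
    frame = calls_to_level_frame(calls, method=method)
    frame = frame[(frame["context"] == context) & (frame["depth"] >= min_depth)]
    if frame.empty:
        return pd.Series(dtype=float)
    binned = (
        frame.assign(block=(frame["pos"] - 1) // block_size)
        .groupby(["chrom", "block"])["level"]
        .mean()
    )
    binned.index = [f"{c}:{b}" for c, b in binned.index]
    return binned


def build_sample_matrix(columns: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Align per-sample binned columns into a blocks × samples matrix
    (NaN marks blocks a sample did not cover)."""
    if not columns:
        raise UsageError("need at least one sample")
    return pd.DataFrame(dict(columns))


def spearman_distance_matrix(
    matrix: pd.DataFrame, complete_only: bool = False
) -> pd.DataFrame:
    """Pairwise 1 − Spearman ρ between sample columns.

    By default each pair uses its pairwise-complete blocks (blocks missing
    in either sample are dropped for that pair); ``complete_only=True``
    first restricts to blocks covered in every sample.
    """
    if matrix.shape[1] < 2:
        raise UsageError("need at least two samples")
    if complete_only:
        matrix = matrix.dropna(axis=0)
    samples = list(matrix.columns)
    dist = pd.DataFrame(0.0, index=samples, columns=samples)
    for a, b in itertools.combinations(samples, 2):
        pair = matrix[[a, b]].dropna()
        if len(pair) < 2:
            raise UsageError(f"samples {a!r} and {b!r} share fewer than two covered blocks")
        rho = stats.spearmanr(pair[a], pair[b]).statistic
        dist.loc[a, b] = dist.loc[b, a] = 1.0 - float(rho)
    return dist


def hierarchical_cluster(distmat: pd.DataFrame, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns the SciPy linkage matrix; leaves are ``distmat``'s row order.
    Average linkage (UPGMA) is the default.
    """
    if linkage not in LINKAGES:
        raise UsageError(f"linkage must be one of {LINKAGES}")
    d = distmat.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise UsageError("distance matrix must be square and symmetric")
    return hierarchy.linkage(squareform(d, checks=False), method=linkage)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick string.

    Branch lengths place each merge at half its merge height (ultrametric
    convention for UPGMA trees), leaves at height zero.
    """
    tree = hierarchy.to_tree(Z)

    def height(node) -> float:
        return node.dist / 2.0

    def render(node, parent_h: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_h:.10g}"
        h = height(node)
        left = render(node.left, h)
        right = render(node.right, h)
        return f"({left},{right}):{parent_h - h:.10g}"

    root_h = height(tree)
    inner = f"({render(tree.left, root_h)},{render(tree.right, root_h)})"
    return inner + ";"


def cut_two_clusters(Z: np.ndarray, labels: Sequence[str]) -> tuple[frozenset, frozenset]:
    """Partition the samples into the two top-level clusters of the tree."""
    assignments = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    g1 = frozenset(l for l, a in zip(labels, assignments) if a == 1)
    g2 = frozenset(l for l, a in zip(labels, assignments) if a == 2)
    return g1, g2


def correlation_report(
    matrix: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman ρ for requested sample pairs (pairwise-complete blocks)."""
    rows = []
    for a, b in pairs:
        pair = matrix[[a, b]].dropna()
        if len(pair) < 2:
            raise UsageError(f"samples {a!r} and {b!r} share fewer than two covered blocks")
        rho = float(stats.spearmanr(pair[a], pair[b]).statistic)
        rows.append({"sample_a": a, "sample_b": b, "spearman_rho": rho, "n_blocks": len(pair)})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "spearman_rho", "n_blocks"])
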