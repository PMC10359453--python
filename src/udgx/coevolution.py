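"""Pairwise column covariation: mutual information, chi-square, phi, trees.

Re-implements the coevolution metrics commonly offered by web servers for
alignment covariation analysis: mutual information (bits), the chi-square
statistic of the residue contingency table, a Pearson correlation between
consensus-residue indicators (the phi coefficient), and joint Shannon
entropy.  A symmetric score matrix over chosen reference positions can be
turned into an average-linkage clustering tree (Newick) of co-varying
positions.

Gap handling is pairwise deletion throughout: a sequence contributes to a
pair of columns iff it holds a countable residue at both.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

from ._alphabet import GAP, UNKNOWN
from .conservation import column_profile, joint_entropy
from .exceptions import InsufficientDataError
from .msa import Msa, ReferenceMap

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "CoevolutionMatrix",
    "pair_contingency",
    "mutual_information",
    "chi_square_stat",
    "consensus_phi",
    "coevolution_matrix",
    "cluster_tree",
    "METRICS",
]

METRICS = ("mi", "chi2", "phi", "joint_entropy")


@dataclass(frozen=True)
class ContingencyTable:
    """Joint residue counts of two alignment columns (pairwise deletion)."""

    residues_i: tuple[str, ...]
    residues_j: tuple[str, ...]
    counts: np.ndarray  # shape (len(residues_i), len(residues_j)), ints

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def pair_contingency(msa: Msa, col_i: int, col_j: int) -> ContingencyTable:
    """Contingency table of residues at two 1-based alignment columns.

    Only sequences countable at both columns contribute.  Raises
    :class:`InsufficientDataError` when fewer than 2 sequences remain.
    """
    ci, cj = msa.column(col_i), msa.column(col_j)
    pairs: dict[tuple[str, str], int] = {}
    for a, b in zip(ci, cj):
        if a in (GAP, UNKNOWN) or b in (GAP, UNKNOWN):
            continue
        pairs[(a, b)] = pairs.get((a, b), 0) + 1
    n = sum(pairs.values())
    if n < 2:
        raise InsufficientDataError(
            f"columns {col_i},{col_j}: only {n} jointly countable sequences"
        )
    res_i = tuple(sorted({a for a, _ in pairs}))
    res_j = tuple(sorted({b for _, b in pairs}))
    counts = np.zeros((len(res_i), len(res_j)), dtype=np.int64)
    for (a, b), c in pairs.items():
        counts[res_i.index(a), res_j.index(b)] = c
    return ContingencyTable(res_i, res_j, counts)


def mutual_information(table: ContingencyTable) -> float:
    """Mutual information in bits: sum p(a,b) log2[p(a,b) / (p(a) p(b))].

    Zero joint counts contribute nothing; the result is >= 0 up to floating
    rounding (clipped at 0).
    """
    n = table.n
    p = table.counts / n
    pi = table.row_margins / n
    pj = table.col_margins / n
    mi = 0.0
    for a in range(p.shape[0]):
        for b in range(p.shape[1]):
            if p[a, b] > 0.0:
                mi += p[a, b] * math.log2(p[a, b] / (pi[a] * pj[b]))
    return max(mi, 0.0)


def chi_square_stat(table: ContingencyTable) -> tuple[float, int]:
    """Pearson chi-square statistic and degrees of freedom of the table.

    dof = (r - 1)(c - 1) over observed categories; a degenerate table with a
    single row or column has statistic 0 and dof 0.  No continuity
    correction.
    """
    r, c = table.counts.shape
    if r < 2 or c < 2:
        return 0.0, 0
    stat, _p, dof, _exp = chi2_contingency(table.counts, correction=False)
    return float(stat), int(dof)


def consensus_phi(msa: Msa, col_i: int, col_j: int) -> float:
    """Phi coefficient between consensus-indicator vectors of two columns.

    For each sequence countable at both columns, the indicator is 1 iff it
    carries the column's consensus residue.  This is the Pearson
    correlation of the two binary vectors.  Returns ``nan`` (with a logged
    warning) when either indicator has zero variance.
    """
    cons_i = column_profile(msa, col_i).consensus
    cons_j = column_profile(msa, col_j).consensus
    if cons_i is None or cons_j is None:
        raise InsufficientDataError(f"columns {col_i},{col_j}: no countable residues")
    ci, cj = msa.column(col_i), msa.column(col_j)
    xi, xj = [], []
    for a, b in zip(ci, cj):
        if a in (GAP, UNKNOWN) or b in (GAP, UNKNOWN):
            continue
        xi.append(1.0 if a == cons_i[0] else 0.0)
        xj.append(1.0 if b == cons_j[0] else 0.0)
    if len(xi) < 2:
        raise InsufficientDataError(
            f"columns {col_i},{col_j}: only {len(xi)} jointly countable sequences"
        )
    vi, vj = np.asarray(xi), np.asarray(xj)
    if vi.std() == 0.0 or vj.std() == 0.0:
        logger.warning("columns %d,%d: zero-variance consensus indicator; phi undefined",
                       col_i, col_j)
        return float("nan")
    return float(np.corrcoef(vi, vj)[0, 1])


@dataclass(frozen=True)
class CoevolutionMatrix:
    """Symmetric pairwise score matrix over reference positions."""

    metric: str
    positions: tuple[int, ...]
    scores: pd.DataFrame  # index/columns = positions

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {METRICS}")

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy()

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


def _pair_score(msa: Msa, ci: int, cj: int, metric: str) -> float:
    if metric == "mi":
        return mutual_information(pair_contingency(msa, ci, cj))
    if metric == "chi2":
        return chi_square_stat(pair_contingency(msa, ci, cj))[0]
    if metric == "phi":
        return consensus_phi(msa, ci, cj)
    if metric == "joint_entropy":
        return joint_entropy(msa, ci, cj)
    raise ValueError(f"unknown metric {metric!r}")


def coevolution_matrix(
    msa: Msa,
    refmap: ReferenceMap,
    positions: Sequence[int],
    metric: str = "mi",
    apc: bool = False,
) -> CoevolutionMatrix:
    """Symmetric matrix of a covariation metric over reference positions.

    Diagonal entries are the metric applied to a column with itself: for
    ``mi`` and ``joint_entropy`` that is the column entropy H(i); for
    ``phi`` it is 1.  Per-pair failures (insufficient data, undefined phi)
    become ``nan`` entries with a logged warning.

    With ``apc=True`` the average-product correction is subtracted from the
    off-diagonal MI scores (off by default: the published analysis uses raw
    scores).
    """
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    pos = tuple(int(p) for p in positions)
    cols = {p: refmap.col_for(p) for p in pos}
    k = len(pos)
    m = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            try:
                s = _pair_score(msa, cols[pos[a]], cols[pos[b]], metric)
            except InsufficientDataError as exc:
                logger.warning("pair (%d, %d): %s", pos[a], pos[b], exc)
                s = float("nan")
            m[a, b] = m[b, a] = s
    if apc and metric == "mi":
        off = ~np.eye(k, dtype=bool)
        mean_all = m[off].mean()
        mean_i = np.array([m[i, off[i]].mean() for i in range(k)])
        if mean_all > 0:
            corr = np.outer(mean_i, mean_i) / mean_all
            m = np.where(off, m - corr, m)
    df = pd.DataFrame(m, index=pos, columns=pos)
    return CoevolutionMatrix(metric=metric, positions=pos, scores=df)


def _linkage_to_newick(node: hierarchy.ClusterNode, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return str(labels[node.id])
    parts = []
    for child in (node.left, node.right):
        sub = _linkage_to_newick(child, labels)
        bl = max(node.dist - child.dist, 0.0)
        parts.append(f"{sub}:{bl:.6g}")
    return "(" + ",".join(parts) + ")"


def cluster_tree(matrix: CoevolutionMatrix) -> str:
    """Average-linkage clustering tree of positions, as a Newick string.

    Scores are converted to distances ``d = 1 - s / max(s)`` over the
    off-diagonal entries (for phi, the absolute score is used), so the most
    strongly co-varying pair has distance 0.  Deterministic given the input
    matrix; ties are resolved by position order.
    """
    if matrix.has_missing():
        raise ValueError("score matrix contains missing entries; cannot cluster")
    k = len(matrix.positions)
    if k < 2:
        raise ValueError("need at least 2 positions to cluster")
    s = matrix.values.astype(float).copy()
    if matrix.metric == "phi":
        s = np.abs(s)
    off = ~np.eye(k, dtype=bool)
    smax = s[off].max()
    if matrix.metric == "joint_entropy":
        # low joint entropy = strong co-conservation: use the score directly
        d = s / smax if smax > 0 else np.zeros_like(s)
    else:
        d = 1.0 - s / smax if smax > 0 else np.zeros_like(s)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # squareform checks symmetry itself
        condensed = squareform(d, checks=False)
    z = hierarchy.average(condensed)
    root = hierarchy.to_tree(z)
    labels = [str(p) for p in matrix.positions]
    return _linkage_to_newick(root, labels) + ";"
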