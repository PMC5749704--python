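"""Diversity analysis: PIC, simple-matching distances, Ward/NJ trees, PAV.

Per-locus variability is the polymorphism information content
``PIC = 1 - sum_i p_i**2`` over the allele frequencies ``p_i``.  Pairwise
accession dissimilarity is the simple-matching distance (fraction of
mismatching loci among loci where both accessions are called), clustered
with a Ward dendrogram and a neighbor-joining tree.  Null-allele (OTV) loci
additionally support presence/absence-variation (PAV) analysis: an OO call
means the probe target is absent from that accession's genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from polyarray.signal_model import CALL_AA, CALL_AB, CALL_BB, CALL_NN, CALL_OO


def allele_frequencies(calls) -> np.ndarray:
    """A/B allele frequencies from a column of genotype calls.

    AA contributes two A alleles, AB one of each, BB two B.  NN is excluded;
    OO is excluded too (the null allele is neither A nor B — it enters the
    PAV analysis instead).  Raises on an all-missing column.
    """
    calls = np.asarray(calls, dtype=object)
    n_aa = int(np.sum(calls == CALL_AA))
    n_ab = int(np.sum(calls == CALL_AB))
    n_bb = int(np.sum(calls == CALL_BB))
    total = 2 * (n_aa + n_ab + n_bb)
    if total == 0:
        raise ValueError("no informative (AA/AB/BB) calls in column")
    a = (2 * n_aa + n_ab) / total
    freqs = np.array([f for f in (a, 1.0 - a) if f > 0.0])
    return freqs


def pic(spectrum) -> float:
    """Polymorphism information content, ``1 - sum(p_i**2)``.

    ``spectrum`` must sum to 1 (tolerance 1e-9).  0 for a monomorphic locus;
    at most ``1 - 1/n`` for ``n`` alleles.
    """
    p = np.asarray(spectrum, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p * p))


def pic_per_locus(matrix: pd.DataFrame) -> pd.Series:
    """PIC for every locus (column) of a genotype matrix.

    Loci with no informative calls get NaN.
    """
    out = {}
    for locus in matrix.columns:
        try:
            out[locus] = pic(allele_frequencies(matrix[locus].to_numpy()))
        except ValueError:
            out[locus] = np.nan
    return pd.Series(out, name="pic")


_ENCODING = {CALL_AA: 0, CALL_AB: 1, CALL_BB: 2, CALL_OO: 3, CALL_NN: -1}


def simple_matching_distance(
    matrix: pd.DataFrame,
    otv_mode: str = "fourth_state",
):
    """Pairwise simple-matching dissimilarities.

    For each pair of samples the distance is the fraction of mismatching
    loci among loci where both are called (pairwise-complete handling of
    missing data).  ``otv_mode`` controls null-allele calls: as a
    ``"fourth_state"`` (default; OO mismatches AA/AB/BB and matches OO) or
    as ``"missing"`` (OO treated like NN).

    Returns ``(dist, n_compared)``: square DataFrames of distances and of
    the per-pair compared-locus counts.  Pairs with zero compared loci get
    distance NaN.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if otv_mode not in ("fourth_state", "missing"):
        raise ValueError(f"unknown otv_mode: {otv_mode}")
    enc = _ENCODING.copy()
    if otv_mode == "missing":
        enc[CALL_OO] = -1
    codes = matrix.apply(lambda col: col.map(enc)).to_numpy(dtype=float)
    codes = np.nan_to_num(codes, nan=-1.0)
    n = codes.shape[0]
    dist = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        valid = (codes[i] >= 0) & (codes[i + 1 :] >= 0)
        mismatch = valid & (codes[i] != codes[i + 1 :])
        nc = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(nc > 0, mismatch.sum(axis=1) / np.maximum(nc, 1), np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        counts[i, i + 1 :] = nc
        counts[i + 1 :, i] = nc
    labels = list(matrix.index)
    return (
        pd.DataFrame(dist, index=labels, columns=labels),
        pd.DataFrame(counts, index=labels, columns=labels),
    )


@dataclass
class TreeResult:
    """A constructed tree: Newick string plus the method-native object."""

    newick: str
    method: str
    linkage: np.ndarray | None = None  # Ward only
    tree: object | None = None  # skbio TreeNode for NJ

    @property
    def labels(self) -> list:
        import re

        toks = re.findall(r"[('),]([^('),:]+):", self.newick)
        return [t.strip().strip("'") for t in toks]


def _check_distance(dist: pd.DataFrame):
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def _linkage_to_newick(Z: np.ndarray, labels) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_quote(labels[node.id])}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = rec(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"


def _quote(label: str) -> str:
    label = str(label)
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def ward_cluster(dist: pd.DataFrame) -> TreeResult:
    """Agglomerative hierarchy under Ward's minimum-variance criterion.

    Uses the Lance–Williams recurrence on the supplied dissimilarities
    (scipy ``linkage(method="ward")``); merge heights are guaranteed
    non-decreasing.  Returns the dendrogram as a Newick tree with branch
    lengths derived from merge heights.
    """
    d = _check_distance(dist)
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    return TreeResult(
        newick=_linkage_to_newick(Z, list(dist.index)),
        method="ward",
        linkage=Z,
    )


def nj_tree(dist: pd.DataFrame) -> TreeResult:
    """Saitou–Nei neighbor joining.

    On an additive (tree-metric) input the generating topology and branch
    lengths are recovered exactly.  Negative branch lengths are clamped to 0
    with the length transferred to the sibling branch (standard practice,
    as implemented by scikit-bio).
    """
    d = _check_distance(dist)
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    dm = _SkbioDM(d, ids=[str(x) for x in dist.index])
    tree = _skbio_nj(dm)
    newick = tree.__str__().strip()
    return TreeResult(newick=newick, method="nj", tree=tree)


def otv_pav_matrix(matrix: pd.DataFrame, categories) -> pd.DataFrame:
    """Presence/absence matrix from null-allele (OTV) loci.

    Restricts to loci categorised OTV, drops any locus with a missing (NN)
    call, and encodes OO as 0 (target absent) and every called genotype as
    1 (present).  Returns an empty frame (with a warning) when no locus
    qualifies.
    """
    cats = pd.Series(categories)
    otv_loci = [loc for loc in matrix.columns if cats.get(loc) == "OTV"]
    keep = [loc for loc in otv_loci if not (matrix[loc] == CALL_NN).any()]
    if not keep:
        import warnings

        warnings.warn("no OTV loci without missing data; PAV matrix is empty")
        return pd.DataFrame(index=matrix.index)
    sub = matrix[keep]
    return (sub != CALL_OO).astype(int)
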