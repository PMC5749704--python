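"""Mapping-population marker filtering, cosegregation bins, map summaries.

A biparental recombinant-inbred population segregates 1:1 for the two
parental alleles at a well-behaved marker.  Before map construction,
markers are filtered: they must be PHR and diploidized on the array, both
parents must be called, homozygous and opposite, missing data must not
exceed 15%, and the 1:1 segregation must not be rejected by a chi-square
test at P <= 0.01.  Markers with identical segregation patterns collapse
into cosegregation bins (one genetic position each); per-chromosome map
summaries report marker counts, map length, unique positions, non-redundant
markers and mean bin length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from polyarray.signal_model import CALL_AA, CALL_AB, CALL_BB, CALL_NN


@dataclass
class SegregationCounts:
    """Genotype tallies for one marker in a biparental inbred population."""

    n_A: int
    n_B: int
    n_het: int = 0
    n_missing: int = 0

    def __post_init__(self):
        if min(self.n_A, self.n_B, self.n_het, self.n_missing) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_A + self.n_B + self.n_het + self.n_missing


def segregation_chi_square(counts: SegregationCounts):
    """One-df chi-square of the homozygote counts against a 1:1 ratio.

    Heterozygous and missing individuals are excluded (residual heterozygotes
    carry no information about allele transmission bias here).  No continuity
    correction, matching the conventional marker-distortion test.

    Returns ``(statistic, p_value)``.
    """
    n = counts.n_A + counts.n_B
    if n == 0:
        raise ValueError("no informative homozygous genotypes")
    stat, p = stats.chisquare([counts.n_A, counts.n_B])
    return float(stat), float(p)


@dataclass
class MarkerFilterReport:
    marker: str
    kept: bool
    rejection_reasons: list = field(default_factory=list)
    chi2_p: float = np.nan


@dataclass
class MappingThresholds:
    max_missing: float = 0.15
    distortion_alpha: float = 0.01


def filter_mapping_markers(
    matrix: pd.DataFrame,
    categories,
    parents=("P1", "P2"),
    diploidized=None,
    thresholds: MappingThresholds | None = None,
) -> list:
    """Apply the mapping-marker filters; all violated reasons are recorded.

    Parameters
    ----------
    matrix : samples x markers genotype matrix including the two parent rows.
    categories : mapping (or Series) marker -> array category; PHR required.
    parents : the two parent row labels; both must be called, homozygous and
        opposite at a kept marker.
    diploidized : optional mapping marker -> bool; when given, diploidization
        is required (the array-side criterion HomRO > 0.3 and HomFLD > 10).
    thresholds : missing-fraction cap (0.15) and distortion alpha (0.01).

    Returns one :class:`MarkerFilterReport` per marker;
    ``kept`` iff ``rejection_reasons`` is empty.
    """
    t = thresholds or MappingThresholds()
    p1, p2 = parents
    for p in parents:
        if p not in matrix.index:
            raise ValueError(f"parent row {p!r} absent from matrix")
    cats = pd.Series(categories) if not isinstance(categories, pd.Series) else categories
    dip = pd.Series(diploidized) if diploidized is not None else None
    progeny = matrix.drop(index=list(parents))

    reports = []
    for marker in matrix.columns:
        reasons = []
        if cats.get(marker) != "PHR":
            reasons.append("not_PHR")
        if dip is not None and not bool(dip.get(marker, False)):
            reasons.append("not_diploidized")
        g1, g2 = matrix.at[p1, marker], matrix.at[p2, marker]
        homs = {CALL_AA, CALL_BB}
        if g1 not in homs or g2 not in homs or g1 == g2:
            reasons.append("parent_missing_or_het")
        col = progeny[marker]
        miss_frac = float((col == CALL_NN).mean())
        if miss_frac > t.max_missing:
            reasons.append("excess_missing")
        n_a = int((col == CALL_AA).sum())
        n_b = int((col == CALL_BB).sum())
        pval = np.nan
        if n_a + n_b > 0:
            _, pval = segregation_chi_square(SegregationCounts(n_a, n_b))
            if pval <= t.distortion_alpha:
                reasons.append("distorted")
        else:
            reasons.append("distorted")  # no informative genotypes to test
        reports.append(
            MarkerFilterReport(
                marker=marker, kept=not reasons, rejection_reasons=reasons, chi2_p=pval
            )
        )
    return reports


@dataclass
class CosegregationBin:
    members: list
    representative: str
    pairwise_identical: bool = True


def cosegregation_bins(matrix: pd.DataFrame) -> list:
    """Group markers with identical segregation patterns.

    Two markers are compatible when their genotype columns agree at every
    individual where both are non-missing.  Missing-tolerant equality is not
    transitive, so bins are the single-linkage transitive closure of the
    compatibility relation; bins whose members are not pairwise compatible
    are flagged (``pairwise_identical=False``).  The representative is the
    member with the fewest missing calls, ties broken by identifier order.
    """
    markers = list(matrix.columns)
    m = len(markers)
    if m == 0:
        raise ValueError("need at least 1 marker")
    enc = {CALL_AA: 0, CALL_AB: 1, CALL_BB: 2, "OO": 3, CALL_NN: -1}
    codes = matrix.apply(lambda col: col.map(enc)).to_numpy(dtype=np.int8).T  # markers x ind

    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    valid = codes >= 0
    for i in range(m):
        vi, ci = valid[i], codes[i]
        both = vi & valid[i + 1 :]
        conflict = both & (ci != codes[i + 1 :])
        compatible = ~conflict.any(axis=1)
        for off in np.nonzero(compatible)[0]:
            union(i, i + 1 + off)

    groups: dict = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)

    bins = []
    for idxs in groups.values():
        names = sorted((markers[i] for i in idxs), key=str)
        n_missing = {markers[i]: int((~valid[i]).sum()) for i in idxs}
        rep = min(names, key=lambda nm: (n_missing[nm], str(nm)))
        pairwise = True
        if len(idxs) > 2:
            for a in range(len(idxs)):
                ia = idxs[a]
                va, ca = valid[ia], codes[ia]
                sub = idxs[a + 1 :]
                both = va & valid[sub]
                if (both & (ca != codes[sub])).any():
                    pairwise = False
                    break
        bins.append(CosegregationBin(members=names, representative=rep, pairwise_identical=pairwise))
    bins.sort(key=lambda b: str(b.members[0]))
    return bins


def map_summary(genetic_map: pd.DataFrame, bins=None) -> pd.DataFrame:
    """Per-chromosome genetic-map summary (plus a Total row).

    ``genetic_map`` needs columns ``marker, chromosome, position_cM``.  For
    each chromosome: marker count, map length (max - min position), number
    of distinct cM positions, number of non-redundant markers (singleton
    cosegregation bins, when ``bins`` is supplied) and mean bin length =
    length / unique positions, rounded to 2 decimals.
    """
    required = {"marker", "chromosome", "position_cM"}
    if not required <= set(genetic_map.columns):
        raise ValueError(f"map table needs columns {sorted(required)}")
    if genetic_map["position_cM"].isna().any():
        raise ValueError("every marker needs a position")

    singleton_markers = set()
    if bins is not None:
        for b in bins:
            if len(b.members) == 1:
                singleton_markers.add(b.members[0])

    rows = []
    for chrom, grp in genetic_map.groupby("chromosome", sort=True):
        pos = grp["position_cM"].to_numpy(dtype=float)
        length = float(pos.max() - pos.min())
        unique = int(np.unique(pos).size)
        rows.append(
            {
                "chromosome": chrom,
                "n_markers": len(grp),
                "map_length_cM": length,
                "n_unique_positions": unique,
                "n_nonredundant": int(grp["marker"].isin(singleton_markers).sum()),
                "bin_length_cM": round(length / unique, 2) if unique else 0.0,
            }
        )
    total_pos = genetic_map.groupby("chromosome")["position_cM"]
    total_length = float(sum(r["map_length_cM"] for r in rows))
    total_unique = int(sum(r["n_unique_positions"] for r in rows))
    rows.append(
        {
            "chromosome": "Total",
            "n_markers": len(genetic_map),
            "map_length_cM": total_length,
            "n_unique_positions": total_unique,
            "n_nonredundant": int(sum(r["n_nonredundant"] for r in rows)),
            "bin_length_cM": round(total_length / total_unique, 2) if total_unique else 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("chromosome")


def compare_maps(map_a: pd.DataFrame, map_b: pd.DataFrame, min_shared: int = 3):
    """Per-chromosome Spearman rank correlation of marker positions.

    Markers are matched by name within each chromosome; chromosomes with
    fewer than ``min_shared`` shared markers are skipped with a warning.
    Returns ``(per_chromosome Series, unweighted average)``.
    """
    out = {}
    for chrom in sorted(set(map_a["chromosome"]) & set(map_b["chromosome"])):
        a = map_a[map_a["chromosome"] == chrom].set_index("marker")["position_cM"]
        b = map_b[map_b["chromosome"] == chrom].set_index("marker")["position_cM"]
        shared = a.index.intersection(b.index)
        if len(shared) < min_shared:
            import warnings

            warnings.warn(f"chromosome {chrom}: only {len(shared)} shared markers; skipped")
            continue
        rho, _ = stats.spearmanr(a.loc[shared], b.loc[shared])
        out[chrom] = float(rho)
    series = pd.Series(out, name="spearman_r")
    return series, float(series.mean()) if len(series) else np.nan
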