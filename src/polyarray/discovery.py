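"""Resequencing SNP discovery: filters, locus classes, accounting, selection.

Variants called from whole-genome resequencing of a line panel are
post-filtered on depth and RMS mapping quality, then classified from the
per-line genotype pattern:

* class 1 — only homozygous AA and BB among the lines;
* class 2 — AA, BB and heterozygous AB all observed;
* class 3 — only one homozygote class plus AB (a one-sided pattern);
* class 4 — AB in every line.

In a polyploid, classes 3 and 4 are enriched for inter-homoeologue
artefacts (reads from the sister subgenomes collapsing onto one locus), so
only classes 1 and 2 are usable downstream.  The module also computes Ts/Tv
and private-allele accounting, chromosome-by-fraction summary tables, and
the array candidate-selection procedure (eligibility rules plus per-arm
quota allocation with a D-genome multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GT_AA = "AA"
GT_AB = "AB"
GT_BB = "BB"
GT_MISSING = "NN"

CLASS1, CLASS2, CLASS3, CLASS4 = "CLASS1", "CLASS2", "CLASS3", "CLASS4"
UNCLASSIFIED = "UNCLASSIFIED"
USABLE_CLASSES = (CLASS1, CLASS2)

FRACTIONS = ("ISBP-derived", "Intergenic", "Exonic", "Intronic")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def filter_variants(records: pd.DataFrame, min_depth: int = 5, min_rms_mq: float = 30.0):
    """Depth / mapping-quality post-filter.

    A record is kept iff ``depth >= min_depth`` and ``rms_mq >= min_rms_mq``
    (the minima are inclusive).  Returns ``(kept, dropped)``; ``dropped``
    carries a ``drop_reason`` column (``low_depth``, ``low_mq`` or both,
    semicolon-joined).
    """
    depth_ok = records["depth"] >= min_depth
    mq_ok = records["rms_mq"] >= min_rms_mq
    kept = records[depth_ok & mq_ok].copy()
    dropped = records[~(depth_ok & mq_ok)].copy()
    reasons = []
    for d_ok, m_ok in zip(depth_ok[~(depth_ok & mq_ok)], mq_ok[~(depth_ok & mq_ok)]):
        r = []
        if not d_ok:
            r.append("low_depth")
        if not m_ok:
            r.append("low_mq")
        reasons.append(";".join(r))
    dropped["drop_reason"] = reasons
    return kept, dropped


def classify_locus(genotypes, strict: bool = False):
    """Assign the four-way locus class from the observed genotype set.

    Missing genotypes are ignored.  Requires at least 2 informative lines.
    Patterns with only one homozygote class plus AB are class 3 regardless
    of which homozygote it is (allele labels are arbitrary); ``strict=True``
    instead returns UNCLASSIFIED for the BB+AB mirror pattern.

    Returns ``(snp_class, usable)`` where ``usable`` means class 1 or 2.
    """
    observed = {g for g in genotypes if g != GT_MISSING and not pd.isna(g)}
    n_informative = sum(1 for g in genotypes if g != GT_MISSING and not pd.isna(g))
    if n_informative < 2:
        raise ValueError("need at least 2 informative lines to classify a locus")
    bad = observed - {GT_AA, GT_AB, GT_BB}
    if bad:
        raise ValueError(f"unknown genotypes: {sorted(bad)}")

    if observed == {GT_AA, GT_BB}:
        cls = CLASS1
    elif observed == {GT_AA, GT_AB, GT_BB}:
        cls = CLASS2
    elif observed == {GT_AA, GT_AB}:
        cls = CLASS3
    elif observed == {GT_AB}:
        cls = CLASS4
    elif observed == {GT_BB, GT_AB}:
        cls = UNCLASSIFIED if strict else CLASS3
    else:  # monomorphic homozygous: no polymorphism at all
        cls = UNCLASSIFIED
    return cls, cls in USABLE_CLASSES


def classify_loci(genotype_matrix: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Vector version of :func:`classify_locus` over rows (loci) of a
    loci x lines genotype matrix.  Returns columns ``snp_class, usable``."""
    out = []
    for locus, row in genotype_matrix.iterrows():
        cls, usable = classify_locus(row.to_numpy(), strict=strict)
        out.append({"snp_class": cls, "usable": usable})
    return pd.DataFrame(out, index=genotype_matrix.index)


def is_transition(ref: str, alt: str) -> bool:
    pair = {ref.upper(), alt.upper()}
    return pair == {"A", "G"} or pair == {"C", "T"}


def ts_tv(records: pd.DataFrame):
    """Transition/transversion counts and ratio.

    Transitions are A<->G and C<->T.  Returns ``(ts, tv, ratio)``; the ratio
    is NaN when there are no transversions.  Rejects non-SNV alleles.
    """
    refs = records["ref"].astype(str)
    alts = records["alt"].astype(str)
    if ((refs.str.len() != 1) | (alts.str.len() != 1)).any():
        raise ValueError("ts_tv expects single-nucleotide alleles")
    ts = int(sum(is_transition(r, a) for r, a in zip(refs, alts)))
    tv = len(records) - ts
    return ts, tv, (ts / tv) if tv else float("nan")


def private_snp_fractions(genotype_matrix: pd.DataFrame, genome_of=None):
    """Private-allele accounting.

    A locus (row) is *private* when exactly one line carries the
    non-reference allele (AB or BB) among the non-missing lines; loci with
    fewer than 2 non-missing lines are excluded from the denominator.

    Returns a dict with ``per_line`` (Series: loci private to each line),
    ``n_assessable``, ``private_fraction`` overall, and — when ``genome_of``
    maps each locus to a genome of origin — ``per_genome`` fractions.
    """
    if genotype_matrix.shape[1] < 2:
        raise ValueError("need at least 2 lines")
    gt = genotype_matrix.to_numpy(dtype=object)
    informative = (gt != GT_MISSING) & ~pd.isna(gt)
    carrier = ((gt == GT_AB) | (gt == GT_BB)) & informative
    assessable = informative.sum(axis=1) >= 2
    n_carriers = carrier.sum(axis=1)
    private = assessable & (n_carriers == 1)

    lines = list(genotype_matrix.columns)
    per_line = pd.Series(
        {ln: int((carrier[private][:, i]).sum()) for i, ln in enumerate(lines)},
        name="n_private",
    )
    out = {
        "per_line": per_line,
        "n_assessable": int(assessable.sum()),
        "private_fraction": float(private.sum() / assessable.sum()) if assessable.any() else np.nan,
        "private_mask": pd.Series(private, index=genotype_matrix.index),
    }
    if genome_of is not None:
        gen = pd.Series(genome_of).reindex(genotype_matrix.index)
        per_genome = {}
        for g in sorted(gen.dropna().unique()):
            sel = (gen == g).to_numpy() & assessable
            per_genome[g] = float(private[sel].sum() / sel.sum()) if sel.any() else np.nan
        out["per_genome"] = pd.Series(per_genome, name="private_fraction")
    return out


def genome_of_chromosome(chrom: str) -> str:
    """Subgenome letter of a wheat-style chromosome name (e.g. '3B' -> 'B')."""
    letter = str(chrom).rstrip("SL")[-1].upper()
    if letter not in ("A", "B", "D"):
        raise ValueError(f"cannot infer genome from chromosome {chrom!r}")
    return letter


def summarize_snps(records: pd.DataFrame, fractions=FRACTIONS) -> pd.DataFrame:
    """Chromosome x fraction count table with genome subtotals.

    ``records`` needs ``chrom`` and ``fraction`` columns; rows are the 21
    wheat-style chromosomes grouped into A/B/D-genome subtotal rows plus a
    grand total, columns the sequence fractions plus ``Total``.
    """
    unknown = set(records["fraction"].unique()) - set(fractions)
    if unknown:
        raise ValueError(f"unknown fraction labels: {sorted(unknown)}")
    counts = (
        records.groupby(["chrom", "fraction"]).size().unstack(fill_value=0)
        if len(records)
        else pd.DataFrame()
    )
    counts = counts.reindex(columns=list(fractions), fill_value=0)
    rows = []
    chroms = sorted(records["chrom"].unique()) if len(records) else []
    genomes = sorted({genome_of_chromosome(c) for c in chroms})
    for g in genomes:
        g_chroms = [c for c in chroms if genome_of_chromosome(c) == g]
        sub = counts.loc[g_chroms].sum()
        rows.append((f"{g}-genome", sub))
        for c in g_chroms:
            rows.append((c, counts.loc[c]))
    total = counts.sum() if len(counts) else pd.Series(0, index=list(fractions))
    rows.append(("Total", total))
    out = pd.DataFrame({name: vals for name, vals in rows}).T
    out.columns = list(fractions)
    out["Total"] = out.sum(axis=1)
    return out.astype(int)


@dataclass
class ArmQuota:
    arm: str
    size: float
    genome: str
    allocated: int


def allocate_quota(arms, total: int, d_multiplier: float = 2.0) -> list:
    """Largest-remainder allocation of SNP counts across chromosome arms.

    Each arm's weight is its physical size, multiplied by ``d_multiplier``
    for D-genome arms (compensating the D subgenome's low polymorphism).
    Allocations are integerised by largest remainder and sum exactly to
    ``total``.
    """
    arms = list(arms)
    if not arms:
        raise ValueError("empty arm list")
    if total <= 0:
        raise ValueError("total must be positive")
    sizes = np.array([float(a[1]) for a in arms])
    if (sizes <= 0).any():
        raise ValueError("arm sizes must be positive")
    genomes = [str(a[2]).upper() for a in arms]
    weights = sizes * np.array([d_multiplier if g == "D" else 1.0 for g in genomes])
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(int)
    remainder = exact - base
    shortfall = total - int(base.sum())
    # ties broken by arm order for determinism
    order = np.argsort(-remainder, kind="stable")
    base[order[:shortfall]] += 1
    return [
        ArmQuota(arm=str(a[0]), size=float(a[1]), genome=g, allocated=int(n))
        for a, g, n in zip(arms, genomes, base)
    ]


def select_candidates(
    records: pd.DataFrame,
    genotype_matrix: pd.DataFrame,
    pools,
    quotas=None,
    min_carrier_lines: int = 2,
    european_pool: str = "European",
    strict_classes: bool = False,
):
    """Array candidate selection with a per-record audit trail.

    Eligibility requires, for each record (aligned with the rows of the
    loci x lines ``genotype_matrix``):

    * the non-reference allele observed in at least ``min_carrier_lines``
      lines (``too_few_carriers``);
    * polymorphism within the European pool — both alleles observed among
      European lines (``not_polymorphic_european``);
    * a single genome-wide hit of the context sequence, ``hit_count == 1``
      (``multi_hit``);
    * a usable locus class, i.e. class 1 or 2 (``unusable_class``).

    When per-arm ``quotas`` (list of :class:`ArmQuota`, matched against the
    ``arm`` column) are given, each arm is filled from its eligible records
    ordered by descending carrier-line count, then position, then identifier;
    under-filled arms produce a warning.

    Returns ``(selected, audit)``: the selected subset of ``records`` and an
    audit table with one row per record listing eligibility and reasons.
    """
    pools = pd.Series(pools)
    euro_lines = [ln for ln in genotype_matrix.columns if pools.get(ln) == european_pool]
    if not euro_lines:
        raise ValueError(f"no lines labelled {european_pool!r}")

    gt = genotype_matrix.to_numpy(dtype=object)
    informative = (gt != GT_MISSING) & ~pd.isna(gt)
    carrier = ((gt == GT_AB) | (gt == GT_BB)) & informative
    n_carriers = carrier.sum(axis=1)

    euro_idx = [genotype_matrix.columns.get_loc(ln) for ln in euro_lines]
    euro_gt = gt[:, euro_idx]
    euro_inf = informative[:, euro_idx]
    has_ref = (((euro_gt == GT_AA) | (euro_gt == GT_AB)) & euro_inf).any(axis=1)
    has_alt = (((euro_gt == GT_BB) | (euro_gt == GT_AB)) & euro_inf).any(axis=1)
    euro_poly = has_ref & has_alt

    classes = classify_loci(genotype_matrix, strict=strict_classes)

    audit_rows = []
    for i, (rid, rec) in enumerate(records.iterrows()):
        reasons = []
        if n_carriers[i] < min_carrier_lines:
            reasons.append("too_few_carriers")
        if not euro_poly[i]:
            reasons.append("not_polymorphic_european")
        if int(rec.get("hit_count", 1)) != 1:
            reasons.append("multi_hit")
        if not bool(classes["usable"].iloc[i]):
            reasons.append("unusable_class")
        audit_rows.append(
            {
                "record": rid,
                "n_carriers": int(n_carriers[i]),
                "snp_class": classes["snp_class"].iloc[i],
                "eligible": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    audit = pd.DataFrame(audit_rows).set_index("record")
    eligible = records[audit["eligible"].to_numpy()].copy()
    eligible["n_carriers"] = audit.loc[eligible.index, "n_carriers"].to_numpy()

    if quotas is None:
        selected = eligible.drop(columns=["n_carriers"])
    else:
        picks = []
        for q in quotas:
            pool_recs = eligible[eligible["arm"] == q.arm]
            ordered = pool_recs.sort_values(
                by=["n_carriers", "pos"],
                ascending=[False, True],
                kind="stable",
            )
            if len(ordered) < q.allocated:
                import warnings

                warnings.warn(
                    f"arm {q.arm}: only {len(ordered)} eligible records for quota {q.allocated}"
                )
            picks.append(ordered.head(q.allocated))
        selected = pd.concat(picks).drop(columns=["n_carriers"]) if picks else eligible.iloc[:0]

    # hard guarantee: nothing selected may fail an eligibility predicate
    assert audit.loc[selected.index, "eligible"].all()
    return selected, audit
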