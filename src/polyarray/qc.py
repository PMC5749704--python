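"""Probeset quality metrics, six-way categories and conversion accounting.

A probeset on a polyploid array is judged on its call rate, the geometry of
its homozygous clusters and whether a minor homozygote cluster exists:

* **HomRO** (homozygote ratio offset) — the contrast position of the
  homozygous cluster closest to zero.  Positive values mean the AA and BB
  clusters flank zero, as they would at a diploid locus; negative values mean
  both sit on the same side, the signature of homoeologous signal
  compression in a polyploid.
* **HomFLD** (homozygote Fisher's linear discriminant) — distance between
  the two homozygous cluster centers over the pooled within-cluster contrast
  SD; high values mean narrow, well-separated clusters.

Categories follow the Axiom convention: PHR (polymorphic high resolution),
OTV (off-target variant / null allele), MHR (monomorphic high resolution),
NMH (no minor homozygote), CRBT (call rate below threshold) and Other.
PHR + OTV are the *converted* probesets — polymorphic assays that can
actually be scored; a converted probeset behaving like a diploid locus
(HomRO > 0.3 and HomFLD > 10) is flagged *diploidized*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polyarray.signal_model import CALL_AA, CALL_AB, CALL_BB, CALL_NN, CALL_OO

CATEGORIES = ("PHR", "OTV", "MHR", "NMH", "CRBT", "Other")
CONVERTED = ("PHR", "OTV")

#: sentinel for metrics that cannot be computed (missing homozygous cluster);
#: NaN compares False against every threshold, i.e. an undefined metric fails.
UNDEFINED = float("nan")


@dataclass
class QcThresholds:
    """QC thresholds; defaults follow Axiom polyploid practice."""

    call_rate_min: float = 0.97
    hom_fld_min: float = 3.6
    min_minor_hom: int = 2
    diploid_hom_ro_min: float = 0.3
    diploid_hom_fld_min: float = 10.0

    def __post_init__(self):
        for name in (
            "call_rate_min",
            "hom_fld_min",
            "min_minor_hom",
            "diploid_hom_ro_min",
            "diploid_hom_fld_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QcMetrics:
    call_rate: float
    het_rate: float
    n_AA: int
    n_AB: int
    n_BB: int
    n_OO: int
    n_NN: int

    @property
    def n_total(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB + self.n_OO + self.n_NN

    @property
    def n_called(self) -> int:
        return self.n_total - self.n_NN

    @property
    def minor_hom_count(self) -> int:
        return min(self.n_AA, self.n_BB)


@dataclass
class ProbesetCategory:
    category: str
    diploidized: bool
    hom_ro: float = UNDEFINED
    hom_fld: float = UNDEFINED

    @property
    def converted(self) -> bool:
        return self.category in CONVERTED


def compute_metrics(calls) -> QcMetrics:
    """Tally calls into QC metrics.

    ``call_rate = 1 - n_NN/total``; ``het_rate`` is the AB fraction of the
    called (non-NN) samples.
    """
    calls = np.asarray(calls, dtype=object)
    n = calls.size
    counts = {lab: int(np.sum(calls == lab)) for lab in (CALL_AA, CALL_AB, CALL_BB, CALL_OO, CALL_NN)}
    unknown = n - sum(counts.values())
    if unknown:
        raise ValueError("calls contain labels outside {AA, AB, BB, OO, NN}")
    called = n - counts[CALL_NN]
    return QcMetrics(
        call_rate=(called / n) if n else 0.0,
        het_rate=(counts[CALL_AB] / called) if called else 0.0,
        n_AA=counts[CALL_AA],
        n_AB=counts[CALL_AB],
        n_BB=counts[CALL_BB],
        n_OO=counts[CALL_OO],
        n_NN=counts[CALL_NN],
    )


def _hom_contrasts(model):
    c_aa = c_bb = None
    for k, lab in enumerate(model.labels):
        if lab == CALL_AA:
            c_aa = float(model.means[k, 0])
        elif lab == CALL_BB:
            c_bb = float(model.means[k, 0])
    return c_aa, c_bb


def hom_ro(model) -> float:
    """Signed contrast offset of the homozygous cluster nearest zero.

    With AA expected at positive and BB at negative contrast: both present
    -> ``min(c_AA, -c_BB)``; only one present -> its signed distance from
    zero in the expected direction.  Positive iff every present homozygous
    cluster lies on its expected side of zero.  Undefined (NaN) without a
    homozygous cluster.
    """
    c_aa, c_bb = _hom_contrasts(model)
    if c_aa is None and c_bb is None:
        return UNDEFINED
    if c_bb is None:
        return c_aa
    if c_aa is None:
        return -c_bb
    return min(c_aa, -c_bb)


def hom_fld(model, min_members: int = 2) -> float:
    """Fisher's linear discriminant between the homozygous clusters.

    ``|c_AA - c_BB|`` over the membership-weighted pooled within-cluster
    contrast SD.  Undefined (NaN) unless both homozygous clusters are present
    with at least ``min_members`` (soft) members each.  Coincident centers
    give 0.
    """
    try:
        k_aa = model.component(CALL_AA)
        k_bb = model.component(CALL_BB)
    except ValueError:
        return UNDEFINED
    n_aa, n_bb = model.counts[k_aa], model.counts[k_bb]
    if n_aa < min_members or n_bb < min_members:
        return UNDEFINED
    sep = abs(model.means[k_aa, 0] - model.means[k_bb, 0])
    pooled_var = (n_aa * model.variances[k_aa, 0] + n_bb * model.variances[k_bb, 0]) / (
        n_aa + n_bb
    )
    pooled_sd = np.sqrt(pooled_var)
    if sep == 0.0:
        return 0.0
    return float(sep / pooled_sd)


def classify_probeset(
    metrics: QcMetrics,
    model,
    thresholds: QcThresholds | None = None,
) -> ProbesetCategory:
    """Assign the six-way category and the diploidized flag.

    Decision cascade:

    1. call rate below threshold -> CRBT;
    2. a detected null-allele (OTV) component -> OTV;
    3. monomorphic among called genotypes -> MHR;
    4. both homozygote clusters present, minor-homozygote count at or above
       the minimum, and HomFLD at or above its filter -> PHR;
    5. minor homozygote absent or too few -> NMH;
    6. everything else (e.g. HomFLD below the filter) -> Other.

    ``diploidized`` requires a converted category (PHR/OTV) plus
    HomRO > 0.3 and HomFLD > 10; undefined metrics fail the comparison.
    """
    t = thresholds or QcThresholds()
    ro = hom_ro(model)
    fld = hom_fld(model)

    if metrics.call_rate < t.call_rate_min:
        cat = "CRBT"
    elif getattr(model, "has_otv", False):
        cat = "OTV"
    else:
        geno_counts = {CALL_AA: metrics.n_AA, CALL_AB: metrics.n_AB, CALL_BB: metrics.n_BB}
        observed = {g for g, n in geno_counts.items() if n > 0}
        if len(observed) <= 1:
            cat = "MHR"
        elif CALL_AA in observed and CALL_BB in observed:
            if metrics.minor_hom_count >= t.min_minor_hom:
                cat = "PHR" if fld >= t.hom_fld_min else "Other"
            else:
                cat = "NMH"
        else:
            cat = "NMH"  # polymorphic but one homozygote class never seen

    diploidized = (
        cat in CONVERTED and ro > t.diploid_hom_ro_min and fld > t.diploid_hom_fld_min
    )
    return ProbesetCategory(category=cat, diploidized=diploidized, hom_ro=ro, hom_fld=fld)


def qc_report(results: dict) -> pd.DataFrame:
    """Flatten per-probeset results (from two-step genotyping) to a table."""
    rows = []
    for pid, res in results.items():
        m: QcMetrics = res["metrics"]
        cat: ProbesetCategory = res["category"]
        rows.append(
            {
                "probeset_id": pid,
                "category": cat.category,
                "call_rate": m.call_rate,
                "het_rate": m.het_rate,
                "hom_ro": cat.hom_ro,
                "hom_fld": cat.hom_fld,
                "n_AA": m.n_AA,
                "n_AB": m.n_AB,
                "n_BB": m.n_BB,
                "n_OO": m.n_OO,
                "n_NN": m.n_NN,
                "diploidized": cat.diploidized,
            }
        )
    return pd.DataFrame(rows)


def qc_summary(
    categories,
    annotations=None,
    diploidized=None,
) -> pd.DataFrame:
    """Category counts overall and by genic/intergenic annotation.

    Parameters
    ----------
    categories : sequence of category strings, one per probeset.
    annotations : optional sequence of "genic"/"intergenic" labels aligned
        with ``categories``; if given, every probeset must carry one.
    diploidized : optional aligned boolean sequence.

    Returns a table with one row per category plus ``Total``, ``Converted``
    and (when available) ``Diploidized`` rows, and columns ``total`` plus one
    per annotation value.
    """
    cats = pd.Series(list(categories), dtype=object)
    bad = set(cats.unique()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    cols = {"total": cats}
    if annotations is not None:
        ann = pd.Series(list(annotations), dtype=object)
        if len(ann) != len(cats) or ann.isna().any():
            raise ValueError("annotation missing for some probesets")
        for value in sorted(ann.unique()):
            cols[value] = cats[ann.to_numpy() == value]

    rows = {}
    rows["Total"] = {name: len(sub) for name, sub in cols.items()}
    for cat in CATEGORIES:
        rows[cat] = {name: int((sub == cat).sum()) for name, sub in cols.items()}
    rows["Converted"] = {
        name: int(sub.isin(CONVERTED).sum()) for name, sub in cols.items()
    }
    if diploidized is not None:
        dip = pd.Series(list(diploidized), dtype=bool)
        rows["Diploidized"] = {"total": int(dip.sum())}
        if annotations is not None:
            for value in sorted(ann.unique()):
                rows["Diploidized"][value] = int(dip[ann.to_numpy() == value].sum())
    out = pd.DataFrame(rows).T
    return out.fillna(0).astype(int)


def conversion_rates(summary: pd.DataFrame, digits: int | None = 0) -> pd.DataFrame:
    """Conversion and diploidization rates from a :func:`qc_summary` table.

    ``conversion = Converted / Total`` per column; ``diploidized_of_converted
    = Diploidized / Converted``.  Percentages, rounded to ``digits`` decimals
    (None = unrounded).
    """
    out = {}
    for col in summary.columns:
        total = summary.loc["Total", col]
        conv = summary.loc["Converted", col]
        rates = {"conversion_pct": 100.0 * conv / total if total else 0.0}
        if "Diploidized" in summary.index:
            rates["diploidized_pct_of_converted"] = (
                100.0 * summary.loc["Diploidized", col] / conv if conv else 0.0
            )
        out[col] = rates
    df = pd.DataFrame(out)
    if digits is not None:
        df = df.round(digits)
    return df
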