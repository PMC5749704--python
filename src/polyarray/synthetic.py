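"""Synthetic-data generators for every pipeline stage, with ground truth.

The generators emulate the statistical structure of a hexaploid SNP-array
experiment without any sequencing data:

* :func:`generate_array_experiment` — two-channel probe signals for a mix of
  probeset classes (diploidized polymorphic, homoeologous-offset,
  monomorphic, null-allele-bearing, low-quality).  Signals are produced by
  drawing (contrast, size) from the class geometry plus Gaussian noise and
  *inverting* the contrast/size transform, so the transform round trip is
  exact.
* :func:`generate_population_panel` — a structured diversity panel: group
  allele frequencies drawn from a Balding–Nichols model (Beta around the
  ancestral frequency with variance ``fst * p * (1-p)``), inbred genotypes
  per accession.
* :func:`generate_ril_f6` — a single-seed-descent recombinant inbred
  population: genotypes follow a Markov chain along each chromosome whose
  adjacent-marker recombination fractions are the inverse mapping function
  (Kosambi or Haldane) of the cM gaps; residual heterozygosity per locus is
  ``(1/2)**(generation-1)``; optional transmission distortion and
  missing-completely-at-random data.
* :func:`generate_variant_records` — VCF-style variant records with per-line
  genotypes realising a configured class mix, ref/alt pairs hitting a target
  Ts/Tv, and depth / RMS-MQ draws for filter testing.

Reproducibility: one master seed per config; each generator derives its RNG
as ``np.random.default_rng([seed, OP_OFFSET])`` with a fixed per-operation
offset, so outputs are bitwise reproducible and independent across
operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polyarray.signal_model import (
    CALL_AA,
    CALL_AB,
    CALL_BB,
    CALL_NN,
    CALL_OO,
    contrast_size_to_signals,
)

_OP_ARRAY, _OP_PANEL, _OP_RIL, _OP_VARIANTS = 1, 2, 3, 4

ARRAY_CLASSES = (
    "diploidized",
    "homoeologous",
    "monomorphic",
    "null_allele",
    "low_quality",
)


@dataclass
class ClassGeometry:
    """Cluster geometry of one probeset class in (contrast, size) space."""

    contrast_centers: dict  # genotype -> contrast center
    contrast_sd: float = 0.1
    size_mean: float = 12.0
    size_sd: float = 0.15
    otv_size_offset: float = 0.9  # null cloud this far below size_mean
    extra_missing_rate: float = 0.0

    def __post_init__(self):
        if self.contrast_sd <= 0 or self.size_sd <= 0:
            raise ValueError("spreads must be > 0")


def default_geometry() -> dict:
    """Per-class defaults.

    Diploidized probesets put AA/BB at +-1.2 (12 contrast-SDs apart, hence
    HomRO 1.2 > 0.3 and HomFLD ~12 > 10); homoeologous-offset probesets
    shift both homozygote clusters to one side so the one nearest zero sits
    at +0.1 (< 0.3, negative HomRO); the null-allele cloud sits 0.9 size
    units (~6 size-SDs) below the genotype clusters; low-quality probesets
    have broad, overlapping clusters plus excess missing data.
    """
    return {
        "diploidized": ClassGeometry({CALL_AA: 1.2, CALL_AB: 0.0, CALL_BB: -1.2}),
        "homoeologous": ClassGeometry({CALL_AA: 0.9, CALL_AB: 0.5, CALL_BB: 0.1}),
        "monomorphic": ClassGeometry({CALL_AA: 1.0, CALL_BB: -1.0}),
        "null_allele": ClassGeometry({CALL_AA: 1.2, CALL_AB: 0.0, CALL_BB: -1.2}),
        "low_quality": ClassGeometry(
            {CALL_AA: 0.4, CALL_AB: 0.0, CALL_BB: -0.4},
            contrast_sd=0.35,
            extra_missing_rate=0.08,
        ),
    }


@dataclass
class ArrayScenarioConfig:
    """Study conditions for the array-signal generator.

    Defaults mirror a 96-accession genotyping run with the category
    spectrum observed on a polyploid wheat array: 59% well-behaved
    polymorphic, 9% null-allele-bearing, 17% monomorphic, 9%
    homoeologous-offset, 6% low-quality.
    """

    n_samples: int = 96
    n_probesets: int = 1000
    category_mix: dict = field(
        default_factory=lambda: {
            "diploidized": 0.59,
            "homoeologous": 0.09,
            "monomorphic": 0.17,
            "null_allele": 0.09,
            "low_quality": 0.06,
        }
    )
    cluster_geometry: dict = field(default_factory=default_geometry)
    otv_frequency: float = 0.25
    missing_rate: float = 0.005
    het_rate: float = 0.015
    allele_freq_range: tuple = (0.25, 0.75)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_probesets <= 0:
            raise ValueError("counts must be positive")
        unknown = set(self.category_mix) - set(ARRAY_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in category_mix: {sorted(unknown)}")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix proportions must sum to 1")
        for name in ("otv_frequency", "missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PanelScenarioConfig:
    """Structured diversity panel: groups with Balding–Nichols divergence."""

    n_groups: int = 5
    samples_per_group: tuple = (20, 20, 20, 20, 16)
    n_loci: int = 500
    fst: float = 0.3
    ancestral_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if len(self.samples_per_group) != self.n_groups:
            raise ValueError("samples_per_group length must equal n_groups")
        if any(n <= 0 for n in self.samples_per_group):
            raise ValueError("sample counts must be positive")


@dataclass
class RilScenarioConfig:
    """Single-seed-descent RIL population (F6 by default, 430 individuals)."""

    n_individuals: int = 430
    n_chromosomes: int = 3
    markers_per_chromosome: tuple = (60, 60, 60)
    chromosome_length_cM: tuple = (150.0, 150.0, 150.0)
    generation: int = 6
    distortion_loci: tuple = ()  # (chromosome index, position cM, P(parent-1 allele))
    missing_rate: float = 0.02
    mapping_function: str = "kosambi"
    marker_positions: tuple | None = None  # optional explicit cM positions per chromosome
    seed: int = 0

    def __post_init__(self):
        if self.generation < 2:
            raise ValueError("generation must be >= 2")
        if self.mapping_function not in ("kosambi", "haldane"):
            raise ValueError("mapping_function must be 'kosambi' or 'haldane'")
        if len(self.markers_per_chromosome) != self.n_chromosomes:
            raise ValueError("markers_per_chromosome length must equal n_chromosomes")
        if len(self.chromosome_length_cM) != self.n_chromosomes:
            raise ValueError("chromosome_length_cM length must equal n_chromosomes")
        if self.marker_positions is not None:
            if len(self.marker_positions) != self.n_chromosomes:
                raise ValueError("marker_positions length must equal n_chromosomes")
            for c, pos in enumerate(self.marker_positions):
                if len(pos) != self.markers_per_chromosome[c]:
                    raise ValueError("marker_positions count mismatch on a chromosome")
                if any(p < 0 or p > self.chromosome_length_cM[c] for p in pos):
                    raise ValueError("marker position outside chromosome")
        for chrom, pos, bias in self.distortion_loci:
            if not 0 <= chrom < self.n_chromosomes:
                raise ValueError(f"distortion chromosome {chrom} out of range")
            if not 0.0 <= pos <= self.chromosome_length_cM[chrom]:
                raise ValueError("distortion position outside chromosome")
            if not 0.0 < bias < 1.0:
                raise ValueError("transmission bias must be in (0, 1)")


@dataclass
class TruthBundle:
    """Ground truth accompanying a generated dataset."""

    genotypes: pd.DataFrame | None = None
    categories: pd.Series | None = None
    cluster_params: dict | None = None
    genetic_map: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def validate_against(self, *, signal_table=None, matrix=None):
        """Check dimensional consistency with emitted data; raises on drift."""
        if signal_table is not None:
            probesets = set(signal_table["probeset_id"].unique())
            samples = set(signal_table["sample_id"].unique())
            if set(self.genotypes.columns) != probesets:
                raise ValueError("truth probesets differ from signal table")
            if set(self.genotypes.index) != samples:
                raise ValueError("truth samples differ from signal table")
            if self.categories is not None and set(self.categories.index) != probesets:
                raise ValueError("truth categories differ from signal table")
        if matrix is not None and self.genotypes is not None:
            if self.genotypes.shape != matrix.shape:
                raise ValueError("truth genotype matrix shape differs from data")
        return True


def _sample_ids(n):
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_array_experiment(config: ArrayScenarioConfig):
    """Generate a two-channel signal table plus truth.

    For each probeset a class is drawn from ``category_mix``; samples get
    true genotypes according to the class (polymorphic classes draw an
    allele frequency uniformly from ``allele_freq_range``, heterozygotes at
    ``het_rate``; null-allele probesets make ``otv_frequency`` of samples
    null carriers; monomorphic probesets fix a single genotype).  Each
    sample's (contrast, size) is its cluster center plus Gaussian noise and
    is inverted into channel signals; missing measurements are NaN.

    Returns ``(signal_table, truth)`` where the truth bundle carries the
    underlying genotypes (OO for null carriers), the generating class per
    probeset and the generating cluster parameters.
    """
    rng = np.random.default_rng([config.seed, _OP_ARRAY])
    samples = _sample_ids(config.n_samples)
    classes = sorted(config.category_mix)
    probs = np.array([config.category_mix[c] for c in classes])

    pids, sids, sig_a, sig_b = [], [], [], []
    truth_geno = {}
    truth_class = {}
    truth_params = {}
    for j in range(config.n_probesets):
        pid = f"AX{j + 1:06d}"
        cls = rng.choice(classes, p=probs)
        geom: ClassGeometry = config.cluster_geometry[cls]

        if cls == "monomorphic":
            fixed = rng.choice([CALL_AA, CALL_BB])
            geno = np.full(config.n_samples, fixed, dtype=object)
            p = 1.0 if fixed == CALL_AA else 0.0
        else:
            p = rng.uniform(*config.allele_freq_range)
            u = rng.random(config.n_samples)
            geno = np.where(u < config.het_rate, CALL_AB,
                            np.where(rng.random(config.n_samples) < p, CALL_AA, CALL_BB))
            geno = geno.astype(object)
        if cls == "null_allele":
            carriers = rng.random(config.n_samples) < config.otv_frequency
            geno[carriers] = CALL_OO

        contrast = np.empty(config.n_samples)
        size = np.empty(config.n_samples)
        for g in np.unique(geno):
            mask = geno == g
            n = int(mask.sum())
            if g == CALL_OO:
                contrast[mask] = rng.normal(0.0, geom.contrast_sd, n)
                size[mask] = rng.normal(geom.size_mean - geom.otv_size_offset, geom.size_sd, n)
            else:
                contrast[mask] = rng.normal(geom.contrast_centers[g], geom.contrast_sd, n)
                size[mask] = rng.normal(geom.size_mean, geom.size_sd, n)
        a, b = contrast_size_to_signals(contrast, size)
        miss = rng.random(config.n_samples) < (config.missing_rate + geom.extra_missing_rate)
        a[miss] = np.nan
        b[miss] = np.nan

        pids.extend([pid] * config.n_samples)
        sids.extend(samples)
        sig_a.append(a)
        sig_b.append(b)
        truth_geno[pid] = geno
        truth_class[pid] = cls
        truth_params[pid] = {
            "class": cls,
            "allele_freq": p,
            "contrast_centers": dict(geom.contrast_centers),
            "contrast_sd": geom.contrast_sd,
            "size_mean": geom.size_mean,
            "size_sd": geom.size_sd,
        }

    table = pd.DataFrame(
        {
            "probeset_id": pids,
            "sample_id": sids,
            "signal_a": np.concatenate(sig_a),
            "signal_b": np.concatenate(sig_b),
        }
    )
    truth = TruthBundle(
        genotypes=pd.DataFrame(truth_geno, index=samples),
        categories=pd.Series(truth_class, name="true_class"),
        cluster_params=truth_params,
    )
    return table, truth


def generate_population_panel(config: PanelScenarioConfig):
    """Generate a structured diversity panel genotype matrix plus truth.

    Ancestral allele frequencies are uniform on ``ancestral_freq_range``;
    each group's frequency is Beta-distributed around the ancestral value
    with variance ``fst * p * (1 - p)`` (Balding–Nichols).  Accessions are
    fully inbred: AA with the group frequency, else BB.  Missingness is
    completely at random.
    """
    rng = np.random.default_rng([config.seed, _OP_PANEL])
    p_anc = rng.uniform(*config.ancestral_freq_range, size=config.n_loci)
    lam = (1.0 - config.fst) / config.fst
    group_freqs = np.empty((config.n_groups, config.n_loci))
    for g in range(config.n_groups):
        group_freqs[g] = rng.beta(p_anc * lam, (1.0 - p_anc) * lam)

    samples, groups = [], []
    rows = []
    for g, n_g in enumerate(config.samples_per_group):
        for i in range(n_g):
            sid = f"G{g + 1}_{i + 1:02d}"
            samples.append(sid)
            groups.append(f"group{g + 1}")
            aa = rng.random(config.n_loci) < group_freqs[g]
            row = np.where(aa, CALL_AA, CALL_BB).astype(object)
            row[rng.random(config.n_loci) < config.missing_rate] = CALL_NN
            rows.append(row)
    loci = [f"L{i + 1:05d}" for i in range(config.n_loci)]
    matrix = pd.DataFrame(rows, index=samples, columns=loci)
    truth = TruthBundle(
        genotypes=matrix,
        categories=pd.Series(groups, index=samples, name="group"),
        cluster_params={"ancestral_freq": p_anc, "group_freqs": group_freqs},
    )
    return matrix, truth


def inverse_mapping_function(d_cM, function: str = "kosambi"):
    """Recombination fraction for a map distance in cM.

    Kosambi: ``r = tanh(0.02 d) / 2``; Haldane: ``r = (1 - exp(-0.02 d)) / 2``.
    """
    d = np.asarray(d_cM, dtype=float)
    if function == "kosambi":
        return 0.5 * np.tanh(0.02 * d)
    if function == "haldane":
        return 0.5 * (1.0 - np.exp(-0.02 * d))
    raise ValueError(f"unknown mapping function: {function}")


def generate_ril_f6(config: RilScenarioConfig):
    """Generate an SSD RIL genotype matrix (parents P1/P2 first) plus truth.

    Each individual's parental-origin vector follows a Markov chain along
    each chromosome: the first marker is either parent with probability 1/2
    and adjacent markers recombine with the inverse mapping function of
    their cM gap.  Residual heterozygosity ``(1/2)**(generation-1)`` and
    missing data are overlaid per genotype; transmission distortion is
    applied at the marker nearest each configured distortion locus by
    resampling alleles toward the configured parent-1 transmission bias.
    """
    rng = np.random.default_rng([config.seed, _OP_RIL])
    n = config.n_individuals
    het_rate = 0.5 ** (config.generation - 1)

    marker_names, chrom_names, positions = [], [], []
    origin_cols = []
    distortion_markers = {}
    for c in range(config.n_chromosomes):
        m = config.markers_per_chromosome[c]
        length = config.chromosome_length_cM[c]
        if config.marker_positions is not None:
            pos = np.sort(np.asarray(config.marker_positions[c], dtype=float))
        else:
            pos = np.sort(rng.uniform(0.0, length, size=m))
        names = [f"chr{c + 1}_m{k + 1:03d}" for k in range(m)]
        marker_names.extend(names)
        chrom_names.extend([f"chr{c + 1}"] * m)
        positions.extend(pos.tolist())

        # the chain, heterozygosity and missingness are keyed by the distinct
        # genetic positions, so markers at an identical cM position produce
        # bitwise-identical genotype columns
        upos, inverse = np.unique(pos, return_inverse=True)
        r = inverse_mapping_function(np.diff(upos), config.mapping_function)
        state = rng.random(n) < 0.5  # True = parent-1 allele
        chrom_states = [state]
        for gap_r in r:
            flip = rng.random(n) < gap_r
            state = np.where(flip, ~chrom_states[-1], chrom_states[-1])
            chrom_states.append(state)
        chrom_states = np.column_stack(chrom_states)  # n x len(upos)

        for dc, dpos, bias in config.distortion_loci:
            if dc != c:
                continue
            k = int(np.argmin(np.abs(upos - dpos)))
            for j in np.nonzero(inverse == k)[0]:
                distortion_markers[names[j]] = bias
            col = chrom_states[:, k].copy()
            if bias >= 0.5:  # flip parent-2 alleles toward parent 1
                q = (bias - 0.5) / 0.5
                flip = (~col) & (rng.random(n) < q)
                col[flip] = True
            else:
                q = (0.5 - bias) / 0.5
                flip = col & (rng.random(n) < q)
                col[flip] = False
            chrom_states[:, k] = col

        ugeno = np.where(chrom_states, CALL_AA, CALL_BB).astype(object)
        het = rng.random(ugeno.shape) < het_rate
        ugeno[het] = CALL_AB
        miss = rng.random(ugeno.shape) < config.missing_rate
        ugeno[miss] = CALL_NN
        origin_cols.append(ugeno[:, inverse])

    geno = np.concatenate(origin_cols, axis=1)  # n x total markers

    individuals = [f"RIL{i + 1:03d}" for i in range(n)]
    progeny = pd.DataFrame(geno, index=individuals, columns=marker_names)
    parents = pd.DataFrame(
        [[CALL_AA] * len(marker_names), [CALL_BB] * len(marker_names)],
        index=["P1", "P2"],
        columns=marker_names,
    )
    matrix = pd.concat([parents, progeny])

    true_map = pd.DataFrame(
        {"marker": marker_names, "chromosome": chrom_names, "position_cM": positions}
    )
    truth = TruthBundle(
        genotypes=matrix,
        genetic_map=true_map,
        extra={
            "het_rate": het_rate,
            "distortion_markers": distortion_markers,
            "mapping_function": config.mapping_function,
        },
    )
    return matrix, truth


_WHEAT_CHROMS = [f"{i}{g}" for g in "ABD" for i in range(1, 8)]
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}
_FRACTION_PROBS = {
    "ISBP-derived": 0.29,
    "Intergenic": 0.636,
    "Exonic": 0.029,
    "Intronic": 0.045,
}


def generate_variant_records(
    n_loci: int,
    n_lines: int,
    class_mix: dict,
    tstv_target: float = 2.0,
    depth_distribution=("poisson", 20.0),
    mq_distribution=("normal", 45.0, 5.0),
    missing_rate: float = 0.0,
    multi_hit_rate: float = 0.0,
    seed: int = 0,
):
    """Generate VCF-style variant records plus per-line genotypes and truth.

    ``class_mix`` maps CLASS1..CLASS4 to proportions summing to 1; per-line
    genotype patterns realise the drawn class exactly.  Ref/alt pairs are
    transitions with probability ``tstv_target / (1 + tstv_target)``.
    Depth and RMS MQ are drawn from ``("constant", v)``, ``("poisson", mean)``
    or ``("normal", mean, sd)`` specifications.  Records are spread over the
    21 wheat-style chromosomes with sequence-fraction labels at realistic
    proportions.

    Returns ``(records, genotype_matrix, truth_classes)``.
    """
    rng = np.random.default_rng([seed, _OP_VARIANTS])
    classes = sorted(class_mix)
    unknown = set(classes) - {"CLASS1", "CLASS2", "CLASS3", "CLASS4"}
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    if n_lines < 2:
        raise ValueError("classes are undefined for fewer than 2 lines")

    lines = [f"Line{i + 1:02d}" for i in range(n_lines)]
    ts_prob = tstv_target / (1.0 + tstv_target)
    fr_names = list(_FRACTION_PROBS)
    fr_probs = np.array(list(_FRACTION_PROBS.values()))
    fr_probs = fr_probs / fr_probs.sum()

    def draw(dist):
        kind = dist[0]
        if kind == "constant":
            return float(dist[1])
        if kind == "poisson":
            return float(rng.poisson(dist[1]))
        if kind == "normal":
            return float(max(rng.normal(dist[1], dist[2]), 0.0))
        raise ValueError(f"unknown distribution kind: {kind}")

    def realize(cls):
        if cls == "CLASS4":
            return np.full(n_lines, "AB", dtype=object)
        if cls == "CLASS1":
            k = int(rng.integers(1, n_lines))  # lines carrying BB
            g = np.array(["AA"] * (n_lines - k) + ["BB"] * k, dtype=object)
        elif cls == "CLASS2":
            if n_lines < 3:
                raise ValueError("CLASS2 needs at least 3 lines")
            counts = rng.multinomial(n_lines - 3, [0.4, 0.2, 0.4])
            g = np.array(
                ["AA"] * (counts[0] + 1) + ["AB"] * (counts[1] + 1) + ["BB"] * (counts[2] + 1),
                dtype=object,
            )
        else:  # CLASS3
            k = int(rng.integers(1, n_lines))  # lines carrying AB
            g = np.array(["AA"] * (n_lines - k) + ["AB"] * k, dtype=object)
        rng.shuffle(g)
        return g

    rows, gts, truth = [], [], []
    pos_counter = {}
    for i in range(n_loci):
        cls = str(rng.choice(classes, p=probs))
        chrom = str(rng.choice(_WHEAT_CHROMS))
        pos_counter[chrom] = pos_counter.get(chrom, 0) + int(rng.integers(100, 10000))
        ref = str(rng.choice(["A", "C", "G", "T"]))
        if rng.random() < ts_prob:
            alt = _TRANSITION_PARTNER[ref]
        else:
            alt = str(rng.choice(_TRANSVERSION_PARTNERS[ref]))
        g = realize(cls)
        if missing_rate > 0:
            g = g.copy()
            g[rng.random(n_lines) < missing_rate] = "NN"
        arm = chrom + str(rng.choice(["S", "L"]))
        rows.append(
            {
                "locus": f"SNP{i + 1:06d}",
                "chrom": chrom,
                "pos": pos_counter[chrom],
                "ref": ref,
                "alt": alt,
                "depth": draw(depth_distribution),
                "rms_mq": draw(mq_distribution),
                "hit_count": 2 if rng.random() < multi_hit_rate else 1,
                "fraction": str(rng.choice(fr_names, p=fr_probs)),
                "arm": arm,
            }
        )
        gts.append(g)
        truth.append(cls)

    records = pd.DataFrame(rows).set_index("locus")
    genotype_matrix = pd.DataFrame(gts, index=records.index, columns=lines)
    truth_classes = pd.Series(truth, index=records.index, name="true_class")
    return records, genotype_matrix, truth_classes
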