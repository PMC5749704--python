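#!/usr/bin/env python
"""Variant discovery accounting and array candidate selection.

Applies the depth >= 5 / RMS MQ >= 30 post-filters to the simulated VCF,
classifies loci into the four genotype-pattern classes, computes Ts/Tv and
private-allele fractions per subgenome, builds the chromosome-by-fraction
summary table, and runs candidate selection against per-arm quotas with the
D-genome multiplier.
"""

from pathlib import Path

import pandas as pd

from polyarray import discovery as disc
from polyarray import io as pio

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "discovery"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    records, gt = pio.read_vcf(ROOT / "data" / "variants.vcf")
    ann = pd.read_csv(ROOT / "data" / "variant_annotations.tsv", sep="\t", index_col=0)
    records = records.join(ann)

    kept, dropped = disc.filter_variants(records)
    dropped["drop_reason"].value_counts().rename_axis("reason").to_frame("n").to_csv(
        OUT / "drop_reasons.tsv", sep="\t"
    )
    print(f"filters: {len(kept)} kept, {len(dropped)} dropped "
          f"({dropped['drop_reason'].value_counts().to_dict()})")

    gt_kept = gt.loc[kept.index]
    classes = disc.classify_loci(gt_kept)
    classes.to_csv(OUT / "classes.tsv", sep="\t")
    print("class spectrum:", (classes["snp_class"].value_counts(normalize=True) * 100)
          .round(1).to_dict())

    ts, tv, ratio = disc.ts_tv(kept)
    print(f"Ts/Tv: {ts}/{tv} = {ratio:.2f} "
          f"({100 * ts / (ts + tv):.0f}% transitions)")

    genome_of = kept["chrom"].map(disc.genome_of_chromosome)
    private = disc.private_snp_fractions(gt_kept, genome_of=genome_of)
    private["per_genome"].rename_axis("genome").to_frame().to_csv(
        OUT / "private_per_genome.tsv", sep="\t"
    )
    print("private-SNP fraction per subgenome:",
          (private["per_genome"] * 100).round(1).to_dict())

    table1 = disc.summarize_snps(kept)
    table1.to_csv(OUT / "snp_summary.tsv", sep="\t")
    print(f"summary grand total: {table1.loc['Total', 'Total']}")

    arms = sorted(kept["arm"].unique())
    arm_spec = [(a, 300.0 + 20.0 * i, disc.genome_of_chromosome(a[:-1]))
                for i, a in enumerate(arms)]
    quotas = disc.allocate_quota(arm_spec, total=2000, d_multiplier=2.0)
    pools = pd.Series({ln: ("European" if i < 4 else "Asian")
                       for i, ln in enumerate(gt.columns)})
    selected, audit = disc.select_candidates(kept, gt_kept, pools, quotas=quotas)
    audit.to_csv(OUT / "candidate_audit.tsv", sep="\t")
    selected.to_csv(OUT / "selected.tsv", sep="\t")
    print(f"candidate selection: {int(audit['eligible'].sum())} eligible, "
          f"{len(selected)} selected against a 2000-SNP quota")


if __name__ == "__main__":
    main()
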