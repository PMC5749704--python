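#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Emits, under results/data/: a 96-sample x 1,000-probeset two-channel signal
table with the polyploid category spectrum (59% diploidized polymorphic, 9%
null-allele, 17% monomorphic, 9% homoeologous-offset, 6% low-quality), a
5-group structured diversity panel, a 430-individual F6 SSD RIL population
with one distorted region, and 10,000 resequencing variant records for 8
lines — each with its ground truth.
"""

from pathlib import Path

from polyarray import io as pio
from polyarray import synthetic as syn

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    array_cfg = syn.ArrayScenarioConfig(n_samples=96, n_probesets=1000, seed=SEED)
    signals, truth = syn.generate_array_experiment(array_cfg)
    truth.validate_against(signal_table=signals)
    pio.write_signal_table(signals, OUT / "signals.tsv")
    pio.write_genotype_matrix(truth.genotypes, OUT / "array_truth_genotypes.tsv")
    truth.categories.rename_axis("probeset_id").to_frame().to_csv(
        OUT / "array_truth_classes.tsv", sep="\t"
    )
    print(f"array: {array_cfg.n_probesets} probesets x {array_cfg.n_samples} samples")
    print(truth.categories.value_counts().to_string())

    panel_cfg = syn.PanelScenarioConfig(seed=SEED)
    panel, panel_truth = syn.generate_population_panel(panel_cfg)
    pio.write_genotype_matrix(panel, OUT / "panel.tsv")
    panel_truth.categories.rename_axis("sample_id").to_frame().to_csv(
        OUT / "panel_groups.tsv", sep="\t"
    )
    print(f"panel: {len(panel)} accessions in {panel_cfg.n_groups} groups, "
          f"{panel_cfg.n_loci} loci, Fst {panel_cfg.fst}")

    # two markers per genetic position: array markers are far denser than
    # recombination resolution, so cosegregation bins are the norm
    import numpy as np

    rng = np.random.default_rng([SEED, 77])
    lengths = (160.0, 150.0, 140.0)
    positions = []
    for L in lengths:
        doubled = np.repeat(rng.uniform(0.0, L, 30), 2)  # 30 shared positions
        single = rng.uniform(0.0, L, 20)  # 20 singleton positions
        positions.append(tuple(np.sort(np.concatenate([doubled, single]))))
    positions = tuple(positions)
    ril_cfg = syn.RilScenarioConfig(
        n_individuals=430, n_chromosomes=3,
        markers_per_chromosome=(80, 80, 80),
        chromosome_length_cM=lengths,
        marker_positions=positions,
        distortion_loci=((1, 75.0, 0.8),),
        seed=SEED,
    )
    ril, ril_truth = syn.generate_ril_f6(ril_cfg)
    pio.write_genotype_matrix(ril, OUT / "ril.tsv")
    pio.write_map(ril_truth.genetic_map, OUT / "ril_true_map.tsv")
    print(f"RIL: {ril_cfg.n_individuals} F{ril_cfg.generation} individuals, "
          f"{ril.shape[1]} markers, distortion at chr2:75cM (bias 0.8)")

    records, gt, classes = syn.generate_variant_records(
        n_loci=10_000, n_lines=8,
        class_mix={"CLASS1": 0.55, "CLASS2": 0.15, "CLASS3": 0.2, "CLASS4": 0.1},
        tstv_target=68.0 / 32.0, multi_hit_rate=0.05, seed=SEED,
    )
    pio.write_vcf(records, gt, OUT / "variants.vcf")
    classes.rename_axis("locus").to_frame().to_csv(OUT / "variant_truth_classes.tsv", sep="\t")
    records[["arm", "fraction", "hit_count"]].to_csv(OUT / "variant_annotations.tsv", sep="\t")
    print(f"variants: {len(records)} loci x 8 lines, target Ts/Tv 2.12")


if __name__ == "__main__":
    main()
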