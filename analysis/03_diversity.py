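#!/usr/bin/env python
"""Diversity analysis: PIC, simple-matching distances, Ward/NJ trees, PAV.

Two analyses: (a) on the structured panel — per-locus PIC, the pairwise
simple-matching dissimilarity matrix, a Ward dendrogram and an NJ tree, with
a check that the generated groups come out as clades; (b) on the array
calls — a presence/absence (PAV) matrix from the OTV probesets without
missing data, and its NJ tree.
"""

from pathlib import Path

import pandas as pd

from polyarray import diversity as div
from polyarray import io as pio

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "diversity"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    panel = pio.read_genotype_matrix(ROOT / "data" / "panel.tsv")
    groups = pd.read_csv(ROOT / "data" / "panel_groups.tsv", sep="\t", index_col=0)["group"]

    pics = div.pic_per_locus(panel)
    pics.rename_axis("locus").to_frame().to_csv(OUT / "pic.tsv", sep="\t")
    print(f"panel PIC: mean {pics.mean():.3f}, "
          f"{(pics.between(0.4, 0.5)).mean() * 100:.0f}% of loci in [0.4, 0.5]")

    dist, _ = div.simple_matching_distance(panel)
    dist.to_csv(OUT / "distance.tsv", sep="\t")
    ward = div.ward_cluster(dist)
    nj = div.nj_tree(dist)
    pio.write_newick(ward.newick, OUT / "ward.nwk")
    pio.write_newick(nj.newick, OUT / "nj.nwk")

    tips = {t.name for t in nj.tree.tips()}
    clades = [frozenset(t.name for t in n.tips()) for n in nj.tree.non_tips()]
    recovered = sum(
        1 for g in groups.unique()
        if frozenset(groups[groups == g].index) in clades
        or frozenset(tips - set(groups[groups == g].index)) in clades
    )
    print(f"NJ tree recovers {recovered}/{groups.nunique()} groups as clades")

    calls = pio.read_genotype_matrix(ROOT / "genotyping" / "calls.tsv")
    report = pd.read_csv(ROOT / "genotyping" / "qc_report.tsv", sep="\t").set_index("probeset_id")
    pav = div.otv_pav_matrix(calls, report["category"])
    pav.to_csv(OUT / "pav.tsv", sep="\t")
    print(f"PAV matrix: {pav.shape[1]} OTV probesets without missing data, "
          f"{len(pav)} accessions")
    if pav.shape[1] >= 1:
        pav_dist = pd.DataFrame(
            (pav.to_numpy()[:, None, :] != pav.to_numpy()[None, :, :]).mean(axis=2),
            index=pav.index, columns=pav.index,
        )
        pio.write_newick(div.nj_tree(pav_dist).newick, OUT / "pav_nj.nwk")
        print("PAV-based NJ tree written")


if __name__ == "__main__":
    main()
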