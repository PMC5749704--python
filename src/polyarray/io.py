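"""Plain-text readers and writers for the pipeline's artifact formats.

Everything on disk is inspectable text: TSV for signal tables, genotype
matrices, maps and reports; VCF v4.2 for variant records; Newick for trees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SIGNAL_COLUMNS = ["probeset_id", "sample_id", "signal_a", "signal_b"]


def write_signal_table(table: pd.DataFrame, path):
    table[SIGNAL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_signal_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    extra = set(table.columns) - set(SIGNAL_COLUMNS)
    missing = set(SIGNAL_COLUMNS) - set(table.columns)
    if extra or missing:
        raise ValueError(
            f"signal table schema mismatch (unexpected: {sorted(extra)}, missing: {sorted(missing)})"
        )
    return table


def write_genotype_matrix(matrix: pd.DataFrame, path):
    """Samples x loci calls in {AA, AB, BB, OO, NN}; first column = sample id."""
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_genotype_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    valid = {"AA", "AB", "BB", "OO", "NN"}
    bad = set(pd.unique(m.to_numpy().ravel())) - valid
    if bad:
        raise ValueError(f"invalid genotype codes: {sorted(bad)}")
    return m


def write_map(genetic_map: pd.DataFrame, path):
    genetic_map[["marker", "chromosome", "position_cM"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})


def write_newick(newick: str, path):
    Path(path).write_text(newick.rstrip("\n") + "\n")


_GT_TO_VCF = {"AA": "0/0", "AB": "0/1", "BB": "1/1", "NN": "./."}
_VCF_TO_GT = {v: k for k, v in _GT_TO_VCF.items()}


def write_vcf(records: pd.DataFrame, genotype_matrix: pd.DataFrame, path):
    """Emit records as VCF v4.2 with INFO DP/MQ and per-sample GT.

    ``records`` rows align with ``genotype_matrix`` rows (loci); columns of
    the matrix are the sample lines.  Positions are 1-based as generated.
    """
    lines = list(genotype_matrix.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(records["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(lines) + "\n")
        for (rid, rec), (_, gts) in zip(records.iterrows(), genotype_matrix.iterrows()):
            info = f"DP={int(rec['depth'])};MQ={rec['rms_mq']:.6g}"
            gt_fields = "\t".join(_GT_TO_VCF[g] for g in gts)
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rid}\t{rec['ref']}\t{rec['alt']}"
                f"\t.\tPASS\t{info}\tGT\t{gt_fields}\n"
            )


def read_vcf(path):
    """Read a VCF with INFO DP/MQ and GT into (records, genotype_matrix)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts = [], []
    for v in vcf:
        rows.append(
            {
                "locus": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "depth": float(v.INFO.get("DP", np.nan)),
                "rms_mq": float(v.INFO.get("MQ", np.nan)),
            }
        )
        calls = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                calls.append("NN")
            elif a == 0 and b == 0:
                calls.append("AA")
            elif a == b:
                calls.append("BB")
            else:
                calls.append("AB")
        gts.append(calls)
    records = pd.DataFrame(rows).set_index("locus")
    genotype_matrix = pd.DataFrame(gts, index=records.index, columns=samples)
    return records, genotype_matrix


def write_annotation_bed(records: pd.DataFrame, path, context: int = 50):
    """BED-like fraction annotation (0-based half-open) for variant records."""
    with open(path, "w") as fh:
        for _, rec in records.iterrows():
            start = max(int(rec["pos"]) - 1, 0)
            fh.write(f"{rec['chrom']}\t{start}\t{start + 1}\t{rec['fraction']}\n")


def read_annotation_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "label"], dtype={"chrom": str}
    )
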