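"""File-format boundaries: minimal VCF, tabular SNP data, layout BED.

Internally every coordinate is 0-based half-open; VCF POS is 1-based at the
boundary. The VCF emitted here is deliberately minimal — CHROM is the
scaffold id, one biallelic ALT, and a per-sample AD (allele depth) field —
which is all the downstream genotype caller consumes. Reading goes through
cyvcf2 so that any standards-compliant VCF with AD fields works.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rilmap.simdata import GenomeLayout, SnpTable


def write_vcf(snps: SnpTable, path: str) -> None:
    """Write a minimal VCF (CHROM=scaffold, 1-based POS, per-sample AD)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##INFO=<ID=IM767,Number=1,Type=String,Description="IM parent call">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(snps.ril_ids)
            + "\n"
        )
        for i in range(snps.n_snps):
            cells = "\t".join(
                f"{snps.im_reads[i, r]},{snps.alt_reads[i, r]}" for r in range(snps.n_rils)
            )
            fh.write(
                f"{snps.scaffold_ids[i]}\t{snps.pos[i] + 1}\t.\t{snps.im_base[i]}\t"
                f"{snps.alt_base[i]}\t.\tPASS\tIM767={snps.im767[i]}\tAD\t{cells}\n"
            )


def read_vcf(path: str) -> SnpTable:
    """Read SNP allele depths from a VCF with per-sample AD fields.

    The REF allele is taken as the IM-parent base; an ``IM767`` INFO tag, if
    present, carries the parent-call status (default unambiguous).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    rils = list(vcf.samples)
    scafs, pos, refs, alts, im767, im_rows, alt_rows = [], [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        scafs.append(var.CHROM)
        pos.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        im767.append((var.INFO.get("IM767") or "IM"))
        im_rows.append(np.maximum(ad[:, 0], 0))
        alt_rows.append(np.maximum(ad[:, 1], 0))
    return SnpTable(
        scaffold_ids=np.array(scafs),
        pos=np.array(pos, dtype=np.int64),
        im_base=np.array(refs),
        alt_base=np.array(alts),
        im767=np.array(im767),
        ril_ids=rils,
        im_reads=np.vstack(im_rows).astype(np.int32),
        alt_reads=np.vstack(alt_rows).astype(np.int32),
    )


def write_snp_tsv(snps: SnpTable, path: str) -> None:
    """Long-format TSV: one row per (SNP, RIL) with read counts."""
    recs = []
    for i in range(snps.n_snps):
        for r, rid in enumerate(snps.ril_ids):
            recs.append(
                (
                    snps.scaffold_ids[i],
                    int(snps.pos[i]),
                    snps.im_base[i],
                    snps.alt_base[i],
                    rid,
                    int(snps.im_reads[i, r]),
                    int(snps.alt_reads[i, r]),
                )
            )
    pd.DataFrame(
        recs, columns=["scaffold", "pos", "im_base", "alt_base", "ril_id", "im_reads", "alt_reads"]
    ).to_csv(path, sep="\t", index=False)


def read_snp_tsv(path: str) -> SnpTable:
    df = pd.read_csv(path, sep="\t")
    rils = sorted(df["ril_id"].unique())
    ril_idx = {r: i for i, r in enumerate(rils)}
    sites = df.drop_duplicates(["scaffold", "pos"])[["scaffold", "pos", "im_base", "alt_base"]]
    sites = sites.reset_index(drop=True)
    key = {(s, p): i for i, (s, p) in enumerate(zip(sites["scaffold"], sites["pos"]))}
    im = np.zeros((len(sites), len(rils)), dtype=np.int32)
    alt = np.zeros_like(im)
    for _, row in df.iterrows():
        i = key[(row["scaffold"], row["pos"])]
        j = ril_idx[row["ril_id"]]
        im[i, j] = row["im_reads"]
        alt[i, j] = row["alt_reads"]
    return SnpTable(
        scaffold_ids=sites["scaffold"].to_numpy(),
        pos=sites["pos"].to_numpy(np.int64),
        im_base=sites["im_base"].to_numpy(),
        alt_base=sites["alt_base"].to_numpy(),
        im767=np.repeat("IM", len(sites)),
        ril_ids=list(rils),
        im_reads=im,
        alt_reads=alt,
    )


def write_layout_bed(layout: GenomeLayout, path: str) -> None:
    """BED-like TSV of scaffolds; unanchored scaffolds hide their chromosome."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tchromosome\tstart\tend\tlength\n")
        for s in layout.scaffolds:
            chrom = s.chromosome_id if s.anchored else "UNANCHORED"
            fh.write(f"{s.scaffold_id}\t{chrom}\t{s.start_bp}\t{s.end_bp}\t{s.length_bp}\n")


def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype TSV: ril_id, growup, method, replicate, then trait columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"ril_id", "growup", "method", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return df
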