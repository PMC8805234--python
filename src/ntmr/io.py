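"""Reading and writing cohort files.

A simulated cohort is stored as a trio VCF (phased parental genotypes,
unphased offspring), a phenotype TSV and a transmission-truth TSV, plus
a JSON manifest recording the seed.  Real data can instead arrive as
three aligned dosage TSVs (mother / child / optional father).
Sample naming convention in trio VCFs: ``M<i>``, ``F<i>``, ``C<i>``
share family index ``i``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simdata import TrioCohort

__all__ = [
    "write_trio_vcf",
    "read_trio_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_manifest",
]


def write_trio_vcf(cohort: TrioCohort, path) -> None:
    """Write parental phased and offspring unphased genotypes as VCF."""
    n = cohort.n_trios
    samples = []
    for i in range(n):
        samples += [f"M{i}", f"F{i}", f"C{i}"]
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        + "".join(f"##contig=<ID={c}>\n" for c in sorted(cohort.snp_meta["chrom"].unique()))
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    mat, pat = cohort.maternal_haplotypes, cohort.paternal_haplotypes
    child = cohort.offspring_genotype
    geno_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(header)
        for j, rec in enumerate(cohort.snp_meta.itertuples(index=False)):
            fields = [str(rec.chrom), str(rec.pos), rec.id, rec.oa, rec.ea, ".", "PASS", "."]
            gts = []
            for i in range(n):
                gts.append(f"{mat[i, 0, j]}|{mat[i, 1, j]}")
                gts.append(f"{pat[i, 0, j]}|{pat[i, 1, j]}")
                gts.append(geno_str[int(child[i, j])])
            fh.write("\t".join(fields + ["GT"] + gts) + "\n")


def read_trio_vcf(path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """Read a trio VCF written by :func:`write_trio_vcf`.

    Returns (snp_meta, maternal haplotypes (n,2,m), paternal haplotypes,
    offspring genotype dosage (n,m), family ids).  The effect allele is
    ALT (the dosage-counted allele).
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    m_idx = [i for i, s in enumerate(samples) if s.startswith("M")]
    f_idx = [i for i, s in enumerate(samples) if s.startswith("F")]
    c_idx = [i for i, s in enumerate(samples) if s.startswith("C")]
    if not (len(m_idx) == len(f_idx) == len(c_idx)):
        raise ValueError("trio VCF must contain matched M/F/C samples")
    fam = pd.Index([f"fam{int(samples[i][1:]):06d}" for i in m_idx], name="family_id")
    meta_rows, mats, pats, childs = [], [], [], []
    for var in vcf:
        meta_rows.append(
            dict(id=var.ID, chrom=int(var.CHROM), pos=var.POS,
                 ea=var.ALT[0], oa=var.REF)
        )
        g = np.array([row[:2] for row in var.genotypes], dtype=np.int8)
        mats.append(g[m_idx])
        pats.append(g[f_idx])
        childs.append(g[c_idx].sum(axis=1))
    snp_meta = pd.DataFrame(meta_rows)
    mat = np.stack(mats, axis=2)  # (n, 2, m)
    pat = np.stack(pats, axis=2)
    child = np.stack(childs, axis=1).astype(np.int8)
    snp_meta["freq"] = mat.sum(axis=1).mean(axis=0) / 2.0
    return snp_meta, mat, pat, child, fam


def write_dosage_tsv(dosages: np.ndarray, snp_ids, family_ids, path) -> None:
    pd.DataFrame(dosages, index=family_ids, columns=snp_ids).to_csv(
        path, sep="\t", index_label="family_id"
    )


def read_dosage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family_id")


def write_manifest(path, **entries) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
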