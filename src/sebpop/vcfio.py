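"""Serialization of simulated datasets: VCF v4.2, metadata TSV, ancestry TSV.

Genotypes are written as an uncompressed VCF v4.2 with a GT-only FORMAT;
hemizygous male X records carry ploidy-1 genotypes ("0"/"1", "." when
missing), everything else is unphased diploid ("0/0".."1/1", "./.").
Import goes through pysam and reverses the export losslessly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import DataError
from .simpop import (
    MISSING,
    REL_COLUMNS,
    Chromosome,
    GenotypeDataset,
    LocalAncestryMatrix,
    VariantMap,
)

__all__ = ["export_dataset", "import_dataset", "write_vcf", "read_vcf"]

_DIPLOID_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_HAPLOID_GT = {0: "0", 1: "1", MISSING: "."}


def write_vcf(dataset: GenotypeDataset, path: str | os.PathLike) -> None:
    v = dataset.variants
    male = (dataset.samples["sex"] == "M").to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sebpop\n")
        if v.chromosomes:
            for c in v.chromosomes:
                fh.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
        else:
            for name in pd.unique(v.chrom):
                length = int(v.pos[v.chrom == name].max())
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples["id"])
            + "\n"
        )
        for j in range(dataset.L):
            table = _HAPLOID_GT if v.is_x[j] else _DIPLOID_GT
            calls = [
                (table if v.is_x[j] and male[i] else _DIPLOID_GT)[int(dataset.G[i, j])]
                for i in range(dataset.n)
            ]
            fh.write(
                f"{v.chrom[j]}\t{int(v.pos[j])}\tvar{j}\t{v.ref[j]}\t{v.alt[j]}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | os.PathLike, samples: pd.DataFrame) -> GenotypeDataset:
    """Read a VCF written by :func:`write_vcf` back into a dataset."""
    vf = pysam.VariantFile(os.fspath(path))
    ids = list(vf.header.samples)
    if ids != list(samples["id"]):
        raise DataError("VCF sample columns do not match the metadata table")
    chroms, pos, ref, alt, rows = [], [], [], [], []
    contigs = [
        Chromosome(name, c.length, c.length / 1e8, is_x=(name.upper() == "X"))
        for name, c in vf.header.contigs.items()
    ]
    for rec in vf:
        chroms.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(rec.alts[0] if rec.alts else ".")
        row = np.empty(len(ids), dtype=np.int8)
        for i, sid in enumerate(ids):
            alleles = rec.samples[sid]["GT"]
            if alleles is None or all(a is None for a in alleles):
                row[i] = MISSING
            else:
                row[i] = sum(a for a in alleles if a is not None)
        rows.append(row)
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(pos, dtype=np.int64)
    is_x = np.array([c == "X" for c in chroms])
    cm = np.empty(len(pos_arr))
    for c in contigs:
        sel = chrom_arr == c.name
        cm[sel] = pos_arr[sel] * (100.0 * c.length_morgans / c.length_bp)
    variants = VariantMap(
        chrom=chrom_arr,
        pos=pos_arr,
        cm=cm,
        is_x=is_x,
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        chromosomes=contigs,
    )
    return GenotypeDataset(
        G=np.vstack(rows).T.copy(), variants=variants, samples=samples.reset_index(drop=True)
    )


def write_local_ancestry(
    la: LocalAncestryMatrix, sample_ids, path: str | os.PathLike
) -> None:
    """Long-format TSV: haplotype, chrom, pos, ancestry, posterior."""
    v = la.variants
    if v is None:
        raise DataError("LocalAncestryMatrix carries no variant map")
    n2, L = la.A.shape
    hap_names = np.array(
        [f"{sample_ids[r // 2]}_h{r % 2}" for r in range(n2)], dtype=object
    )
    valid = la.A >= 0
    rows, cols = np.nonzero(valid)
    df = pd.DataFrame(
        {
            "haplotype": hap_names[rows],
            "chrom": v.chrom[cols],
            "pos": v.pos[cols],
            "ancestry": la.A[rows, cols],
            "posterior": la.P[rows, cols],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_local_ancestry(
    path: str | os.PathLike, sample_ids, variants: VariantMap, K: int
) -> LocalAncestryMatrix:
    df = pd.read_csv(path, sep="\t")
    n2 = 2 * len(sample_ids)
    A = np.full((n2, len(variants)), MISSING, dtype=np.int8)
    P = np.zeros((n2, len(variants)), dtype=np.float32)
    hap_index = {
        f"{sid}_h{h}": 2 * i + h for i, sid in enumerate(sample_ids) for h in (0, 1)
    }
    col_index = {
        (c, int(p)): j for j, (c, p) in enumerate(zip(variants.chrom, variants.pos))
    }
    r = df["haplotype"].map(hap_index).to_numpy()
    c = [col_index[(ch, int(p))] for ch, p in zip(df["chrom"], df["pos"])]
    A[r, c] = df["ancestry"].to_numpy(dtype=np.int8)
    P[r, c] = df["posterior"].to_numpy(dtype=np.float32)
    return LocalAncestryMatrix(A=A, P=P, K=K, variants=variants)


def export_dataset(
    dataset: GenotypeDataset,
    la: LocalAncestryMatrix | None,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write genotypes.vcf, samples.tsv and (optionally) local_ancestry.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(out / "genotypes.vcf"),
        "samples": str(out / "samples.tsv"),
    }
    write_vcf(dataset, paths["vcf"])
    cols = ["id", "group", "site", "sex", "self_ethnicity", *REL_COLUMNS]
    dataset.samples[cols].to_csv(paths["samples"], sep="\t", index=False)
    if la is not None:
        paths["local_ancestry"] = str(out / "local_ancestry.tsv")
        write_local_ancestry(la, dataset.samples["id"].to_numpy(), paths["local_ancestry"])
    return paths


def import_dataset(
    vcf_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    la_path: str | os.PathLike | None = None,
    K: int = 3,
) -> tuple[GenotypeDataset, LocalAncestryMatrix | None]:
    samples = pd.read_csv(samples_path, sep="\t")
    dataset = read_vcf(vcf_path, samples)
    la = None
    if la_path is not None:
        la = read_local_ancestry(
            la_path, samples["id"].to_numpy(), dataset.variants, K
        )
    return dataset, la
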