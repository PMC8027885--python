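#!/usr/bin/env python
"""Genome scans: PBS selection statistic, Khoe-San ancestry enrichment,
and allele-frequency fold changes between groups.

PBS contrasts the highest- and lowest-Khoe-San groups against an outgroup;
the enrichment scan flags runs of >= 3 SNPs whose Khoe-San local-ancestry
dosage exceeds the genome-wide mean by 3 SD (posterior > 0.8, 2 Mb
centromere/telomere exclusion); the fold-change scan ranks variants with a
>= 3-fold allele-frequency difference, with the 50 x 30 bootstrap SE.
"""

import argparse
from pathlib import Path

import numpy as np

from sebpop import ancestry, simpop, structure


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/scans"))
    ap.add_argument("--L", type=int, default=6000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # three groups: high-KS, low-KS and an outgroup-like third population
    cfg = simpop.SimConfig(
        groups=[
            simpop.GroupSpec(name="Tswana-like", n=120, q=[0.78, 0.21, 0.01],
                             drift=0.004, g=24),
            simpop.GroupSpec(name="Tsonga-like", n=120, q=[0.978, 0.015, 0.007],
                             drift=0.004, g=45),
            simpop.GroupSpec(name="Outgroup", n=120, q=[0.02, 0.01, 0.97],
                             drift=0.004, g=10),
        ],
        chroms=simpop.default_chromosomes(4, include_x=False),
        L=args.L,
        F_anc=simpop.DEFAULT_F_ANC,
        seed=args.seed,
    )
    ds, la, _ = simpop.simulate_genotypes(cfg)
    labels = ds.samples["group"].to_numpy()

    # --- PBS: per-locus F_ST ratios between the three pairs, MAF > 0.01
    f = ds.G.mean(axis=0) / 2
    maf_ok = np.minimum(f, 1 - f) > 0.01

    def per_locus_fst(a, b):
        ca, cb, cc, _ = structure.weir_cockerham_fst(ds.G, labels, a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ca + cb + cc != 0, ca / (ca + cb + cc), 0.0)

    ab = per_locus_fst("Tswana-like", "Tsonga-like")
    ac = per_locus_fst("Tswana-like", "Outgroup")
    bc = per_locus_fst("Tsonga-like", "Outgroup")
    pbs = ancestry.pbs_scores(ab[maf_ok], ac[maf_ok], bc[maf_ok])
    order = np.argsort(np.nan_to_num(pbs.pbs))[::-1]
    idx = np.flatnonzero(maf_ok)
    print("top PBS variants (Tswana-like branch):")
    with open(args.out / "pbs_top.tsv", "w") as fh:
        fh.write("chrom\tpos\tPBS\tFST_ab\tFST_ac\tFST_bc\n")
        for r in order[:10]:
            j = idx[r]
            fh.write(
                f"{ds.variants.chrom[j]}\t{ds.variants.pos[j]}\t{pbs.pbs[r]:.4f}"
                f"\t{ab[j]:.4f}\t{ac[j]:.4f}\t{bc[j]:.4f}\n"
            )
        for r in order[:3]:
            j = idx[r]
            print(f"  {ds.variants.chrom[j]}:{ds.variants.pos[j]}  "
                  f"PBS={pbs.pbs[r]:.3f}")

    # --- Khoe-San enrichment scan on the high-KS group's haplotypes
    rows = np.flatnonzero(labels == "Tswana-like")
    hap = np.sort(np.concatenate([2 * rows, 2 * rows + 1]))
    la_grp = simpop.LocalAncestryMatrix(
        A=la.A[hap], P=la.P[hap], K=la.K, variants=la.variants
    )
    regions = ancestry.khoesan_enrichment_scan(la_grp, ancestry_index=1)
    (args.out / "ks_enrichment.bed").write_text(ancestry.regions_to_bed(regions))
    print(f"\nKhoe-San enrichment: {len(regions)} candidate regions "
          f"(>= +3 SD, >= 3 SNPs)")

    # --- allele-frequency fold changes between the two Bantu-speaker groups
    sel = labels != "Outgroup"
    ranked, unbounded = ancestry.allele_frequency_scan(
        ds.G[sel], labels[sel], fold_min=3.0, n_boot=50, subsample=30,
        seed=args.seed, variants=ds.variants,
    )
    ranked.to_csv(args.out / "fold_changes.tsv", sep="\t", index=False)
    print(f"\n{len(ranked)} variants with >= 3-fold frequency difference "
          f"({len(unbounded)} unbounded excluded); top entries:")
    if len(ranked):
        print(ranked.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
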