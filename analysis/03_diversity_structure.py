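#!/usr/bin/env python
"""Diversity, differentiation, isolation-by-distance, tree and PCA.

Reports per-location H_O / H_E / Pi, the pairwise Weir–Cockerham F_ST
matrix with permutation significance, gene flow Nm among the river
systems, Mantel isolation-by-distance (all native locations and
excluding the admixed Nenjiang), the bootstrap NJ tree on Nei distance,
and individual PCA coordinates.
"""

import argparse
from pathlib import Path

from ctenopop import diversity as dv
from ctenopop import io_core as io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=999)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    g = io.read_vcf(args.datadir / "filtered.vcf")
    popmap = io.read_population_map(args.datadir / "popmap.tsv")
    sites = io.read_site_table(args.datadir / "sites.tsv", popmap.populations)

    div = dv.per_pop_diversity(g, popmap)
    print(div.round(4).to_string())
    div.to_csv(args.outdir / "diversity.tsv", sep="\t")

    fst, pvals, signif = dv.pairwise_fst_test(g, popmap, n_perm=args.n_perm, seed=args.seed)
    fst.values.round(4).to_csv(args.outdir / "pairwise_fst.tsv", sep="\t")
    pvals.round(4).to_csv(args.outdir / "pairwise_fst_p.tsv", sep="\t")
    n_sig = int(signif.to_numpy().sum() // 2)
    print(f"significant pairs after Bonferroni: {n_sig} of {signif.shape[0]*(signif.shape[0]-1)//2}")

    native = [p for p in popmap.populations if popmap.native[p]]
    reps = {"Heilongjiang": "Nenjiang", "Yangtze": "Hanjiang", "Pearl": "Zhaoqing"}
    nms = {
        f"{a}-{b}": dv.nm_from_fst(fst.values.loc[reps[a], reps[b]])
        for i, a in enumerate(reps)
        for b in list(reps)[i + 1 :]
    }
    print("Nm among river systems:", {k: round(v, 2) for k, v in nms.items()})

    for label, pops in [
        ("all_native", native),
        ("excluding_nenjiang", [p for p in native if p != "Nenjiang"]),
    ]:
        dm = dv.DistanceMatrix(fst.values.loc[pops, pops], "fst")
        res = dv.mantel_test(
            dv.geographic_distance(sites, pops), dv.linearized_fst(dm),
            n_perm=999, seed=args.seed,
        )
        print(f"IBD {label}: R^2 = {res.r_squared:.3f}, P = {res.p_value:.4f}")

    tree, _support = dv.nj_tree_with_support(g, popmap, n_bootstrap=500, seed=args.seed)
    (args.outdir / "nj_tree.nwk").write_text(str(tree))

    pca = dv.pca_genotypes(g)
    pca.coordinates.round(4).to_csv(args.outdir / "pca_coordinates.tsv", sep="\t")
    print("PCA leading eigenvalues:", pca.eigenvalues[:4].round(2))


if __name__ == "__main__":
    main()
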