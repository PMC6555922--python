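#!/usr/bin/env python
"""The three selection scans and their combination.

Environmental association (covariance-controlled Bayes factors for
temperature and latitude across the native locations), the
hierarchical-island F_ST outlier test and the F-model outlier test
(both across all nine locations, where balancing selection is
interpretable), set combination, and power/false-positive accounting
against the planted truth labels.
"""

import argparse
from pathlib import Path

import pandas as pd

from ctenopop import filtering as flt
from ctenopop import io_core as io
from ctenopop import selection as sel


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    g = flt.filter_maf(io.read_vcf(args.datadir / "filtered.vcf"), 0.05)
    popmap = io.read_population_map(args.datadir / "popmap.tsv")
    sites = io.read_site_table(args.datadir / "sites.tsv", popmap.populations)
    truth = pd.read_csv(args.datadir / "truth.tsv", sep="\t", index_col=0).reindex(g.loci.index)

    native = [p for p in popmap.populations if popmap.native[p]]
    pm_nat = popmap.subset(native)
    g_nat = g.take_individuals([i for i in g.individuals if i in pm_nat.population_of.index])

    # --- environmental association across native locations
    pc = sel.estimate_pop_cov(g_nat, pm_nat, n_iter=800, seed=args.seed)
    bf_t = sel.env_bayes_factor(
        g_nat, pm_nat, pc, sites.covariate("temp_c", pm_nat.populations), seed=args.seed + 1
    )
    bf_l = sel.env_bayes_factor(
        g_nat, pm_nat, pc, sites.covariate("latitude", pm_nat.populations), seed=args.seed + 2
    )
    latitudinal = sel.latitudinal_candidates(bf_t, bf_l)
    print(f"latitudinal candidates (BF > 3 for temperature AND latitude): {len(latitudinal)}")

    # --- F_ST outlier tests across all nine locations
    fd = sel.fdist_hier_outliers(g, popmap, n_sims=50_000, seed=args.seed + 3, calib_loci=10_000)
    fm = sel.fmodel_outliers(g, popmap, n_iter=1500, burn=500, seed=args.seed + 4)
    print(
        f"hierarchical-island outliers: {int(fd['positive'].sum())} positive, "
        f"{int(fd['balancing'].sum())} balancing"
    )
    print(
        f"F-model outliers: {int(fm.table['positive'].sum())} positive, "
        f"{int(fm.table['balancing'].sum())} balancing"
    )

    combo = sel.combine_outlier_sets(
        {
            "hier_positive": set(fd.index[fd["positive"]]),
            "fmodel_positive": set(fm.table.index[fm.table["positive"].astype(bool)]),
            "latitudinal": set(latitudinal),
        }
    )
    print(f"union of outlier sets: {combo['union_size']}")
    print("pairwise intersections:", combo["pairwise_intersections"])

    # --- accounting against planted truth
    for cls, col_tab, col in [
        ("clinal", bf_t, "significant"),
        ("divergent", fd, "positive"),
        ("balanced", fd, "balancing"),
    ]:
        ids = truth.index[truth["class"] == cls]
        rate = float(col_tab.loc[ids, col].mean()) if len(ids) else float("nan")
        print(f"power on planted {cls} loci ({col}): {rate:.2f}")

    table = pd.DataFrame(
        {
            "He": fd["He"],
            "theta": fd["theta"],
            "BF_temp": bf_t["BF"].reindex(g.loci.index),
            "BF_lat": bf_l["BF"].reindex(g.loci.index),
            "p_hier": fd["p_high"],
            "q_fmodel": fm.table["q"],
            "hier_positive": fd["positive"],
            "hier_balancing": fd["balancing"],
            "fmodel_positive": fm.table["positive"],
            "fmodel_balancing": fm.table["balancing"],
            "latitudinal": fd.index.isin(latitudinal),
            "truth": truth["class"],
        }
    )
    table.round(5).to_csv(args.outdir / "outlier_table.tsv", sep="\t")
    io.write_manifest(
        args.outdir / "manifest_selection.json",
        "selection_scan",
        args.seed,
        {"bf_threshold": 3, "hier_quantile": 0.995, "hier_fdr": 0.01, "q_threshold": 0.05},
        {"loci": g.n_loci, "union": combo["union_size"]},
    )


if __name__ == "__main__":
    main()
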