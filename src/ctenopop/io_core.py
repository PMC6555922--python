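"""Readers and writers for the interchange formats the pipeline touches.

VCF 4.x is the genotype interchange dialect (read through cyvcf2); the
population map, site table and plain genotype table are tab-separated text
with a header row.  Every stage can drop a JSON manifest recording inputs,
seed, thresholds and counts for provenance.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, SiteTable, make_locus_table

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF into a :class:`GenotypeMatrix`.

    Biallelic records become alt-dosage columns (0/1/2); multi-allelic
    records are carried with ``n_alleles`` set accordingly (any non-ref
    allele counts toward the dosage) so the paralog-tag filter can act on
    them.  ``./.`` becomes :data:`~ctenopop.core.MISSING`.  The RAD tag id
    is taken from an ``INFO/TAG`` field when present, else from the VCF ID
    up to the first ``_``.

    Raises
    ------
    ValueError
        On haploid or polyploid GT fields (unsupported ploidy).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    dosages, ids, tags, scaffolds, positions, refs, alts, nalls = (
        [], [], [], [], [], [], [], [],
    )
    for i, rec in enumerate(vcf):
        gts = rec.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is the phasing flag
            raise ValueError(
                f"unsupported ploidy {gts.shape[1] - 1} at record {i + 1} "
                f"({rec.CHROM}:{rec.POS})"
            )
        alleles = gts[:, :2]
        miss = (alleles < 0).any(axis=1)
        dos = (alleles > 0).sum(axis=1).astype(np.int8)
        dos[miss] = MISSING
        dosages.append(dos)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        ids.append(vid)
        tag = rec.INFO.get("TAG")
        tags.append(str(tag) if tag is not None else vid.split("_")[0])
        scaffolds.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(",".join(rec.ALT) if rec.ALT else ".")
        nalls.append(1 + len(rec.ALT))
    loci = make_locus_table(ids, tags, scaffolds, positions, refs, alts, nalls)
    dosage = (
        np.stack(dosages, axis=1)
        if dosages
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, loci, dosage)


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=TAG,Number=1,Type=String,Description="RAD tag id">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    loci = g.loci
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for scaf in dict.fromkeys(loci["scaffold"]):
            sub = loci[loci["scaffold"] == scaf]
            length = int(sub["position"].max()) + 1000 if len(sub) else 1000
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.individuals))
            + "\n"
        )
        dosage = g.dosage
        for j, (locus_id, row) in enumerate(loci.iterrows()):
            gts = "\t".join(_GT_STRING[int(d)] for d in dosage[:, j])
            fh.write(
                f"{row['scaffold']}\t{int(row['position'])}\t{locus_id}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\tTAG={row['tag_id']}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_population_map(path) -> PopulationMap:
    """TSV with columns individual, population, group, native (0/1 or bool)."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    need = {"individual", "population", "group", "native"}
    if not need.issubset(t.columns):
        raise ValueError(f"population map needs columns {sorted(need)}")
    if t["individual"].duplicated().any():
        dupes = t.loc[t["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"duplicate individual ids in population map: {dupes[:5]}")
    per_pop = t.drop_duplicates("population").set_index("population")
    native = per_pop["native"].str.lower().isin({"1", "true", "yes"})
    return PopulationMap(
        population_of=t.set_index("individual")["population"],
        group_of=per_pop["group"],
        native=native,
    )


def write_population_map(pm: PopulationMap, path) -> None:
    rows = [
        {
            "individual": ind,
            "population": pop,
            "group": pm.group_of[pop],
            "native": int(pm.native[pop]),
        }
        for ind, pop in pm.population_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_site_table(path, known_populations=None) -> SiteTable:
    """TSV with columns population, latitude, longitude, temp_c."""
    t = pd.read_csv(path, sep="\t").set_index("population")
    if known_populations is not None:
        unknown = set(t.index) - set(known_populations)
        if unknown:
            warnings.warn(
                f"site table lists unknown populations: {sorted(unknown)}",
                stacklevel=2,
            )
    return SiteTable(t)


def write_site_table(st: SiteTable, path) -> None:
    st.table.to_csv(path, sep="\t", index_label="population")


def read_genotype_table(path) -> GenotypeMatrix:
    """Individuals x loci dosage TSV: first column individual id, header row
    of locus ids, cells 0/1/2 or NA."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    dosage = t.to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(list(t.index), make_locus_table(list(t.columns)), dosage)


def write_genotype_table(g: GenotypeMatrix, path) -> None:
    d = g.dosage.astype(object)
    d[g.dosage == MISSING] = "NA"
    pd.DataFrame(d, index=g.individuals, columns=g.loci.index).to_csv(
        path, sep="\t", index_label="individual"
    )


def check_individuals_mapped(g: GenotypeMatrix, pm: PopulationMap) -> None:
    """Hard error listing genotyped individuals absent from the map."""
    absent = [i for i in g.individuals if i not in pm.population_of.index]
    if absent:
        raise KeyError(f"individuals missing from population map: {absent}")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def write_manifest(path, stage: str, seed, params: dict, counts: dict) -> None:
    """Per-stage provenance record (inputs, seed, thresholds, counts)."""
    payload = {"stage": stage, "seed": seed, "params": params, "counts": counts}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
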