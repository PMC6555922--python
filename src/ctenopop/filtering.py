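"""The SNP quality cascade, stage by stage, with per-stage counting.

Order of the full cascade: per-population call rate > 0.7, paralog-tag
removal (multi-allelic or observed heterozygosity > 0.5 anywhere on the
tag), one SNP per tag (lowest coordinate), Hardy–Weinberg exact test at
alpha = 0.01 per location, and — for the demographic-inference subset —
pooled MAF > 0.05, overall missingness <= 0.05 and LD pruning at
R^2 >= 0.05.

Every filter is a pure projection: surviving genotypes are never altered.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import MISSING, GenotypeMatrix, PopulationMap, RunConfig


@dataclass
class FilterReport:
    """Ordered per-stage accounting: (stage, in, removed, out, params)."""

    stages: list = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, params: dict) -> None:
        self.stages.append(
            {
                "stage": name,
                "loci_in": int(n_in),
                "loci_removed": int(n_in - n_out),
                "loci_out": int(n_out),
                "params": dict(params),
            }
        )
        assert self.stages[-1]["loci_out"] == n_in - self.stages[-1]["loci_removed"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.stages)


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------


def call_rate_mask(g: GenotypeMatrix, popmap: PopulationMap, min_prop: float = 0.7) -> np.ndarray:
    """Keep a locus iff in *every* population the fraction of non-missing
    genotypes is strictly greater than ``min_prop``."""
    rows = popmap.row_indices(g)
    keep = np.ones(g.n_loci, dtype=bool)
    called = g.dosage != MISSING
    for pop, idx in rows.items():
        frac = called[idx].mean(axis=0)
        keep &= frac > min_prop
    return keep


def filter_call_rate(g, popmap, min_prop: float = 0.7) -> GenotypeMatrix:
    return g.take_loci(call_rate_mask(g, popmap, min_prop))


def observed_het(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus observed heterozygosity across all genotyped individuals."""
    called = g.dosage != MISSING
    het = g.dosage == 1
    with np.errstate(invalid="ignore"):
        n = called.sum(axis=0).astype(float)
        return np.where(n > 0, het.sum(axis=0) / n, np.nan)


def paralog_tag_mask(g: GenotypeMatrix, literal_and: bool = False) -> np.ndarray:
    """Drop whole tags where any SNP looks paralogous.

    A SNP is a paralogy signal if it has more than two alleles or observed
    heterozygosity > 0.5.  By default the two signals combine as OR (a
    multi-allelic SNP is unrepresentable as a biallelic dosage column and
    is an independent red flag); ``literal_and`` requires both.
    """
    ho = observed_het(g)
    multi = g.loci["n_alleles"].to_numpy() > 2
    high_het = ho > 0.5
    bad_snp = (multi & high_het) if literal_and else (multi | high_het)
    bad_tags = set(g.loci.loc[bad_snp, "tag_id"])
    return ~g.loci["tag_id"].isin(bad_tags).to_numpy()


def filter_paralog_tags(g, literal_and: bool = False) -> GenotypeMatrix:
    return g.take_loci(paralog_tag_mask(g, literal_and))


def first_snp_mask(g: GenotypeMatrix) -> np.ndarray:
    """Keep exactly the lowest-coordinate SNP of each tag."""
    loci = g.loci
    best = (
        loci.assign(_col=np.arange(len(loci)))
        .sort_values(["tag_id", "position"], kind="mergesort")
        .drop_duplicates("tag_id")["_col"]
        .to_numpy()
    )
    keep = np.zeros(g.n_loci, dtype=bool)
    keep[best] = True
    return keep


def thin_first_snp_per_tag(g) -> GenotypeMatrix:
    return g.take_loci(first_snp_mask(g))


# -- Hardy–Weinberg exact test ---------------------------------------------


@lru_cache(maxsize=200_000)
def _hwe_het_distribution(n: int, n_a: int):
    """Levene/Haldane distribution of heterozygote counts given ``n``
    diploids and ``n_a`` copies of allele A (n_a <= n alleles of 2n).

    Returns (het_counts, probabilities).
    """
    n_b = 2 * n - n_a
    hets = list(range(n_a % 2, min(n_a, n_b) + 1, 2))
    logs = []
    lf = math.lgamma
    base = lf(n + 1) + lf(n_a + 1) + lf(n_b + 1) - lf(2 * n + 1)
    for h in hets:
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        logs.append(base + h * math.log(2.0) - lf(naa + 1) - lf(h + 1) - lf(nbb + 1))
    probs = np.exp(np.array(logs))
    probs /= probs.sum()
    return np.array(hets), probs


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value by full enumeration of
    heterozygote counts conditional on allele counts: the sum of all
    outcome probabilities <= that of the observed table."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return 1.0  # monomorphic: defined as 1
    hets, probs = _hwe_het_distribution(n, min(n_a, 2 * n - n_a))
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_mask(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    alpha: float = 0.01,
    rule: str = "any",
) -> np.ndarray:
    """Remove loci deviating from HWE (exact test) per location.

    ``rule='any'`` removes a locus deviating in >= 1 population (default,
    the inclusive reading); ``rule='exactly_one'`` in exactly one.
    """
    rows = popmap.row_indices(g)
    n_dev = np.zeros(g.n_loci, dtype=int)
    for pop, idx in rows.items():
        d = g.dosage[idx]
        n_bb_arr = (d == 2).sum(axis=0)
        n_ab_arr = (d == 1).sum(axis=0)
        n_aa_arr = (d == 0).sum(axis=0)
        for j in range(g.n_loci):
            p = hwe_exact_pvalue(int(n_aa_arr[j]), int(n_ab_arr[j]), int(n_bb_arr[j]))
            if p < alpha:
                n_dev[j] += 1
    if rule == "any":
        return n_dev == 0
    if rule == "exactly_one":
        return n_dev != 1
    raise ValueError(f"unknown HWE rule {rule!r}")


def hwe_exact_filter(g, popmap, alpha: float = 0.01, rule: str = "any") -> GenotypeMatrix:
    return g.take_loci(hwe_mask(g, popmap, alpha, rule))


# -- frequency / missingness / LD ------------------------------------------


def maf_mask(g: GenotypeMatrix, threshold: float = 0.05) -> np.ndarray:
    """Keep loci with pooled minor allele frequency strictly > threshold."""
    maf = g.minor_allele_freq()
    return np.nan_to_num(maf, nan=0.0) > threshold


def filter_maf(g, threshold: float = 0.05) -> GenotypeMatrix:
    return g.take_loci(maf_mask(g, threshold))


def missing_fraction_mask(g: GenotypeMatrix, cutoff: float = 0.05) -> np.ndarray:
    return g.missing_mask().mean(axis=0) <= cutoff


def filter_missing_fraction(g, cutoff: float = 0.05) -> GenotypeMatrix:
    return g.take_loci(missing_fraction_mask(g, cutoff))


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    called individuals; 0 when either is constant."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune_mask(
    g: GenotypeMatrix, r2_max: float = 0.05, window: int = 200
) -> np.ndarray:
    """Greedy genome-order LD pruning.

    Scans loci in column (genome) order; a candidate is dropped if its
    genotype R^2 with any previously kept locus among the last ``window``
    kept loci on the same scaffold is >= ``r2_max``.
    """
    keep = np.zeros(g.n_loci, dtype=bool)
    kept_idx: list = []
    scafs = g.loci["scaffold"].to_numpy()
    d = g.dosage
    for j in range(g.n_loci):
        ok = True
        for i in reversed(kept_idx[-window:]):
            if scafs[i] != scafs[j]:
                break
            if genotype_r2(d[:, i], d[:, j]) >= r2_max:
                ok = False
                break
        if ok:
            keep[j] = True
            kept_idx.append(j)
    return keep


def ld_prune(g, r2_max: float = 0.05, window: int = 200) -> GenotypeMatrix:
    return g.take_loci(ld_prune_mask(g, r2_max, window))


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def run_filter_cascade(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    config: RunConfig | None = None,
    abc_subset: bool = False,
):
    """The full quality cascade in study order.

    call-rate -> paralog-tag -> first-SNP thinning -> HWE, then (when
    ``abc_subset``) MAF -> missingness -> LD pruning.  Returns the
    filtered matrix and a :class:`FilterReport`.
    """
    cfg = config or RunConfig()
    report = FilterReport()
    stages = [
        ("call_rate", lambda m: filter_call_rate(m, popmap, cfg.call_rate_min),
         {"min_prop": cfg.call_rate_min}),
        ("paralog_tags", filter_paralog_tags, {}),
        ("first_snp_per_tag", thin_first_snp_per_tag, {}),
        ("hwe_exact", lambda m: hwe_exact_filter(m, popmap, cfg.hwe_alpha),
         {"alpha": cfg.hwe_alpha}),
    ]
    if abc_subset:
        stages += [
            ("maf", lambda m: filter_maf(m, cfg.maf_min), {"threshold": cfg.maf_min}),
            ("missing_fraction", lambda m: filter_missing_fraction(m, cfg.missing_max),
             {"cutoff": cfg.missing_max}),
            ("ld_prune", lambda m: ld_prune(m, cfg.ld_r2_max), {"r2_max": cfg.ld_r2_max}),
        ]
    for name, fn, params in stages:
        n_in = g.n_loci
        g = fn(g)
        report.add(name, n_in, g.n_loci, params)
        if g.n_loci == 0:
            raise ValueError(f"filter stage {name!r} removed every locus")
    return g, report
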