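"""Sliding-window differentiation along scaffolds and island detection.

Windows tile each scaffold (tumbling by default, step = size; an arbitrary
step gives overlapping windows) in half-open [start, end) base-pair
coordinates; SNP positions are 1-based and converted at the boundary.
Per window: SNP count, mean per-locus Weir–Cockerham theta between two
pooled river-system groups (defined only above a minimum SNP count), SNP
density, and an elevation flag for island detection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationMap
from .diversity import wc_fst_grouped


def _group_rows(g: GenotypeMatrix, popmap: PopulationMap, group: str) -> np.ndarray:
    pops = [p for p in popmap.populations if popmap.group_of[p] == group]
    if not pops:
        raise ValueError(f"no populations in group {group!r}")
    rows = popmap.row_indices(g)
    return np.concatenate([rows[p] for p in pops])


def window_fst(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    window_size: int,
    step: int | None = None,
    min_snps: int = 3,
) -> pd.DataFrame:
    """Windowed mean per-locus theta between two pooled groups.

    Returns one row per window: scaffold, start, end (half-open bp),
    n_snps, mean_theta (NaN under ``min_snps``), partial flag for the
    trailing short window.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    step = step or window_size
    per_locus, _multi = wc_fst_grouped(
        g, _group_rows(g, popmap, group_a), _group_rows(g, popmap, group_b)
    )
    loci = g.loci
    pos0 = loci["position"].to_numpy() - 1  # 1-based -> 0-based half-open
    rows = []
    for scaf in dict.fromkeys(loci["scaffold"]):
        m = (loci["scaffold"] == scaf).to_numpy()
        length = int(pos0[m].max()) + 1
        start = 0
        while start < length:
            end = start + window_size
            inw = m & (pos0 >= start) & (pos0 < end)
            th = per_locus[inw]
            th = th[np.isfinite(th)]
            rows.append(
                {
                    "scaffold": scaf,
                    "start": start,
                    "end": end,
                    "n_snps": int(inw.sum()),
                    "mean_theta": float(th.mean()) if len(th) >= min_snps else np.nan,
                    "partial": end > length,
                }
            )
            start += step
    return pd.DataFrame(rows)


def snp_density(windows: pd.DataFrame) -> pd.DataFrame:
    """Append SNPs-per-bp density."""
    out = windows.copy()
    out["density"] = out["n_snps"] / (out["end"] - out["start"])
    return out


def density_independence(windows: pd.DataFrame, n_perm: int = 999, seed: int = 0):
    """Spearman correlation between window mean theta and SNP density with
    a permutation p-value; (0, 1.0, flagged) when either is constant."""
    from scipy.stats import rankdata

    w = snp_density(windows)
    ok = w["mean_theta"].notna()
    if ok.sum() < 20:
        raise ValueError("need >= 20 defined windows for the diagnostic")
    x = w.loc[ok, "mean_theta"].to_numpy()
    y = w.loc[ok, "density"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": 0.0, "p": 1.0, "constant": True, "n_windows": int(ok.sum())}
    rx, ry = rankdata(x), rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    count = sum(
        abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= abs(rho_obs) - 1e-15
        for _ in range(n_perm)
    )
    return {
        "rho": rho_obs,
        "p": (1.0 + count) / (n_perm + 1.0),
        "constant": False,
        "n_windows": int(ok.sum()),
    }


def detect_islands(
    windows: pd.DataFrame,
    outlier_loci,
    loci_table: pd.DataFrame,
    z_threshold: float = 3.0,
    min_outliers: int = 1,
) -> pd.DataFrame:
    """Genomic islands: maximal runs of adjacent elevated windows.

    A window is elevated when its mean theta exceeds the background mean
    plus ``z_threshold`` standard deviations (background: all defined
    windows).  An island is a maximal run of adjacent elevated windows on
    one scaffold containing at least ``min_outliers`` outlier SNPs; its
    size is end - start in bp.
    """
    defined = windows["mean_theta"].notna()
    if not defined.any():
        raise ValueError("no defined windows")
    bg_mean = windows.loc[defined, "mean_theta"].mean()
    bg_sd = windows.loc[defined, "mean_theta"].std(ddof=1)
    cut = bg_mean + z_threshold * (bg_sd if np.isfinite(bg_sd) else 0.0)
    elevated = defined & (windows["mean_theta"] > cut)

    out_set = set(outlier_loci)
    out_pos = loci_table.loc[loci_table.index.isin(out_set)]

    islands = []
    for scaf, sub in windows.groupby("scaffold", sort=False):
        sub = sub.sort_values("start")
        run: list = []
        for idx, row in sub.iterrows():
            if elevated.loc[idx]:
                run.append(row)
            else:
                if run:
                    islands.append((scaf, run))
                run = []
        if run:
            islands.append((scaf, run))

    rows = []
    for scaf, run in islands:
        start = int(run[0]["start"])
        end = int(run[-1]["end"])
        on = out_pos[
            (out_pos["scaffold"] == scaf)
            & (out_pos["position"] - 1 >= start)
            & (out_pos["position"] - 1 < end)
        ]
        if len(on) >= min_outliers:
            rows.append(
                {
                    "scaffold": scaf,
                    "start": start,
                    "end": end,
                    "size_bp": end - start,
                    "n_windows": len(run),
                    "n_outlier_snps": int(len(on)),
                }
            )
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "size_bp", "n_windows", "n_outlier_snps"])
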