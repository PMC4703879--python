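"""Joint-outlier selective-sweep calling, validation and enrichment.

The scan z-scores the per-window wild/domestic π log-ratio and FST against
their empirical genome-wide distributions and flags windows that fall in the
upper tail of BOTH (one-sided Z test, joint AND) — the signature of a
domestication sweep: lost domestic diversity plus shifted allele
frequencies.  Flagged windows are merged into regions, annotated with
overlapping genes, and validated by rank-sum contrasts of domestic Tajima's
D (expected lower in sweeps) and linkage disequilibrium (expected higher).

Fixed statistic cutoffs from a previous analysis may be supplied instead of
a tail probability; either way the realised cutoffs on the statistic scale
are reported for comparability across datasets.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "SweepRegion",
    "joint_outlier_scan",
    "merge_regions",
    "read_genes_bed",
    "read_genes_gff3",
    "annotate_genes",
    "wilcoxon_rank_sum",
    "validate_sweeps",
    "robustness_check",
    "chi2_2x2",
    "bh_fdr",
    "category_enrichment",
    "regions_to_bed",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: upper-tail probability and optional fixed cutoffs."""

    p: float = 0.005
    fixed_log_ratio_cutoff: float | None = None
    fixed_fst_cutoff: float | None = None


@dataclass
class SweepRegion:
    """Merged run of jointly significant windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_fst: float
    peak_log_ratio: float
    genes: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


def joint_outlier_scan(
    window_stats: pd.DataFrame,
    p: float = 0.005,
    config: ScanConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flag windows jointly extreme in π log-ratio and FST.

    Each statistic is z-scored against its empirical genome-wide mean/SD
    (NaN windows excluded); a window is flagged when both one-sided
    upper-tail normal p-values are below ``p``.  Returns the table with a
    boolean ``flagged`` column and a dict of realised statistic cutoffs.
    """
    if config is not None:
        p = config.p
    stats_df = window_stats.copy()
    cutoffs: dict[str, float] = {"p": p}
    flags = np.zeros(len(stats_df), dtype=bool)
    defined = np.isfinite(stats_df["log_ratio"]) & np.isfinite(stats_df["fst"])
    z_crit = stats.norm.isf(p)
    joint = defined.to_numpy().copy()
    for col in ("log_ratio", "fst"):
        vals = stats_df.loc[defined, col].to_numpy()
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance in {col}; cannot z-score")
        if config is not None and getattr(config, f"fixed_{col}_cutoff", None) is not None:
            cut = getattr(config, f"fixed_{col}_cutoff")
        else:
            cut = mean + z_crit * sd
        cutoffs[f"{col}_cutoff"] = float(cut)
        cutoffs[f"{col}_mean"] = float(mean)
        cutoffs[f"{col}_sd"] = float(sd)
        joint &= (stats_df[col] > cut).to_numpy()
    flags[joint] = True
    stats_df["flagged"] = flags
    return stats_df, cutoffs


def merge_regions(scan_df: pd.DataFrame, min_span: int = 0) -> list[SweepRegion]:
    """Merge overlapping or bookended flagged windows into sweep regions.

    Windows must be sorted in genomic order; each flagged window ends up in
    exactly one region, whose peak statistics are the window maxima.
    """
    regions: list[SweepRegion] = []
    current: SweepRegion | None = None
    flagged = scan_df[scan_df["flagged"]]
    for row in flagged.itertuples():
        if (
            current is not None
            and row.chrom == current.chrom
            and row.start <= current.end
        ):
            current.end = max(current.end, int(row.end))
            current.n_windows += 1
            current.peak_fst = max(current.peak_fst, row.fst)
            current.peak_log_ratio = max(current.peak_log_ratio, row.log_ratio)
        else:
            current = SweepRegion(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                n_windows=1,
                peak_fst=float(row.fst),
                peak_log_ratio=float(row.log_ratio),
            )
            regions.append(current)
    return [r for r in regions if r.span >= min_span]


# ---------------------------------------------------------------------------
# gene annotation


def read_genes_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (>=4 columns; 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            rows.append((f[0], int(f[1]), int(f[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def read_genes_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from GFF3 via gffutils (coordinates converted to
    0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for g in db.features_of_type(feature):
        name = g.attributes.get("ID", [g.id])[0]
        rows.append((g.seqid, g.start - 1, g.end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def annotate_genes(regions: list[SweepRegion], genes: pd.DataFrame) -> list[SweepRegion]:
    """Attach genes overlapping each region by >= 1 bp (half-open intervals).

    Gene chromosomes absent from the regions are skipped with a warning.
    """
    region_chroms = {r.chrom for r in regions}
    unknown = set(genes["chrom"]) - region_chroms
    if unknown:
        logger.warning("annotation chromosomes not in scan: %s", sorted(unknown))
    by_chrom = {c: sub for c, sub in genes.groupby("chrom")}
    for r in regions:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            r.genes = []
            continue
        hit = (sub["start"] < r.end) & (sub["end"] > r.start)
        r.genes = list(sub.loc[hit, "gene"])
    return regions


def regions_to_bed(regions: list[SweepRegion], path) -> None:
    """Write regions as BED6 (score = peak FST scaled to 0-1000)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = int(round(min(max(r.peak_fst, 0.0), 1.0) * 1000))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tsweep_{i+1}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# rank-sum test (Mann-Whitney U)


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and tie-group sizes."""
    ranks = stats.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def wilcoxon_rank_sum(
    values_a, values_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of the first sample, p-value).

    Mid-ranks handle ties.  Groups of fewer than 10 each are tested by exact
    enumeration of all group assignments of the observed values; larger
    groups use the normal approximation with tie correction and a 0.5
    continuity correction.  ``alternative`` 'less' means the first sample
    tends to be smaller.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks, tie_counts = _rank_with_ties(pooled)
    u_obs = _u_statistic(ranks, n1)
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    if n1 < 10 and n2 < 10:
        # exact: enumerate which pooled positions form the first group
        us = np.array(
            [
                float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
                for comb in itertools.combinations(range(n1 + n2), n1)
            ]
        )
        eps = 1e-9
        p_le = float((us <= u_obs + eps).mean())
        p_ge = float((us >= u_obs - eps).mean())
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, p
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u_obs, 1.0
    sd = math.sqrt(var_u)
    if alternative == "less":
        z = (u_obs - mean_u + 0.5) / sd
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        z = (u_obs - mean_u - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        z = (abs(u_obs - mean_u) - 0.5) / sd
        p = 2.0 * stats.norm.sf(z)
    return u_obs, float(min(1.0, p))


# ---------------------------------------------------------------------------
# validation, robustness, enrichment


def _window_in_regions(scan_df: pd.DataFrame, regions: list[SweepRegion]) -> np.ndarray:
    hit = np.zeros(len(scan_df), dtype=bool)
    by_chrom: dict[str, list[SweepRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for i, row in enumerate(scan_df.itertuples()):
        for r in by_chrom.get(row.chrom, ()):
            if row.start < r.end and row.end > r.start:
                hit[i] = True
                break
    return hit


def validate_sweeps(
    scan_df: pd.DataFrame,
    regions: list[SweepRegion],
    r2_by_window: np.ndarray | None = None,
) -> dict:
    """Rank-sum validation of called sweep regions.

    Compares domestic Tajima's D in sweep windows against all other windows
    (one-sided: expected lower) and, when per-window mean r² is supplied,
    linkage disequilibrium (one-sided: expected higher).
    """
    if not regions:
        raise ValueError("no sweep regions to validate")
    in_sweep = _window_in_regions(scan_df, regions)
    if not in_sweep.any():
        raise ValueError("no windows overlap the sweep regions")
    if in_sweep.all():
        raise ValueError("no background windows left to compare against")
    report: dict = {"n_sweep_windows": int(in_sweep.sum()), "n_background_windows": int((~in_sweep).sum())}
    tajd = scan_df["tajd_d"].to_numpy()
    ok = np.isfinite(tajd)
    u, p = wilcoxon_rank_sum(tajd[in_sweep & ok], tajd[~in_sweep & ok], alternative="less")
    report["tajima_d"] = {
        "U": u,
        "p_one_sided": p,
        "median_sweep": float(np.median(tajd[in_sweep & ok])),
        "median_background": float(np.median(tajd[~in_sweep & ok])),
    }
    if r2_by_window is not None:
        r2 = np.asarray(r2_by_window, dtype=float)
        ok = np.isfinite(r2)
        u, p = wilcoxon_rank_sum(r2[in_sweep & ok], r2[~in_sweep & ok], alternative="greater")
        report["r2"] = {
            "U": u,
            "p_one_sided": p,
            "median_sweep": float(np.median(r2[in_sweep & ok])),
            "median_background": float(np.median(r2[~in_sweep & ok])),
        }
    return report


def _genes_hit(scan_df: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    regions = merge_regions(scan_df)
    annotated = annotate_genes(regions, genes)
    return set().union(*(set(r.genes) for r in annotated)) if annotated else set()


def robustness_check(
    scan_d1: pd.DataFrame,
    scan_d2: pd.DataFrame,
    pooled_genes: set[str] | list[str],
    genes: pd.DataFrame,
) -> dict:
    """Population-structure robustness of the pooled scan.

    Both per-population scans (D1 vs W, D2 vs W) must share the pooled
    scan's window grid.  A gene counts as significant in a subscan when it
    overlaps one of that subscan's flagged windows.  Returns the fraction of
    pooled-scan genes significant in both subscans.
    """
    grid_cols = ["chrom", "start", "end"]
    if not scan_d1[grid_cols].reset_index(drop=True).equals(
        scan_d2[grid_cols].reset_index(drop=True)
    ):
        raise ValueError("subscans were not computed on identical windows")
    pooled = set(pooled_genes)
    if not pooled:
        raise ValueError("pooled scan selected no genes")
    hit1 = _genes_hit(scan_d1, genes)
    hit2 = _genes_hit(scan_d2, genes)
    both = pooled & hit1 & hit2
    either = pooled & (hit1 | hit2)
    return {
        "n_pooled_genes": len(pooled),
        "n_both": len(both),
        "n_either": len(either),
        "fraction_both": len(both) / len(pooled),
        "genes_both": sorted(both),
    }


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson χ² for a 2x2 table (no Yates correction); returns (χ², p).

    Table rows are (in-category, not) for selected and background genes.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    if np.any(expected == 0):
        return 0.0, 1.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


def category_enrichment(
    selected_genes,
    universe,
    category_map: dict[str, set[str] | list[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-category χ² enrichment of selected genes with BH-FDR control.

    ``category_map`` maps category id to its gene set.  Each category is
    tested on the 2x2 table of (selected vs background) x (in vs out of
    category); categories with q below ``fdr`` are flagged.
    """
    universe = set(universe)
    selected = set(selected_genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    background = universe - selected
    rows = []
    for cat, members in category_map.items():
        members = set(members) & universe
        a = len(selected & members)
        b = len(selected - members)
        c = len(background & members)
        d = len(background - members)
        chi2, p = chi2_2x2(a, b, c, d)
        rows.append({"category": cat, "n_selected_in": a, "n_background_in": c, "chi2": chi2, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] < fdr
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def write_validation_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
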