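"""Window-based and pairwise population-genetic statistics.

Per-window statistics (π per population, Watterson θ, Tajima's D, Hudson
FST, π log-ratio) feed the selective-sweep scan; pairwise statistics (r²
linkage disequilibrium, identity-by-state, per-SNP identity scores, great
circle distances) support validation and relatedness checks.

Conventions chosen where the source protocol is silent:

* π and θ_w are reported per callable base pair so windows of unequal
  callable length stay comparable; Tajima's D consumes the unnormalised
  window sum of per-site heterozygosity.
* FST is Hudson's estimator aggregated as a ratio of averages over sites,
  which is robust to unequal sample sizes and rare variants.
* Undefined statistics are NaN sentinels and are excluded from empirical
  distributions, never imputed as zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, Window

__all__ = [
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajima_constants",
    "hudson_fst_components",
    "hudson_fst",
    "pi_log_ratio",
    "genotype_r2",
    "ld_decay",
    "window_mean_r2",
    "ibs_matrix",
    "identity_score",
    "great_circle_km",
    "compute_window_stats",
    "site_frequencies",
]

EARTH_RADIUS_KM = 6378.135


# ---------------------------------------------------------------------------
# per-site frequency helpers


def site_frequencies(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and called allele number per site.

    ``dosages`` is (sites, samples) with -1 for missing.  Sites with no
    called genotype get frequency NaN and n 0.
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    called = dosages != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    return freq, n_alleles


def _pi_site_terms(dosages: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity (n/(n-1)) * 2p(1-p)."""
    freq, n = site_frequencies(dosages)
    terms = np.zeros(len(freq))
    ok = n >= 2
    terms[ok] = n[ok] / (n[ok] - 1) * 2.0 * freq[ok] * (1.0 - freq[ok])
    return terms


def nucleotide_diversity(dosages: np.ndarray, callable_bp: int) -> float:
    """π per callable base pair for one window of one population.

    Sums the unbiased per-site pairwise diversity (n/(n-1))·2p̂(1-p̂) over
    sites and divides by the callable length; equals the mean pairwise
    difference per bp.
    """
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    return float(_pi_site_terms(dosages).sum() / callable_bp)


def watterson_theta(s: int, n: int, callable_bp: int) -> float:
    """Watterson θ per bp: S / (a1 * L) with a1 the (n-1)-th harmonic number."""
    if n < 2:
        raise ValueError("need at least two sampled alleles")
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    a1 = sum(1.0 / i for i in range(1, n))
    return s / (a1 * callable_bp)


def tajima_constants(n: int) -> dict[str, float]:
    """The textbook normalising constants of Tajima's D for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(s: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating sites and the window π sum (not per bp).

    Returns NaN when S = 0 (the statistic is undefined and the window is
    excluded from summaries).
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if s < 1:
        return math.nan
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi_sum - s / k["a1"]) / math.sqrt(var)


# ---------------------------------------------------------------------------
# FST (Hudson estimator, ratio of averages)


def hudson_fst_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites with fewer than two called alleles in either population return 0/0
    and drop out of the ratio of averages.
    """
    p1, n1, p2, n2 = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (p1, n1, p2, n2))
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    num = np.zeros(len(p1))
    den = np.zeros(len(p1))
    num[ok] = (
        (p1[ok] - p2[ok]) ** 2
        - p1[ok] * (1 - p1[ok]) / (n1[ok] - 1)
        - p2[ok] * (1 - p2[ok]) / (n2[ok] - 1)
    )
    den[ok] = p1[ok] * (1 - p2[ok]) + p2[ok] * (1 - p1[ok])
    return num, den


def hudson_fst(p1, n1, p2, n2) -> float:
    """Window FST as Σnum/Σden over sites (ratio of averages).

    NaN when every site is monomorphic across both populations.
    """
    num, den = hudson_fst_components(p1, n1, p2, n2)
    total_den = den.sum()
    if total_den == 0:
        return math.nan
    return float(num.sum() / total_den)


def pi_log_ratio(pi_w: float, pi_d: float) -> float:
    """ln(π_W) - ln(π_D); NaN when either diversity is zero or undefined."""
    if not (pi_w > 0 and pi_d > 0):
        return math.nan
    return math.log(pi_w) - math.log(pi_d)


# ---------------------------------------------------------------------------
# linkage disequilibrium (genotype r², Rogers-Huff convention)


def genotype_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors at two sites.

    Computed over samples called at both sites (unphased genotype r²); NaN
    when fewer than two such samples exist or either site has zero variance.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return math.nan
    va = a - a.mean()
    vb = b - b.mean()
    ssa = (va**2).sum()
    ssb = (vb**2).sum()
    if ssa == 0 or ssb == 0:
        return math.nan
    return float((va @ vb) ** 2 / (ssa * ssb))


def _pairwise_r2(dosages: np.ndarray, positions: np.ndarray, max_dist: int):
    """All within-range site pairs: (distance, r²) arrays."""
    n_sites = len(positions)
    dists, r2s = [], []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            d = positions[j] - positions[i]
            if d > max_dist:
                break
            r2 = genotype_r2(dosages[i], dosages[j])
            if not math.isnan(r2):
                dists.append(d)
                r2s.append(r2)
    return np.array(dists), np.array(r2s)


def ld_decay(
    gm: GenotypeMatrix,
    sample_idx: np.ndarray,
    bin_edges: Sequence[int],
    max_dist: int | None = None,
) -> pd.DataFrame:
    """Mean genotype r² by physical-distance bin, pooled over chromosomes."""
    bin_edges = np.asarray(bin_edges, dtype=np.int64)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must strictly increase")
    if max_dist is None:
        max_dist = int(bin_edges[-1])
    sums = np.zeros(len(bin_edges) - 1)
    counts = np.zeros(len(bin_edges) - 1, dtype=np.int64)
    for chrom in gm.chrom_order():
        sel = gm.chrom == chrom
        dists, r2s = _pairwise_r2(gm.dosages[sel][:, sample_idx], gm.pos[sel], max_dist)
        if len(dists) == 0:
            continue
        which = np.digitize(dists, bin_edges) - 1
        ok = (which >= 0) & (which < len(sums))
        np.add.at(sums, which[ok], r2s[ok])
        np.add.at(counts, which[ok], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"bin_start": bin_edges[:-1], "bin_end": bin_edges[1:], "mean_r2": mean, "n_pairs": counts}
    )


def window_mean_r2(
    gm: GenotypeMatrix,
    window: Window,
    sample_idx: np.ndarray,
    max_pairs: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean r² over SNP pairs inside one window (subsampled if numerous)."""
    i0, i1 = window.site_start, window.site_end
    n = i1 - i0
    if n < 2:
        return math.nan
    pairs = [(i, j) for i in range(i0, i1) for j in range(i + 1, i1)]
    if len(pairs) > max_pairs:
        rng = rng or np.random.default_rng(0)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in keep]
    vals = [
        genotype_r2(gm.dosages[i][sample_idx], gm.dosages[j][sample_idx]) for i, j in pairs
    ]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


# ---------------------------------------------------------------------------
# relatedness and identity


def ibs_matrix(gm: GenotypeMatrix, flag_threshold: float = 0.9):
    """Pairwise identity-by-state: mean over co-called sites of 1-|gi-gj|/2.

    Returns (matrix as DataFrame, list of sample pairs with IBS above the
    flagging threshold — candidate close relatives).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    n = gm.n_samples
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(d[:, i] - d[:, j])
            ok = ~np.isnan(diff)
            if not ok.any():
                continue
            score = float(1.0 - diff[ok].mean() / 2.0)
            out[i, j] = out[j, i] = score
            if score > flag_threshold:
                flagged.append((gm.samples[i], gm.samples[j], score))
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples), flagged


def identity_score(gm: GenotypeMatrix, window: Window) -> float:
    """Mean per-SNP identity with the (haploid) reference over a window.

    Per SNP the score is Σ_allele f_sample(allele)·f_ref(allele); with a
    haploid reference f_ref is 1 for REF, so the score is the sample REF
    frequency.  NaN for windows without SNPs.
    """
    i0, i1 = window.site_start, window.site_end
    if i1 <= i0:
        return math.nan
    freq, n = site_frequencies(gm.dosages[i0:i1])
    ok = n > 0
    if not ok.any():
        return math.nan
    return float((1.0 - freq[ok]).mean())


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6378.135 km.

    Evaluates acos(sin·sin + cos·cos·cosΔλ)·R with the acos argument
    clamped to [-1, 1] against rounding.
    """
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    rad = math.pi / 180.0
    arg = math.sin(lat1 * rad) * math.sin(lat2 * rad) + math.cos(lat1 * rad) * math.cos(
        lat2 * rad
    ) * math.cos(lon2 * rad - lon1 * rad)
    return math.acos(min(1.0, max(-1.0, arg))) * EARTH_RADIUS_KM


# ---------------------------------------------------------------------------
# per-window scan table


def compute_window_stats(
    gm: GenotypeMatrix,
    windows: Iterable[Window],
    wild_idx: np.ndarray | None = None,
    dom_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """WindowStats table for the sweep scan.

    One row per window: SNP count, π per bp and Watterson θ per bp and
    Tajima's D for each population, Hudson FST and the wild/domestic π
    log-ratio.  Undefined entries are NaN.
    """
    wild_idx = gm.wild_indices() if wild_idx is None else wild_idx
    dom_idx = gm.domestic_indices() if dom_idx is None else dom_idx
    rows = []
    for w in windows:
        d = gm.dosages[w.site_start : w.site_end]
        dw = d[:, wild_idx]
        dd = d[:, dom_idx]
        fw, nw = site_frequencies(dw)
        fd, nd = site_frequencies(dd)
        pi_terms_w = _pi_site_terms(dw)
        pi_terms_d = _pi_site_terms(dd)
        s_w = int(((fw > 0) & (fw < 1)).sum())
        s_d = int(((fd > 0) & (fd < 1)).sum())
        pi_w = pi_terms_w.sum() / w.callable_bp
        pi_d = pi_terms_d.sum() / w.callable_bp
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "callable_bp": w.callable_bp,
                "n_snps": w.n_sites,
                "pi_w": pi_w,
                "pi_d": pi_d,
                "theta_w_w": watterson_theta(s_w, 2 * len(wild_idx), w.callable_bp),
                "theta_w_d": watterson_theta(s_d, 2 * len(dom_idx), w.callable_bp),
                "tajd_w": tajimas_d(s_w, pi_terms_w.sum(), 2 * len(wild_idx)),
                "tajd_d": tajimas_d(s_d, pi_terms_d.sum(), 2 * len(dom_idx)),
                "fst": hudson_fst(fw, nw, fd, nd),
                "log_ratio": pi_log_ratio(pi_w, pi_d),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "callable_bp",
            "n_snps",
            "pi_w",
            "pi_d",
            "theta_w_w",
            "theta_w_d",
            "tajd_w",
            "tajd_d",
            "fst",
            "log_ratio",
        ],
    )
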