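"""Genotype I/O, site filtering and window iteration.

All internal coordinates are 0-based half-open; VCF positions are converted
on read and write.  Dosages are alternate-allele counts 0/1/2 with -1 as the
missing sentinel (never conflated with homozygous reference).

Population labels follow the study design: "W" wild, "D1"/"D2" the two
domestic herds (Tianzhu white and ordinary landraces); filters that the
source protocol applies to "the domestic population" pool D1 and D2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1

WILD = "W"
DOMESTIC_LABELS = ("D1", "D2")
VALID_LABELS = (WILD,) + DOMESTIC_LABELS


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP; ``pos`` is the 1-based VCF position."""

    chrom: str
    pos: int
    ref: str
    alt: str


class GenotypeMatrix:
    """Diploid dosage table (sites x samples) with population labels.

    Sites are sorted by (chrom, pos) with no duplicates; every sample has a
    label in {W, D1, D2}.  Chromosome order follows first appearance.
    """

    def __init__(
        self,
        samples: list[str],
        pop_of: Mapping[str, str],
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        dosages: np.ndarray,
    ):
        self.samples = list(samples)
        for s in self.samples:
            if s not in pop_of:
                raise ValueError(f"sample {s!r} has no population label")
            if pop_of[s] not in VALID_LABELS:
                raise ValueError(f"sample {s!r}: unknown population {pop_of[s]!r}")
        self.pop_of = {s: pop_of[s] for s in self.samples}
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.dosages = np.asarray(dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage table shape mismatch")
        self._check_sorted()

    def _check_sorted(self):
        seen: dict[str, int] = {}
        last_chrom = None
        last_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != last_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c} occurs in non-contiguous blocks")
                seen[c] = 1
                last_chrom, last_pos = c, p
            else:
                if p <= last_pos:
                    raise ValueError(f"sites not sorted/unique at {c}:{p}")
                last_pos = p

    # -- basic views -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, *labels: str) -> np.ndarray:
        """Column indices of samples whose population is in ``labels``."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.pop_of[s] in labels],
            dtype=np.int64,
        )

    def wild_indices(self) -> np.ndarray:
        return self.sample_indices(WILD)

    def domestic_indices(self) -> np.ndarray:
        return self.sample_indices(*DOMESTIC_LABELS)

    def sites(self) -> Iterator[SiteRecord]:
        for c, p, r, a in zip(self.chrom, self.pos, self.ref, self.alt):
            yield SiteRecord(c, int(p), r, a)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples,
            self.pop_of,
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.dosages[mask],
        )

    def chrom_order(self) -> list[str]:
        order: list[str] = []
        for c in self.chrom:
            if not order or order[-1] != c:
                order.append(c)
        return order

    def site_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Index range [i0, i1) of sites on ``chrom`` with 0-based position
        in [start, end)."""
        in_chrom = np.nonzero(self.chrom == chrom)[0]
        if len(in_chrom) == 0:
            return 0, 0
        lo, hi = in_chrom[0], in_chrom[-1] + 1
        pos0 = self.pos[lo:hi] - 1  # 0-based
        i0 = int(np.searchsorted(pos0, start, side="left"))
        i1 = int(np.searchsorted(pos0, end, side="left"))
        return lo + i0, lo + i1


# ---------------------------------------------------------------------------
# sample map, VCF


def read_sample_map(path) -> dict[str, str]:
    """Two-column TSV: sample <tab> population (W, D1 or D2)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"malformed sample-map line: {line!r}")
            sample, pop = fields
            if pop not in VALID_LABELS:
                raise ValueError(f"unknown population label {pop!r} for {sample!r}")
            out[sample] = pop
    return out


_SNP_BASES = frozenset("ACGT")


def read_vcf(path, sample_map: Mapping[str, str]) -> GenotypeMatrix:
    """Load a VCF 4.x of diploid biallelic SNPs.

    Multiallelic and non-SNP records are skipped (count logged); the VCF
    must be coordinate-sorted.  Every VCF sample must appear in
    ``sample_map`` or a ValueError is raised.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_map]
    if unknown:
        raise ValueError(f"samples missing from sample map: {unknown}")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    skipped = 0
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    for variant in vcf:
        if len(variant.ALT) != 1 or variant.REF not in _SNP_BASES or variant.ALT[0] not in _SNP_BASES:
            skipped += 1
            continue
        if last is not None:
            if variant.CHROM == last[0]:
                if variant.POS <= last[1]:
                    raise ValueError(f"VCF not sorted at {variant.CHROM}:{variant.POS}")
            elif variant.CHROM in seen_chroms:
                raise ValueError(f"VCF not sorted: chromosome {variant.CHROM} reappears")
        seen_chroms.add(variant.CHROM)
        last = (variant.CHROM, variant.POS)
        # gts012: 0/1/2 dosage, 3 = unknown
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        rows.append(gt)
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    dosages = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), np.int8)
    gm = GenotypeMatrix(
        samples,
        {s: sample_map[s] for s in samples},
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        dosages,
    )
    gm.n_skipped = skipped
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=yakpop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in gm.chrom_order():
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosages[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_aa_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic site.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (same parity as the minor-allele count) that are no
    more probable than the observed one — the standard exact SNP-HWE test.
    Returns 1.0 for monomorphic sites.
    """
    counts = (n_aa_hom, n_het, n_alt_hom)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes observed")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_alt_hom + n_het
    # order the alleles so the result is exactly invariant to relabelling
    n_a, n_b = min(n_a, n_b), max(n_a, n_b)
    n_minor = n_a
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | n, n_minor) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_het)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# site filtering


@dataclass
class FilterReport:
    """Counts of sites removed by each filtering rule."""

    n_input: int = 0
    n_call_rate: int = 0
    n_hwe: int = 0
    n_excluded: int = 0
    n_retained: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def filter_sites(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.9,
    hwe_alpha: float = 1e-3,
    exclude: "CallabilityMask | None" = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the study's site filters to called genotypes.

    A site is dropped when its call rate is below ``min_call_rate`` in the
    wild samples or in the pooled domestic samples, or when the exact
    Hardy-Weinberg test on the pooled sample gives p < ``hwe_alpha``.
    Read-depth filtering is honoured through ``exclude``, a precomputed
    exclusion mask of positions to drop (depth is not modelled here).
    """
    wild = gm.wild_indices()
    dom = gm.domestic_indices()
    if len(wild) == 0 or len(dom) == 0:
        raise ValueError("both wild (W) and domestic (D1/D2) samples are required")
    report = FilterReport(n_input=gm.n_sites)
    called = gm.dosages != MISSING
    rate_w = called[:, wild].mean(axis=1)
    rate_d = called[:, dom].mean(axis=1)
    keep = (rate_w >= min_call_rate) & (rate_d >= min_call_rate)
    report.n_call_rate = int((~keep).sum())
    hwe_drop = np.zeros(gm.n_sites, dtype=bool)
    for i in np.nonzero(keep)[0]:
        d = gm.dosages[i][called[i]]
        if len(d) == 0:
            continue
        p = hwe_exact_test(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
        if p < hwe_alpha:
            hwe_drop[i] = True
    report.n_hwe = int(hwe_drop.sum())
    keep &= ~hwe_drop
    if exclude is not None:
        in_excl = np.array(
            [exclude.contains(c, int(p) - 1) for c, p in zip(gm.chrom, gm.pos)]
        )
        report.n_excluded = int((keep & in_excl).sum())
        keep &= ~in_excl
    report.n_retained = int(keep.sum())
    return gm.subset_sites(keep), report


# ---------------------------------------------------------------------------
# callability mask and windows


class CallabilityMask:
    """Per-chromosome sorted, non-overlapping 0-based half-open intervals."""

    def __init__(self, intervals: Mapping[str, np.ndarray]):
        self.intervals: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            arr = arr[np.argsort(arr[:, 0])]
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"empty/negative interval on {chrom}")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self.intervals[chrom] = arr

    @classmethod
    def from_bed(cls, path) -> "CallabilityMask":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                per_chrom.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        return cls({c: np.array(v) for c, v in per_chrom.items()})

    def callable_bp(self, chrom: str, start: int, end: int) -> int:
        """Total masked-in bases overlapping [start, end)."""
        arr = self.intervals.get(chrom)
        if arr is None:
            return 0
        lo = np.clip(arr[:, 0], start, end)
        hi = np.clip(arr[:, 1], start, end)
        return int(np.maximum(hi - lo, 0).sum())

    def contains(self, chrom: str, pos0: int) -> bool:
        arr = self.intervals.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], pos0, side="right")) - 1
        return i >= 0 and pos0 < arr[i, 1]


@dataclass(frozen=True)
class Window:
    """Genomic window, 0-based half-open, with its site index range."""

    chrom: str
    start: int
    end: int
    callable_bp: int
    site_start: int
    site_end: int

    @property
    def n_sites(self) -> int:
        return self.site_end - self.site_start


def iter_windows(
    gm: GenotypeMatrix,
    chrom_lengths: Mapping[str, int],
    mask: CallabilityMask | None = None,
    size: int = 50_000,
    step: int = 10_000,
    min_callable_frac: float = 0.8,
) -> Iterator[Window]:
    """Sliding windows (default 50 kb sliding by 10 kb) in genomic order.

    Windows with callable coverage below ``min_callable_frac`` of the window
    size are omitted (the protocol requires at least 80% of bases covered).
    Without a mask the whole chromosome is callable.  Chromosomes shorter
    than one window yield a single truncated window.
    """
    if step > size:
        raise ValueError("step must not exceed window size")
    for chrom in chrom_lengths:
        length = int(chrom_lengths[chrom])
        if length >= size:
            starts = range(0, length - size + 1, step)
        else:
            starts = range(0, 1)
        for start in starts:
            end = min(start + size, length)
            if mask is None:
                callable_bp = end - start
            else:
                callable_bp = mask.callable_bp(chrom, start, end)
            if callable_bp / size < min_callable_frac:
                continue
            i0, i1 = gm.site_range(chrom, start, end)
            yield Window(chrom, start, end, callable_bp, i0, i1)
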