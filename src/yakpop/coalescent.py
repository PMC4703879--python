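"""Two-population coalescent with piecewise-constant demography, and SFS tools.

The model covers a wild (W) and a domestic (D) population that merge into a
common ancestor ``t_div`` generations before present (backwards in time all D
lineages move into the ancestral population, which continues with size
``n_anc``).  Population sizes change only instantaneously at epoch
boundaries; there is no continuous growth.  Optional migration is expressed
backwards in time as per-lineage, per-generation movement probabilities.

Two simulation paths are provided:

* :func:`simulate_locus` draws a full genealogy in Python and places
  infinite-sites mutations on it, returning haplotypes (used to emit VCFs).
* :func:`expected_sfs` / :func:`sample_sfs` use a compiled branch-length
  kernel: the expected joint SFS is proportional to the expected branch
  length subtending each (i, j) descendant configuration, and the sampled
  SFS is a Poisson draw on mu * L * (summed branch lengths), which for
  independent loci is distributionally identical to site-by-site simulation.

Times are in generations; calendar years convert via the generation time
(3 yr for yak) with :func:`years_to_generations`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernel import branch_length_matrix

__all__ = [
    "SizeEpoch",
    "DemographicModel",
    "SampleConfig",
    "LocusResult",
    "JointSFS",
    "domestication_scenario",
    "simulate_locus",
    "joint_sfs",
    "expected_sfs",
    "sample_sfs",
    "years_to_generations",
    "mutation_rate_from_divergence",
]

_FAR_FUTURE = 1e18


@dataclass(frozen=True)
class SizeEpoch:
    """Constant diploid size ``size`` starting ``start`` generations ago."""

    start: float
    size: float


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes (diploids x 2) for the two populations."""

    n_w: int
    n_d: int

    def __post_init__(self):
        if self.n_w < 0 or self.n_d < 0 or self.n_w + self.n_d < 2:
            raise ValueError("need at least two haploid samples in total")


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant two-population history.

    Epoch lists run from the present backwards: the first epoch of each
    population must start at 0 and start times must strictly increase.
    Epochs starting at or after ``t_div`` are unreachable (the population has
    already merged) and are ignored.
    """

    wild_epochs: tuple[SizeEpoch, ...]
    dom_epochs: tuple[SizeEpoch, ...]
    t_div: float
    n_anc: float
    m_wd: float = 0.0
    m_dw: float = 0.0

    def __post_init__(self):
        for name, epochs in (("wild", self.wild_epochs), ("dom", self.dom_epochs)):
            if not epochs or epochs[0].start != 0:
                raise ValueError(f"{name} epochs must begin at time 0")
            starts = [e.start for e in epochs]
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError(f"{name} epoch start times must strictly increase")
            if any(e.size <= 0 for e in epochs):
                raise ValueError(f"{name} population sizes must be positive")
        if self.t_div <= 0:
            raise ValueError("divergence time must be positive")
        if self.n_anc <= 0:
            raise ValueError("ancestral size must be positive")
        if self.m_wd < 0 or self.m_dw < 0:
            raise ValueError("migration rates must be non-negative")

    @staticmethod
    def _size_at(epochs: tuple[SizeEpoch, ...], t: float) -> float:
        size = epochs[0].size
        for e in epochs:
            if e.start <= t:
                size = e.size
            else:
                break
        return size

    def to_kernel_arrays(self):
        """Per-interval arrays consumed by the compiled kernel."""
        cuts = {0.0, self.t_div}
        for e in self.wild_epochs + self.dom_epochs:
            if 0.0 < e.start < self.t_div:
                cuts.add(float(e.start))
        times = np.array(sorted(cuts) + [_FAR_FUTURE], dtype=np.float64)
        n_int = len(times) - 1
        size_w = np.empty(n_int)
        size_d = np.empty(n_int)
        mig_wd = np.zeros(n_int)
        mig_dw = np.zeros(n_int)
        merged = np.zeros(n_int, dtype=np.int64)
        for b in range(n_int):
            t = times[b]
            if t >= self.t_div:
                merged[b] = 1
                size_w[b] = self.n_anc
                size_d[b] = 1.0  # unused: no D lineages remain
            else:
                size_w[b] = self._size_at(self.wild_epochs, t)
                size_d[b] = self._size_at(self.dom_epochs, t)
                mig_wd[b] = self.m_wd
                mig_dw[b] = self.m_dw
        return times, size_w, size_d, mig_wd, mig_dw, merged


def domestication_scenario(
    t_div_yr: float = 7_300.0,
    n_dom_early: float = 1_100.0,
    n_dom_recent: float = 6_500.0,
    t_dom_expand_yr: float = 3_600.0,
    n_wild_historic: float = 21_200.0,
    n_wild_recent: float = 1_700.0,
    t_wild_decline_yr: float = 500.0,
    n_anc: float | None = None,
    generation_time: float = 3.0,
    m_wd: float = 0.0,
    m_dw: float = 0.0,
) -> DemographicModel:
    """Best-supported wild/domestic yak history, parameterised in years BP.

    Defaults: domestication (divergence) 7,300 yr BP; the domestic herd at
    Ne=1,100 until a six-fold expansion to 6,500 at 3,600 yr BP; wild yak at
    Ne=21,200 until a recent crash to 1,700 about 500 yr BP.  The ancestral
    size defaults to the historic wild size.  All times convert to
    generations at 3 yr per generation.
    """
    g = generation_time
    if n_anc is None:
        n_anc = n_wild_historic
    wild = [SizeEpoch(0.0, n_wild_recent)]
    if t_wild_decline_yr > 0:
        wild.append(SizeEpoch(t_wild_decline_yr / g, n_wild_historic))
    else:
        wild = [SizeEpoch(0.0, n_wild_historic)]
    dom = [SizeEpoch(0.0, n_dom_recent)]
    if t_dom_expand_yr > 0:
        dom.append(SizeEpoch(t_dom_expand_yr / g, n_dom_early))
    return DemographicModel(
        wild_epochs=tuple(wild),
        dom_epochs=tuple(dom),
        t_div=t_div_yr / g,
        n_anc=n_anc,
        m_wd=m_wd,
        m_dw=m_dw,
    )


def years_to_generations(t_years: float, g: float = 3.0) -> float:
    """Convert years to generations at generation time ``g`` (yr)."""
    if g <= 0:
        raise ValueError("generation time must be positive")
    return t_years / g


def mutation_rate_from_divergence(d_pairwise: float, g: float, t_years: float) -> float:
    """Per-generation, per-site mutation rate mu = D*g/(2T).

    ``d_pairwise`` is the between-species pairwise difference frequency and
    ``t_years`` the species divergence time in years.
    """
    if d_pairwise < 0 or g <= 0 or t_years <= 0:
        raise ValueError("inputs must be positive (D may be 0)")
    return d_pairwise * g / (2.0 * t_years)


# ---------------------------------------------------------------------------
# joint SFS container


class JointSFS:
    """Joint site-frequency matrix over (count in W, count in D).

    ``matrix[i, j]`` counts (or weights) sites carried by i of the n_w wild
    and j of the n_d domestic haploid samples.  Folded spectra pool each cell
    with its complement (n_w-i, n_d-j); a pair whose pooled count is exactly
    half the total maps to its lexicographically smaller member.
    """

    def __init__(self, matrix: np.ndarray, n_w: int, n_d: int, folded: bool = False):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (n_w + 1, n_d + 1):
            raise ValueError("matrix shape must be (n_w+1, n_d+1)")
        if np.any(matrix < 0):
            raise ValueError("SFS entries must be non-negative")
        self.matrix = matrix
        self.n_w = int(n_w)
        self.n_d = int(n_d)
        self.folded = bool(folded)

    # -- folding ---------------------------------------------------------
    def _canonical_cell(self, i: int, j: int) -> tuple[int, int]:
        ci, cj = self.n_w - i, self.n_d - j
        pooled = 2 * (i + j)
        if pooled < self.n_w + self.n_d:
            return i, j
        if pooled > self.n_w + self.n_d:
            return ci, cj
        return min((i, j), (ci, cj))

    def fold(self) -> "JointSFS":
        if self.folded:
            return self
        out = np.zeros_like(self.matrix)
        for i in range(self.n_w + 1):
            for j in range(self.n_d + 1):
                if self.matrix[i, j] != 0:
                    ci, cj = self._canonical_cell(i, j)
                    out[ci, cj] += self.matrix[i, j]
        return JointSFS(out, self.n_w, self.n_d, folded=True)

    def polymorphic_mask(self) -> np.ndarray:
        """Cells that enter likelihoods: segregating configurations only."""
        mask = np.zeros(self.matrix.shape, dtype=bool)
        for i in range(self.n_w + 1):
            for j in range(self.n_d + 1):
                if (i, j) == (0, 0) or (i, j) == (self.n_w, self.n_d):
                    continue
                if self.folded:
                    if self._canonical_cell(i, j) == (i, j):
                        mask[i, j] = True
                else:
                    mask[i, j] = True
        return mask

    def total_polymorphic(self) -> float:
        return float(self.matrix[self.polymorphic_mask()].sum())

    def normalized(self, floor: float | None = None) -> "JointSFS":
        """Per-polymorphic-site cell probabilities, optionally floor-bounded.

        The floor replaces zero/near-zero cells before renormalising so that
        composite log-likelihoods stay finite.
        """
        mask = self.polymorphic_mask()
        total = self.matrix[mask].sum()
        if total <= 0:
            raise ValueError("no polymorphic mass to normalize")
        probs = np.zeros_like(self.matrix)
        probs[mask] = self.matrix[mask] / total
        if floor is not None and floor > 0:
            probs[mask] = np.maximum(probs[mask], floor)
            probs[mask] /= probs[mask].sum()
        return JointSFS(probs, self.n_w, self.n_d, folded=self.folded)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#n_w={self.n_w}\tn_d={self.n_d}\tfolded={int(self.folded)}\n")
            for i in range(self.n_w + 1):
                fh.write("\t".join(repr(float(v)) for v in self.matrix[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing SFS header line")
            fields = dict(kv.split("=") for kv in header[1:].split())
            n_w, n_d = int(fields["n_w"]), int(fields["n_d"])
            folded = bool(int(fields["folded"]))
            rows = [
                [float(x) for x in line.split("\t")] for line in fh if line.strip()
            ]
        matrix = np.array(rows)
        if matrix.shape != (n_w + 1, n_d + 1):
            raise ValueError("SFS matrix shape does not match header")
        return cls(matrix, n_w, n_d, folded=folded)


# ---------------------------------------------------------------------------
# haplotype-level simulation (Python path)


@dataclass
class LocusResult:
    """One locus: infinite-sites haplotypes and per-population counts.

    ``haplotypes`` is (S, n_w + n_d) with wild columns first; ``positions``
    are 0-based offsets within the locus; counts are derived-allele counts.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    counts_w: np.ndarray
    counts_d: np.ndarray
    locus_bp: int


def _simulate_tree(model: DemographicModel, n_w: int, n_d: int, rng: np.random.Generator):
    """One genealogy; returns (parent, node_time, order) arrays.

    Nodes 0..n_w-1 are wild tips, n_w..n-1 domestic tips; internal nodes are
    created in coalescence order, the last one being the root.
    """
    times, size_w, size_d, mig_wd, mig_dw, merged = model.to_kernel_arrays()
    n = n_w + n_d
    tot = 2 * n - 1
    parent = np.full(tot, -1, dtype=np.int64)
    node_time = np.zeros(tot, dtype=np.float64)
    pool_w = list(range(n_w))
    pool_d = list(range(n_w, n))
    if merged[0]:
        pool_w += pool_d
        pool_d = []
    t = 0.0
    b = 0
    node = n
    max_events = 10_000 * n
    events = 0
    while len(pool_w) + len(pool_d) > 1:
        events += 1
        if events > max_events:
            raise RuntimeError("coalescent event budget exceeded")
        k_w, k_d = len(pool_w), len(pool_d)
        r_cw = k_w * (k_w - 1) / (4.0 * size_w[b])
        r_cd = k_d * (k_d - 1) / (4.0 * size_d[b])
        r_mw = k_w * mig_wd[b]
        r_md = k_d * mig_dw[b]
        rate = r_cw + r_cd + r_mw + r_md
        boundary = times[b + 1]
        if rate <= 0.0:
            t, b = boundary, b + 1
        else:
            dt = rng.exponential(1.0 / rate)
            if t + dt >= boundary:
                t, b = boundary, b + 1
            else:
                t += dt
                u = rng.random() * rate
                if u < r_cw:
                    pool, other, coalesce = pool_w, pool_d, True
                elif u < r_cw + r_cd:
                    pool, other, coalesce = pool_d, pool_w, True
                elif u < r_cw + r_cd + r_mw:
                    pool, other, coalesce = pool_w, pool_d, False
                else:
                    pool, other, coalesce = pool_d, pool_w, False
                if coalesce:
                    i, j = rng.choice(len(pool), size=2, replace=False)
                    a, c = pool[i], pool[j]
                    parent[a] = parent[c] = node
                    node_time[node] = t
                    for k in sorted((i, j), reverse=True):
                        pool.pop(k)
                    pool.append(node)
                    node += 1
                else:
                    i = int(rng.integers(len(pool)))
                    other.append(pool.pop(i))
                continue
        if merged[b] and pool_d:
            pool_w += pool_d
            pool_d = []
    return parent, node_time, node


def simulate_locus(
    model: DemographicModel,
    sample_config: SampleConfig,
    locus_bp: int,
    mu: float,
    rng: np.random.Generator,
) -> LocusResult:
    """Simulate one non-recombining locus under the infinite-sites model.

    Mutations are Poisson with rate mu per bp per generation on total branch
    length and placed uniformly; each segregating site is hit exactly once.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if locus_bp <= 0:
        raise ValueError("locus_bp must be positive")
    n_w, n_d = sample_config.n_w, sample_config.n_d
    n = n_w + n_d
    parent, node_time, n_nodes = _simulate_tree(model, n_w, n_d, rng)
    # leaf sets bottom-up: children are always created before their parent
    leaves: list[list[int]] = [[i] for i in range(n)] + [[] for _ in range(n_nodes - n)]
    for v in range(n_nodes - 1):
        leaves[parent[v]].extend(leaves[v])
    columns = []
    for v in range(n_nodes - 1):  # root excluded
        blen = node_time[parent[v]] - node_time[v]
        n_mut = rng.poisson(mu * locus_bp * blen)
        for _ in range(n_mut):
            col = np.zeros(n, dtype=np.int8)
            col[leaves[v]] = 1
            columns.append(col)
    s = len(columns)
    if s > locus_bp:
        raise RuntimeError("more mutations than sites; locus too short for mu")
    haplotypes = np.array(columns, dtype=np.int8) if s else np.zeros((0, n), np.int8)
    positions = np.sort(rng.choice(locus_bp, size=s, replace=False)) if s else np.zeros(0, np.int64)
    counts_w = haplotypes[:, :n_w].sum(axis=1) if s else np.zeros(0, np.int64)
    counts_d = haplotypes[:, n_w:].sum(axis=1) if s else np.zeros(0, np.int64)
    return LocusResult(
        haplotypes=haplotypes,
        positions=positions.astype(np.int64),
        counts_w=np.asarray(counts_w, dtype=np.int64),
        counts_d=np.asarray(counts_d, dtype=np.int64),
        locus_bp=locus_bp,
    )


def joint_sfs(loci: Sequence[LocusResult], sample_config: SampleConfig, folded: bool = True) -> JointSFS:
    """Aggregate per-locus derived-allele counts into a joint SFS."""
    n_w, n_d = sample_config.n_w, sample_config.n_d
    matrix = np.zeros((n_w + 1, n_d + 1))
    for locus in loci:
        if locus.haplotypes.shape[1] != n_w + n_d:
            raise ValueError("locus sample size does not match sample_config")
        for cw, cd in zip(locus.counts_w, locus.counts_d):
            matrix[cw, cd] += 1
    sfs = JointSFS(matrix, n_w, n_d, folded=False)
    return sfs.fold() if folded else sfs


# ---------------------------------------------------------------------------
# kernel-backed SFS estimation / sampling


def _branch_lengths(model, sample_config, n_loci, seed):
    arrays = model.to_kernel_arrays()
    return branch_length_matrix(seed, n_loci, sample_config.n_w, sample_config.n_d, arrays)


def expected_sfs(
    model: DemographicModel,
    sample_config: SampleConfig,
    n_loci: int,
    locus_bp: int,
    mu: float,
    seed: int,
    folded: bool = True,
    floor: float | None = None,
) -> JointSFS:
    """Monte-Carlo expected per-polymorphic-site cell probabilities.

    Estimated from ``n_loci`` simulated genealogies via expected branch
    lengths.  Zero cells are floor-bounded (default: one tenth of a site out
    of the expected total polymorphic count) so downstream composite
    log-likelihoods stay finite.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    lengths = _branch_lengths(model, sample_config, n_loci, seed)
    expected_counts = mu * locus_bp * lengths
    sfs = JointSFS(expected_counts, sample_config.n_w, sample_config.n_d, folded=False)
    if folded:
        sfs = sfs.fold()
    total = sfs.total_polymorphic()
    if total <= 0:
        raise ValueError("no polymorphic sites simulated; increase n_loci or mu")
    if floor is None:
        floor = 1.0 / (10.0 * total)
    return sfs.normalized(floor=floor)


def sample_sfs(
    model: DemographicModel,
    sample_config: SampleConfig,
    n_loci: int,
    locus_bp: int,
    mu: float,
    seed: int,
    folded: bool = True,
) -> JointSFS:
    """Draw one joint SFS for ``n_loci`` independent loci.

    Counts are Poisson on mu * L * (summed branch lengths); summing the
    per-locus Poisson rates first is exact because loci are independent.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    lengths = _branch_lengths(model, sample_config, n_loci, seed)
    rng = np.random.default_rng(seed + 0x5F5E100)
    counts = rng.poisson(mu * locus_bp * lengths).astype(np.float64)
    sfs = JointSFS(counts, sample_config.n_w, sample_config.n_d, folded=False)
    return sfs.fold() if folded else sfs
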