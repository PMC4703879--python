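"""Truth-annotated synthetic study generator.

Emulates the statistical structure of a wild/domestic yak resequencing
panel: 13 wild and 59 domestic diploids (11 Tianzhu-like D1 + 48 landrace
D2) drawn from the domestication demography (recent divergence with
bottlenecks, expansion and a recent wild decline), tiled into chromosomes
from independent non-recombining loci.  Selective sweeps are injected
phenomenologically: within each sweep interval the domestic effective size
is multiplied by a strength ``s`` in (0, 1] during a transient bottleneck
running from the sweep onset until a recovery time, and local gene flow is
suppressed.  The bottleneck collapses domestic diversity and builds up
allele-frequency divergence; the recovery phase regrows an excess of rare
variants — together exactly the signatures the scan targets: reduced
domestic π, elevated FST, negative domestic Tajima's D and extended LD.
``s = 1`` is a no-op.

Outputs are standard formats (VCF, sample-map TSV, gene BED, truth
BED/JSON, folded joint-SFS TSV) plus a run manifest, so every pipeline
stage can be exercised against known truth without any external data.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coalescent import (
    DemographicModel,
    JointSFS,
    SampleConfig,
    SizeEpoch,
    domestication_scenario,
    joint_sfs,
    simulate_locus,
)
from .genotype_io import GenotypeMatrix, write_vcf

logger = logging.getLogger(__name__)

__all__ = ["Sweep", "StudyConfig", "TruthTable", "StudyBundle", "generate_study", "generate_null_window_stats", "sweep_model"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Sweep:
    """One injected sweep: interval, strength, onset and recovery times.

    The sweep is a transient domestic bottleneck: between ``recovery_gen``
    and ``onset_gen`` generations ago the local domestic size is multiplied
    by ``s``; afterwards (towards the present) it recovers to the genome-wide
    size.  The recovery phase is what generates the excess of rare variants
    (negative Tajima's D) that real sweeps leave behind.  Defaults: onset at
    domestication, recovery a quarter of the way back.
    """

    chrom: str
    start: int
    end: int
    s: float = 0.1
    onset_gen: float | None = None  # None -> domestication time (model t_div)
    recovery_gen: float | None = None  # None -> onset / 4

    def __post_init__(self):
        if not (0 < self.s <= 1):
            raise ValueError("sweep strength s must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("sweep interval must be non-empty")
        if (
            self.onset_gen is not None
            and self.recovery_gen is not None
            and self.recovery_gen >= self.onset_gen
        ):
            raise ValueError("recovery_gen must be more recent than onset_gen")


def _default_chroms() -> dict[str, int]:
    return {"chr1": 3_000_000, "chr2": 3_000_000}


def _default_sweeps() -> tuple[Sweep, ...]:
    return (
        Sweep("chr1", 600_000, 700_000),
        Sweep("chr1", 2_000_000, 2_100_000),
        Sweep("chr2", 1_000_000, 1_100_000),
        Sweep("chr2", 2_400_000, 2_500_000),
    )


def _default_model() -> DemographicModel:
    # domestication demography plus symmetric gene flow; the migration rate
    # is set so the neutral background reproduces the study's structure
    # (weak differentiation, FST ~ 0.05, near-equal wild/domestic diversity)
    return domestication_scenario(m_wd=5e-4, m_dw=5e-4)


@dataclass
class StudyConfig:
    """Study-generator settings; defaults mirror the real study design."""

    model: DemographicModel = field(default_factory=_default_model)
    n_wild: int = 13
    n_d1: int = 11
    n_d2: int = 48
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    locus_bp: int = 1_000
    mu: float = 1e-8
    sweeps: tuple[Sweep, ...] = field(default_factory=_default_sweeps)
    n_background_genes: int = 40
    gene_bp: int = 20_000
    seed: int = 0

    def __post_init__(self):
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom}")
            if sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError("sweep extends beyond chromosome end")
            if sw.s == 1.0:
                warnings.warn("sweep with s=1 carries no signal", stacklevel=2)

    @property
    def n_dom(self) -> int:
        return self.n_d1 + self.n_d2

    def sample_config(self) -> SampleConfig:
        return SampleConfig(n_w=2 * self.n_wild, n_d=2 * self.n_dom)


@dataclass
class TruthTable:
    """Exactly what the generator used: sweep intervals and demography."""

    sweeps: list[dict]
    demography: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"sweeps": self.sweeps, "demography": self.demography}, fh, indent=2)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, sw in enumerate(self.sweeps):
                fh.write(
                    f"{sw['chrom']}\t{sw['start']}\t{sw['end']}\tsweep_truth_{i+1}\t"
                    f"{int(sw['s'] * 1000)}\t.\n"
                )


@dataclass
class StudyBundle:
    genotypes: GenotypeMatrix
    truth: TruthTable
    sfs: JointSFS
    genes: pd.DataFrame
    paths: dict[str, str]


def sweep_model(
    model: DemographicModel,
    s: float,
    onset_gen: float,
    recovery_gen: float,
    suppress_migration: bool = True,
) -> DemographicModel:
    """Domestic-size-scaled model used inside a sweep interval.

    The domestic size is multiplied by ``s`` over the time slice
    [``recovery_gen``, ``onset_gen``) generations ago and left unchanged
    outside it.  Because the locus is under divergent selection, effective
    gene flow is suppressed there (``suppress_migration``), which keeps the
    wild population's local diversity intact and lets the allele-frequency
    divergence build up.  ``s = 1`` returns the model unchanged.
    """
    if s == 1.0 or onset_gen <= 0 or recovery_gen >= onset_gen:
        return model

    def scaled_size(t: float) -> float:
        size = DemographicModel._size_at(model.dom_epochs, t)
        return size * s if recovery_gen <= t < onset_gen else size

    bounds = {0.0, recovery_gen}
    if onset_gen < model.t_div:
        bounds.add(onset_gen)
    for e in model.dom_epochs:
        if e.start < model.t_div:
            bounds.add(e.start)
    new_epochs = tuple(SizeEpoch(b, scaled_size(b)) for b in sorted(bounds))
    return DemographicModel(
        wild_epochs=model.wild_epochs,
        dom_epochs=new_epochs,
        t_div=model.t_div,
        n_anc=model.n_anc,
        m_wd=0.0 if suppress_migration else model.m_wd,
        m_dw=0.0 if suppress_migration else model.m_dw,
    )


def _sample_names(config: StudyConfig) -> tuple[list[str], dict[str, str]]:
    samples, pop_of = [], {}
    for i in range(config.n_wild):
        name = f"W{i+1:02d}"
        samples.append(name)
        pop_of[name] = "W"
    for i in range(config.n_d1):
        name = f"D1_{i+1:02d}"
        samples.append(name)
        pop_of[name] = "D1"
    for i in range(config.n_d2):
        name = f"D2_{i+1:02d}"
        samples.append(name)
        pop_of[name] = "D2"
    return samples, pop_of


def _place_genes(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random gene intervals, guaranteeing one gene inside each sweep."""
    rows = []
    for i, sw in enumerate(config.sweeps):
        length = min(config.gene_bp, sw.end - sw.start)
        start = int(rng.integers(sw.start, sw.end - length + 1))
        rows.append((sw.chrom, start, start + length, f"gene_sweep_{i+1}"))
    chroms = list(config.chrom_lengths)
    for i in range(config.n_background_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = config.gene_bp
        start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
        rows.append((chrom, start, start + length, f"gene_bg_{i+1}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def generate_study(config: StudyConfig, outdir) -> StudyBundle:
    """Simulate the full study bundle and write all artifacts to ``outdir``.

    The neutral background is simulated locus by locus and tiled into
    chromosomes; loci overlapping a sweep interval use the sweep-scaled
    model.  Haplotypes are paired into diploids in sample order and written
    as VCF with the ancestral allele as REF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sc = config.sample_config()
    samples, pop_of = _sample_names(config)
    n = sc.n_w + sc.n_d

    base_model = config.model
    loci = []
    chroms_col, pos_col, ref_col, alt_col, dos_rows = [], [], [], [], []
    for chrom, length in config.chrom_lengths.items():
        n_loci = length // config.locus_bp
        chrom_sweeps = [sw for sw in config.sweeps if sw.chrom == chrom]
        for k in range(n_loci):
            lo = k * config.locus_bp
            hi = lo + config.locus_bp
            model = base_model
            for sw in chrom_sweeps:
                if lo < sw.end and hi > sw.start:
                    onset = sw.onset_gen if sw.onset_gen is not None else base_model.t_div
                    recovery = sw.recovery_gen if sw.recovery_gen is not None else onset / 4.0
                    model = sweep_model(base_model, sw.s, onset, recovery)
                    break
            locus = simulate_locus(model, sc, config.locus_bp, config.mu, rng)
            loci.append(locus)
            if locus.haplotypes.shape[0] == 0:
                continue
            dosages = locus.haplotypes[:, 0::2] + locus.haplotypes[:, 1::2]
            for s_idx in range(locus.haplotypes.shape[0]):
                ref_i = int(rng.integers(4))
                alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
                chroms_col.append(chrom)
                pos_col.append(lo + int(locus.positions[s_idx]) + 1)
                ref_col.append(_BASES[ref_i])
                alt_col.append(_BASES[alt_i])
                dos_rows.append(dosages[s_idx])

    gm = GenotypeMatrix(
        samples,
        pop_of,
        np.array(chroms_col, dtype=object),
        np.array(pos_col, dtype=np.int64),
        np.array(ref_col, dtype=object),
        np.array(alt_col, dtype=object),
        np.array(dos_rows, dtype=np.int8) if dos_rows else np.zeros((0, len(samples)), np.int8),
    )
    sfs = joint_sfs(loci, sc, folded=True)
    genes = _place_genes(config, rng)
    truth = TruthTable(
        sweeps=[
            {
                "chrom": sw.chrom,
                "start": sw.start,
                "end": sw.end,
                "s": sw.s,
                "onset_gen": sw.onset_gen if sw.onset_gen is not None else base_model.t_div,
                "recovery_gen": sw.recovery_gen
                if sw.recovery_gen is not None
                else (sw.onset_gen if sw.onset_gen is not None else base_model.t_div) / 4.0,
            }
            for sw in config.sweeps
        ],
        demography={
            "t_div_gen": base_model.t_div,
            "n_anc": base_model.n_anc,
            "wild_epochs": [(e.start, e.size) for e in base_model.wild_epochs],
            "dom_epochs": [(e.start, e.size) for e in base_model.dom_epochs],
            "m_wd": base_model.m_wd,
            "m_dw": base_model.m_dw,
            "mu": config.mu,
            "locus_bp": config.locus_bp,
        },
    )

    paths = {
        "vcf": str(outdir / "study.vcf"),
        "sample_map": str(outdir / "samples.tsv"),
        "genes_bed": str(outdir / "genes.bed"),
        "truth_bed": str(outdir / "truth.bed"),
        "truth_json": str(outdir / "truth.json"),
        "sfs": str(outdir / "joint_sfs.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_vcf(gm, paths["vcf"], contig_lengths=config.chrom_lengths)
    with open(paths["sample_map"], "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{pop_of[s]}\n")
    with open(paths["genes_bed"], "w") as fh:
        for row in genes.itertuples():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene}\t0\t.\n")
    truth.to_bed(paths["truth_bed"])
    truth.to_json(paths["truth_json"])
    sfs.to_tsv(paths["sfs"])
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "n_wild": config.n_wild,
        "n_d1": config.n_d1,
        "n_d2": config.n_d2,
        "chrom_lengths": config.chrom_lengths,
        "locus_bp": config.locus_bp,
        "mu": config.mu,
        "n_sweeps": len(config.sweeps),
        "n_snps": gm.n_sites,
        "files": paths,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return StudyBundle(genotypes=gm, truth=truth, sfs=sfs, genes=genes, paths=paths)


def generate_null_window_stats(
    n_windows: int, correlation: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Null WindowStats table with (fst, log_ratio) from a bivariate normal.

    Used to calibrate the joint-outlier scan: with correlation 0 the joint
    flag rate at tail probability p is p²; with correlation 1 it is p.
    """
    if not (-1.0 <= correlation <= 1.0):
        raise ValueError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((max(n_windows, 0), 2))
    draws = np.column_stack(
        [z[:, 0], correlation * z[:, 0] + math.sqrt(1.0 - correlation**2) * z[:, 1]]
    )
    step = 10_000
    return pd.DataFrame(
        {
            "chrom": "null",
            "start": np.arange(n_windows) * step,
            "end": np.arange(n_windows) * step + 50_000,
            "n_snps": 0,
            "fst": draws[:, 0],
            "log_ratio": draws[:, 1],
        }
    )
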