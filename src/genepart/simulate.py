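"""Synthetic genotype/annotation/phenotype generator.

Emulates the statistical structure the partitioning method assumes in a
dairy-cattle-style SNP panel: biallelic dosages with block LD over several
chromosomes, gene intervals covering a configurable fraction of markers
(default 0.4, the regime where ~40 % of panel SNPs fall inside genes),
genome-scattered pathways of heterogeneous size, and phenotypes built from
marker effects plus (optionally reliability-weighted, heteroskedastic)
Gaussian residuals.  Trait models:

- ``infinitesimal_null``: every marker draws an effect with equal variance
  (the competitive null — a random gene group is expected to explain a
  share m_S / m of the genomic variance);
- ``pathway_enriched``: markers of a designated set carry a share ``rho_S``
  of the genetic variance;
- ``focal_locus``: one marker inside a designated focal gene carries a
  single large effect on top of an infinitesimal background (a DGAT1-like
  causative locus).

All generators are pure functions of (scenario, seed): child RNG streams
are derived per stage from the scenario's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneTable, GenotypeMatrix, PathwayMap, PhenotypeTable, DataError
from .mapping import FeatureSet
from .grm import center_scale

__all__ = [
    "SimulationScenario",
    "TrueParams",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_phenotypes",
]


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic dataset.

    Counts and variances follow the regime of a sire-panel analysis scaled
    to desk size: 500 individuals, 5000 markers in LD blocks across 5
    chromosomes, genes covering 40 % of markers, 20 pathways.  ``h2_total``
    is the genomic heritability of the simulated records (pseudo-phenotypes
    such as EBV/DRP carry most of the genetic signal, hence the 0.5
    default); ``rho_S`` is the share of genetic variance assigned to the
    target set under ``pathway_enriched``.
    """

    n_individuals: int = 500
    n_markers: int = 5000
    n_chromosomes: int = 5
    ld_block_size: int = 25
    rho_ld: float = 0.6
    freq_range: tuple[float, float] = (0.05, 0.95)
    marker_spacing: int = 4000
    n_genes: int = 300
    gene_coverage: float = 0.4
    gene_length_log_mean: float = float(np.log(40_000))
    gene_length_log_sd: float = 1.0
    n_pathways: int = 20
    pathway_genes_log_mean: float = float(np.log(10))
    pathway_genes_log_sd: float = 0.6
    trait_model: str = "infinitesimal_null"
    h2_total: float = 0.5
    rho_S: Optional[float] = None
    focal_variance_share: float = 0.25
    reliability_dist: Optional[tuple[float, float]] = None  # Beta(a, b), or None for unit weights
    trait_name: str = "sim_trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.h2_total < 1):
            raise ValueError("h2_total must lie in (0, 1)")
        if self.rho_S is not None and not (0 <= self.rho_S <= 1):
            raise ValueError("rho_S must lie in [0, 1]")
        if not (0 <= self.rho_ld < 1):
            raise ValueError("rho_ld must lie in [0, 1)")
        for name in ("n_individuals", "n_markers", "n_chromosomes", "ld_block_size", "n_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrueParams:
    """Ground truth recorded for parameter-recovery tests."""

    sigma2_g: float
    sigma2_e: float
    h2_total: float
    trait_model: str
    rho_S: Optional[float] = None
    target_name: Optional[str] = None
    focal_marker: Optional[int] = None
    marker_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    genetic_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    reliabilities: Optional[np.ndarray] = None


def _stage_rng(scn: SimulationScenario, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(scn.seed) % (2**31), stage]))


def simulate_genotypes(scn: SimulationScenario) -> GenotypeMatrix:
    """Hardy-Weinberg dosages with blockwise LD.

    Each gamete's alleles come from latent Gaussians sharing a per-block
    factor with loading sqrt(rho_ld), thresholded at the allele-frequency
    quantile, so adjacent markers within a block are in LD while blocks are
    independent.
    """
    rng = _stage_rng(scn, 1)
    n, m = scn.n_individuals, scn.n_markers
    per_chrom = np.full(scn.n_chromosomes, m // scn.n_chromosomes)
    per_chrom[: m % scn.n_chromosomes] += 1
    freqs = rng.uniform(*scn.freq_range, size=m)
    thresh = stats.norm.ppf(freqs)
    dosages = np.zeros((n, m), dtype=np.int8)
    sr, se = np.sqrt(scn.rho_ld), np.sqrt(1.0 - scn.rho_ld)
    col = 0
    rows = []
    for c, mc in enumerate(per_chrom):
        for start in range(0, mc, scn.ld_block_size):
            width = min(scn.ld_block_size, mc - start)
            block = slice(col, col + width)
            alleles = np.zeros((n, width), dtype=np.int8)
            for _gamete in range(2):
                f = rng.standard_normal((n, 1))
                z = sr * f + se * rng.standard_normal((n, width))
                alleles += (z < thresh[None, block]).astype(np.int8)
            dosages[:, block] = alleles
            col += width
        for k in range(mc):
            rows.append((f"M{len(rows):06d}", str(c + 1), scn.marker_spacing * (k + 1)))
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    ids = [f"I{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages.astype(float), ids, markers)


def simulate_annotation(
    scn: SimulationScenario, geno: GenotypeMatrix
) -> tuple[GeneTable, PathwayMap, str]:
    """Gene intervals covering ~``gene_coverage`` of the markers, pathways
    scattered across chromosomes, and a designated focal gene.

    Genes are non-overlapping intervals with log-normal lengths placed
    uniformly until the requested marker coverage is met (error if it
    cannot be approached).  Each pathway samples genes without replacement,
    re-drawn if it would sit on a single chromosome when several are
    available.  The focal gene is the mapped gene carrying the most markers.
    """
    rng = _stage_rng(scn, 2)
    chroms = geno.markers["chrom"].astype(str).to_numpy()
    pos = geno.markers["pos"].to_numpy()
    chrom_names = list(dict.fromkeys(chroms))
    chrom_len = {c: int(pos[chroms == c].max()) + scn.marker_spacing for c in chrom_names}
    chrom_pos = {c: np.sort(pos[chroms == c]) for c in chrom_names}
    target_cov = int(round(scn.gene_coverage * geno.n_markers))
    intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    genes: list[tuple[str, str, int, int, int]] = []  # id, chrom, start, stop, n_markers
    covered = 0
    attempts = 0
    max_attempts = 200 * scn.n_genes
    while covered < target_cov and len(genes) < scn.n_genes and attempts < max_attempts:
        attempts += 1
        c = chrom_names[int(rng.integers(len(chrom_names)))]
        length = int(np.clip(rng.lognormal(scn.gene_length_log_mean, scn.gene_length_log_sd),
                             2 * scn.marker_spacing, chrom_len[c] // 4))
        start = int(rng.integers(1, max(2, chrom_len[c] - length)))
        stop = start + length - 1
        if any(s <= stop and start <= e for s, e in intervals[c]):
            continue
        cp = chrom_pos[c]
        nmk = int(np.searchsorted(cp, stop, side="right") - np.searchsorted(cp, start, side="left"))
        if nmk == 0:
            continue
        intervals[c].append((start, stop))
        genes.append((f"G{len(genes):04d}", c, start, stop, nmk))
        covered += nmk
    if covered < 0.9 * target_cov:
        raise DataError(
            f"infeasible gene coverage request: reached {covered}/{target_cov} markers "
            f"with {len(genes)} genes"
        )
    table = GeneTable(pd.DataFrame([g[:4] for g in genes], columns=["gene_id", "chrom", "start", "stop"]))
    gene_ids = [g[0] for g in genes]
    gene_chrom = {g[0]: g[1] for g in genes}
    pathways: dict[str, frozenset[str]] = {}
    for p in range(scn.n_pathways):
        size = int(np.clip(round(rng.lognormal(scn.pathway_genes_log_mean, scn.pathway_genes_log_sd)),
                           3, len(gene_ids)))
        for _ in range(50):
            chosen = [gene_ids[i] for i in rng.choice(len(gene_ids), size=size, replace=False)]
            if size < 4 or len(chrom_names) < 2 or len({gene_chrom[g] for g in chosen}) >= 2:
                break
        pathways[f"P{p:03d}"] = frozenset(chosen)
    by_markers = sorted(genes, key=lambda g: (-g[4], g[0]))
    focal_gene = by_markers[0][0]
    return table, PathwayMap(pathways), focal_gene


def simulate_phenotypes(
    scn: SimulationScenario,
    geno: GenotypeMatrix,
    annotation: tuple[GeneTable, PathwayMap, str] | None = None,
    target_set: FeatureSet | None = None,
    focal_markers: np.ndarray | None = None,
) -> tuple[PhenotypeTable, TrueParams]:
    """Phenotypes y = g + e on a unit phenotypic-variance scale.

    Genetic values are g = W a with W the centered/scaled marker matrix and
    i.i.d. effects per stratum (see the trait models in the module
    docstring), so sigma2_g = h2_total and sigma2_e = 1 - h2_total.  With a
    reliability distribution configured, residual variances are
    sigma2_e / w_i with w_i = r_i^2 / (1 - r_i^2).

    ``focal_markers`` (the marker indices of the focal gene) is required for
    ``focal_locus``; ``target_set`` for ``pathway_enriched``.
    """
    rng = _stage_rng(scn, 3)
    w = center_scale(geno)
    n, m = w.n, w.m
    s2g = scn.h2_total
    s2e = 1.0 - scn.h2_total
    effects = np.zeros(m)
    focal_marker = None
    rho_S = scn.rho_S
    target_name = None
    if scn.trait_model == "infinitesimal_null":
        effects = rng.normal(0.0, np.sqrt(s2g / m), size=m)
    elif scn.trait_model == "pathway_enriched":
        if target_set is None or target_set.m_S == 0:
            raise DataError("pathway_enriched requires a non-empty target set")
        if rho_S is None:
            raise ValueError("pathway_enriched requires rho_S")
        target_name = target_set.name
        m_s = target_set.m_S
        in_s = np.zeros(m, dtype=bool)
        in_s[target_set.marker_indices] = True
        effects[in_s] = rng.normal(0.0, np.sqrt(rho_S * s2g / m_s), size=m_s)
        effects[~in_s] = rng.normal(0.0, np.sqrt((1.0 - rho_S) * s2g / (m - m_s)), size=m - m_s)
    elif scn.trait_model == "focal_locus":
        if focal_markers is None or len(focal_markers) == 0:
            raise DataError("focal_locus requires the focal gene's marker indices")
        share = scn.focal_variance_share
        effects = rng.normal(0.0, np.sqrt((1.0 - share) * s2g / m), size=m)
        # the focal-gene marker with frequency closest to 1/2 carries the hit
        freqs = geno.allele_freqs[np.asarray(focal_markers)]
        focal_marker = int(np.asarray(focal_markers)[np.argmin(np.abs(freqs - 0.5))])
        effects[focal_marker] += rng.choice([-1.0, 1.0]) * np.sqrt(share * s2g)
    else:
        raise ValueError(f"unknown trait model {scn.trait_model!r}")
    g = w.W @ effects
    reliabilities = None
    if scn.reliability_dist is not None:
        a, b = scn.reliability_dist
        reliabilities = np.clip(rng.beta(a, b, size=n), 0.05, 0.99)
        wts = reliabilities**2 / (1.0 - reliabilities**2)
        e = rng.normal(0.0, np.sqrt(s2e / wts))
    else:
        e = rng.normal(0.0, np.sqrt(s2e), size=n)
    y = g + e
    records = pd.DataFrame(
        {
            "individual_id": geno.individual_ids,
            "trait": scn.trait_name,
            "value": y,
            "reliability": reliabilities if reliabilities is not None else np.nan,
        }
    )
    truth = TrueParams(
        sigma2_g=s2g,
        sigma2_e=s2e,
        h2_total=scn.h2_total,
        trait_model=scn.trait_model,
        rho_S=rho_S,
        target_name=target_name,
        focal_marker=focal_marker,
        marker_effects=effects,
        genetic_values=g,
        reliabilities=reliabilities,
    )
    return PhenotypeTable(records), truth
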