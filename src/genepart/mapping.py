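"""Positional marker-to-gene mapping and marker feature sets.

A marker belongs to a gene when its position falls inside the gene's
(optionally flanked) 1-based closed interval on the same chromosome; strand
is ignored.  A pathway's marker set is the deduplicated union over its
genes — a marker inside two overlapping genes of the same pathway counts
once, while across pathways it may count repeatedly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .data import GeneTable, GenotypeMatrix, PathwayMap, DataError

log = logging.getLogger(__name__)

__all__ = [
    "MarkerGeneIndex",
    "FeatureSet",
    "map_markers_to_genes",
    "pathway_marker_set",
    "focal_region_genes",
    "complement_set",
    "write_feature_sets",
    "read_feature_sets",
]


@dataclass
class FeatureSet:
    """A named set of marker (column) indices — a pathway, a random gene
    group, or a complement set.

    ``genes`` records the contributing gene ids (sampling order for random
    groups); ``contains_focal`` flags intersection with a focal-region gene
    list.  ``target`` and ``exhausted`` are populated by the random-group
    sampler.
    """

    name: str
    marker_indices: np.ndarray
    contains_focal: bool = False
    genes: tuple[str, ...] = ()
    target: int | None = None
    exhausted: bool = False

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.marker_indices, dtype=np.intp))
        if idx.size == 0:
            raise DataError(f"feature set {self.name!r} is empty")
        if idx.min() < 0:
            raise DataError("negative marker index")
        self.marker_indices = idx

    @property
    def m_S(self) -> int:
        return int(self.marker_indices.size)

    def __len__(self) -> int:
        return self.m_S


@dataclass
class MarkerGeneIndex:
    """Bidirectional marker/gene association built at a fixed flank.

    ``gene_markers`` maps gene_id -> sorted marker indices (possibly empty);
    ``marker_genes`` lists the gene ids covering each marker (possibly many
    for overlapping genes).
    """

    gene_markers: dict[str, np.ndarray]
    marker_genes: list[tuple[str, ...]]
    flank: int
    n_markers: int

    def mapped_genes(self) -> list[str]:
        """Gene ids with at least one associated marker, in table order."""
        return [g for g, m in self.gene_markers.items() if m.size > 0]

    @property
    def n_mapped_markers(self) -> int:
        return int(sum(1 for gs in self.marker_genes if gs))


def map_markers_to_genes(g: GenotypeMatrix, genes: GeneTable, flank: int = 0) -> MarkerGeneIndex:
    """Associate markers with genes by position, with a symmetric ``flank``
    (bp) added both upstream and downstream of every gene.

    Interval boundaries are inclusive; a marker may map to several
    overlapping genes.  Genes on chromosomes absent from the genotypes get
    an empty marker list (with a warning).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for _, r in genes.records.iterrows():
        lo = max(1, int(r["start"]) - flank)
        hi = int(r["stop"]) + flank
        # IntervalTree is half-open; +1 makes the stop position inclusive
        trees.setdefault(str(r["chrom"]), IntervalTree()).addi(lo, hi + 1, str(r["gene_id"]))
    geno_chroms = set(g.markers["chrom"].astype(str))
    for _, r in genes.records.iterrows():
        if str(r["chrom"]) not in geno_chroms:
            log.warning("gene %s on chromosome %s absent from genotypes", r["gene_id"], r["chrom"])
    gene_markers: dict[str, list[int]] = {gid: [] for gid in genes.records["gene_id"]}
    marker_genes: list[tuple[str, ...]] = []
    chroms = g.markers["chrom"].astype(str).to_numpy()
    poss = g.markers["pos"].to_numpy()
    for i in range(g.n_markers):
        tree = trees.get(chroms[i])
        hits = sorted(iv.data for iv in tree[int(poss[i])]) if tree is not None else []
        marker_genes.append(tuple(hits))
        for gid in hits:
            gene_markers[gid].append(i)
    return MarkerGeneIndex(
        gene_markers={gid: np.asarray(v, dtype=np.intp) for gid, v in gene_markers.items()},
        marker_genes=marker_genes,
        flank=flank,
        n_markers=g.n_markers,
    )


def pathway_marker_set(
    pathway_id: str,
    pmap: PathwayMap,
    index: MarkerGeneIndex,
    focal_genes: set[str] | None = None,
) -> FeatureSet:
    """Union of marker indices over the pathway's genes, each marker counted
    once per pathway.  Genes absent from the annotation or without mapped
    markers contribute nothing; an empty union is an error (the set cannot
    be modelled)."""
    if pathway_id not in pmap:
        raise KeyError(pathway_id)
    genes = sorted(pmap[pathway_id])
    arrays = [index.gene_markers[g] for g in genes if g in index.gene_markers]
    idx = np.unique(np.concatenate(arrays)) if arrays else np.empty(0, dtype=np.intp)
    if idx.size == 0:
        raise DataError(f"pathway {pathway_id!r} has no mapped markers")
    focal = bool(focal_genes and set(genes) & set(focal_genes))
    return FeatureSet(pathway_id, idx, contains_focal=focal, genes=tuple(genes))


def focal_region_genes(focal_gene_id: str, genes: GeneTable, window: int = 500_000) -> set[str]:
    """Genes whose interval overlaps the focal gene's interval padded by
    ``window`` bp on both sides, on the focal chromosome (the focal gene is
    always included)."""
    chrom, start, stop = genes.interval(focal_gene_id)  # KeyError if unknown
    lo, hi = start - window, stop + window
    df = genes.records
    sel = (df["chrom"].astype(str) == chrom) & (df["start"] <= hi) & (df["stop"] >= lo)
    return set(df.loc[sel, "gene_id"])


def complement_set(s: FeatureSet, g: GenotypeMatrix) -> FeatureSet:
    """All markers not in ``s``; errors if ``s`` covers the full panel."""
    m = g.n_markers
    if s.marker_indices.max() >= m:
        raise DataError("feature set indices exceed the genotype panel")
    mask = np.ones(m, dtype=bool)
    mask[s.marker_indices] = False
    if not mask.any():
        raise DataError("feature set equals the full marker panel; complement is empty")
    return FeatureSet(f"not_{s.name}", np.nonzero(mask)[0], contains_focal=False)


def write_feature_sets(sets: list[FeatureSet], path: str | Path) -> None:
    """Serialize feature sets to TSV, one marker index per row."""
    rows = []
    for s in sets:
        for i in s.marker_indices:
            rows.append((s.name, int(s.contains_focal), int(i)))
    pd.DataFrame(rows, columns=["name", "contains_focal", "marker_index"]).to_csv(path, sep="\t", index=False)


def read_feature_sets(path: str | Path) -> list[FeatureSet]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    out = []
    for name, grp in df.groupby("name", sort=False):
        out.append(
            FeatureSet(name, grp["marker_index"].to_numpy(), contains_focal=bool(grp["contains_focal"].iloc[0]))
        )
    return out
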