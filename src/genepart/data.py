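"""Genotype, annotation, pathway and phenotype containers and file I/O.

Genotypes are biallelic allele dosages (count of the alternate allele, 0/1/2)
held as a dense individuals x markers matrix together with marker coordinates.
Supported on-disk dialects: plain dosage TSV, VCF (via cyvcf2) and PLINK
bed/bim/fam.  Gene annotation comes from GFF3 (via gffutils) or a 4-column
TSV; pathway-to-gene maps from GMT (via gseapy) or a 2-column TSV.

All coordinates are 1-based, fully closed intervals (GFF3/VCF convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "GenotypeMatrix",
    "GeneTable",
    "PathwayMap",
    "PhenotypeTable",
    "read_genotypes",
    "write_dosage_tsv",
    "filter_maf",
    "read_gene_annotation",
    "read_pathway_map",
    "read_phenotypes",
    "write_phenotypes_tsv",
    "write_gene_tsv",
    "write_gff3",
    "write_pathway_tsv",
    "write_gmt",
    "write_vcf",
]


class DataError(ValueError):
    """Raised when an input file violates the format or an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x markers alternate-allele dosage matrix.

    Attributes
    ----------
    dosages : (n, m) ndarray
        Allele dosages in {0, 1, 2}; float when mean-imputed.
    individual_ids : list of str
        Unique sample identifiers, row-aligned with ``dosages``.
    markers : pandas.DataFrame
        One row per marker with columns ``marker_id``, ``chrom``, ``pos``
        (1-based bp) and ``allele_freq`` (alternate-allele frequency,
        always recomputed as column mean / 2).
    """

    dosages: np.ndarray
    individual_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        self.individual_ids = [str(i) for i in self.individual_ids]
        if len(self.individual_ids) != n:
            raise DataError("individual_ids length does not match dosage rows")
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual ids")
        if len(self.markers) != m:
            raise DataError("marker table length does not match dosage columns")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise DataError(f"duplicate marker id: {dup!r}")
        finite = np.isfinite(self.dosages)
        if not finite.all():
            raise DataError("missing dosage values present; use missing='mean' or clean the input")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise DataError("dosages must lie in [0, 2]")
        self._sort_markers()
        self.markers = self.markers.reset_index(drop=True)
        self.markers["allele_freq"] = self.dosages.mean(axis=0) / 2.0 if n else np.nan

    def _sort_markers(self) -> None:
        """Sort positions within each chromosome (chromosome blocks keep
        first-appearance order); duplicate positions violate the invariant."""
        chrom = self.markers["chrom"].astype(str)
        order_of = {c: i for i, c in enumerate(dict.fromkeys(chrom))}
        key = pd.DataFrame({"c": chrom.map(order_of), "p": self.markers["pos"].to_numpy()})
        idx = np.lexsort((key["p"].to_numpy(), key["c"].to_numpy()))
        self.markers = self.markers.iloc[idx]
        self.dosages = self.dosages[:, idx]
        pos = self.markers["pos"].to_numpy()
        cix = key["c"].to_numpy()[idx]
        same = cix[1:] == cix[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise DataError("duplicate marker position within a chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.markers["allele_freq"].to_numpy()

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        """Return a copy restricted to ``ids``, in the given order."""
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise DataError(f"unknown individual ids: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return GenotypeMatrix(self.dosages[rows], list(ids), self.markers.drop(columns=["allele_freq"]).copy())


@dataclass
class GeneTable:
    """Gene intervals: one row per gene with gene_id, chrom, start, stop."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["gene_id", "chrom", "start", "stop"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise DataError(f"gene table missing columns: {missing}")
        df = self.records[req].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(int)
        df["stop"] = df["stop"].astype(int)
        if (df["start"] > df["stop"]).any():
            bad = df.loc[df["start"] > df["stop"], "gene_id"].iloc[0]
            raise DataError(f"gene {bad!r} has start > stop")
        if df["gene_id"].duplicated().any():
            bad = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DataError(f"duplicate gene id: {bad!r}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def interval(self, gene_id: str) -> tuple[str, int, int]:
        row = self.records.loc[self.records["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["stop"])


@dataclass
class PathwayMap:
    """pathway_id -> set of gene ids, with an optional group label each."""

    pathways: dict[str, frozenset[str]]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for pid, genes in self.pathways.items():
            gs = frozenset(str(g) for g in genes)
            if not gs:
                raise DataError(f"pathway {pid!r} has no genes")
            clean[str(pid)] = gs
        self.pathways = clean

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.pathways[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways


@dataclass
class PhenotypeTable:
    """Long-format trait records: individual_id, trait, value, reliability.

    Reliability is the accuracy r of a deregressed proof in [0, 1); absent
    (NaN) reliability means unit residual weight for that record.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["individual_id", "trait", "value"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise DataError(f"phenotype table missing columns: {missing}")
        df = self.records.copy()
        df["individual_id"] = df["individual_id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        if "reliability" not in df.columns:
            df["reliability"] = np.nan
        df["reliability"] = df["reliability"].astype(float)
        if df.duplicated(subset=["individual_id", "trait"]).any():
            raise DataError("duplicate (individual, trait) record")
        r = df["reliability"].dropna()
        if ((r < 0) | (r >= 1)).any():
            raise DataError("reliabilities must lie in [0, 1)")
        if not np.isfinite(df["value"]).all():
            raise DataError("non-finite trait value")
        self.records = df.reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def trait_frame(self, trait: str) -> pd.DataFrame:
        df = self.records.loc[self.records["trait"] == trait]
        if df.empty:
            raise DataError(f"no records for trait {trait!r}")
        return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "dosage_tsv", missing: str = "reject") -> GenotypeMatrix:
    """Read genotypes from ``path`` in one of the supported dialects.

    Parameters
    ----------
    format : {"dosage_tsv", "vcf", "plink"}
    missing : {"reject", "mean"}
        Policy for missing calls: raise, or impute the per-marker mean dosage.
    """
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "vcf":
        return _read_vcf(path, missing=missing)
    if format == "plink":
        return _read_plink(path, missing=missing)
    raise DataError(f"unknown genotype format {format!r}")


def _parse_marker_header(tok: str) -> tuple[str, int, str]:
    parts = tok.split(":")
    if len(parts) != 3:
        raise DataError(
            f"dosage TSV marker column {tok!r} must be 'chrom:pos:marker_id'"
        )
    chrom, pos, mid = parts
    return chrom, int(pos), mid


def _read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "iid":
        raise DataError("dosage TSV must start with an 'iid' column")
    ids = df["iid"].tolist()
    cols = list(df.columns[1:])
    meta = [_parse_marker_header(c) for c in cols]
    markers = pd.DataFrame(meta, columns=["chrom", "pos", "marker_id"])
    dos = df[cols].to_numpy(dtype=float)
    if np.isnan(dos).any():
        raise DataError("missing values in dosage TSV")
    if not np.all(np.isin(np.round(dos, 10), [0.0, 1.0, 2.0]) | ((dos >= 0) & (dos <= 2))):
        raise DataError("dosages outside [0, 2]")
    return GenotypeMatrix(dos, ids, markers[["marker_id", "chrom", "pos"]])


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage TSV dialect read back by :func:`read_genotypes`."""
    cols = [f"{c}:{p}:{m}" for m, c, p in zip(g.markers["marker_id"], g.markers["chrom"], g.markers["pos"])]
    dos = g.dosages
    as_int = np.array_equal(dos, np.round(dos))
    out = pd.DataFrame(dos.astype(int) if as_int else dos, columns=cols)
    out.insert(0, "iid", g.individual_ids)
    out.to_csv(path, sep="\t", index=False)


def _read_vcf(path: str | Path, missing: str = "reject") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    rows, meta = [], []
    for k, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise DataError(f"non-biallelic site at {v.CHROM}:{v.POS}")
        gt = np.asarray(v.gt_types, dtype=float)  # 0/1/2 dosage, 3 = missing
        miss = gt == 3
        if miss.any():
            if missing == "reject":
                raise DataError(f"missing genotype at {v.CHROM}:{v.POS}")
            gt[miss] = np.nan
            mean = np.nanmean(gt)
            if np.isnan(mean):
                raise DataError(f"all calls missing at {v.CHROM}:{v.POS}")
            gt[miss] = mean
            log.warning("mean-imputed %d missing calls at %s:%d", int(miss.sum()), v.CHROM, v.POS)
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append(gt)
        meta.append((mid, v.CHROM, v.POS))
    if not rows:
        raise DataError("VCF contains no variants")
    markers = pd.DataFrame(meta, columns=["marker_id", "chrom", "pos"])
    return GenotypeMatrix(np.column_stack(rows), ids, markers)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal plain-text VCF with GT fields (ref allele 'A', alt 'C')."""
    dos = g.dosages
    if not np.array_equal(dos, np.round(dos)):
        raise DataError("cannot write imputed (non-integer) dosages to VCF")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.markers["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.individual_ids) + "\n")
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            calls = "\t".join(gt_str[int(d)] for d in dos[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['marker_id']}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")


def _read_plink(prefix: str | Path, missing: str = "reject") -> GenotypeMatrix:
    """Read PLINK bed/bim/fam.  ``prefix`` may include or omit the .bed suffix.

    Dosage counts the A1 allele (bim column 5), PLINK's usual minor allele;
    .bed 2-bit codes: 00 hom A1 -> 2, 10 het -> 1, 11 hom A2 -> 0, 01 missing.
    """
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, usecols=[0, 1], names=["fid", "iid"], dtype=str)
    ids = fam["iid"].tolist()
    n, m = len(ids), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:3] != b"\x6c\x1b\x01":
        raise DataError("not a SNP-major PLINK .bed file")
    bpm = (n + 3) // 4  # bytes per marker
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bpm * m:
        raise DataError(".bed size does not match .bim/.fam dimensions")
    body = body.reshape(m, bpm)
    # unpack 2-bit genotype codes, little-endian within each byte
    codes = np.empty((m, bpm * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    dosage_of = np.array([2.0, np.nan, 1.0, 0.0])  # code 01 = missing
    dos = dosage_of[codes].T  # -> n x m
    miss = np.isnan(dos)
    if miss.any():
        if missing == "reject":
            j = int(np.where(miss.any(axis=0))[0][0])
            raise DataError(f"missing genotype at marker {bim['marker_id'].iloc[j]!r}")
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(miss, col_mean[None, :], dos)
        log.warning("mean-imputed %d missing PLINK calls", int(miss.sum()))
    return GenotypeMatrix(dos, ids, bim[["marker_id", "chrom", "pos"]])


def filter_maf(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Retain markers with minor-allele frequency strictly above ``threshold``.

    The frequency is min(p, 1-p) of the observed alternate-allele frequency;
    the comparison is strict, so monomorphic markers and markers at exactly
    the threshold are removed.  Marker order is preserved.
    """
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    p = g.allele_freqs
    keep = np.minimum(p, 1.0 - p) > threshold
    markers = g.markers.loc[keep, ["marker_id", "chrom", "pos"]].copy()
    return GenotypeMatrix(g.dosages[:, keep], list(g.individual_ids), markers)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | Path, format: str = "tsv") -> GeneTable:
    """Read gene intervals from GFF3 (``type == gene``) or a 4-column TSV."""
    if format == "gff3":
        return _read_gff3(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return GeneTable(df)
    raise DataError(f"unknown annotation format {format!r}")


def _read_gff3(path: str | Path) -> GeneTable:
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="error", from_string=False,
        )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid is None or gid == "":
            raise DataError(f"gene feature at {feat.seqid}:{feat.start} lacks an ID")
        rows.append((gid, feat.seqid, feat.start, feat.end))
    if not rows:
        raise DataError("GFF3 contains no gene features")
    return GeneTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "stop"]))


def write_gene_tsv(genes: GeneTable, path: str | Path) -> None:
    genes.records.to_csv(path, sep="\t", index=False)


def write_gff3(genes: GeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in genes.records.iterrows():
            fh.write(
                f"{r['chrom']}\tgenepart\tgene\t{r['start']}\t{r['stop']}\t.\t+\t.\tID={r['gene_id']}\n"
            )


# ---------------------------------------------------------------------------
# pathway I/O
# ---------------------------------------------------------------------------


def read_pathway_map(path: str | Path, format: str = "tsv") -> PathwayMap:
    """Read a pathway -> genes map from GMT or a 2-column TSV of pairs."""
    if format == "gmt":
        from gseapy import read_gmt

        raw = read_gmt(str(path))
        return PathwayMap({k: frozenset(v) for k, v in raw.items()})
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, names=["pathway_id", "gene_id"], dtype=str)
        if list(df.iloc[0]) == ["pathway_id", "gene_id"]:
            df = df.iloc[1:]
        mapping: dict[str, set[str]] = {}
        for pid, gid in zip(df["pathway_id"], df["gene_id"]):
            mapping.setdefault(pid, set()).add(gid)
        return PathwayMap({k: frozenset(v) for k, v in mapping.items()})
    raise DataError(f"unknown pathway format {format!r}")


def write_pathway_tsv(pmap: PathwayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tgene_id\n")
        for pid in sorted(pmap.pathways):
            for gid in sorted(pmap.pathways[pid]):
                fh.write(f"{pid}\t{gid}\n")


def write_gmt(pmap: PathwayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(pmap.pathways):
            desc = pmap.groups.get(pid, "na")
            fh.write(pid + "\t" + desc + "\t" + "\t".join(sorted(pmap.pathways[pid])) + "\n")


# ---------------------------------------------------------------------------
# phenotype I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with columns id, trait, value[, reliability]."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise DataError("phenotype TSV must have an 'id' column")
    df = df.rename(columns={"id": "individual_id"})
    return PhenotypeTable(df)


def write_phenotypes_tsv(pheno: PhenotypeTable, path: str | Path) -> None:
    out = pheno.records.rename(columns={"individual_id": "id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
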