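"""Genomic relationship matrices from centered, scaled marker dosages.

Columns are standardized per marker as (x - 2p) / sqrt(2 p (1 - p)) with p
the observed alternate-allele frequency, and a subset GRM is W_S W_S' / m_S.
With this per-marker scaling the full-panel GRM decomposes exactly as
G = (m_S G_S + m_notS G_notS) / m for any partition of the markers, which is
what makes the one- and two-component models nested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, DataError
from .mapping import FeatureSet

__all__ = [
    "ScaledMarkerMatrix",
    "GRM",
    "center_scale",
    "build_grm",
    "build_full_grm",
    "partition_grms",
    "verify_partition_identity",
    "write_grm",
    "read_grm",
]


@dataclass
class ScaledMarkerMatrix:
    """Centered and scaled n x m marker matrix with its scaling constants."""

    W: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    marker_ids: list[str]
    individual_ids: list[str]

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class GRM:
    """n x n genomic relationship matrix for a named marker subset."""

    matrix: np.ndarray
    m_used: int
    name: str = "all"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def center_scale(g: GenotypeMatrix) -> ScaledMarkerMatrix:
    """Standardize dosages to W with zero-mean, unit-2p(1-p)-variance columns.

    Monomorphic markers (p of 0 or 1) cannot be scaled and must be removed
    beforehand with :func:`genepart.data.filter_maf`.
    """
    p = g.allele_freqs
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise DataError("monomorphic marker present; apply filter_maf first")
    means = 2.0 * p
    scales = np.sqrt(2.0 * p * (1.0 - p))
    W = (g.dosages - means[None, :]) / scales[None, :]
    return ScaledMarkerMatrix(W, means, scales, g.markers["marker_id"].tolist(), list(g.individual_ids))


def build_grm(w: ScaledMarkerMatrix, s: FeatureSet) -> GRM:
    """G_S = W_S W_S' / m_S for the subset ``s``."""
    idx = s.marker_indices
    if idx.size == 0:
        raise DataError("empty marker subset")
    if idx.max() >= w.m:
        raise DataError("subset indices exceed the scaled matrix")
    Ws = w.W[:, idx]
    G = Ws @ Ws.T / idx.size
    return GRM(G, int(idx.size), name=s.name)


def build_full_grm(w: ScaledMarkerMatrix) -> GRM:
    """All-marker GRM W W' / m (the simple-model relationship matrix)."""
    return GRM(w.W @ w.W.T / w.m, w.m, name="all")


def partition_grms(w: ScaledMarkerMatrix, s: FeatureSet, g_all: GRM | None = None) -> tuple[GRM, GRM]:
    """(G_S, G_notS) for the partition induced by ``s``.

    When the full GRM is supplied, the complement matrix is recovered from
    the identity m_notS G_notS = m G - m_S G_S instead of a second large
    matrix product.
    """
    m, m_s = w.m, s.m_S
    if m_s >= m:
        raise DataError("subset must be a strict subset of the markers")
    gs = build_grm(w, s)
    if g_all is not None:
        if g_all.m_used != m:
            raise DataError("full GRM marker count does not match the scaled matrix")
        gn_mat = (m * g_all.matrix - m_s * gs.matrix) / (m - m_s)
    else:
        mask = np.ones(m, dtype=bool)
        mask[s.marker_indices] = False
        Wn = w.W[:, mask]
        gn_mat = Wn @ Wn.T / (m - m_s)
    return gs, GRM(gn_mat, m - m_s, name=f"not_{s.name}")


def verify_partition_identity(G: GRM, G_S: GRM, G_notS: GRM, m: int, m_S: int) -> float:
    """Max absolute deviation of G from (m_S G_S + (m - m_S) G_notS) / m."""
    if not (G.matrix.shape == G_S.matrix.shape == G_notS.matrix.shape):
        raise DataError("GRM dimension mismatch")
    recon = (m_S * G_S.matrix + (m - m_S) * G_notS.matrix) / m
    return float(np.max(np.abs(G.matrix - recon)))


def write_grm(grm: GRM, ids: list[str], path: str | Path) -> None:
    """Export the lower triangle (including diagonal) as TSV at 12
    significant digits: id_i, id_j, value."""
    n = grm.n
    with open(path, "w") as fh:
        fh.write(f"# m_used={grm.m_used}\tname={grm.name}\n")
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm.matrix[i, j]:.12g}\n")


def read_grm(path: str | Path) -> tuple[GRM, list[str]]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise DataError("GRM TSV must start with a '# m_used=...' header")
        fields = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh, sep="\t", header=None, names=["id_i", "id_j", "value"], dtype={0: str, 1: str})
    ids = list(dict.fromkeys(df["id_i"]))
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    G = np.zeros((n, n))
    for a, b, v in zip(df["id_i"], df["id_j"], df["value"]):
        i, j = pos[a], pos[b]
        G[i, j] = G[j, i] = v
    return GRM(G, int(fields["m_used"]), name=fields.get("name", "all")), ids
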