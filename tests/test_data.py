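"""Genotype/annotation/pathway/phenotype I-O and the MAF filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import genepart as gp
from genepart.data import (
    DataError,
    write_dosage_tsv,
    write_gene_tsv,
    write_gff3,
    write_gmt,
    write_pathway_tsv,
    write_phenotypes_tsv,
    write_vcf,
)

from conftest import make_genotypes


class TestDosageTSV:
    def test_read_back_values_and_freqs(self, tmp_path):
        g = make_genotypes([[0, 2], [1, 1], [2, 0]])
        path = tmp_path / "dos.tsv"
        write_dosage_tsv(g, path)
        g2 = gp.read_genotypes(path, "dosage_tsv")
        np.testing.assert_array_equal(g2.dosages, g.dosages)
        assert g2.individual_ids == g.individual_ids
        np.testing.assert_allclose(g2.allele_freqs, g.dosages.mean(axis=0) / 2)

    def test_round_trip_exact(self, tmp_path, small_dataset):
        g = small_dataset["geno"]
        path = tmp_path / "dos.tsv"
        write_dosage_tsv(g, path)
        g2 = gp.read_genotypes(path, "dosage_tsv")
        np.testing.assert_array_equal(g2.dosages, g.dosages)
        pd.testing.assert_frame_equal(g2.markers, g.markers)

    def test_duplicate_marker_id_rejected(self):
        markers = pd.DataFrame({"marker_id": ["M0", "M0"], "chrom": ["1", "1"], "pos": [1, 2]})
        with pytest.raises(DataError, match="duplicate marker"):
            gp.GenotypeMatrix(np.zeros((2, 2)), ["a", "b"], markers)

    def test_duplicate_individual_rejected(self):
        markers = pd.DataFrame({"marker_id": ["M0"], "chrom": ["1"], "pos": [1]})
        with pytest.raises(DataError, match="duplicate individual"):
            gp.GenotypeMatrix(np.zeros((2, 1)), ["a", "a"], markers)

    def test_markers_sorted_within_chromosome(self):
        g = make_genotypes([[0, 1, 2]], positions=[300, 100, 200])
        assert g.markers["pos"].tolist() == [100, 200, 300]
        np.testing.assert_array_equal(g.dosages[0], [1, 2, 0])


class TestVCF:
    def test_het_call_is_dosage_one(self, tmp_path):
        g = make_genotypes([[1], [0], [2]])
        path = tmp_path / "x.vcf"
        write_vcf(g, path)
        g2 = gp.read_genotypes(path, "vcf")
        np.testing.assert_array_equal(g2.dosages[:, 0], [1, 0, 2])

    def test_round_trip(self, tmp_path, small_dataset):
        g = small_dataset["geno"]
        path = tmp_path / "x.vcf"
        write_vcf(g, path)
        g2 = gp.read_genotypes(path, "vcf")
        np.testing.assert_array_equal(g2.dosages, g.dosages)
        assert g2.markers["pos"].tolist() == g.markers["pos"].tolist()

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\tm1\tA\tC,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(DataError, match="non-biallelic"):
            gp.read_genotypes(path, "vcf")

    @pytest.mark.parametrize("policy,ok", [("reject", False), ("mean", True)])
    def test_missing_call_policy(self, tmp_path, policy, ok):
        path = tmp_path / "miss.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tm1\tA\tC\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n"
        )
        if ok:
            g = gp.read_genotypes(path, "vcf", missing=policy)
            np.testing.assert_allclose(g.dosages[0, 0], 1.5)  # mean of 1 and 2
        else:
            with pytest.raises(DataError, match="missing"):
                gp.read_genotypes(path, "vcf", missing=policy)


class TestPlink:
    @staticmethod
    def _write_triplet(tmp_path, codes_per_marker, n):
        """Hand-pack 2-bit codes (2 bits per sample, little-endian within a
        byte) for a SNP-major .bed plus matching .bim/.fam."""
        m = len(codes_per_marker)
        body = bytearray(b"\x6c\x1b\x01")
        for codes in codes_per_marker:
            for byte_start in range(0, n, 4):
                b = 0
                for k, code in enumerate(codes[byte_start : byte_start + 4]):
                    b |= code << (2 * k)
                body.append(b)
        (tmp_path / "t.bed").write_bytes(bytes(body))
        with open(tmp_path / "t.bim", "w") as fh:
            for j in range(m):
                fh.write(f"1\tM{j}\t0\t{100 * (j + 1)}\tA\tG\n")
        with open(tmp_path / "t.fam", "w") as fh:
            for i in range(n):
                fh.write(f"F{i}\tI{i}\t0\t0\t0\t-9\n")
        return tmp_path / "t"

    def test_codes_decode_to_a1_dosage(self, tmp_path):
        # codes: 0 = hom A1 (dosage 2), 2 = het, 3 = hom A2 (dosage 0)
        prefix = self._write_triplet(tmp_path, [[0, 2, 3, 2, 0], [3, 3, 2, 0, 2]], n=5)
        g = gp.read_genotypes(prefix, "plink")
        np.testing.assert_array_equal(g.dosages[:, 0], [2, 1, 0, 1, 2])
        np.testing.assert_array_equal(g.dosages[:, 1], [0, 0, 1, 2, 1])
        assert g.individual_ids == [f"I{i}" for i in range(5)]

    def test_missing_code_policies(self, tmp_path):
        prefix = self._write_triplet(tmp_path, [[0, 1, 3, 3, 0]], n=5)  # code 1 = missing
        with pytest.raises(DataError, match="missing"):
            gp.read_genotypes(prefix, "plink")
        g = gp.read_genotypes(prefix, "plink", missing="mean")
        np.testing.assert_allclose(g.dosages[1, 0], 1.0)  # mean of (2,0,0,2)

    def test_bad_magic_rejected(self, tmp_path):
        prefix = self._write_triplet(tmp_path, [[0, 0, 0, 0, 0]], n=5)
        (tmp_path / "t.bed").write_bytes(b"\x00\x00\x00")
        with pytest.raises(DataError, match="SNP-major"):
            gp.read_genotypes(prefix, "plink")


class TestFilterMaf:
    def test_threshold_examples(self):
        g = make_genotypes([[0, 0], [0, 0], [0, 0], [1, 0]])  # freqs 0.125, 0
        out = gp.filter_maf(g)
        assert out.markers["marker_id"].tolist() == ["M0"]  # 0.125 kept, monomorphic dropped

    def test_exact_threshold_removed(self):
        dos = np.zeros((50, 1))
        dos[0, 0] = 1  # freq exactly 0.01
        out = gp.filter_maf(make_genotypes(dos), 0.01)
        assert out.n_markers == 0

    def test_symmetric_in_allele_coding(self):
        dos = np.full((100, 1), 2.0)
        dos[0, 0] = 1  # freq 0.995 -> MAF 0.005 < 0.01
        assert gp.filter_maf(make_genotypes(dos), 0.01).n_markers == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.integers(0, 3, size=(20, 15)).astype(float)
        g = make_genotypes(dos)
        once = gp.filter_maf(g, 0.01)
        twice = gp.filter_maf(once, 0.01)
        assert once.markers["marker_id"].tolist() == twice.markers["marker_id"].tolist()
        if once.n_markers:
            assert np.all((once.allele_freqs > 0.01) & (once.allele_freqs < 0.99))


class TestGeneAnnotation:
    def test_gff3_field_mapping(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=G1\n"
            "chr1\tsrc\texon\t120\t180\t.\t+\t.\tID=E1;Parent=G1\n"
            "chr2\tsrc\tgene\t50\t400\t.\t-\t.\tID=G2\n"
        )
        table = gp.read_gene_annotation(path, "gff3")
        assert table.interval("G1") == ("chr1", 100, 200)
        assert table.interval("G2") == ("chr2", 50, 400)
        assert len(table) == 2  # non-gene features ignored

    def test_tsv_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "genes.tsv"
        write_gene_tsv(small_dataset["genes"], path)
        table = gp.read_gene_annotation(path, "tsv")
        pd.testing.assert_frame_equal(table.records, small_dataset["genes"].records)

    def test_gff3_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "genes.gff3"
        write_gff3(small_dataset["genes"], path)
        table = gp.read_gene_annotation(path, "gff3")
        a = table.records.sort_values("gene_id").reset_index(drop=True)
        b = small_dataset["genes"].records.sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_start_after_stop_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tchrom\tstart\tstop\nG2\tchr2\t50\t40\n")
        with pytest.raises(DataError, match="start > stop"):
            gp.read_gene_annotation(path, "tsv")

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\tchrom\tstart\tstop\nG1\t1\t1\t10\nG1\t1\t20\t30\n")
        with pytest.raises(DataError, match="duplicate gene"):
            gp.read_gene_annotation(path, "tsv")


class TestPathwayMap:
    def test_tsv_pairs_deduplicated(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("P1\tG1\nP1\tG1\nP1\tG2\n")
        pmap = gp.read_pathway_map(path, "tsv")
        assert pmap["P1"] == frozenset({"G1", "G2"})

    def test_gmt_fields(self, tmp_path):
        path = tmp_path / "p.gmt"
        path.write_text("P2\tdesc\tG3\tG4\n")
        pmap = gp.read_pathway_map(path, "gmt")
        assert pmap["P2"] == frozenset({"G3", "G4"})

    def test_empty_pathway_rejected(self):
        with pytest.raises(DataError, match="no genes"):
            gp.PathwayMap({"P1": frozenset()})

    def test_writers_round_trip(self, tmp_path, small_dataset):
        pmap = small_dataset["pmap"]
        write_pathway_tsv(pmap, tmp_path / "p.tsv")
        write_gmt(pmap, tmp_path / "p.gmt")
        assert gp.read_pathway_map(tmp_path / "p.tsv", "tsv").pathways == pmap.pathways
        assert gp.read_pathway_map(tmp_path / "p.gmt", "gmt").pathways == pmap.pathways


class TestPhenotypes:
    def test_round_trip_and_reliability(self, tmp_path):
        df = pd.DataFrame(
            {
                "individual_id": ["a", "b", "a"],
                "trait": ["milk", "milk", "fat"],
                "value": [1.5, -0.5, 3.0],
                "reliability": [0.8, 0.9, np.nan],
            }
        )
        tab = gp.PhenotypeTable(df)
        path = tmp_path / "ph.tsv"
        write_phenotypes_tsv(tab, path)
        back = gp.read_phenotypes(path)
        assert back.traits() == ["fat", "milk"]
        milk = back.trait_frame("milk")
        assert milk["value"].tolist() == [1.5, -0.5]
        assert milk["reliability"].tolist() == [0.8, 0.9]

    def test_duplicate_record_rejected(self):
        df = pd.DataFrame({"individual_id": ["a", "a"], "trait": ["t", "t"], "value": [1.0, 2.0]})
        with pytest.raises(DataError, match="duplicate"):
            gp.PhenotypeTable(df)

    def test_reliability_bounds(self):
        df = pd.DataFrame({"individual_id": ["a"], "trait": ["t"], "value": [1.0], "reliability": [1.0]})
        with pytest.raises(DataError, match="reliabilities"):
            gp.PhenotypeTable(df)
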