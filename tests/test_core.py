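"""Domain types and file round trips: VCF, pedigree, marker grids, BED."""

import numpy as np
import pytest

from pedscout.core import (
    GeneInterval,
    GenotypeCall,
    Interval,
    MarkerGrid,
    Role,
    Variant,
    most_severe,
    read_bed,
    read_marker_grid,
    read_pedigree,
    read_vcf,
    write_bed,
    write_marker_grid,
    write_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=27>
##INFO=<ID=EFFECT,Number=.,Type=String,Description="Consequence">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCASE1\tSIRE\tDAM\tSIB1
"""


def _write(tmp_path, body, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_gt_states_decode(self, tmp_path):
        path = _write(
            tmp_path,
            "27\t37468611\t.\tG\tA\t.\t.\tEFFECT=missense_variant\tGT\t1/1\t0/1\t0/1\t0/0\n",
        )
        (v,) = read_vcf(path)
        assert (v.chrom, v.pos, v.ref, v.alt) == ("27", 37468611, "G", "A")
        assert v.consequence == "missense_variant"
        assert [v.genotypes[s] for s in ("CASE1", "SIRE", "DAM", "SIB1")] == [
            GenotypeCall.HOM_ALT, GenotypeCall.HET, GenotypeCall.HET, GenotypeCall.HOM_REF,
        ]

    def test_phase_separator_ignored_and_missing(self, tmp_path):
        path = _write(
            tmp_path, "27\t100\t.\tG\tA\t.\t.\t.\tGT\t1|1\t0|1\t./.\t0/0\n"
        )
        (v,) = read_vcf(path)
        assert v.genotypes["CASE1"] is GenotypeCall.HOM_ALT
        assert v.genotypes["SIRE"] is GenotypeCall.HET
        assert v.genotypes["DAM"] is GenotypeCall.MISSING

    def test_multiallelic_split_matches_manual_recoding(self, tmp_path):
        # three samples carrying: A/T het-het, A hom, T het-with-ref
        body = "27\t500\t.\tG\tA,T\t.\t.\t.\tGT\t1/2\t1/1\t0/2\t0/0\n"
        path = _write(tmp_path, body)
        va, vt = read_vcf(path)
        assert (va.alt, vt.alt) == ("A", "T")
        # per-allele manual recoding of 1/2, 1/1, 0/2, 0/0
        assert [va.genotypes[s] for s in ("CASE1", "SIRE", "DAM", "SIB1")] == [
            GenotypeCall.HET, GenotypeCall.HOM_ALT, GenotypeCall.HOM_REF, GenotypeCall.HOM_REF,
        ]
        assert [vt.genotypes[s] for s in ("CASE1", "SIRE", "DAM", "SIB1")] == [
            GenotypeCall.HET, GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_REF,
        ]
        # the sample whose genotype refers to the other alt is flagged
        assert va.genotypes["DAM"] is GenotypeCall.HOM_REF
        assert "DAM" in va.other_alt_samples
        assert "SIRE" in vt.other_alt_samples

    def test_multiallelic_split_preserves_allele_multiset(self, tmp_path):
        body = "27\t500\t.\tG\tA,T\t.\t.\t.\tGT\t1/2\t1/1\t0/2\t0/1\n"
        path = _write(tmp_path, body)
        split = read_vcf(path)
        # each sample's total alt dose across the split variants matches the GT
        dose = {GenotypeCall.HOM_REF: 0, GenotypeCall.HET: 1, GenotypeCall.HOM_ALT: 2}
        total = {
            s: sum(dose[v.genotypes[s]] for v in split)
            for s in ("CASE1", "SIRE", "DAM", "SIB1")
        }
        assert total == {"CASE1": 2, "SIRE": 2, "DAM": 1, "SIB1": 1}

    def test_vep_csq_dialect_most_severe_wins(self, tmp_path):
        header = VCF_HEADER.replace(
            '##INFO=<ID=EFFECT,Number=.,Type=String,Description="Consequence">',
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="VEP. Format: Allele|Consequence|Gene">',
        )
        path = tmp_path / "vep.vcf"
        path.write_text(
            header
            + "27\t100\t.\tG\tA\t.\t.\tCSQ=A|intron_variant|g1,A|missense_variant&splice_region_variant|g2\tGT\t1/1\t0/1\t0/1\t0/0\n"
        )
        (v,) = read_vcf(path, dialect="vep")
        assert v.consequence == "missense_variant"

    def test_unknown_dialect_rejected(self, tmp_path):
        path = _write(tmp_path, "")
        with pytest.raises(ValueError, match="dialect"):
            read_vcf(path, dialect="snpeff")

    def test_write_read_round_trip_preserves_states(self, tmp_path):
        rng = np.random.default_rng(0)
        samples = ["CASE1", "SIRE", "DAM", "SIB1"]
        states = list(GenotypeCall)
        variants = [
            Variant(chrom="5", pos=int(p), ref="C", alt="T",
                    consequence="synonymous_variant",
                    genotypes={s: states[rng.integers(4)] for s in samples})
            for p in sorted(rng.choice(10_000_000, size=40, replace=False) + 1)
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(variants, samples, path)
        back = read_vcf(path)
        assert len(back) == len(variants)
        for orig, rec in zip(variants, back):
            assert orig.key == rec.key
            assert orig.genotypes == rec.genotypes


def test_most_severe_ranking():
    assert most_severe(["synonymous_variant", "missense_variant"]) == "missense_variant"
    assert most_severe(["intergenic_variant"]) == "intergenic_variant"
    # unknown terms rank last
    assert most_severe(["made_up_term", "intron_variant"]) == "intron_variant"


def test_variant_invariants():
    with pytest.raises(ValueError):
        Variant(chrom="1", pos=0, ref="G", alt="A", consequence="")
    with pytest.raises(ValueError):
        Variant(chrom="1", pos=5, ref="G", alt="G", consequence="")
    with pytest.raises(ValueError):
        Variant(chrom="1", pos=5, ref="", alt="A", consequence="")


class TestPedigree:
    def test_seven_member_family(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text(
            "CASE1\tCASE\tGS\nCASE2\tCASE\tGS\nSIRE\tOBLIGATE_CARRIER\tGS\n"
            "DAM\tOBLIGATE_CARRIER\tGS\nSIB1\tUNAFFECTED\tGS\n"
            "SIB2\tUNAFFECTED\tGS\nSIB3\tUNAFFECTED\tGS\n"
        )
        roles = read_pedigree(path)
        assert len(roles) == 7
        assert sum(r.role is Role.CASE for r in roles) == 2

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text("A\tCASE\tGS\nA\tUNAFFECTED\tGS\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_pedigree(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="CASE"):
            read_pedigree(path)

    def test_unknown_role_lists_valid_tokens(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text("A\tPROBAND\tGS\n")
        with pytest.raises(ValueError, match="OBLIGATE_CARRIER"):
            read_pedigree(path)


class TestMarkerGrid:
    def test_tsv_round_trip(self, tmp_path):
        positions = np.array([100, 5000, 10_000, 20_000])
        grid = MarkerGrid(
            chrom="1",
            positions=positions,
            genotypes={"S1": np.array([0, 1, 2, -1], dtype=np.int8),
                       "S2": np.array([2, 2, 0, 1], dtype=np.int8)},
        )
        path = tmp_path / "grid.tsv"
        write_marker_grid([grid], path)
        (back,) = read_marker_grid(path)
        assert np.array_equal(back.positions, grid.positions)
        for s in ("S1", "S2"):
            assert np.array_equal(back.genotypes[s], grid.genotypes[s])

    def test_duplicate_positions_rejected(self, tmp_path):
        path = tmp_path / "grid.tsv"
        path.write_text("chrom\tpos\tS1\n1\t100\t0\n1\t100\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_marker_grid(path)

    def test_vcf_grid_drops_non_biallelic_snvs(self, tmp_path):
        header = VCF_HEADER
        body = (
            "27\t100\t.\tG\tA\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
            "27\t200\t.\tG\tA,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"  # multiallelic: drop
            "27\t300\t.\tGA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"   # indel: drop
            "27\t400\t.\tC\tT\t.\t.\t.\tGT\t1/1\t1/1\t0/0\t0/1\n"
        )
        path = tmp_path / "grid.vcf"
        path.write_text(header + body)
        (grid,) = read_marker_grid(path)
        assert grid.positions.tolist() == [100, 400]
        assert grid.genotypes["CASE1"].tolist() == [0, 2]
        assert grid.genotypes["SIB1"].tolist() == [-1, 1]

    def test_unsorted_input_is_sorted(self, tmp_path):
        path = tmp_path / "grid.tsv"
        path.write_text("chrom\tpos\tS1\n1\t500\t0\n1\t100\t1\n")
        (grid,) = read_marker_grid(path)
        assert grid.positions.tolist() == [100, 500]
        assert grid.genotypes["S1"].tolist() == [1, 0]


class TestBed:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "segs.bed"
        write_bed([Interval("27", 36_722_004, 45_753_342)], path)
        assert path.read_text() == "27\t36722003\t45753342\n"

    def test_empty_list_writes_header_comment(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed([], path)
        assert path.read_text().startswith("#")

    def test_thirteen_segments_sorted(self, tmp_path):
        from pedscout.datasets import CASE_SHARED_ROH

        path = tmp_path / "roh.bed"
        intervals = [Interval(c, s, e) for c, s, e, _ in reversed(CASE_SHARED_ROH)]
        write_bed(intervals, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 13
        chroms = [int(line.split("\t")[0]) for line in lines]
        assert chroms == sorted(chroms)

    def test_bed_read_back_is_one_based(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("27\t37460606\t37506942\tNECAP1\n")
        (gene,) = read_bed(path)
        assert gene == GeneInterval("27", 37_460_607, 37_506_942, "NECAP1")
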