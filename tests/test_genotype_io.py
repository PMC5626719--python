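import numpy as np
import pytest

from fipsa import (
    GenotypeMatrix,
    MISSING,
    ld_prune,
    read_matrix,
    read_vcf,
    simulate,
    write_matrix,
    SimulationSpec,
)

from conftest import gm_from_strings

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(tmp_path, body: str):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestMatrixFormat:
    def test_all_ref_two_by_two(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("id\tl1\tl2\na\t0/0\t0/0\nb\t0/0\t0/0\n")
        gm = read_matrix(p)
        assert gm.n_individuals == 2 and gm.n_loci == 2
        assert gm.n_alleles.tolist() == [1, 1]

    def test_round_trip_preserves_calls_and_missingness(self, tmp_path):
        gm = gm_from_strings(
            [["0/1", "2/0", "./."], ["1/1", "0/0", "1/."], ["0/0", "1/1", "0/1"]]
        )
        path = tmp_path / "rt.tsv"
        write_matrix(gm, path)
        assert read_matrix(path) == gm

    def test_max_code_rule_for_multiallelic_cell(self, tmp_path):
        gm = gm_from_strings([["0/0"], ["1/1"], ["2/0"]])
        assert gm.n_alleles.tolist() == [3]

    @pytest.mark.parametrize(
        "text",
        [
            "id\tl1\na\t0/1\tEXTRA\n",  # ragged row
            "id\tl1\na\tx/1\n",  # non-integer token
            "id\tl1\na\t0/1\na\t0/0\n",  # duplicate individual id
        ],
    )
    def test_malformed_matrix_rejected(self, tmp_path, text):
        p = tmp_path / "bad.tsv"
        p.write_text(text)
        with pytest.raises(ValueError):
            read_matrix(p)

    def test_duplicate_locus_ids_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tl1\tl1\na\t0/1\t0/0\n")
        with pytest.raises(ValueError):
            read_matrix(p)


class TestVCF:
    def test_gt_mapping_and_missing_convention(self, tmp_path):
        body = "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0|1\t./.\n" \
               "1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t1/.\t0/0\t1/1\n"
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.individual_ids == ["S1", "S2", "S3"]
        assert sorted(gm.calls[0, 0].tolist()) == [0, 1]  # "0/1"
        assert sorted(gm.calls[1, 0].tolist()) == [0, 1]  # phase discarded
        assert gm.calls[2, 0].tolist() == [MISSING, MISSING]  # "./."
        assert sorted(gm.calls[0, 1].tolist()) == [MISSING, 1]  # "1/."

    def test_monomorphic_record_dropped_by_min_allele_count(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
            "1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n"
            "1\t300\trs3\tT\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body), min_allele_count=1)
        assert gm.n_loci == 2
        assert gm.locus_ids == ["rs1", "rs3"]

    def test_biallelic_only_drops_multiallelic_records(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n"
            "1\t200\trs2\tC\tG,T\t.\tPASS\t.\tGT\t1/2\t0/1\t0/0\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body), biallelic_only=True)
        assert gm.n_loci == 1
        full = read_vcf(write_vcf(tmp_path, body))
        assert full.n_loci == 2
        assert full.n_alleles.tolist() == [2, 3]
        # codes never exceed ALT count
        assert full.calls.max() <= 2

    def test_all_filtered_reports_counts(self, tmp_path):
        body = "1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\n"
        with pytest.raises(ValueError, match="min_allele_count"):
            read_vcf(write_vcf(tmp_path, body), min_allele_count=1)

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            read_vcf(tmp_path / "absent.vcf")


class TestLDPrune:
    def test_duplicated_locus_removed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, size=(30, 1, 2)).astype(np.int16)
        other = rng.integers(0, 2, size=(30, 1, 2)).astype(np.int16)
        calls = np.concatenate([col, col, other], axis=1)
        gm = GenotypeMatrix([f"i{j}" for j in range(30)], ["a", "b", "c"], calls)
        kept = ld_prune(gm, r2_max=0.2)
        assert 0 in kept and 1 not in kept

    def test_r2_max_one_retains_everything(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 2, size=(20, 1, 2)).astype(np.int16)
        calls = np.concatenate([col, col], axis=1)
        gm = GenotypeMatrix([f"i{j}" for j in range(20)], ["a", "b"], calls)
        assert ld_prune(gm, r2_max=1.0) == [0, 1]

    def test_independent_loci_typically_all_retained(self):
        gm, _ = simulate(SimulationSpec(K=1, sizes=(200,), n_loci=120, F=0.0, seed=5))
        kept = ld_prune(gm, r2_max=0.99)
        assert kept == list(range(120))

    def test_idempotent_and_increasing(self):
        gm, _ = simulate(SimulationSpec(K=1, sizes=(40,), n_loci=80, F=0.0, seed=6))
        kept = ld_prune(gm, r2_max=0.05, window=20, step=5)
        assert kept == sorted(set(kept))
        pruned = gm.subset_loci(kept)
        again = ld_prune(pruned, r2_max=0.05, window=20, step=5)
        assert again == list(range(len(kept)))

    def test_non_biallelic_passed_through(self):
        gm = gm_from_strings([["0/1", "2/0"], ["0/1", "1/1"], ["1/0", "0/2"]])
        with pytest.warns(UserWarning, match="non-biallelic"):
            kept = ld_prune(gm, r2_max=0.0, window=2, step=1)
        assert 1 in kept  # the triallelic locus is untouched

    def test_invalid_r2(self, two_block_gm):
        with pytest.raises(ValueError):
            ld_prune(two_block_gm, r2_max=1.5)
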