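"""Input parsing, SNP quality control, flanking selection, model files."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import libag
from libag import MISSING, DataFormatError


def write_tsv_panel(tmp_path, samples, snps, values):
    """values: list of rows of string tokens ('0','1','2','NA')."""
    geno = tmp_path / "g.tsv"
    info = tmp_path / "snps.tsv"
    header = "sample\t" + "\t".join(s.snp_id for s in snps)
    lines = [header] + [
        f"{sample}\t" + "\t".join(row) for sample, row in zip(samples, values)
    ]
    geno.write_text("\n".join(lines) + "\n")
    info_lines = ["snp_id\tchrom\tpos\tallele_a\tallele_b"] + [
        f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.allele_a}\t{s.allele_b}" for s in snps
    ]
    info.write_text("\n".join(info_lines) + "\n")
    return geno, info


class TestTSVReader:
    def test_direct_encoding_and_missing_token(self, tmp_path):
        snps = [libag.SNPMeta("rs1", "19", 100, "A", "G")]
        geno, info = write_tsv_panel(tmp_path, ["S1", "S2"], snps, [["0"], ["2"]])
        g = libag.read_genotypes(geno, format="tsv", snp_info=info)
        assert g.codes.tolist() == [[0], [2]]
        assert g.samples == ["S1", "S2"]

        geno, info = write_tsv_panel(tmp_path, ["S1"], snps, [["NA"]])
        g = libag.read_genotypes(geno, format="tsv", snp_info=info)
        assert g.codes[0, 0] == MISSING

    def test_bad_token_names_line(self, tmp_path):
        snps = [libag.SNPMeta("rs1", "19", 100, "A", "G")]
        geno, info = write_tsv_panel(tmp_path, ["S1"], snps, [["7"]])
        with pytest.raises(DataFormatError, match="line"):
            libag.read_genotypes(geno, format="tsv", snp_info=info)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        geno = tmp_path / "g.tsv"
        geno.write_text("sample\trs1\trs1\nS1\t0\t1\n")
        info = tmp_path / "snps.tsv"
        info.write_text(
            "snp_id\tchrom\tpos\tallele_a\tallele_b\nrs1\t19\t100\tA\tG\n"
        )
        with pytest.raises(DataFormatError, match="duplicated"):
            libag.read_genotypes(geno, format="tsv", snp_info=info)


class TestPlinkReader:
    def test_hand_decoded_bed_byte(self, tmp_path):
        # 3 samples x 2 variants, variant-major.  2-bit codes (little-end
        # first): 00=hom A1 -> 0 copies of allele_b, 10=het -> 1, 11=hom A2
        # -> 2, 01=missing.
        # variant 1: S1=0 (00), S2=1 (10), S3=2 (11) -> byte 0b00111000
        # variant 2: S1=missing (01), S2=0 (00), S3=1 (10) -> byte 0b00100001
        (tmp_path / "p.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b00111000, 0b00100001]))
        (tmp_path / "p.bim").write_text("19\trs1\t0\t100\tA\tG\n19\trs2\t0\t200\tC\tT\n")
        (tmp_path / "p.fam").write_text(
            "F1 S1 0 0 0 -9\nF2 S2 0 0 0 -9\nF3 S3 0 0 0 -9\n"
        )
        g = libag.read_genotypes(tmp_path / "p", format="plink-bed")
        assert g.samples == ["S1", "S2", "S3"]
        assert g.codes.tolist() == [[0, MISSING], [1, 0], [2, 1]]
        assert g.snps[0].allele_a == "A" and g.snps[0].allele_b == "G"

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "p.bed").write_bytes(bytes([0, 0, 1, 0]))
        (tmp_path / "p.bim").write_text("19\trs1\t0\t100\tA\tG\n")
        (tmp_path / "p.fam").write_text("F1 S1 0 0 0 -9\n")
        with pytest.raises(DataFormatError, match="magic"):
            libag.read_genotypes(tmp_path / "p", format="plink-bed")


class TestCNLabels:
    def test_pair_total_and_bounds(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("sample\tcn1\tcn2\nS1\t1\t0\nS2\t2\tNA\n")
        labels = libag.read_cn_labels(path)
        assert labels["S1"].cn_pair == (0, 1) and labels["S1"].known_phase_split
        assert labels["S2"].total == 2 and not labels["S2"].known_phase_split

        path.write_text("sample\tcn1\tcn2\nS3\t5\t0\n")
        with pytest.raises(DataFormatError, match="outside"):
            libag.read_cn_labels(path, cn_max=4)


class TestHWEExactTest:
    @pytest.mark.parametrize(
        "counts,check",
        [
            ((100, 0, 0), lambda p: p == 1.0),  # monomorphic
            ((50, 0, 50), lambda p: p < 1e-5),  # extreme het deficit: removed
            ((25, 50, 25), lambda p: p > 0.05),  # modal configuration: kept
        ],
    )
    def test_reference_configurations(self, counts, check):
        assert check(libag.hwe_exact_test(*counts))

    def test_matches_direct_enumeration(self):
        # independent oracle: exact probabilities from factorials at tiny n
        from math import factorial

        def oracle(n_aa, n_ab, n_bb):
            n = n_aa + n_ab + n_bb
            n_a = 2 * n_aa + n_ab
            n_b = 2 * n_bb + n_ab
            if n_a == 0 or n_b == 0:
                return 1.0

            def prob(h):
                if (n_a - h) % 2 or (n_a - h) < 0 or (n_b - h) < 0:
                    return 0.0
                return (
                    factorial(n)
                    / (factorial((n_a - h) // 2) * factorial(h) * factorial((n_b - h) // 2))
                    * 2**h
                    / (factorial(2 * n) / (factorial(n_a) * factorial(n_b)))
                )

            p_obs = prob(n_ab)
            return sum(
                prob(h) for h in range(min(n_a, n_b) + 1) if 0 < prob(h) <= p_obs * (1 + 1e-12)
            )

        for counts in [(5, 2, 3), (1, 8, 1), (4, 0, 4), (0, 10, 0), (7, 1, 2)]:
            assert libag.hwe_exact_test(*counts) == pytest.approx(oracle(*counts), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    def test_symmetric_under_allele_relabeling(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert libag.hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
            libag.hwe_exact_test(n_bb, n_ab, n_aa), abs=1e-12
        )


class TestSNPQC:
    def make_matrix(self, columns):
        snps = [
            libag.SNPMeta(f"rs{j}", "19", 100 + j, "A", "G") for j in range(len(columns))
        ]
        codes = np.array(columns).T
        samples = [f"S{i}" for i in range(codes.shape[0])]
        return libag.GenotypeMatrix(samples=samples, snps=snps, codes=codes)

    def test_removal_reasons_and_retention(self):
        n = 40
        rng = np.random.default_rng(0)
        good = rng.choice([0, 1, 2], size=n, p=[0.49, 0.42, 0.09])  # HWE at p=0.3
        mono = np.zeros(n, dtype=int)  # MAF 0
        gappy = good.copy()
        gappy[: n // 10 + 1] = MISSING  # call rate <= 0.95
        g = self.make_matrix([list(good), list(mono), list(gappy)])
        filtered, report = libag.snp_qc(g)
        t = report.table.set_index("snp_id")
        assert t.loc["rs0", "passed"]
        assert not t.loc["rs1", "passed"] and "maf" in t.loc["rs1", "reasons"]
        assert not t.loc["rs2", "passed"] and "call_rate" in t.loc["rs2", "reasons"]
        assert [s.snp_id for s in filtered.snps] == ["rs0"]

    def test_idempotent(self, small_panel):
        g, _, _, _ = small_panel
        once, _ = libag.snp_qc(g)
        twice, _ = libag.snp_qc(once)
        assert [s.snp_id for s in once.snps] == [s.snp_id for s in twice.snps]
        assert np.array_equal(once.codes, twice.codes)


class TestSelectFlanking:
    def test_closed_boundary(self):
        snps = [
            libag.SNPMeta("in_edge", "19", 990_000, "A", "G"),
            libag.SNPMeta("out_edge", "19", 989_999, "A", "G"),
            libag.SNPMeta("wrong_chrom", "1", 1_000_000, "A", "G"),
        ]
        g = libag.GenotypeMatrix(
            samples=["S1"], snps=snps, codes=np.zeros((1, 3), dtype=int)
        )
        sub = libag.select_flanking(g, "19", 1_000_000, 10)
        assert [s.snp_id for s in sub.snps] == ["in_edge"]

    def test_windows_nest(self, small_panel):
        g, _, _, _ = small_panel
        prev = set()
        for w in range(10, 101, 10):
            ids = {s.snp_id for s in libag.select_flanking(g, "19", 54_700_000, w).snps}
            assert prev <= ids
            prev = ids


class TestModelSerialization:
    def test_round_trip_identical_predictions(self, small_model, small_panel, tmp_path):
        g, _, _, _ = small_panel
        path = tmp_path / "model.json"
        libag.serialize_model(small_model, path)
        loaded = libag.deserialize_model(path)
        before, _ = libag.predict(small_model, g, ct=0.5)
        after, _ = libag.predict(loaded, g, ct=0.5)
        assert before == after  # bit-identical posteriors and calls

    def test_unknown_version_rejected(self, small_model, tmp_path):
        path = tmp_path / "model.json"
        libag.serialize_model(small_model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = "libag-model-99"
        path.write_text(json.dumps(doc))
        with pytest.raises(DataFormatError, match="libag-model-99"):
            libag.deserialize_model(path)

    def test_minimal_hand_written_model(self, tmp_path):
        # a single-haplotype degenerate model must predict its CN pair with
        # probability 1 for any compatible genotype
        doc = {
            "format_version": "libag-model-1",
            "gene": "LILRA6", "chrom": "19", "center": 1000, "window_kb": 10.0,
            "cn_min": 0, "cn_max": 4,
            "config": {
                "n_classifiers": 1, "mtry": None, "max_snps": None,
                "em_tol": 1e-6, "em_max_iter": 200, "prune_freq": None,
                "rng_seed": 0,
            },
            "snps": [
                {"snp_id": "rs1", "chrom": "19", "pos": 900,
                 "allele_a": "A", "allele_b": "G"}
            ],
            "classifiers": [
                {"seed": 0, "bootstrap_seed": 0, "in_bag": [0, 0],
                 "oob_accuracy": 1.0, "history": [[0, 1.0]],
                 "snp_subset": [0], "log_lik": 0.0,
                 "haplotypes": [{"alleles": [1], "cn": 2, "freq": 1.0}]}
            ],
        }
        path = tmp_path / "mini.json"
        path.write_text(json.dumps(doc))
        model = libag.deserialize_model(path)
        target = libag.GenotypeMatrix(
            samples=["S1"],
            snps=[libag.SNPMeta("rs1", "19", 900, "A", "G")],
            codes=np.array([[2]]),
        )
        calls, _ = libag.predict(model, target, ct=0.5)
        assert calls[0].best_cn_pair == (2, 2)
        assert calls[0].aggregated_prob == 1.0 and calls[0].called
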