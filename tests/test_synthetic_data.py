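import math

import numpy as np
import pandas as pd
import pytest

from krascope.quant_stats import recombination_fraction, relative_level
from krascope.read_processing import merge_pairs
from krascope.refmodel import revcomp
from krascope.synthetic_data import (
    AmpliconTruth,
    ArmSpec,
    MdsTruth,
    SimulationConfigError,
    _draw_family_plan,
    effective_frequencies,
    recombination_design,
    simulate_mds_library,
    simulate_qpcr_table,
    simulate_tumor_amplicon,
    simulate_tumor_cohort,
)


class TestAmpliconSimulator:
    def test_truth_validation(self):
        with pytest.raises(SimulationConfigError):
            AmpliconTruth("S1", "nat", "T", "WT", 1.2, 10)
        with pytest.raises(SimulationConfigError):
            AmpliconTruth("S1", "nat", "T", "WT", 0.5, 10, per_base_error=0.5)
        with pytest.raises(SimulationConfigError):
            AmpliconTruth("S1", "sideways", "T", "WT", 0.5, 10)

    def test_unknown_variant_label(self, locus, index_table):
        truth = AmpliconTruth("S1", "nat", "T", "Q61Z", 0.5, 5)
        with pytest.raises(KeyError):
            simulate_tumor_amplicon(locus, truth, index_table)

    def test_error_free_wildtype_reconstructs_reference(self, locus, index_table):
        truth = AmpliconTruth("S1", "nat", "T", "WT", 0.0, 50, 0.0, seed=1)
        reads1, reads2 = simulate_tumor_amplicon(locus, truth, index_table)
        row = index_table.df.iloc[0]
        expected = (
            row["five_prime_index"] + locus.coding_sequence + row["three_prime_index"]
        )
        for r1, r2 in zip(reads1, reads2):
            merged = merge_pairs(r1, r2)
            assert merged is not None and merged.sequence == expected

    def test_mutant_count_is_replayable_binomial_draw(self, locus, index_table):
        truth = AmpliconTruth("S2", "ex3op", "C", "Q61L", 0.5, 400, 0.0, seed=11)
        reads1, _ = simulate_tumor_amplicon(locus, truth, index_table)
        expected_mutants = int(np.random.default_rng(11).binomial(400, 0.5))
        # position of CDS 182 within read 1: after the 7-nt 5' index of S2
        offset = len(index_table.df.set_index("sample_id").loc["S2", "five_prime_index"])
        observed = sum(r.sequence[offset + 181] == "T" for r in reads1)
        assert observed == expected_mutants

    def test_seed_determinism_byte_identical(self, locus, index_table, tmp_path):
        truth = AmpliconTruth("S1", "nat", "T", "G12D", 0.3, 100, 1e-2, seed=5)
        for run in ("a", "b"):
            simulate_tumor_amplicon(
                locus, truth, index_table,
                out_r1=tmp_path / f"{run}.R1.fastq", out_r2=tmp_path / f"{run}.R2.fastq",
            )
        assert (tmp_path / "a.R1.fastq").read_bytes() == (
            tmp_path / "b.R1.fastq"
        ).read_bytes()
        assert (tmp_path / "a.R2.fastq").read_bytes() == (
            tmp_path / "b.R2.fastq"
        ).read_bytes()
        manifest = pd.read_csv(tmp_path / "a.R1.fastq.truth.tsv", sep="\t")
        assert manifest["variant_label"].iloc[0] == "G12D"

    def test_empirical_fraction_converges(self, locus, index_table):
        n = 100_000
        truth = AmpliconTruth("S1", "ex3op", "T", "Q61L", 0.6, n, 0.0, seed=13)
        reads1, _ = simulate_tumor_amplicon(locus, truth, index_table)
        offset = len(index_table.df.iloc[0]["five_prime_index"])
        observed = sum(r.sequence[offset + 181] == "T" for r in reads1) / n
        assert abs(observed - 0.6) <= 3 * math.sqrt(0.6 * 0.4 / n)


class TestMdsSimulator:
    def test_all_zero_truth_zero_error_equals_reference(self, locus):
        truth = MdsTruth({}, n_families=20, per_base_error=0.0, seed=2,
                         family_size_distribution={"kind": "fixed", "size": 3})
        reads = simulate_mds_library(locus, truth, region_name="exon2")
        region = locus.mds_region("exon2")
        expected_target = revcomp(region.sequence)
        assert len(reads) == 60
        for read in reads:
            assert read.sequence[14:] == expected_target

    def test_mutant_family_count_replayable(self, locus):
        truth = MdsTruth({(182, "T"): 1e-2}, n_families=10_000, seed=9,
                         family_size_distribution={"kind": "fixed", "size": 2},
                         per_base_error=0.0)
        region = locus.mds_region("exon2")
        reads = simulate_mds_library(locus, truth, region_name="exon2")
        _, _, mutations = _draw_family_plan(
            np.random.default_rng(9), truth, region
        )
        expected = len(mutations)
        # count distinct mutant payloads among error-free reads
        mutant_reads = sum(
            read.sequence[14:] != revcomp(region.sequence) for read in reads
        )
        assert mutant_reads == 2 * expected

    def test_seed_determinism(self, locus, tmp_path):
        truth = MdsTruth({(182, "T"): 1e-3}, n_families=500, per_base_error=1e-3,
                         seed=4)
        for run in ("a", "b"):
            simulate_mds_library(
                locus, truth, region_name="exon2", out_fastq=tmp_path / f"{run}.fq"
            )
        assert (tmp_path / "a.fq").read_bytes() == (tmp_path / "b.fq").read_bytes()

    def test_signature_bias_scales_consensus_sites(self, locus):
        truth = MdsTruth(
            {(182, "T"): 1e-4, (35, "A"): 1e-4},
            signature_bias=10.0, n_families=10,
        )
        region2 = locus.mds_region("exon2")
        truth2 = MdsTruth({(182, "T"): 1e-4}, signature_bias=10.0, n_families=10)
        eff = effective_frequencies(truth2, region2)
        # CDS 182 is an A in C-A context: the urethane bias applies
        assert eff[("182", "T")] == pytest.approx(1e-3)
        region1 = locus.mds_region("exon1")
        truth1 = MdsTruth({(35, "A"): 1e-4}, signature_bias=10.0, n_families=10)
        eff1 = effective_frequencies(truth1, region1)
        # CDS 35 is G>A, outside the C-A consensus: unscaled
        assert eff1[("35", "A")] == pytest.approx(1e-4)

    def test_unknown_family_size_distribution(self, locus):
        truth = MdsTruth({}, n_families=5,
                         family_size_distribution={"kind": "zipf"})
        with pytest.raises(SimulationConfigError):
            simulate_mds_library(locus, truth)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(SimulationConfigError):
            MdsTruth({(182, "T"): 1.5})


class TestQpcrSimulator:
    def test_two_fold_abundance_is_minus_one_delta_ct(self):
        design = [
            {"sample_id": "s", "target": "gene", "relative_abundance": 2.0},
            {"sample_id": "s", "target": "ref", "relative_abundance": 1.0},
        ]
        table = simulate_qpcr_table(design, noise_sd=0.0)
        ct = table.set_index("target")["ct"]
        assert ct["gene"] - ct["ref"] == pytest.approx(-1.0)
        assert relative_level(ct["gene"], ct["ref"]) == pytest.approx(2.0)

    def test_recombination_design_round_trip(self):
        table = simulate_qpcr_table(recombination_design({"m1": 0.5}), noise_sd=0.0)
        ct = table.set_index("target")["ct"]
        rel_del = relative_level(ct["Trp53_Del"], ct["Tflc"])
        rel_wt = relative_level(ct["Trp53_WT"], ct["Tflc"])
        assert recombination_fraction(rel_del, rel_wt) == pytest.approx(0.5)

    def test_noise_is_seed_deterministic(self):
        design = [{"sample_id": f"s{i}", "target": "g", "relative_abundance": 1.0}
                  for i in range(10)]
        a = simulate_qpcr_table(design, noise_sd=0.5, seed=3)
        b = simulate_qpcr_table(design, noise_sd=0.5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_noise_rejected(self):
        with pytest.raises(SimulationConfigError):
            simulate_qpcr_table([], noise_sd=-1.0)


class TestCohortSimulator:
    def test_fixed_sizes_give_exact_volumes(self):
        arm = ArmSpec("a", n_mice=3,
                      count_distribution={"kind": "fixed", "n": 2},
                      size_distribution={"kind": "fixed", "length": 10, "width": 5})
        df = simulate_tumor_cohort([arm], seed=1)
        assert len(df) == 6
        volumes = 0.5 * df["length_mm"] * df["width_mm"] ** 2
        assert (volumes == 125.0).all()

    def test_zero_mice_arm_is_empty_not_error(self):
        arm = ArmSpec("empty", n_mice=0)
        df = simulate_tumor_cohort([arm], seed=1)
        assert df.empty

    def test_empty_arm_list_rejected(self):
        with pytest.raises(SimulationConfigError):
            simulate_tumor_cohort([])

    def test_length_width_convention(self):
        arm = ArmSpec("a", n_mice=5,
                      count_distribution={"kind": "poisson", "mean": 4})
        df = simulate_tumor_cohort([arm], seed=7)
        assert (df["length_mm"] >= df["width_mm"]).all()

    def test_two_class_fraction_controls_large_tumors(self):
        arm = ArmSpec(
            "a", n_mice=40,
            count_distribution={"kind": "poisson", "mean": 5},
            size_distribution={
                "kind": "two_class", "frac_large": 0.3,
                "small": {"length": 4, "width": 2},    # 8 mm3
                "large": {"length": 10, "width": 5},   # 125 mm3
            },
        )
        df = simulate_tumor_cohort([arm], seed=5)
        volumes = 0.5 * df["length_mm"] * df["width_mm"] ** 2
        frac = (volumes >= 100).mean()
        n = len(df)
        assert abs(frac - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / n)
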