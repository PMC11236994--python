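import numpy as np
import pandas as pd
import pytest

import egranule as eg
from egranule.simulate import LENGTH_PMF, expected_fold_change, expected_rates


class TestSirnaLibrary:
    def test_wt_reads_are_antisense_substrings_with_5prime_g(self, one_gene_genome):
        model = eg.GenotypeModel.for_genotype("WT")
        lib = eg.simulate_sirna_library(
            one_gene_genome, model, depth=1000, seed=4, contamination=0.0, p_g=1.0
        )
        t = one_gene_genome.transcript("solo")
        rc = eg.revcomp(t)
        assert len(lib) == 1000
        for r in lib.reads:
            assert r.sequence in rc
            assert r.sequence[0] == "G"
            assert r.sequence == eg.revcomp(
                t[r.truth_template_start : r.truth_template_start + len(r.sequence)]
            )

    def test_zero_delta5_removes_5prime_reads_only(self, one_gene_genome):
        model = eg.GenotypeModel.for_genotype("egc1", delta5=0.0, delta3=1.0)
        lib = eg.simulate_sirna_library(
            one_gene_genome, model, depth=5000, seed=8, contamination=0.0
        )
        T = len(one_gene_genome.transcript("solo"))
        for r in lib.reads:
            n5_starts = round(0.8 * (T - len(r.sequence) + 1))
            assert r.truth_template_start >= n5_starts
        # the 3' rate parameter itself is untouched relative to wild type
        wt_rates = expected_rates(one_gene_genome, eg.GenotypeModel.for_genotype("WT"))
        mut_rates = expected_rates(one_gene_genome, model)
        assert mut_rates.loc["solo", "rate3"] == wt_rates.loc["solo", "rate3"]

    def test_read_length_distribution_matches_configured_peak(self, tiny_genome):
        depth = 100_000
        lib = eg.simulate_sirna_library(
            tiny_genome, eg.GenotypeModel.for_genotype("WT"), depth, seed=7
        )
        frac22 = np.mean([len(r.sequence) == 22 for r in lib.reads])
        p = LENGTH_PMF[22]
        sigma = np.sqrt(p * (1 - p) / depth)
        assert abs(frac22 - p) <= 3 * sigma

    def test_per_gene_counts_follow_rate_model(self, tiny_genome):
        depth = 100_000
        model = eg.GenotypeModel.for_genotype("WT")
        lib = eg.simulate_sirna_library(tiny_genome, model, depth, seed=9, contamination=0.0)
        rates = expected_rates(tiny_genome, model)["total"]
        p = rates / rates.sum()
        observed = pd.Series(0, index=rates.index, dtype=float)
        for r in lib.reads:
            observed[r.truth_gene_id] += 1
        z = (observed - depth * p) / np.sqrt(depth * p * (1 - p))
        assert (np.abs(z) <= 3).mean() >= 0.99
        assert (np.abs(z) <= 5).all()

    def test_same_seed_gives_identical_fastq(self, tiny_genome, tmp_path):
        for rep in ("a", "b"):
            lib = eg.simulate_sirna_library(
                tiny_genome, eg.GenotypeModel.for_genotype("egc1"), 5000, seed=13
            )
            lib.to_fastq(tmp_path / f"{rep}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_input_validation(self, tiny_genome, one_gene_genome):
        wt = eg.GenotypeModel.for_genotype("WT")
        with pytest.raises(ValueError, match="depth"):
            eg.simulate_sirna_library(tiny_genome, wt, 0, seed=1)
        soma_only = eg.AnnotatedGenome(
            one_gene_genome.chromosomes,
            [eg.GeneRecord("s", "chr1", 100, 400, "+", "soma_coding", "NA", 1.0)],
        )
        with pytest.raises(ValueError, match="germline"):
            eg.simulate_sirna_library(soma_only, wt, 100, seed=1)
        with pytest.raises(ValueError, match="rRNA"):
            eg.simulate_sirna_library(one_gene_genome, wt, 100, seed=1, contamination=0.05)


class TestGenotypeModel:
    def test_double_mutants_compose_multiplicatively(self, tiny_genome):
        wt = expected_rates(tiny_genome, eg.GenotypeModel.for_genotype("WT"))
        egc1 = expected_rates(tiny_genome, eg.GenotypeModel.for_genotype("egc1"))
        mut16 = expected_rates(tiny_genome, eg.GenotypeModel.for_genotype("mut16"))
        double = expected_rates(tiny_genome, eg.GenotypeModel.for_genotype("egc1_mut16"))
        for col in ("rate5", "rate3"):
            np.testing.assert_allclose(
                double[col], egc1[col] * mut16[col] / wt[col], rtol=1e-12
            )

    def test_ego1_scales_both_regions_equally(self):
        m = eg.GenotypeModel.for_genotype("ego1")
        assert m.delta5 == m.delta3 < 1

    def test_region_fractions_must_partition(self):
        with pytest.raises(ValueError):
            eg.GenotypeModel("WT", five_prime_fraction=0.8, three_prime_fraction=0.3)

    def test_expected_fold_change_is_compositional(self, tiny_genome):
        fc = expected_fold_change(tiny_genome, eg.GenotypeModel.for_genotype("egc1"))
        e_genes = tiny_genome.truth_genes("E")
        neutral = tiny_genome.truth_genes("NEUTRAL")
        assert (fc[e_genes] < 0.5).all()
        # library renormalization lifts unaffected genes slightly above 1
        assert (fc[neutral] > 1.0).all() and (fc[neutral] < 2.0).all()


class TestMrnaCounts:
    def test_silencing_factor_recovered_in_low_noise_limit(self, tiny_genome):
        silenced = tiny_genome.truth_genes("UP")[:2]
        wt = eg.simulate_mrna_counts(tiny_genome, "WT", 1e6, dispersion=1e-4, seed=1)
        mut = eg.simulate_mrna_counts(
            tiny_genome, "egc1", 1e6, dispersion=1e-4, seed=2,
            silenced_genes=silenced, silencing_factor=4.0,
        )
        fc = mut.mean(axis=1) / wt.mean(axis=1)
        assert np.allclose(fc[silenced], 0.25, atol=0.01)

    def test_same_seed_gives_identical_table(self, tiny_genome):
        a = eg.simulate_mrna_counts(tiny_genome, "WT", 1e5, 0.05, seed=3)
        b = eg.simulate_mrna_counts(tiny_genome, "WT", 1e5, 0.05, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_no_silencing_gives_negligible_false_positives(self, tiny_genome):
        # Monte-Carlo over 200 simulated table pairs with no true signal
        flagged = total = 0
        for i in range(200):
            wt = eg.simulate_mrna_counts(tiny_genome, "WT", 2e5, 0.05, seed=1000 + i)
            mut = eg.simulate_mrna_counts(tiny_genome, "egc1", 2e5, 0.05, seed=5000 + i)
            up, down = eg.mrna_de_genes(mut, wt)
            flagged += len(up) + len(down)
            total += len(wt)
        assert flagged / total <= 0.01

    def test_dispersion_must_be_positive(self, tiny_genome):
        with pytest.raises(ValueError):
            eg.simulate_mrna_counts(tiny_genome, "WT", 1e5, 0.0, seed=1)


class TestCtTables:
    def test_noise_free_table_inverts_exactly(self):
        levels = {"sid-1": {"control": 1.0, "mutant": 0.25}}
        tab = eg.simulate_ct_table(levels, noise_sd=0.0, seed=0)
        res = eg.ddct(tab, control_sample="control")
        assert res.summary.loc[("sid-1", "mutant"), "mean_level"] == pytest.approx(0.25)
        assert res.summary.loc[("sid-1", "control"), "mean_level"] == pytest.approx(1.0)

    def test_noisy_recovery_is_unbiased(self):
        # 200 seeded repeats; mean recovered level within 2% of truth
        truth = 0.25
        recovered = []
        for i in range(200):
            tab = eg.simulate_ct_table(
                {"g": {"control": 1.0, "mutant": truth}}, noise_sd=0.1, seed=i
            )
            res = eg.ddct(tab, control_sample="control")
            recovered.append(res.summary.loc[("g", "mutant"), "mean_level"])
        assert abs(np.mean(recovered) - truth) / truth <= 0.02

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            eg.simulate_ct_table({"g": {"a": 0.0}}, 0.1, 1)
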