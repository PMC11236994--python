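import numpy as np
import pytest

import egranule as eg
from egranule.quant import brute_force_hits
from egranule.simulate import DEFAULT_ADAPTER3, Read, ReadSet


def make_readset(seqs):
    return ReadSet([Read(f"r{i}", s) for i, s in enumerate(seqs)])


class TestCleaning:
    def test_insert_with_full_adapter_is_recovered(self):
        insert = "G" + "ACGTA" * 4 + "C"  # 22 nt
        raw = make_readset([insert + DEFAULT_ADAPTER3])
        out = eg.clean_reads(raw)
        assert [r.sequence for r in out.reads] == [insert]

    def test_read_without_adapter_dropped_when_discard_untrimmed(self):
        raw = make_readset(["GT" * 15])
        assert len(eg.clean_reads(raw)) == 0
        kept = eg.clean_reads(raw, eg.CleaningParams(discard_untrimmed=False))
        assert len(kept) == 1

    def test_short_inserts_fail_the_length_filter(self):
        raw = make_readset(["G" * 16 + DEFAULT_ADAPTER3, "G" * 17 + DEFAULT_ADAPTER3])
        out = eg.clean_reads(raw)
        assert [len(r.sequence) for r in out.reads] == [17]

    def test_partial_adapter_prefix_is_found(self):
        insert = "A" * 22
        raw = make_readset([insert + DEFAULT_ADAPTER3[:9]])
        out = eg.clean_reads(raw)
        assert [r.sequence for r in out.reads] == [insert]

    def test_metagene_window_is_18_to_26(self):
        params = eg.CleaningParams.metagene()
        raw = make_readset(
            ["C" * 17 + DEFAULT_ADAPTER3, "A" * 18 + DEFAULT_ADAPTER3, "T" * 27 + DEFAULT_ADAPTER3]
        )
        out = eg.clean_reads(raw, params)
        assert [len(r.sequence) for r in out.reads] == [18]

    def test_empty_input_is_empty_output(self):
        assert len(eg.clean_reads(make_readset([]))) == 0


class TestIs22G:
    @pytest.mark.parametrize(
        "seq,strict,expected",
        [
            ("G" + "A" * 21, True, True),
            ("G" + "A" * 21, False, True),
            ("A" + "C" * 21, True, False),
            ("A" + "C" * 21, False, False),
            ("G" + "A" * 22, False, True),   # 23 nt relaxed
            ("G" + "A" * 22, True, False),   # 23 nt strict
            ("G" + "A" * 19, False, False),  # 20 nt
        ],
    )
    def test_rules(self, seq, strict, expected):
        assert eg.is_22g(seq, strict=strict) is expected

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            eg.is_22g("")


class TestMapper:
    def test_antisense_offset_follows_5prime_most_base_convention(self, manual_genome):
        tB = manual_genome.transcript("geneB")
        read = eg.revcomp(tB[10:32])
        hits, stats = eg.map_reads(make_readset([read]), manual_genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.gene_id, h.orientation, h.weight) == ("geneB", "antisense", 1.0)
        assert (h.span_start, h.span_end) == (10, 32)
        assert h.offset == 31  # the read's 5' base pairs the span's rightmost base
        assert stats.total_genome_mappers == 1

    def test_multimapping_read_gets_fractional_weight(self, manual_genome):
        tA = manual_genome.transcript("geneA")  # geneC shares this sequence
        read = eg.revcomp(tA[5:27])
        hits, _ = eg.map_reads(make_readset([read]), manual_genome)
        assert sorted(h.gene_id for h in hits) == ["geneA", "geneC"]
        assert all(h.weight == 0.5 for h in hits)

    def test_non_acgt_characters_raise(self, manual_genome):
        with pytest.raises(ValueError, match="non-ACGT"):
            eg.map_reads(make_readset(["GNNN" + "A" * 18]), manual_genome)

    def test_mapper_equals_brute_force_oracle(self, manual_genome):
        rng = np.random.default_rng(21)
        transcripts = [manual_genome.transcript(g.gene_id) for g in manual_genome.genes]
        seqs = []
        for _ in range(200):
            kind = rng.integers(3)
            t = transcripts[rng.integers(len(transcripts))]
            L = int(rng.integers(17, 27))
            s = int(rng.integers(0, len(t) - L + 1))
            sub = t[s : s + L]
            if kind == 0:
                seqs.append(sub)
            elif kind == 1:
                seqs.append(eg.revcomp(sub))
            else:
                seqs.append("".join(rng.choice(list("ACGT"), size=L)))
        hits, _ = eg.map_reads(make_readset(seqs), manual_genome)
        by_read: dict[str, set] = {}
        for h in hits:
            by_read.setdefault(h.read_id, set()).add((h.gene_id, h.orientation, h.span_start))
        for i, seq in enumerate(seqs):
            assert by_read.get(f"r{i}", set()) == brute_force_hits(seq, manual_genome)


class TestCounting:
    @pytest.fixture()
    def counted(self, manual_genome):
        tB = manual_genome.transcript("geneB")
        rrna = manual_genome.transcript("rrna1")
        # three antisense 22G reads on geneB (start positions chosen so the
        # read's 5' base is a G), one sense geneB read, two sense rRNA reads
        starts = [s for s in range(len(tB) - 22) if tB[s + 21] == "C"][:3]
        assert len(starts) == 3
        seqs = [eg.revcomp(tB[s : s + 22]) for s in starts]
        seqs.append(tB[40:62])
        seqs += [rrna[0:22], rrna[30:52]]
        hits, stats = eg.map_reads(make_readset(seqs), manual_genome)
        return hits, stats, eg.count_genes(hits, manual_genome, stats)

    def test_denominator_subtracts_sense_rrna(self, counted):
        _, stats, _ = counted
        assert stats.total_genome_mappers == 6
        assert stats.sense_rRNA_reads == 2
        assert stats.denom_quant == 4

    def test_rpm_is_raw_per_million_denominator(self, counted):
        _, stats, gct = counted
        np.testing.assert_allclose(
            gct.table["rpm"], gct.table["raw"] * 1e6 / stats.denom_quant
        )
        assert gct.table.loc["geneB", "raw"] == 3
        assert gct.table.loc["geneB", "rpm"] == pytest.approx(3e6 / 4)

    def test_sense_hits_never_count_toward_gene_totals(self, counted):
        hits, _, gct = counted
        assert any(h.gene_id == "geneB" and h.orientation == "sense" for h in hits)
        assert gct.table.loc["geneB", "raw"] == 3  # the sense read adds nothing
        assert gct.table.loc["rrna1", "raw"] == 0

    def test_weight_conservation_is_exact(self, counted):
        hits, stats, _ = counted
        assert sum(h.weight for h in hits) == stats.total_genome_mappers

    def test_inconsistent_stats_raise(self, counted, manual_genome):
        hits, stats, _ = counted
        bad = eg.NormalizationStats(
            total_genome_mappers=stats.total_genome_mappers + 5,
            sense_rRNA_reads=stats.sense_rRNA_reads,
            nonstructural_mappers=stats.nonstructural_mappers,
        )
        with pytest.raises(ValueError, match="tally"):
            eg.count_genes(hits, manual_genome, bad)

    def test_biotype_and_soma_flags(self, tiny_genome):
        lib = eg.simulate_sirna_library(
            tiny_genome, eg.GenotypeModel.for_genotype("WT"), 5000, seed=2
        )
        hits, stats = eg.map_reads(lib, tiny_genome)
        gct = eg.count_genes(hits, tiny_genome, stats)
        t = gct.table
        assert (t["excluded_biotype"] == t["biotype"].isin(["miRNA", "piRNA_21U"])).all()
        assert (t["soma_specific"] == (t["biotype"] == "soma_coding")).all()


class TestNormalizationProperties:
    def test_rpm_invariant_under_read_duplication(self, tiny_genome):
        lib = eg.simulate_sirna_library(
            tiny_genome, eg.GenotypeModel.for_genotype("WT"), 20_000, seed=6
        )
        hits, stats = eg.map_reads(lib, tiny_genome)
        gct = eg.count_genes(hits, tiny_genome, stats)
        doubled = ReadSet(
            [Read(f"{r.read_id}_{k}", r.sequence) for k in (0, 1) for r in lib.reads]
        )
        hits2, stats2 = eg.map_reads(doubled, tiny_genome)
        gct2 = eg.count_genes(hits2, tiny_genome, stats2)
        np.testing.assert_allclose(gct2.table["rpm"], gct.table["rpm"], rtol=1e-12)
        np.testing.assert_allclose(gct2.table["raw"], 2 * gct.table["raw"], rtol=1e-12)

    def test_sense_rrna_fraction_recovers_contamination_rate(self, tiny_genome):
        depth, f = 30_000, 0.05
        lib = eg.simulate_sirna_library(
            tiny_genome, eg.GenotypeModel.for_genotype("WT"), depth, seed=12, contamination=f
        )
        _, stats = eg.map_reads(lib, tiny_genome)
        frac = stats.sense_rRNA_reads / stats.total_genome_mappers
        assert abs(frac - f) <= 3 * np.sqrt(f * (1 - f) / depth)
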