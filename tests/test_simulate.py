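"""The synthetic decay generator: determinism, decay semantics, planted truth."""

import numpy as np
import pytest

from cpgoe import seqstats, simulate
from cpgoe.orthocompare import nway_shared_genes, read_orthogroups, write_orthogroups
from cpgoe.simulate import (
    LengthDist,
    RepeatParams,
    SimulationParams,
    apply_methylation_decay,
    simulate_baseline_gene,
    simulate_panel,
    simulate_repeat_landscape,
    simulate_species,
)

SHORT = LengthDist(law="uniform", min_bp=600, max_bp=600)


class TestBaseline:
    def test_long_gene_oe_near_one(self):
        rec = simulate_baseline_gene(100_000, 0.5, seed=1)
        oe = seqstats.compute_cpg_oe(seqstats.count_dinucleotides(rec.seq))
        assert 0.98 <= oe <= 1.02

    def test_gc_composition_respected(self):
        rec = simulate_baseline_gene(50_000, 0.3, seed=2)
        gc = (rec.seq.count("C") + rec.seq.count("G")) / len(rec.seq)
        assert abs(gc - 0.3) < 0.01

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_degenerate_gc_raises(self, gc):
        with pytest.raises(ValueError):
            simulate_baseline_gene(1000, gc, seed=0)

    def test_identical_seed_identical_sequence(self):
        a = simulate_baseline_gene(5000, 0.4, seed=9)
        b = simulate_baseline_gene(5000, 0.4, seed=9)
        assert a.seq == b.seq


class TestDecay:
    def test_d_zero_identity(self):
        rec = simulate_baseline_gene(5000, 0.4, seed=3)
        out, n = apply_methylation_decay(rec.seq, 0.0, seed=4)
        assert out == rec.seq and n == 0

    def test_d_one_removes_all_cpgs(self):
        rec = simulate_baseline_gene(5000, 0.4, seed=5)
        out, n = apply_methylation_decay(rec.seq, 1.0, seed=6)
        assert "CG" not in out
        assert n == rec.seq.count("CG")

    def test_conversion_count_binomial_band(self):
        # 1e5 isolated CpGs: conversions within 3 sigma of 50,000
        seq = "CGAATT" * 100_000
        _, n = apply_methylation_decay(seq, 0.5, seed=7)
        sigma = np.sqrt(100_000 * 0.25)
        assert abs(n - 50_000) <= 3 * sigma

    def test_hamming_distance_equals_conversions(self):
        rec = simulate_baseline_gene(20_000, 0.4, seed=8)
        out, n = apply_methylation_decay(rec.seq, 0.5, seed=9)
        ham = sum(a != b for a, b in zip(rec.seq, out))
        assert ham == n

    def test_only_cpg_positions_touched(self):
        rec = simulate_baseline_gene(10_000, 0.4, seed=10)
        out, _ = apply_methylation_decay(rec.seq, 1.0, seed=11)
        for i, (a, b) in enumerate(zip(rec.seq, out)):
            if a != b:
                was_cpg = (a == "C" and rec.seq[i + 1] == "G") or (
                    a == "G" and rec.seq[i - 1] == "C"
                )
                assert was_cpg
                assert (a, b) in {("C", "T"), ("G", "A")}

    def test_decay_enriches_tpg(self):
        rec = simulate_baseline_gene(50_000, 0.4, seed=12)
        pre = seqstats.compute_tpg_oe(seqstats.count_dinucleotides(rec.seq))
        out, _ = apply_methylation_decay(rec.seq, 0.8, seed=13)
        post = seqstats.compute_tpg_oe(seqstats.count_dinucleotides(out))
        assert post > pre


class TestSpecies:
    def test_determinism(self):
        params = SimulationParams(n_genes=50, length=SHORT, seed=21)
        recs_a, truth_a = simulate_species(params)
        recs_b, truth_b = simulate_species(params)
        assert [(r.id, r.seq) for r in recs_a] == [(r.id, r.seq) for r in recs_b]
        assert truth_a.equals(truth_b)

    def test_truth_consistent_with_sequences(self):
        params = SimulationParams(n_genes=40, length=SHORT, seed=22)
        recs, truth = simulate_species(params)
        for rec, row in zip(recs, truth.itertuples()):
            assert rec.id == row.gene_id
            oe = seqstats.compute_cpg_oe(seqstats.count_dinucleotides(rec.seq))
            assert oe == pytest.approx(row.post_decay_cpg_oe)

    def test_mixture_weight_matches_labels(self):
        params = SimulationParams(n_genes=2000, length=SHORT, pi_methylated=0.3,
                                  seed=23)
        _, truth = simulate_species(params)
        assert abs(truth.methylated.mean() - 0.3) < 0.04

    def test_no_methylation_gives_unimodal_high(self):
        params = SimulationParams(
            n_genes=300,
            length=LengthDist(law="uniform", min_bp=1500, max_bp=1500),
            pi_methylated=0.0,
            seed=24,
        )
        _, truth = simulate_species(params)
        assert abs(truth.post_decay_cpg_oe.mean() - 1.0) < 0.03

    def test_lengths_respect_bounds(self):
        params = SimulationParams(n_genes=500, seed=25)
        _, truth = simulate_species(params)
        assert truth.length.between(300, 20_000).all()


class TestRepeatLandscape:
    def test_target_fraction_hit(self):
        genome, rep_iv, gene_iv, truth = simulate_repeat_landscape(
            RepeatParams(genome_length=100_000, repeat_fraction=0.3, family_count=5),
            seed=31,
        )
        covered = sum(e - s for _, s, e, _ in rep_iv)
        assert abs(covered / 100_000 - 0.3) <= 0.02

    def test_zero_families_empty_bed(self):
        genome, rep_iv, gene_iv, _ = simulate_repeat_landscape(
            RepeatParams(genome_length=50_000, repeat_fraction=0.0, family_count=0),
            seed=32,
        )
        assert rep_iv == []
        assert len(genome["chr1"]) == 50_000

    def test_intervals_match_genome_content(self):
        genome, rep_iv, gene_iv, truth = simulate_repeat_landscape(
            RepeatParams(genome_length=60_000, repeat_fraction=0.2, family_count=3),
            seed=33,
        )
        chrom = genome["chr1"]
        assert len(chrom) == 60_000
        for contig, s, e, fam in rep_iv + gene_iv:
            assert 0 <= s < e <= len(chrom)

    def test_filter_contract_on_copy_numbers(self):
        from cpgoe.repeats import RepeatAnnotation, filter_repeats

        twelve = [("c", 200 * i, 200 * i + 80, "famA") for i in range(12)]
        eight = [("c", 5000 + 200 * i, 5000 + 200 * i + 80, "famB") for i in range(8)]
        kept = filter_repeats(RepeatAnnotation(twelve + eight)).intervals
        assert {iv[3] for iv in kept} == {"famA"}

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_repeat_landscape(
                RepeatParams(genome_length=10_000, repeat_fraction=0.9,
                             family_count=2, n_genes=20, gene_length=1000),
                seed=34,
            )


class TestPanel:
    def make_panel(self, bias, seed, n_species=3, n_genes=200):
        params = [
            (f"sp{i}", SimulationParams(n_genes=n_genes, length=SHORT))
            for i in range(n_species)
        ]
        return simulate_panel(params, shared_fraction=0.3, complete_fraction=0.6,
                              bias=bias, seed=seed)

    def test_orthogroups_roundtrip(self, tmp_path):
        panel = self.make_panel(bias=1.0, seed=41)
        path = tmp_path / "og.tsv"
        write_orthogroups(panel.partition, path)
        assert read_orthogroups(path) == panel.partition

    def test_complete_groups_recovered_exactly(self):
        panel = self.make_panel(bias=0.5, seed=42)
        species = list(panel.records)
        shared = nway_shared_genes(panel.partition, species)
        expected = {sp: set() for sp in species}
        for og in panel.complete_orthogroups:
            for sp in species:
                expected[sp].update(panel.partition[og][sp])
        assert shared == expected

    def test_full_bias_tags_only_methylated(self):
        panel = self.make_panel(bias=1.0, seed=43)
        for sp, truth in panel.truths.items():
            meth = set(truth.loc[truth.methylated, "gene_id"])
            tagged = {g for og in panel.partition.values() for g in og[sp]}
            assert tagged <= meth

    def test_gene_ids_unique_across_orthogroups(self):
        panel = self.make_panel(bias=0.0, seed=44)
        for sp in panel.records:
            tagged = [g for og in panel.partition.values() for g in og[sp]]
            assert len(tagged) == len(set(tagged))

    def test_panel_determinism(self):
        a = self.make_panel(bias=0.7, seed=45)
        b = self.make_panel(bias=0.7, seed=45)
        assert a.partition == b.partition
        for sp in a.records:
            assert [r.seq for r in a.records[sp]] == [r.seq for r in b.records[sp]]
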