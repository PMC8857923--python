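"""Repeat filtering, repeat CpG_o/e, and the panel contrast/correlation stats."""

import itertools

import numpy as np
import pytest

from cpgoe import repeats, simulate
from cpgoe.comparative import load_species_table
from cpgoe.repeats import (
    RepeatAnnotation,
    correlate_table,
    filter_repeats,
    pearson_correlation,
    repeat_cpg_oe,
    repeat_vs_gene_contrast,
    union_coverage,
)
from conftest import pearson_oracle


def annot(intervals, genome=None):
    return RepeatAnnotation(intervals=list(intervals), genome=genome)


class TestFilters:
    # fam_big has 12 copies (passes >10), fam_small has 8 (fails)
    BIG = [("chr1", 100 * i, 100 * i + 80, "fam_big") for i in range(12)]
    SMALL = [("chr1", 2000 + 100 * i, 2000 + 100 * i + 80, "fam_small") for i in range(8)]

    def test_length_boundary_strict(self):
        ivs = self.BIG[:-1] + [("chr1", 5000, 5050, "fam_big")]  # exactly 50 bp
        kept = filter_repeats(annot(ivs), min_len=50, min_copies=10).intervals
        assert ("chr1", 5000, 5050, "fam_big") not in kept
        assert len(kept) == 11

    def test_copy_number_boundary_strict(self):
        ten = [("chr1", 100 * i, 100 * i + 80, "fam_ten") for i in range(10)]
        with pytest.raises(ValueError, match="no repeat elements"):
            filter_repeats(annot(ten), min_copies=10)
        eleven = ten + [("chr1", 5000, 5080, "fam_ten")]
        assert len(filter_repeats(annot(eleven), min_copies=10).intervals) == 11

    def test_one_base_gene_overlap_excludes(self):
        genes = [("chr1", 179, 180, "geneA")]  # shares only base 179 with the 2nd element
        kept = filter_repeats(annot(self.BIG), gene_intervals=genes).intervals
        assert ("chr1", 100, 180, "fam_big") not in kept
        assert len(kept) == 11

    def test_low_copy_family_removed(self):
        kept = filter_repeats(annot(self.BIG + self.SMALL)).intervals
        assert {iv[3] for iv in kept} == {"fam_big"}

    def test_filters_commute(self):
        ivs = self.BIG + self.SMALL + [("chr1", 5000, 5049, "fam_big")]
        genes = [("chr1", 0, 150, "geneA")]

        def run(order):
            a = annot(ivs)
            for step in order:
                if step == "len":
                    a = filter_repeats(a, min_len=50, min_copies=0)
                elif step == "copy":
                    a = RepeatAnnotation(
                        [iv for iv in a.intervals
                         if sum(j[3] == iv[3] for j in ivs) > 10],
                        a.genome,
                    )
                else:
                    a = filter_repeats(a, min_len=0, min_copies=0, gene_intervals=genes)
            return sorted(a.intervals)

        results = {tuple(run(order)) for order in itertools.permutations(["len", "copy", "gene"])}
        assert len(results) == 1
        assert list(results)[0] == tuple(
            sorted(filter_repeats(annot(ivs), gene_intervals=genes).intervals)
        )


class TestRepeatStats:
    def test_full_cover_content_one(self):
        genome = {"chr1": "ACGTACGTAC" * 30}
        stats = repeat_cpg_oe(annot([("chr1", 0, 300, "f")], genome))
        assert stats.repeat_content == pytest.approx(1.0)
        assert stats.n_elements == 1

    def test_overlapping_intervals_union_not_sum(self):
        assert union_coverage([("c", 0, 100, "f"), ("c", 50, 150, "f")]) == 150
        assert union_coverage([("c", 0, 100, "f"), ("c", 200, 250, "g")]) == 150

    def test_content_invariant_to_interval_splitting(self):
        whole = [("c", 10, 110, "f")]
        split = [("c", 10, 60, "f"), ("c", 60, 110, "f")]
        assert union_coverage(whole) == union_coverage(split)

    def test_planted_repeat_fraction_recovered(self):
        params = simulate.RepeatParams(genome_length=150_000, repeat_fraction=0.30,
                                       family_count=5)
        genome, rep_iv, gene_iv, truth = simulate.simulate_repeat_landscape(
            params, seed=7)
        stats = repeat_cpg_oe(annot(rep_iv, genome))
        assert abs(stats.repeat_content - 0.30) <= 0.02
        assert stats.n_families == 5

    def test_undefined_elements_counted(self):
        genome = {"chr1": "AAAATTTTAAAATTTT" + "ACGGACGG" * 20}
        stats = repeat_cpg_oe(
            annot([("chr1", 0, 16, "f"), ("chr1", 16, 176, "f")], genome))
        assert stats.n_undefined == 1


class TestContrast:
    def test_fixture_exception_is_myxobolus_squamalis(self):
        contrast = repeat_vs_gene_contrast(load_species_table())
        assert contrast.exceptions == ("Myxobolus squamalis",)
        assert contrast.n_compared == 14
        assert contrast.n_repeat_higher == 13

    def test_tie_flagged_not_exception(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "species": ["a", "b"],
                "mean_gene_body_cpg_oe": [0.7, 0.7],
                "mean_repeat_cpg_oe": [0.7, 0.9],
            }
        )
        contrast = repeat_vs_gene_contrast(table)
        assert contrast.ties == ("a",)
        assert contrast.exceptions == ()

    def test_planted_exceptions_recovered(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        gene = rng.uniform(0.6, 0.8, 10)
        rep = gene + 0.15
        rep[[2, 7]] = gene[[2, 7]] - 0.1  # planted exceptions
        table = pd.DataFrame(
            {"species": [f"s{i}" for i in range(10)],
             "mean_gene_body_cpg_oe": gene,
             "mean_repeat_cpg_oe": rep}
        )
        contrast = repeat_vs_gene_contrast(table)
        assert set(contrast.exceptions) == {"s2", "s7"}


class TestPearson:
    def test_perfect_correlation_raises(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="perfect"):
            pearson_correlation(x, x)

    def test_near_perfect_negative(self, rng):
        x = np.linspace(0, 1, 10)
        y = -x + rng.normal(0, 1e-6, 10)
        r, t, df, p = pearson_correlation(x, y)
        assert r < -0.999
        assert t < 0
        assert df == 8

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            x = rng.normal(0, 1, n)
            y = 0.4 * x + rng.normal(0, 1, n)
            r, t, df, p = pearson_correlation(x, y)
            ro, to, po = pearson_oracle(x, y)
            assert r == pytest.approx(ro, abs=1e-9)
            assert t == pytest.approx(to, abs=1e-9)
            assert p == pytest.approx(po, abs=1e-9)

    def test_exclusion_applied_by_name(self):
        table = load_species_table()
        rec = correlate_table(
            table,
            "mean_repeat_cpg_oe",
            "mean_gene_body_cpg_oe",
            exclude=["Hydra vulgaris", "Myxobolus squamalis"],
        )
        assert rec["n"] == 12
        assert set(rec["excluded"]) == {"Hydra vulgaris", "Myxobolus squamalis"}
        assert rec["r"] > 0  # repeat and gene-body depletion co-vary

    def test_common_decay_factor_induces_positive_correlation(self):
        """Species sharing a decay factor across genes and repeats correlate."""
        rng = np.random.default_rng(11)
        rows = []
        for i in range(15):
            d = rng.uniform(0.0, 0.6)
            params = simulate.SimulationParams(
                n_genes=60,
                length=simulate.LengthDist(law="uniform", min_bp=800, max_bp=800),
                pi_methylated=1.0,
                decay_methylated=d,
                seed=100 + i,
            )
            _, truth = simulate.simulate_species(params)
            rep_params = simulate.RepeatParams(
                genome_length=40_000, repeat_fraction=0.25, family_count=3,
                decay=d)
            genome, rep_iv, _, _ = simulate.simulate_repeat_landscape(
                rep_params, seed=200 + i)
            rstats = repeat_cpg_oe(annot(rep_iv, genome))
            rows.append((truth.post_decay_cpg_oe.mean(), rstats.mean_repeat_cpg_oe))
        gene_means, rep_means = zip(*rows)
        r, t, df, p = pearson_correlation(gene_means, rep_means)
        assert r > 0
        assert p < 0.05
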