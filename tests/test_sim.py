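"""Forward-simulator components: DFE and dominance map, gamete formation,
the yearly life cycle, ROH tracking, and scenario running."""

import numpy as np
import pandas as pd
import pytest

from gibbonpop.sim import (
    AGE_MORTALITY,
    GIBBON_SCENARIO,
    ISLAND_CONTROL_SCENARIO,
    DemographicScenario,
    DfeParams,
    Epoch,
    GenomeLayout,
    MutationEffect,
    Population,
    Split,
    deleterious_class,
    dominance_coefficient,
    draw_mutation_effect,
    fitness_from_mutations,
    make_gamete,
    run_scenario,
)


class TestGenomeLayout:
    def test_intergene_crossover_probability(self):
        assert GenomeLayout().intergene_crossover_prob == pytest.approx(1e-3)

    def test_coding_length(self):
        assert GenomeLayout().coding_length == 19_197 * 1458

    def test_scaling_preserves_genes_per_chromosome_and_diversity_products(self):
        base = GenomeLayout()
        scaled = base.scaled(0.05)
        assert scaled.n_genes / scaled.n_chromosomes == pytest.approx(
            round(base.n_genes / base.n_chromosomes)
        )
        # theta proxy K*u and the per-interval map scale together
        assert scaled.mutation_rate * 0.05 == pytest.approx(base.mutation_rate)
        assert scaled.intergene_crossover_prob * 0.05 == pytest.approx(
            base.intergene_crossover_prob
        )

    def test_scenario_scaling_keeps_tiny_k_unscaled(self):
        scn = GIBBON_SCENARIO.scaled(0.05)
        assert scn.split.k_a == 6 and scn.split.k_b == 5
        assert scn.epochs[0].k == 500
        assert scn.epochs[0].duration_years == 2500


class TestMutationEffects:
    @pytest.mark.parametrize(
        "s,h",
        [(-0.2, 0.0), (-0.05, 0.01), (-0.005, 0.1), (-0.0005, 0.4), (0.0, 0.4)],
    )
    def test_dominance_map(self, s, h):
        assert dominance_coefficient(s) == h

    def test_boundary_values_join_more_recessive_neighbour(self):
        assert dominance_coefficient(-0.1) == 0.0
        assert dominance_coefficient(-0.01) == 0.01
        assert dominance_coefficient(-0.1, boundary="dominant") == 0.01
        assert dominance_coefficient(-0.01, boundary="dominant") == 0.1

    @pytest.mark.parametrize(
        "s,label",
        [
            (0.0, "neutral"),
            (-0.0005, "weak"),
            (-0.005, "moderate"),
            (-0.05, "strong"),
            (-0.1, "very_strong"),
            (-0.5, "very_strong"),
        ],
    )
    def test_class_boundaries(self, s, label):
        assert deleterious_class(s) == label

    def test_draw_distribution_matches_configured_dfe(self, rng):
        dfe = DfeParams()
        s, h, code = [], [], []
        from gibbonpop.sim import _vector_effects

        s, h, code = _vector_effects(100_000, dfe, rng)
        neutral_frac = (s == 0).mean()
        se = 2.576 * np.sqrt(0.3 * 0.7 / s.size)
        assert abs(neutral_frac - dfe.neutral_fraction) < se
        deleterious = s[s < 0]
        # gamma mean check (truncation at s_min barely matters)
        sem = deleterious.std() / np.sqrt(deleterious.size)
        assert abs(-deleterious.mean() - dfe.gamma_mean) < 4 * sem + 1e-4

    def test_single_draw_consistent_with_maps(self, rng):
        for _ in range(50):
            eff = draw_mutation_effect(rng)
            assert eff.h == dominance_coefficient(eff.s)
            assert eff.label == deleterious_class(eff.s)
            assert eff.s <= 0

    def test_unconfigured_gamma_rejected_at_startup(self):
        with pytest.raises(ValueError, match="gamma"):
            DfeParams(gamma_shape=0.0)

    def test_fitness_examples(self):
        assert fitness_from_mutations([], []) == 1.0
        hom = [MutationEffect(s=-0.1, h=0.0, label="very_strong")]
        assert fitness_from_mutations(hom, []) == pytest.approx(0.9)
        het = [MutationEffect(s=-0.1, h=0.01, label="very_strong")]
        assert fitness_from_mutations([], het) == pytest.approx(0.999)
        lethal = [MutationEffect(s=-1.5, h=0.0, label="very_strong")]
        assert fitness_from_mutations(lethal, []) == 0.0


class TestMakeGamete:
    layout = GenomeLayout(n_chromosomes=2, n_genes=40, gene_length=1000,
                          intergenic_length=100_000, mutation_rate=0.0)

    def test_zero_crossover_transmits_whole_parental_chromosomes(self, rng):
        layout = GenomeLayout(n_chromosomes=2, n_genes=40, recomb_rate_per_site=0.0)
        parent_anc = np.stack([np.zeros(40, dtype=np.uint32), np.ones(40, dtype=np.uint32)])
        chrom = layout.chromosome_of_gene()
        for _ in range(20):
            anc, _ = make_gamete(parent_anc, np.empty((2, 0), bool), np.empty(0, int), layout, rng)
            for c in range(2):
                assert len(set(anc[chrom == c])) == 1

    def test_crossover_frequency_matches_layout_probability(self, rng):
        layout = GenomeLayout(n_chromosomes=1, n_genes=200)
        parent_anc = np.stack([np.zeros(200, np.uint32), np.ones(200, np.uint32)])
        switches = total = 0
        for _ in range(300):
            anc, _ = make_gamete(parent_anc, np.empty((2, 0), bool), np.empty(0, int), layout, rng)
            switches += (anc[1:] != anc[:-1]).sum()
            total += 199
        p = layout.intergene_crossover_prob
        se = np.sqrt(p * (1 - p) / total)
        assert abs(switches / total - p) < 4 * se + 1e-6

    def test_alleles_within_one_gene_never_separated(self, rng):
        layout = GenomeLayout(n_chromosomes=1, n_genes=50, mutation_rate=0.0)
        parent_anc = np.stack([np.zeros(50, np.uint32), np.ones(50, np.uint32)])
        parent_mut = np.array([[True, True, False], [False, False, True]])
        mut_gene = np.array([7, 7, 7])  # three mutations in the same gene
        for _ in range(100):
            _, mut = make_gamete(parent_anc, parent_mut, mut_gene, layout, rng)
            assert mut.tolist() in ([True, True, False], [False, False, True])


def small_population(n=60, seed=0, **kwargs):
    layout = GenomeLayout(n_chromosomes=5, n_genes=100)
    return Population.founders(n, layout, DfeParams(), seed=seed, **kwargs)


class TestLifeCycle:
    def test_age_mortality_table_values(self):
        assert AGE_MORTALITY[0] == 0.10
        assert AGE_MORTALITY[2] == 0.05
        assert AGE_MORTALITY[5] == 0.03
        assert AGE_MORTALITY[7] == 0.10
        assert AGE_MORTALITY[20] == 0.05
        assert AGE_MORTALITY[33] == 0.25
        assert AGE_MORTALITY[38] == 0.50
        assert AGE_MORTALITY[41] == 1.0

    def test_nobody_survives_past_max_age(self):
        pop = small_population(30, seed=1)
        pop.age[:] = 41
        pop.sex[:] = 1  # no females, so no newborns either
        pop.step(0, {0: 100})
        assert pop.size == 0

    def test_zero_fitness_means_certain_death(self):
        pop = small_population(30, seed=2)
        pop.sex[:] = 1  # no newborns; every existing individual has fitness 0
        pop.log_fitness[:] = -np.inf
        pop.step(0, {0: 100})
        assert pop.size == 0

    def test_no_breeding_males_no_newborns(self):
        pop = small_population(30, seed=3)
        pop.sex[:] = 0  # all female
        before = pop.size
        pop._reproduce(0, None)
        assert pop.size == before

    def test_male_alternates_between_two_mates(self):
        pop = small_population(3, seed=4)
        pop.sex[:] = [1, 0, 0]
        pop.age[:] = [10, 10, 10]
        mothers = []
        for year in range(4):
            pop._pair_vacant_males(year, None)
            fathers, mums = pop._breed(year)
            mothers.append(set(mums.tolist()))
        # one offspring per year, alternating between the two females
        assert all(len(m) == 1 for m in mothers)
        seq = [next(iter(m)) for m in mothers]
        assert seq[0] != seq[1] and seq[:2] == seq[2:]

    def test_female_breeding_interval_two_years(self):
        pop = small_population(2, seed=5)
        pop.sex[:] = [1, 0]
        pop.age[:] = [10, 10]
        bred_years = []
        for year in range(6):
            pop._pair_vacant_males(year, None)
            _, mums = pop._breed(year)
            if mums.size:
                bred_years.append(year)
        assert bred_years == [0, 2, 4]

    def test_offspring_haplotypes_reachable_from_parents(self):
        pop = small_population(40, seed=6, label_refresh=0.0)
        before = pop.size
        anc_parents = pop.anc.copy()
        pop._reproduce(0, None)
        newborn_rows = range(before, pop.size)
        for r in newborn_rows:
            father_row = np.nonzero(pop.ids == pop.father[r])[0][0]
            mother_row = np.nonzero(pop.ids == pop.mother[r])[0][0]
            for hap, parent in ((0, father_row), (1, mother_row)):
                choices = anc_parents[parent]
                ok = (pop.anc[r, hap] == choices[0]) | (pop.anc[r, hap] == choices[1])
                assert ok.all()

    def test_population_respects_carrying_capacity(self):
        pop = small_population(50, seed=7)
        sizes = []
        for year in range(120):
            pop.step(year, {0: 50})
            sizes.append(pop.size)
        assert max(sizes) < 2.5 * 50
        assert np.mean(sizes[40:]) > 20  # viable, not collapsing


class TestStatsTracking:
    def test_froh_thresholds_are_nested(self):
        pop = small_population(30, seed=8)
        for year in range(80):
            pop.step(year, {0: 30})
        fr = pop.froh((500_000, 1_000_000), max_individuals=None)
        assert fr[1_000_000] <= fr[500_000] <= 1.0
        assert fr[500_000] > 0  # small population: some recent autozygosity

    def test_neutral_only_configuration_has_zero_load(self):
        layout = GenomeLayout(n_chromosomes=5, n_genes=100, mutation_rate=1e-6)
        pop = Population.founders(40, layout, DfeParams(neutral_fraction=1.0), seed=9)
        for year in range(40):
            pop.step(year, {0: 40})
        load = pop.load_by_class()
        assert (load["realized"] == 0).all() and (load["masked"] == 0).all()
        assert pop.n_segregating > 0  # neutral variation does accumulate

    def test_wright_fisher_drift_variance_proportional_to_p_one_minus_p(self):
        """Neutral drift check: across injected allele frequencies the
        per-generation increment variance follows p(1-p)/(2Ne) with one
        shared Ne of plausible magnitude."""
        layout = GenomeLayout(n_chromosomes=10, n_genes=200, mutation_rate=0.0)
        n = 80
        implied_ne = {}
        for p0 in (0.1, 0.3, 0.5):
            deltas = []
            for rep in range(12):
                pop = Population.founders(n, layout, DfeParams(neutral_fraction=1.0),
                                          seed=1000 + rep)
                # burn a few years so the age/pair structure settles
                for year in range(5):
                    pop.step(year, {0: n})
                rng = np.random.default_rng(rep)
                cols = []
                for m in range(40):
                    k = round(2 * pop.size * p0)
                    flat = rng.choice(2 * pop.size, size=k, replace=False)
                    carriers = np.stack([flat // 2, flat % 2], axis=1)
                    cols.append(pop.inject_mutation(0.0, 0.4, gene=m * 5, carrier_haplotypes=carriers))
                f0 = pop.allele_frequencies()[cols]
                for year in range(5, 15):  # one generation's worth of years
                    pop.step(year, {0: n})
                f1 = pop.allele_frequencies()[cols]
                deltas.extend((f1 - f0).tolist())
            deltas = np.asarray(deltas)
            implied_ne[p0] = p0 * (1 - p0) / max(deltas.var(), 1e-9) / 2
        values = np.array(list(implied_ne.values()))
        assert values.max() / values.min() < 2.5  # proportionality to p(1-p)
        assert n / 10 < values.mean() < 3 * n


class TestScenarios:
    def test_load_rises_in_bottleneck_and_falls_in_expansion(self):
        """Replicate-averaged realized load moves with the demography:
        up through the bottleneck, down through the expansion."""
        burn, lgm, peak = [], [], []
        for child in np.random.SeedSequence(77).spawn(3):
            res = run_scenario(GIBBON_SCENARIO, seed=np.random.default_rng(child),
                               scale=0.05, stop_before_split=True)
            if res.extinct:
                continue
            tr = res.trajectory
            burn.append(tr[tr.phase == "epoch_0"]["realized_all_deleterious"].iloc[-1])
            lgm.append(tr[tr.phase == "epoch_1"]["realized_all_deleterious"].iloc[-1])
            peak.append(tr[tr.phase == "epoch_2"]["realized_all_deleterious"].iloc[-1])
        assert len(burn) >= 2
        assert np.mean(lgm) > np.mean(burn)
        assert np.mean(peak) < np.mean(lgm)

    def test_scenario_definitions_match_reported_history(self):
        ks = [e.k for e in GIBBON_SCENARIO.epochs]
        assert ks == [10_000, 500, 500, 3_000]
        assert GIBBON_SCENARIO.epochs[2].k_end == 20_000
        assert GIBBON_SCENARIO.split == Split(450, 6, 5)
        # island control: same minus the expansion epoch
        assert len(ISLAND_CONTROL_SCENARIO.epochs) == 3
        assert [e.k for e in ISLAND_CONTROL_SCENARIO.epochs] == [10_000, 500, 3_000]

    def test_run_scenario_deterministic_under_seed(self):
        scn = DemographicScenario(epochs=(Epoch(60, 40),), label="tiny")
        layout = GenomeLayout(n_chromosomes=5, n_genes=100)
        a = run_scenario(scn, layout=layout, seed=5)
        b = run_scenario(scn, layout=layout, seed=5)
        pd.testing.assert_frame_equal(a.trajectory, b.trajectory)

    def test_extinction_truncates_with_flag(self):
        scn = DemographicScenario(epochs=(Epoch(400, 3),), label="doomed")
        layout = GenomeLayout(n_chromosomes=2, n_genes=40)
        res = run_scenario(scn, layout=layout, seed=1)
        assert res.extinct
        assert res.trajectory["n"].iloc[-1] == 0
        assert res.trajectory["year"].iloc[-1] < 399

    def test_split_partitions_population_into_lineages(self):
        scn = DemographicScenario(
            epochs=(Epoch(40, 60),), split=Split(10, 20, 20), label="split"
        )
        layout = GenomeLayout(n_chromosomes=5, n_genes=100)
        res = run_scenario(scn, layout=layout, seed=2)
        pop = res.population
        if not res.extinct:
            classes = set(pop._lineage_class().tolist())
            assert classes <= {0, 1}
            assert set(pop.subpop.tolist()) == {1, 2}
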