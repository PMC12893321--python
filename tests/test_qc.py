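"""ADO counting rules, duplicate-library discordance, the depth profile,
and the coverage-saturation fit."""

import itertools

import numpy as np
import pytest

from gibbonpop.core import MISSING, GenotypeMatrix, TrioSet
from gibbonpop.qc import (
    NoInformativeSitesError,
    SolowFitError,
    ado_depth_profile,
    count_mendelian_ado,
    fit_solow,
    genotype_discordance,
)
from gibbonpop.synth import SynthConfig, gen_duplicate_libraries, gen_trios


def make_trios(genotypes, depth=None):
    """TrioSet from a list of (father, mother, offspring) per-site columns."""
    g = np.asarray(genotypes, dtype=np.int8)  # (n_sites, 3)
    g = g.T[None, :, :]  # one trio
    n_sites = g.shape[2]
    return TrioSet(
        genotypes=g,
        chrom=np.array(["1"] * n_sites),
        pos=np.arange(n_sites),
        ref=np.array(["A"] * n_sites),
        alt=np.array(["G"] * n_sites),
        depth=None if depth is None else np.asarray(depth).T[None, :, :],
    )


def brute_force_ado(genotypes):
    """Independent re-statement of the two detection rules, site by site.

    Rule 1: hom x het parents with the offspring homozygous for the allele
    the hom parent cannot transmit. Rule 2: opposite-homozygote parents
    with a homozygous offspring.
    """
    n_events = n_informative = 0
    for f, m, o in genotypes:
        if MISSING in (f, m, o):
            continue
        pair = {f, m}
        if pair == {0, 1} or pair == {1, 2}:
            n_informative += 1
            hom = f if f != 1 else m
            if o == 2 - hom:
                n_events += 1
        elif pair == {0, 2}:
            n_informative += 1
            if o != 1:
                n_events += 1
    return n_events, n_informative


class TestMendelianAdo:
    def test_hom_het_parents_opposite_hom_offspring_is_one_event(self):
        est = count_mendelian_ado(make_trios([(0, 1, 2)]))
        assert est.n_events == 1 and est.n_informative == 1

    def test_opposite_hom_parents_het_offspring_is_consistent(self):
        est = count_mendelian_ado(make_trios([(0, 2, 1)]))
        assert est.n_events == 0 and est.n_informative == 1

    def test_opposite_hom_parents_hom_offspring_is_event(self):
        for o in (0, 2):
            est = count_mendelian_ado(make_trios([(0, 2, o)]))
            assert est.n_events == 1

    def test_uninformative_configurations_raise_distinctly_from_zero(self):
        # het x het and missing members can never expose a dropout
        trios = make_trios([(1, 1, 0), (0, MISSING, 2), (0, 0, 0)])
        with pytest.raises(NoInformativeSitesError):
            count_mendelian_ado(trios)

    def test_matches_exhaustive_rule_enumeration(self):
        """Every genotype combination, checked against an independent loop."""
        combos = list(itertools.product([0, 1, 2, MISSING], repeat=3))
        est = count_mendelian_ado(make_trios(combos))
        events, informative = brute_force_ado(combos)
        assert (est.n_events, est.n_informative) == (events, informative)

    @pytest.mark.parametrize("n_sites", [10**3, 10**4, 10**5])
    def test_consistency_against_enumeration_oracle(self, n_sites):
        """Deviation from the analytic detection rate stays within the
        shrinking binomial envelope as the site count grows."""
        from conftest import expected_ado_detection

        cfg = SynthConfig(n_sites=n_sites, n_individuals=3, ado_rate=0.05, seed=n_sites)
        est = count_mendelian_ado(gen_trios(cfg)[0])
        expected = expected_ado_detection(0.05)
        half = 3.3 * np.sqrt(expected * (1 - expected) / est.n_informative)
        assert abs(est.rate - expected) < half + 1e-3

    def test_recovers_truth_record_count_on_synthetic_trios(self, trio_cfg):
        trios, _ = gen_trios(trio_cfg)
        est = count_mendelian_ado(trios)
        flat = trios.genotypes.transpose(0, 2, 1).reshape(-1, 3)
        events, informative = brute_force_ado(flat)
        assert (est.n_events, est.n_informative) == (events, informative)
        assert est.rate > 0


class TestDiscordance:
    @staticmethod
    def _gm(genotypes):
        g = np.atleast_2d(np.asarray(genotypes, dtype=np.int8))
        n = g.shape[1]
        return GenotypeMatrix(
            genotypes=g,
            samples=[f"s{i}" for i in range(g.shape[0])],
            chrom=np.array(["1"] * n),
            pos=np.arange(n),
            ref=np.array(["A"] * n),
            alt=np.array(["G"] * n),
        )

    def test_identical_matrices_zero(self):
        gm = self._gm([0, 1, 2, 1])
        assert genotype_discordance(gm, gm) == 0.0

    def test_one_of_three_differs(self):
        assert genotype_discordance(self._gm([0, 1, 2]), self._gm([0, 2, 2])) == pytest.approx(1 / 3)

    def test_symmetric(self):
        a, b = self._gm([0, 1, 2, 0]), self._gm([2, 1, 0, 0])
        assert genotype_discordance(a, b) == genotype_discordance(b, a)

    def test_missing_sites_excluded_and_all_missing_is_error(self):
        a, b = self._gm([0, MISSING, 1]), self._gm([1, 0, MISSING])
        assert genotype_discordance(a, b) == 1.0  # only site 0 jointly called
        with pytest.raises(ValueError, match="jointly"):
            genotype_discordance(self._gm([MISSING]), self._gm([0]))

    def test_equals_truth_site_fraction_exactly_on_synthetic_duplicates(self):
        cfg = SynthConfig(n_sites=5000, n_individuals=3, genotype_error_rate=0.02, seed=11)
        a, b, truth = gen_duplicate_libraries(cfg)
        expected = truth["discordant"].sum() / a.genotypes.size
        assert genotype_discordance(a, b) == pytest.approx(expected)


class TestAdoDepthProfile:
    def test_flat_profile_plateaus_at_first_bin(self):
        sites = [(0, 1, 2)] * 10 + [(0, 2, 1)] * 90
        depth = [(d, d, d) for d in np.tile([2, 7, 12, 20], 25)]
        trios = make_trios(sites, depth)
        estimates, plateau = ado_depth_profile(trios, [0, 5, 10, 15, 100], tolerance=0.2)
        assert plateau == 0

    def test_step_profile_detects_step_location(self):
        # high ADO below depth 10, zero above
        sites, depth = [], []
        for d in (2, 7):
            sites += [(0, 1, 2)] * 30 + [(0, 2, 1)] * 70
            depth += [(d, d, d)] * 100
        for d in (12, 20):
            sites += [(0, 2, 1)] * 100
            depth += [(d, d, d)] * 100
        trios = make_trios(sites, depth)
        estimates, plateau = ado_depth_profile(trios, [0, 5, 10, 15, 100], tolerance=0.01)
        rates = [e.rate for e in estimates]
        assert rates[0] == rates[1] == pytest.approx(0.3)
        assert rates[2] == rates[3] == 0.0
        assert plateau == 10

    def test_monotone_decreasing_profile_with_depth_dependent_dropout(self, rng):
        # generator-style construction: dropout probability halves per bin
        sites, depth = [], []
        for d, p in [(2, 0.4), (7, 0.2), (12, 0.1), (25, 0.05)]:
            for _ in range(400):
                o = 2 if rng.random() < p else 1
                sites.append((0, 2, o))
                depth.append((d, d, d))
        estimates, _ = ado_depth_profile(make_trios(sites, depth), [0, 5, 10, 15, 100])
        rates = [e.rate for e in estimates]
        assert all(a > b for a, b in zip(rates[:-1], rates[1:]))

    def test_empty_bin_reported_but_excluded(self):
        trios = make_trios([(0, 2, 1)] * 10, [(3, 3, 3)] * 10)
        estimates, plateau = ado_depth_profile(trios, [0, 5, 10], tolerance=0.01)
        assert estimates[1].n_informative == 0
        assert plateau == 0


class TestSolowFit:
    def test_recovers_parameters_on_noiseless_curve(self):
        # x grid starts where the curve enters [0, 1] (valid coverages)
        a, b, c = 0.9, 0.1, 1.0
        x = np.arange(12, 42, 5, dtype=float)
        y = a - np.exp(-b * x + c)
        fit = fit_solow(x, y)
        assert fit.a == pytest.approx(a, rel=1e-4)
        assert fit.b == pytest.approx(b, rel=1e-4)
        assert fit.c == pytest.approx(c, rel=1e-4)

    def test_constant_coverage_is_degenerate(self):
        with pytest.raises(SolowFitError, match="degenerate"):
            fit_solow([5, 10, 15], [0.5, 0.5, 0.5])

    def test_fitted_curve_monotone_increasing(self):
        x = np.arange(5, 35, 5, dtype=float)
        y = 0.8 - np.exp(-0.15 * x + 0.5)
        fit = fit_solow(x, y)
        grid = fit.predict(np.linspace(x.min(), x.max(), 50))
        assert np.all(np.diff(grid) > 0)

    def test_residual_trace_non_increasing(self, rng):
        x = np.arange(5, 45, 5, dtype=float)
        y = np.clip(0.85 - np.exp(-0.12 * x + 0.8) + rng.normal(0, 0.01, x.size), 0, 1)
        fit = fit_solow(x, y)
        assert all(b <= a + 1e-12 for a, b in zip(fit.residual_trace[:-1], fit.residual_trace[1:]))

    def test_tipping_point_is_where_marginal_gain_crosses_tolerance(self):
        x = np.arange(12, 42, 5.0)
        fit = fit_solow(x, 0.9 - np.exp(-0.1 * x + 1.0))
        tol = 0.01
        eps = 1e-6
        gain = lambda x: fit.b * np.exp(-fit.b * x + fit.c)  # noqa: E731
        assert gain(fit.tipping_point + eps) < tol < gain(fit.tipping_point - eps)

    def test_needs_three_distinct_amounts(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_solow([5, 5, 5], [0.1, 0.2, 0.3])
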