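"""Population viability analysis under lineage-cross mating scenarios.

Replicated stochastic projections of the gibbon population over future
generations (default 100 generations at K = 2000), comparing three mating
policies: ``all_cross`` (every pairing must join individuals of different
lineages), ``half_cross`` (each pairing is constrained inter-lineage with
probability 0.5) and ``random`` (unconstrained). Hybrid offspring carry
admixture fractions and count as inter-lineage partners for either pure
lineage. Reported per scenario: the extinction rate, and per-replicate
population-size and F_ROH(>=500 kb) trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sim import (
    GIBBON_SCENARIO,
    DfeParams,
    GenomeLayout,
    Population,
    ScenarioResult,
    run_scenario,
)

__all__ = ["PvaResult", "run_pva", "compare_scenarios", "burn_in_start", "MATING_SCENARIOS"]

MATING_SCENARIOS = ("all_cross", "half_cross", "random")


@dataclass
class PvaResult:
    """Replicate trajectories and the extinct fraction for one mating scenario."""

    scenario: str
    n_replicates: int
    generations: int
    years_per_generation: int
    seed: int
    extinct: np.ndarray  # (n_replicates,) bool
    size: np.ndarray  # (n_replicates, generations + 1); 0 after extinction
    froh: np.ndarray  # (n_replicates, generations + 1); NaN after extinction

    @property
    def extinction_rate(self) -> float:
        return float(self.extinct.mean())


def _scale_k(k: int, q: float, min_k: int = 6) -> int:
    return k if k * q < min_k else round(k * q)


def run_pva(
    start_pop: Population,
    scenario: str = "all_cross",
    n_replicates: int = 200,
    generations: int = 100,
    k: int = 2000,
    seed: int = 0,
    years_per_generation: int = 10,
    scale: float = 1.0,
    froh_min_length: int = 500_000,
) -> PvaResult:
    """Project ``start_pop`` forward under one mating scenario.

    ``start_pop`` is typically the end state of the gibbon demographic
    scenario (the two lineages after their split); the subpopulations are
    merged so that mate choice is governed solely by the mating policy.
    Each generation spans ``years_per_generation`` yearly cycles. ``scale``
    rescales K with the same rule used for scenario rescaling.
    """
    if scenario not in MATING_SCENARIOS:
        raise ValueError(f"unknown mating scenario {scenario!r}; pick from {MATING_SCENARIOS}")
    classes = start_pop._lineage_class()
    if scenario in ("all_cross", "half_cross") and not ({0, 1} <= set(classes.tolist())):
        raise ValueError("start population must carry both lineages for cross scenarios")
    k_run = _scale_k(k, scale)
    policy = None if scenario == "random" else scenario
    n_points = generations + 1
    size = np.zeros((n_replicates, n_points))
    froh = np.full((n_replicates, n_points), np.nan)
    extinct = np.zeros(n_replicates, dtype=bool)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for r in range(n_replicates):
        pop = start_pop.copy(rng=np.random.default_rng(children[r]))
        pop.merge_subpops()
        # the extinction-determining early generations run at absolute
        # population sizes (~11 founders), so the projection uses the raw
        # selection coefficients throughout
        pop.set_selection_scale(1.0)
        size[r, 0] = pop.size
        froh[r, 0] = pop.froh((froh_min_length,), max_individuals=50)[froh_min_length]
        year = 0
        for g in range(1, n_points):
            for _ in range(years_per_generation):
                pop.step(year, {0: k_run}, policy=policy)
                year += 1
                if pop.size == 0:
                    break
            size[r, g] = pop.size
            if pop.size == 0:
                extinct[r] = True
                break
            froh[r, g] = pop.froh((froh_min_length,), max_individuals=50)[froh_min_length]
    return PvaResult(
        scenario=scenario,
        n_replicates=n_replicates,
        generations=generations,
        years_per_generation=years_per_generation,
        seed=seed,
        extinct=extinct,
        size=size,
        froh=froh,
    )


def compare_scenarios(results: list[PvaResult], alpha: float = 0.05) -> dict:
    """Paired nonparametric comparison of PVA scenarios.

    Requires matched replicate structure (equal replicate counts and the
    same base seed so replicate r shares its random stream across
    scenarios). Returns per-generation Wilcoxon signed-rank tests on
    inbreeding and population size for every scenario pair, plus
    extinction rates with binomial (Clopper-Pearson) confidence intervals.
    """
    if len(results) < 2:
        raise ValueError("need at least two scenarios to compare")
    first = results[0]
    for res in results[1:]:
        if (
            res.n_replicates != first.n_replicates
            or res.generations != first.generations
            or res.seed != first.seed
        ):
            raise ValueError("unmatched replicate structure across scenarios")

    rows = []
    for i, a in enumerate(results):
        for b in results[i + 1 :]:
            for metric in ("froh", "size"):
                xa = getattr(a, metric)
                xb = getattr(b, metric)
                for g in range(first.generations + 1):
                    va, vb = xa[:, g], xb[:, g]
                    ok = ~(np.isnan(va) | np.isnan(vb))
                    diff = va[ok] - vb[ok]
                    if diff.size == 0 or np.allclose(diff, 0.0):
                        stat, p = 0.0, 1.0
                    else:
                        w = stats.wilcoxon(va[ok], vb[ok])
                        stat, p = float(w.statistic), float(w.pvalue)
                    rows.append(
                        {
                            "pair": f"{a.scenario}_vs_{b.scenario}",
                            "metric": metric,
                            "generation": g,
                            "n_pairs": int(ok.sum()),
                            "statistic": stat,
                            "p_value": p,
                        }
                    )
    ext_rows = []
    for res in results:
        n_ext = int(res.extinct.sum())
        ci = stats.binomtest(n_ext, res.n_replicates).proportion_ci(1 - alpha)
        ext_rows.append(
            {
                "scenario": res.scenario,
                "n_replicates": res.n_replicates,
                "n_extinct": n_ext,
                "extinction_rate": res.extinction_rate,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
            }
        )
    return {"tests": pd.DataFrame(rows), "extinction": pd.DataFrame(ext_rows)}


def burn_in_start(
    seed: int = 0,
    scale: float = 1.0,
    layout: GenomeLayout | None = None,
    dfe: DfeParams | None = None,
    max_attempts: int = 60,
    rebound_years: int = 0,
    rebound_k_per_lineage: int = 21,
    min_start_size: int = 6,
    min_per_lineage: int = 3,
) -> ScenarioResult:
    """Gibbon-scenario burn-in providing the PVA start population.

    The start state is the end of the gibbon demographic scenario: the two
    lineages after their 450-year decline to K = 6 and 5, roughly the ~13
    individuals observed at the population's 2003 minimum. Each lineage
    must retain a potential breeding pair (viability conditioning, retried
    deterministically from ``seed``) — the real population's persistence
    embodies the same survivorship. ``rebound_years`` > 0 optionally grows
    each lineage separately at K = ``rebound_k_per_lineage`` before the
    projection, emulating a pre-rebounded present-day census instead.
    """
    # One expensive burn-in to the pre-split state. The split-plus-rebound
    # tail (declining K down to 6 and 5, heavy demographic stochasticity)
    # is then retried with fresh randomness until it survives — the same
    # survivorship conditioning the real population's persistence
    # represents. The two lineages evolve independently after the split,
    # so each lineage's tail is retried separately and the survivors are
    # merged, which is statistically equivalent to retrying joint
    # survival but needs ~1/P(joint) fewer attempts.
    from .sim import merge_populations

    outer_ss, tail_ss = np.random.SeedSequence(seed).spawn(2)
    for outer in outer_ss.spawn(5):
        pre = run_scenario(GIBBON_SCENARIO, layout=layout, dfe=dfe,
                           seed=np.random.default_rng(outer), scale=scale,
                           stop_before_split=True)
        if pre.extinct:
            continue
        split = pre.scenario.split
        last = pre.scenario.epochs[-1]
        k_pre_split = last.k_end if last.k_end is not None else last.k
        year0 = int(pre.trajectory["year"].iloc[-1]) + 1
        seed_pop = pre.population.copy(rng=np.random.default_rng(outer.spawn(1)[0]))
        seed_pop.split_lineages()
        n_shared = seed_pop.n_segregating

        def lineage_tail(sub: int, ss: np.random.SeedSequence):
            base = seed_pop.subset(seed_pop.subpop == sub)
            if not split.k_is_scaled:
                # the decline to K=6/5 runs at absolute population sizes,
                # so selection acts with the raw coefficients there
                base.set_selection_scale(1.0)
            for child in ss.spawn(max_attempts):
                pop = base.copy(rng=np.random.default_rng(child))
                pop._next_label += 2_000_000 * sub  # keep label spaces disjoint
                year = year0
                for t in range(split.duration_years):
                    pop.step(year, {sub: split.k_at(t, k_pre_split)[sub]},
                             cleanup_interval=10**9)
                    year += 1
                    if pop.size == 0:
                        break
                for _ in range(rebound_years):
                    if pop.size == 0:
                        break
                    pop.step(year, {sub: rebound_k_per_lineage}, cleanup_interval=10**9)
                    year += 1
                if pop.size == 0:
                    continue
                counts = np.bincount(pop._lineage_class(), minlength=3)
                has_pair = (pop.sex == 0).any() and (pop.sex == 1).any()
                if counts[sub - 1] >= min_per_lineage and has_pair:
                    return pop
            return None

        ss_a, ss_b = tail_ss.spawn(2)
        pop_a = lineage_tail(1, ss_a)
        pop_b = lineage_tail(2, ss_b)
        if pop_a is None or pop_b is None:
            continue
        merged = merge_populations(pop_a, pop_b, n_shared)
        merged.rng = np.random.default_rng(tail_ss.spawn(3)[2])
        if merged.size >= min_start_size:
            return ScenarioResult(
                trajectory=pre.trajectory, population=merged, extinct=False,
                scale=scale, scenario=pre.scenario, layout=pre.layout,
            )
    raise RuntimeError(
        f"no split/rebound attempt of {max_attempts} produced a viable "
        "two-lineage start population"
    )
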