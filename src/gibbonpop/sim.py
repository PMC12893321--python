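"""Individual-based non-Wright-Fisher forward simulator of gibbon demography.

The model follows the eco-evolutionary simulation framework used for small
endangered populations: explicit individuals with age, sex and a diploid
genome; yearly cycles of polygynous reproduction followed by viability
selection; and density regulation through a carrying capacity K.

Genome model
    The genome is a chain of gene blocks: ``n_genes`` coding "genes" of
    ``gene_length`` bp distributed over ``n_chromosomes`` chromosomes and
    separated by ``intergenic_length`` bp of non-coding sequence. New coding
    mutations arise at ``mutation_rate`` per site per meiosis; 30% are
    neutral and the rest draw a negative selection coefficient s from a
    gamma distribution of fitness effects, with a dominance coefficient h
    stepping from fully recessive (h = 0 for the strongest mutations) to
    nearly additive (h = 0.4 for the weakest). Recombination is free
    between chromosomes, never occurs within a gene, and crossovers fall
    between adjacent genes with probability
    ``intergenic_length * recomb_rate_per_site`` (1e-3 at defaults).

Life cycle (one calendar year)
    Every breeding male (age >= 7) keeps up to two fixed female mates
    (age >= 7), pairing initially only with females that did not breed the
    previous year, and alternates partners between years; a female breeds
    at most every second year, and each successful copulation produces one
    offspring. Viability selection then removes individuals with
    probability 1 - fitness x (1 - age-specific mortality) x min(1, K/N);
    nobody survives past age 40.

Inbreeding is tracked two ways: runs of genes where both haplotypes carry
the same founder-ancestry label (IBD autozygosity over a rolling
recent-ancestry reference, on the physical coordinate) and runs of genes
free of heterozygous sites (the operational sequence-data definition, on
the coding coordinate).

Whole scenarios (sequences of epochs with carrying capacities, optionally
ending in a split into two lineages) can be rescaled for desk runs with a
single scale factor q: chromosome count, K values and epoch durations are
multiplied by q, per-site rates by 1/q, and the fitness effect of s by 1/q
in phases whose K is scaled — the standard rescaling that preserves
diversity, the genetic map and the drift-selection balance. Phases whose K
stays absolute (the tiny terminal lineages) keep their duration and the
raw selection coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "DfeParams",
    "MutationEffect",
    "Epoch",
    "Split",
    "DemographicScenario",
    "GIBBON_SCENARIO",
    "ISLAND_CONTROL_SCENARIO",
    "Population",
    "ScenarioResult",
    "dominance_coefficient",
    "deleterious_class",
    "draw_mutation_effect",
    "fitness_from_mutations",
    "make_gamete",
    "run_scenario",
    "DELETERIOUS_CLASSES",
]


# ------------------------------------------------------------------ genome layout

@dataclass(frozen=True)
class GenomeLayout:
    """Gene-block genome geometry and per-meiosis mutation/recombination rates."""

    n_chromosomes: int = 25
    n_genes: int = 19_197
    gene_length: int = 1458
    intergenic_length: int = 100_000
    mutation_rate: float = 1e-8  # per coding site per meiosis
    recomb_rate_per_site: float = 1e-8  # per site per meiosis

    def __post_init__(self) -> None:
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")

    @property
    def intergene_crossover_prob(self) -> float:
        """Per-meiosis crossover probability between adjacent genes."""
        return self.intergenic_length * self.recomb_rate_per_site

    @property
    def coding_length(self) -> int:
        return self.n_genes * self.gene_length

    @property
    def unit_bp(self) -> int:
        """Physical span of one gene block (gene plus trailing intergenic)."""
        return self.gene_length + self.intergenic_length

    @property
    def genome_length_bp(self) -> int:
        return self.n_genes * self.unit_bp

    @property
    def mutations_per_gamete(self) -> float:
        return self.mutation_rate * self.coding_length

    def chromosome_of_gene(self) -> np.ndarray:
        """(n_genes,) chromosome index per gene, contiguous near-equal blocks."""
        return np.repeat(
            np.arange(self.n_chromosomes),
            np.diff(np.linspace(0, self.n_genes, self.n_chromosomes + 1).astype(int)),
        )

    def scaled(self, q: float) -> "GenomeLayout":
        """Diversity-preserving desk rescaling of the genome by factor q.

        The chromosome count is scaled by q with the gene count per
        chromosome preserved (so ROH length thresholds remain attainable
        within a chromosome), and the mutation and recombination rates are
        scaled by 1/q. Together with scaling carrying capacities and epoch
        durations by q this preserves the population-scaled diversity
        4(Kq)(u/q), the per-chromosome genetic map, and the correspondence
        between IBD segment length and ancestry depth. The matching 1/q
        fitness rescaling of s is handled per phase by the scenario runner
        (see :class:`DfeParams` and :meth:`Population.set_selection_scale`).
        """
        if q == 1.0:
            return self
        genes_per_chrom = round(self.n_genes / self.n_chromosomes)
        n_chrom = max(1, round(self.n_chromosomes * q))
        new_r = self.recomb_rate_per_site / q
        if self.intergenic_length * new_r > 0.5:
            raise ValueError(f"scale {q} would push the inter-gene crossover probability above 0.5")
        return replace(
            self,
            n_chromosomes=n_chrom,
            n_genes=n_chrom * genes_per_chrom,
            mutation_rate=self.mutation_rate / q,
            recomb_rate_per_site=new_r,
        )


# ------------------------------------------------------------------ fitness effects

#: Deleterious-class labels, weakest to strongest.
DELETERIOUS_CLASSES = ("neutral", "weak", "moderate", "strong", "very_strong")
_CLASS_CODE = {name: i for i, name in enumerate(DELETERIOUS_CLASSES)}


@dataclass(frozen=True)
class DfeParams:
    """Distribution of fitness effects of new coding mutations.

    30% of mutations are neutral; the rest draw |s| from a gamma
    distribution. The default gamma (shape 0.186, mean |s| 0.01314833) is
    the human-derived DFE commonly used for primate load simulations; it is
    external input to this package and fully configurable.
    """

    neutral_fraction: float = 0.3
    gamma_shape: float = 0.186
    gamma_mean: float = 0.01314833
    s_min: float = -0.999999  # floor keeps log-fitness finite (effectively lethal)
    #: Fitness-only rescaling of s for desk runs (1/q under standard
    #: rescaling, preserving the N*s drift-selection balance). Class labels
    #: and dominance coefficients are always assigned from the unscaled s,
    #: so the printed class boundaries keep their meaning.
    s_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.neutral_fraction <= 1.0:
            raise ValueError("neutral_fraction outside [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_mean <= 0:
            raise ValueError("gamma parameters must be positive and configured")
        if self.s_scale <= 0:
            raise ValueError("s_scale must be positive")


@dataclass(frozen=True)
class MutationEffect:
    s: float
    h: float
    label: str


def dominance_coefficient(s: float, boundary: str = "recessive") -> float:
    """Step map from selection coefficient to dominance coefficient.

    h = 0 for s < -0.1, h = 0.01 for -0.1 < s < -0.01, h = 0.1 for
    -0.01 <= s < -0.001, h = 0.4 for s >= -0.001: the strongest mutations
    are fully recessive, the weakest nearly additive.
    """
    if boundary not in ("recessive", "dominant"):
        raise ValueError("boundary must be 'recessive' or 'dominant'")
    # Exact boundaries (s = -0.1) are not covered by the strict inequalities
    # of the map; they join the more recessive neighbour by default.
    if s < -0.1 or (s == -0.1 and boundary == "recessive"):
        return 0.0
    if s < -0.01 or (s == -0.01 and boundary == "recessive"):
        return 0.01
    if s < -0.001:
        return 0.1
    return 0.4


def deleterious_class(s: float, boundary: str = "recessive") -> str:
    """Class label of a selection coefficient (boundaries per the h-map)."""
    if s == 0:
        return "neutral"
    if s <= -0.1:
        return "very_strong"
    if s < -0.01 or (s == -0.01 and boundary == "recessive"):
        return "strong"
    if s < -0.001:
        return "moderate"
    return "weak"


def _vector_effects(
    n: int, dfe: DfeParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw n mutation effects; returns (s, h, class_code) arrays."""
    s = np.zeros(n)
    deleterious = rng.random(n) >= dfe.neutral_fraction
    n_del = int(deleterious.sum())
    if n_del:
        draws = -rng.gamma(dfe.gamma_shape, dfe.gamma_mean / dfe.gamma_shape, n_del)
        s[deleterious] = np.maximum(draws, dfe.s_min)
    h = np.select(
        [s <= -0.1, s < -0.01, s < -0.001],
        [0.0, 0.01, 0.1],
        default=0.4,
    )
    code = np.select(
        [s == 0, s <= -0.1, s < -0.01, s < -0.001],
        [0, 4, 3, 2],
        default=1,
    ).astype(np.int8)
    return s, h, code


def draw_mutation_effect(rng: np.random.Generator, dfe: DfeParams = DfeParams()) -> MutationEffect:
    """Draw one mutation effect from the configured DFE."""
    s, h, code = _vector_effects(1, dfe, rng)
    return MutationEffect(s=float(s[0]), h=float(h[0]), label=DELETERIOUS_CLASSES[code[0]])


def fitness_from_mutations(
    homozygous: list[MutationEffect], heterozygous: list[MutationEffect]
) -> float:
    """Multiplicative absolute fitness: x(1+s) per hom, x(1+h*s) per het; floor 0."""
    w = 1.0
    for e in homozygous:
        w *= 1.0 + e.s
    for e in heterozygous:
        w *= 1.0 + e.h * e.s
    return max(w, 0.0)


# ------------------------------------------------------------------ life table

# Age-specific annual mortalities realizing the gibbon life history:
# 0.1 for newborns, 0.05 ages 1-2, 0.03 ages 3-6, 0.1 age 7, 0.05 ages 8-30,
# 0.25 ages 31-35, 0.5 ages 36-40; nothing survives past 40.
MAX_AGE = 40


def _mortality_lookup() -> np.ndarray:
    m = np.empty(MAX_AGE + 2)
    m[0] = 0.10
    m[1:3] = 0.05
    m[3:7] = 0.03
    m[7:8] = 0.10
    m[8:31] = 0.05
    m[31:36] = 0.25
    m[36:41] = 0.50
    m[41] = 1.0
    return m


AGE_MORTALITY = _mortality_lookup()
MIN_BREEDING_AGE = 7


# ------------------------------------------------------------------ scenarios

@dataclass(frozen=True)
class Epoch:
    """A demographic epoch: duration in years and carrying capacity.

    ``k_end`` different from ``k`` makes K ramp linearly across the epoch
    (used for the post-glacial expansion phase).
    """

    duration_years: int
    k: int
    k_end: int | None = None
    #: False when desk rescaling left this epoch's K (and duration) absolute;
    #: selection then acts with the unscaled coefficients.
    k_is_scaled: bool = True

    def k_at(self, t: int) -> int:
        if self.k_end is None or self.k_end == self.k:
            return self.k
        frac = (t + 1) / self.duration_years
        return int(round(self.k + frac * (self.k_end - self.k)))


@dataclass(frozen=True)
class Split:
    """Terminal split into lineages A and B with declining carrying capacities.

    ``k_a`` and ``k_b`` are the terminal (present-day) capacities; since
    the lineages "continued to decline" after separating, K follows a ramp
    from half the pre-split K down to the terminal value over the split
    duration (``ramp``: "exponential" halves K at a constant rate, which
    reaches the tiny terminal sizes only towards the end; "linear" and
    "step" are alternatives).
    """

    duration_years: int
    k_a: int
    k_b: int
    ramp: str = "exponential"
    k_is_scaled: bool = True

    def k_at(self, t: int, k_start_total: int) -> dict[int, int]:
        """Carrying capacities {lineage A: K, lineage B: K} in split year t."""
        out = {}
        for sub, k_end in ((1, self.k_a), (2, self.k_b)):
            k0 = max(k_end, k_start_total // 2)
            if self.ramp == "step" or k0 <= k_end:
                out[sub] = k_end
                continue
            frac = (t + 1) / self.duration_years
            if self.ramp == "linear":
                k = k0 + frac * (k_end - k0)
            elif self.ramp == "exponential":
                k = k0 * (k_end / k0) ** frac
            else:
                raise ValueError(f"unknown split ramp {self.ramp!r}")
            out[sub] = max(k_end, round(k))
        return out


@dataclass(frozen=True)
class DemographicScenario:
    epochs: tuple[Epoch, ...]
    split: Split | None = None
    label: str = "scenario"

    @property
    def total_years(self) -> int:
        return sum(e.duration_years for e in self.epochs) + (
            self.split.duration_years if self.split else 0
        )

    def scaled(self, q: float, min_k: int = 6) -> "DemographicScenario":
        """Rescale epoch durations and K values by q.

        Carrying capacities that would fall below ``min_k`` stay unscaled
        (the terminal lineage sizes of 6 and 5 are already tiny), and the
        duration of a phase whose K is left unscaled is likewise left
        unscaled: the rescaling preserves the ratio of elapsed time to
        population size, so compressing the time spent at an absolute
        (unscaled) K would erase the drift and purging that phase produces
        — most importantly the 45 generations of lineage differentiation
        in the terminal split.
        """
        if q == 1.0:
            return self

        def keep(k: int) -> bool:
            return k * q < min_k

        def sk(k: int) -> int:
            return k if keep(k) else round(k * q)

        def sd(d: int, unscaled: bool) -> int:
            return d if unscaled else max(1, round(d * q))

        epochs = tuple(
            Epoch(
                sd(e.duration_years, keep(e.k) and (e.k_end is None or keep(e.k_end))),
                sk(e.k),
                None if e.k_end is None else sk(e.k_end),
                k_is_scaled=not keep(e.k),
            )
            for e in self.epochs
        )
        split = (
            Split(
                sd(self.split.duration_years, keep(self.split.k_a) or keep(self.split.k_b)),
                sk(self.split.k_a),
                sk(self.split.k_b),
                self.split.ramp,
                k_is_scaled=not (keep(self.split.k_a) or keep(self.split.k_b)),
            )
            if self.split
            else None
        )
        return DemographicScenario(epochs=epochs, split=split, label=self.label)


#: Demography inferred for the Hainan gibbon: 50 ky burn-in at K = 10,000,
#: a 20-ky pre-LGM bottleneck at K = 500, a 15-ky post-glacial expansion to
#: a peak K of 20,000 at 5 kya, decline to K = 3000, and a split 450 years
#: ago into lineage A (K = 6) and lineage B (K = 5).
GIBBON_SCENARIO = DemographicScenario(
    epochs=(
        Epoch(50_000, 10_000),
        Epoch(20_000, 500),
        Epoch(15_000, 500, 20_000),
        Epoch(4_550, 3_000),
    ),
    split=Split(450, 6, 5),
    label="gibbon",
)

#: Island control: identical history minus the post-glacial expansion phase.
ISLAND_CONTROL_SCENARIO = DemographicScenario(
    epochs=(
        Epoch(50_000, 10_000),
        Epoch(20_000, 500),
        Epoch(4_550, 3_000),
    ),
    split=Split(450, 6, 5),
    label="island_control",
)


# ------------------------------------------------------------------ gametes

def _switch_prob_vector(layout: GenomeLayout) -> np.ndarray:
    chrom = layout.chromosome_of_gene()
    prob = np.full(layout.n_genes, layout.intergene_crossover_prob, dtype=np.float32)
    starts = np.r_[True, chrom[1:] != chrom[:-1]]
    prob[starts] = 0.5
    return prob


def _crossover_patterns(
    n: int, switch_prob: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, n_genes) haplotype-of-origin indicators for n independent meioses.

    Chromosomes assort independently (switch probability 0.5 at chromosome
    starts); within a chromosome the origin switches between adjacent genes
    with the inter-gene crossover probability. The indicator is the running
    parity of the switch events.
    """
    switches = rng.random((n, switch_prob.size), dtype=np.float32) < switch_prob[None, :]
    return np.bitwise_xor.accumulate(switches, axis=1).astype(np.int8)


def make_gamete(
    parent_anc: np.ndarray,
    parent_mut: np.ndarray,
    mut_gene: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete from a parent genome.

    ``parent_anc`` is (2, n_genes) ancestry labels, ``parent_mut`` a
    (2, n_mutations) presence matrix with ``mut_gene`` giving each
    mutation's gene index. Returns (gamete ancestry, gamete mutations);
    alleles within one gene are never separated because the gene is the
    atomic unit of inheritance.
    """
    pattern = _crossover_patterns(1, _switch_prob_vector(layout), rng)[0]
    anc = parent_anc[pattern, np.arange(layout.n_genes)]
    mut = parent_mut[pattern[mut_gene], np.arange(mut_gene.size)] if mut_gene.size else parent_mut[0, :0]
    return anc, mut


# ------------------------------------------------------------------ population

_ANC_DTYPE = np.uint32


class Population:
    """Array-of-individuals state with vectorised yearly updates."""

    def __init__(
        self,
        layout: GenomeLayout,
        dfe: DfeParams,
        rng: np.random.Generator,
        age_table_is_survival: bool = False,
        fecundity: float = 1.0,
        label_refresh: float = 0.01,
    ):
        self.layout = layout
        self.dfe = dfe
        self.rng = rng
        self.age_table_is_survival = age_table_is_survival
        self.fecundity = fecundity
        # Per-gamete probability of re-basing the ancestry reference: the
        # whole gamete receives one fresh label, so label-based ROH measures
        # autozygosity over a rolling recent-ancestry horizon instead of
        # saturating once old founder labels drift to fixation.
        self.label_refresh = label_refresh
        self._chrom = layout.chromosome_of_gene()
        self._switch_prob = _switch_prob_vector(layout)
        self._gene_idx = np.arange(layout.n_genes)
        # per-individual state
        self.age = np.empty(0, dtype=np.int16)
        self.sex = np.empty(0, dtype=np.int8)  # 0 female, 1 male
        self.subpop = np.empty(0, dtype=np.int8)
        self.lineage_frac = np.empty(0, dtype=np.float64)  # ancestry fraction of lineage A
        self.log_fitness = np.empty(0, dtype=np.float64)
        self.mate = np.empty((0, 2), dtype=np.int64)  # row indices of mates (males)
        self.paired = np.empty(0, dtype=np.int64)  # row index of male (females)
        self.next_slot = np.empty(0, dtype=np.int8)
        self.last_bred = np.empty(0, dtype=np.int32)
        self.mother = np.empty(0, dtype=np.int64)  # parent ids, for pedigree checks
        self.father = np.empty(0, dtype=np.int64)
        self.ids = np.empty(0, dtype=np.int64)
        self._next_id = 0
        self.anc = np.empty((0, 2, layout.n_genes), dtype=_ANC_DTYPE)
        self._next_label = 0
        self.mut = np.empty((0, 2, 0), dtype=bool)
        # per-mutation state
        self.mut_s = np.empty(0)
        self.mut_h = np.empty(0)
        self.mut_gene = np.empty(0, dtype=np.int64)
        self.mut_class = np.empty(0, dtype=np.int8)
        self.fixed_per_class = np.zeros(len(DELETERIOUS_CLASSES), dtype=np.int64)
        self._log_w_hom = np.empty(0)
        self._log_w_het = np.empty(0)

    # -------------------------------------------------- construction

    @classmethod
    def founders(
        cls,
        n: int,
        layout: GenomeLayout | None = None,
        dfe: DfeParams | None = None,
        seed: int | np.random.Generator = 0,
        **kwargs,
    ) -> "Population":
        """Mutation-free founder population with unique ancestry labels."""
        layout = layout or GenomeLayout()
        dfe = dfe or DfeParams()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        pop = cls(layout, dfe, rng, **kwargs)
        pop.age = rng.integers(0, 26, size=n).astype(np.int16)
        pop.sex = (rng.random(n) < 0.5).astype(np.int8)
        pop.subpop = np.zeros(n, dtype=np.int8)
        pop.lineage_frac = np.full(n, np.nan)
        pop.log_fitness = np.zeros(n)
        pop.mate = np.full((n, 2), -1, dtype=np.int64)
        pop.paired = np.full(n, -1, dtype=np.int64)
        pop.next_slot = np.zeros(n, dtype=np.int8)
        pop.last_bred = np.full(n, -10, dtype=np.int32)
        pop.mother = np.full(n, -1, dtype=np.int64)
        pop.father = np.full(n, -1, dtype=np.int64)
        pop.ids = np.arange(n, dtype=np.int64)
        pop._next_id = n
        labels = np.arange(2 * n, dtype=_ANC_DTYPE).reshape(n, 2)
        pop.anc = np.repeat(labels[:, :, None], layout.n_genes, axis=2)
        pop._next_label = 2 * n
        pop.mut = np.empty((n, 2, 0), dtype=bool)
        return pop

    def copy(self, rng: np.random.Generator | None = None) -> "Population":
        new = Population(
            self.layout,
            self.dfe,
            rng if rng is not None else self.rng,
            self.age_table_is_survival,
            self.fecundity,
            self.label_refresh,
        )
        for name in (
            "age", "sex", "subpop", "lineage_frac", "log_fitness", "mate", "paired",
            "next_slot", "last_bred", "mother", "father", "ids", "anc", "mut",
            "mut_s", "mut_h", "mut_gene", "mut_class", "fixed_per_class",
            "_log_w_hom", "_log_w_het",
        ):
            setattr(new, name, getattr(self, name).copy())
        new._next_id = self._next_id
        new._next_label = self._next_label
        return new

    @property
    def size(self) -> int:
        return self.age.size

    @property
    def n_segregating(self) -> int:
        return self.mut_s.size

    def individual_fitness(self, row: int) -> float:
        """Absolute multiplicative fitness of one individual."""
        return float(np.exp(self.log_fitness[row]))

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of each tracked (segregating) mutation."""
        if self.size == 0:
            return np.zeros(self.n_segregating)
        return self.mut.sum(axis=(0, 1)) / (2 * self.size)

    # -------------------------------------------------- mutation bookkeeping

    def _append_mutations(self, s: np.ndarray, h: np.ndarray, gene: np.ndarray) -> np.ndarray:
        """Register new mutation columns (zero everywhere); returns their indices."""
        start = self.mut_s.size
        code = np.select([s == 0, s <= -0.1, s < -0.01, s < -0.001], [0, 4, 3, 2], default=1).astype(np.int8)
        s_eff = np.maximum(s * self.dfe.s_scale, self.dfe.s_min)
        self.mut_s = np.concatenate([self.mut_s, s])
        self.mut_h = np.concatenate([self.mut_h, h])
        self.mut_gene = np.concatenate([self.mut_gene, gene])
        self.mut_class = np.concatenate([self.mut_class, code])
        self._log_w_hom = np.concatenate([self._log_w_hom, np.log1p(s_eff)])
        self._log_w_het = np.concatenate([self._log_w_het, np.log1p(h * s_eff)])
        if self.mut.shape[2] != self.mut_s.size:
            pad = np.zeros((self.size, 2, self.mut_s.size - self.mut.shape[2]), dtype=bool)
            self.mut = np.concatenate([self.mut, pad], axis=2)
        return np.arange(start, self.mut_s.size)

    def inject_mutation(
        self, s: float, h: float, gene: int, carrier_haplotypes: np.ndarray
    ) -> int:
        """Add a mutation with explicit effect to chosen (row, hap) carriers.

        Intended for experiments (e.g. seeding an overdominant allele via
        h < 0) and for drift checks; refreshes carrier fitness.
        """
        idx = self._append_mutations(np.array([s]), np.array([h]), np.array([gene]))[0]
        rows = np.asarray(carrier_haplotypes)
        self.mut[rows[:, 0], rows[:, 1], idx] = True
        self._refresh_fitness()
        return int(idx)

    def set_selection_scale(self, s_scale: float) -> None:
        """Re-express mutation fitness effects under a new selection rescaling.

        Used when a desk-scaled run enters a phase whose population size is
        absolute (left unscaled): the drift-selection balance there requires
        the raw coefficients, so the fitness vectors and every individual's
        fitness are recomputed with the phase-appropriate scaling. Class
        labels and dominance always derive from the raw s and are untouched.
        """
        if s_scale == self.dfe.s_scale:
            return
        self.dfe = replace(self.dfe, s_scale=s_scale)
        s_eff = np.maximum(self.mut_s * s_scale, self.dfe.s_min)
        self._log_w_hom = np.log1p(s_eff)
        self._log_w_het = np.log1p(self.mut_h * s_eff)
        self._refresh_fitness()

    def _refresh_fitness(self) -> None:
        hom = (self.mut[:, 0, :] & self.mut[:, 1, :]).astype(np.float64)
        het = (self.mut[:, 0, :] ^ self.mut[:, 1, :]).astype(np.float64)
        self.log_fitness = hom @ self._log_w_hom + het @ self._log_w_het

    def _cleanup_mutations(self) -> None:
        """Drop lost columns; convert fixed mutations to substitutions."""
        if self.n_segregating == 0 or self.size == 0:
            return
        counts = self.mut.sum(axis=(0, 1))
        fixed = counts == 2 * self.size
        keep = (counts > 0) & ~fixed
        if fixed.any():
            np.add.at(self.fixed_per_class, self.mut_class[fixed], 1)
        if keep.all():
            return
        self.mut = np.ascontiguousarray(self.mut[:, :, keep])
        for name in ("mut_s", "mut_h", "mut_gene", "mut_class", "_log_w_hom", "_log_w_het"):
            setattr(self, name, getattr(self, name)[keep])
        # Fitness is recomputed from the remaining segregating mutations:
        # fixed deleterious mutations become substitutions and stop
        # affecting survival, the convention of the simulation framework
        # this model follows.
        self._refresh_fitness()

    # -------------------------------------------------- reproduction

    def _pair_vacant_males(self, year: int, policy: str | None) -> None:
        eligible_f = (self.sex == 0) & (self.age >= MIN_BREEDING_AGE)
        available = eligible_f & (self.paired == -1) & (self.last_bred != year - 1)
        males = np.nonzero((self.sex == 1) & (self.age >= MIN_BREEDING_AGE) & (self.mate == -1).any(axis=1))[0]
        if males.size == 0 or not available.any():
            return
        if policy is None:
            # fast path: per-subpopulation shuffled queues of available females
            queues = {}
            for sp in np.unique(self.subpop[males]):
                q = np.nonzero(available & (self.subpop == sp))[0]
                queues[sp] = list(self.rng.permutation(q))
            for m in self.rng.permutation(males):
                q = queues.get(self.subpop[m])
                for slot in (0, 1):
                    if self.mate[m, slot] == -1 and q:
                        f = int(q.pop())
                        self.mate[m, slot] = f
                        self.paired[f] = m
            return
        lin_class = self._lineage_class()
        n_avail = int(available.sum())
        for m in self.rng.permutation(males):
            if n_avail == 0:
                break
            for slot in (0, 1):
                if self.mate[m, slot] != -1:
                    continue
                cand_mask = available & (self.subpop == self.subpop[m])
                require_cross = policy == "all_cross" or bool(self.rng.random() < 0.5)
                if require_cross:
                    crossed = cand_mask & (
                        (lin_class != lin_class[m]) | (lin_class == 2) | (lin_class[m] == 2)
                    )
                    # the constraint binds only while satisfiable: once drift
                    # has blended or eliminated a lineage class, pairing falls
                    # back to the unconstrained pool instead of deadlocking
                    if crossed.any():
                        cand_mask = crossed
                cands = np.nonzero(cand_mask)[0]
                if cands.size == 0:
                    continue
                f = int(self.rng.choice(cands))
                self.mate[m, slot] = f
                self.paired[f] = m
                available[f] = False
                n_avail -= 1

    def _lineage_class(self) -> np.ndarray:
        """0 = lineage A, 1 = lineage B, 2 = hybrid (admixture fraction 0.5)."""
        cls = np.full(self.size, 2, dtype=np.int8)
        cls[self.lineage_frac > 0.5] = 0
        cls[self.lineage_frac < 0.5] = 1
        return cls

    def _breed(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        males = np.nonzero((self.sex == 1) & (self.age >= MIN_BREEDING_AGE) & (self.mate != -1).any(axis=1))[0]
        fathers, mothers = [], []
        for m in males:
            first = int(self.next_slot[m])
            for slot in (first, 1 - first):
                f = self.mate[m, slot]
                if f == -1 or self.last_bred[f] > year - 2:
                    continue
                if self.fecundity < 1.0 and self.rng.random() >= self.fecundity:
                    break
                fathers.append(m)
                mothers.append(int(f))
                self.last_bred[f] = year
                self.next_slot[m] = 1 - slot
                break
        return np.asarray(fathers, dtype=np.int64), np.asarray(mothers, dtype=np.int64)

    def _gametes(self, parent_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batch of one gamete per listed parent; returns (anc, mut) arrays."""
        b = parent_rows.size
        pattern = _crossover_patterns(b, self._switch_prob, self.rng)
        take1 = pattern.astype(bool)
        pa = self.anc[parent_rows]  # (b, 2, G) contiguous row gather
        anc = np.where(take1, pa[:, 1, :], pa[:, 0, :])
        if self.label_refresh > 0.0:
            refresh = np.nonzero(self.rng.random(b) < self.label_refresh)[0]
            for j, g in enumerate(refresh):
                anc[g, :] = self._next_label + j
            self._next_label += refresh.size
        if self.n_segregating:
            sel = take1[:, self.mut_gene]  # (b, M)
            pm = self.mut[parent_rows]
            mut = np.where(sel, pm[:, 1, :], pm[:, 0, :])
        else:
            mut = np.empty((b, 0), dtype=bool)
        return anc, mut

    def _add_new_mutations(self, gam_mut_f: np.ndarray, gam_mut_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sprinkle de-novo mutations on a batch of father/mother gametes."""
        b = gam_mut_f.shape[0]
        n_new = self.rng.poisson(self.layout.mutations_per_gamete, size=2 * b)
        total = int(n_new.sum())
        if total == 0:
            return gam_mut_f, gam_mut_m
        s, h, _ = _vector_effects(total, self.dfe, self.rng)
        gene = self.rng.integers(0, self.layout.n_genes, size=total)
        cols = self._append_mutations(s, h, gene)
        grow = np.zeros((b, cols.size), dtype=bool)
        gam_mut_f = np.concatenate([gam_mut_f, grow], axis=1)
        gam_mut_m = np.concatenate([gam_mut_m, grow.copy()], axis=1)
        owner = np.repeat(np.arange(2 * b), n_new)  # gamete index per new mutation
        for k, g in enumerate(owner):
            target = gam_mut_f if g < b else gam_mut_m
            target[g % b, cols[k]] = True
        return gam_mut_f, gam_mut_m

    def _reproduce(self, year: int, policy: str | None) -> None:
        self._pair_vacant_males(year, policy)
        fathers, mothers = self._breed(year)
        b = fathers.size
        if b == 0:
            return
        anc_f, mut_f = self._gametes(fathers)
        anc_m, mut_m = self._gametes(mothers)
        mut_f, mut_m = self._add_new_mutations(mut_f, mut_m)
        hom = (mut_f & mut_m).astype(np.float64)
        het = (mut_f ^ mut_m).astype(np.float64)
        logw = hom @ self._log_w_hom + het @ self._log_w_het

        self.age = np.concatenate([self.age, np.zeros(b, dtype=np.int16)])
        self.sex = np.concatenate([self.sex, (self.rng.random(b) < 0.5).astype(np.int8)])
        self.subpop = np.concatenate([self.subpop, self.subpop[mothers]])
        child_frac = (self.lineage_frac[fathers] + self.lineage_frac[mothers]) / 2.0
        self.lineage_frac = np.concatenate([self.lineage_frac, child_frac])
        self.log_fitness = np.concatenate([self.log_fitness, logw])
        self.mate = np.concatenate([self.mate, np.full((b, 2), -1, dtype=np.int64)])
        self.paired = np.concatenate([self.paired, np.full(b, -1, dtype=np.int64)])
        self.next_slot = np.concatenate([self.next_slot, np.zeros(b, dtype=np.int8)])
        self.last_bred = np.concatenate([self.last_bred, np.full(b, -10, dtype=np.int32)])
        self.mother = np.concatenate([self.mother, self.ids[mothers]])
        self.father = np.concatenate([self.father, self.ids[fathers]])
        self.ids = np.concatenate(
            [self.ids, np.arange(self._next_id, self._next_id + b, dtype=np.int64)]
        )
        self._next_id += b
        self.anc = np.concatenate([self.anc, np.stack([anc_f, anc_m], axis=1)])
        # _add_new_mutations already padded self.mut to the new column count
        self.mut = np.concatenate([self.mut, np.stack([mut_f, mut_m], axis=1)], axis=0)

    # -------------------------------------------------- viability selection

    def _select(self, k_by_subpop: dict[int, int]) -> None:
        n = self.size
        if n == 0:
            return
        if self.age_table_is_survival:
            # literal reading of the age table as survival multipliers
            age_factor = AGE_MORTALITY[np.clip(self.age, 0, MAX_AGE + 1)]
        else:
            age_factor = 1.0 - AGE_MORTALITY[np.clip(self.age, 0, MAX_AGE + 1)]
        density = np.ones(n)
        for sp, k in k_by_subpop.items():
            mask = self.subpop == sp
            n_sp = int(mask.sum())
            if n_sp:
                density[mask] = min(1.0, k / n_sp)
        p = np.exp(self.log_fitness) * age_factor * density
        survive = self.rng.random(n) < p
        self._compact(survive)
        self.age += 1

    def _compact(self, keep: np.ndarray) -> None:
        remap = np.full(self.size, -1, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        for name in (
            "age", "sex", "subpop", "lineage_frac", "log_fitness", "next_slot",
            "last_bred", "mother", "father", "ids", "paired",
        ):
            setattr(self, name, getattr(self, name)[keep])
        self.mate = self.mate[keep]
        self.anc = self.anc[keep]
        self.mut = self.mut[keep]
        live = self.mate >= 0
        self.mate[live] = remap[self.mate[live]]
        live = self.paired >= 0
        self.paired[live] = remap[self.paired[live]]

    # -------------------------------------------------- yearly step

    def step(
        self,
        year: int,
        k_by_subpop: dict[int, int],
        policy: str | None = None,
        cleanup_interval: int = 25,
    ) -> None:
        """One year: reproduction, then viability selection."""
        self._reproduce(year, policy)
        self._select(k_by_subpop)
        if year % cleanup_interval == 0:
            self._cleanup_mutations()

    # -------------------------------------------------- lineage split / merge

    def split_lineages(self) -> None:
        """Randomly partition into lineage A (subpop 1) and B (subpop 2)."""
        order = self.rng.permutation(self.size)
        half = self.size // 2
        self.subpop = np.zeros(self.size, dtype=np.int8)
        self.subpop[order[:half]] = 1
        self.subpop[order[half:]] = 2
        self.lineage_frac = np.where(self.subpop == 1, 1.0, 0.0)
        # dissolve pairs that straddle the split
        for m in np.nonzero(self.sex == 1)[0]:
            for slot in (0, 1):
                f = self.mate[m, slot]
                if f >= 0 and self.subpop[f] != self.subpop[m]:
                    self.paired[f] = -1
                    self.mate[m, slot] = -1

    def merge_subpops(self) -> None:
        self.subpop = np.zeros(self.size, dtype=np.int8)

    def subset(self, keep: np.ndarray, rng: np.random.Generator | None = None) -> "Population":
        """New population holding the selected rows (pairs remapped)."""
        new = self.copy(rng=rng)
        new._compact(np.asarray(keep, dtype=bool))
        return new

    # -------------------------------------------------- statistics

    def _sample_rows(self, max_individuals: int | None) -> np.ndarray:
        rows = np.arange(self.size)
        if max_individuals is not None and self.size > max_individuals:
            rows = self.rng.choice(self.size, max_individuals, replace=False)
        return rows

    def _run_froh(
        self, eq: np.ndarray, unit_bp: int, genome_len: int, min_lengths: tuple[int, ...]
    ) -> dict[int, float]:
        """Mean per-individual fraction of genome in runs of True >= threshold.

        ``eq`` is (individuals, genes); runs never cross chromosome bounds
        and a run of k genes spans k * unit_bp on the chosen coordinate.
        """
        chrom = self._chrom
        chrom_start = np.r_[True, chrom[1:] != chrom[:-1]]
        chrom_end = np.r_[chrom[1:] != chrom[:-1], True]
        prev = np.zeros_like(eq)
        prev[:, 1:] = eq[:, :-1]
        prev[:, chrom_start] = False
        nxt = np.zeros_like(eq)
        nxt[:, :-1] = eq[:, 1:]
        nxt[:, chrom_end] = False
        s_rows, s_cols = np.nonzero(eq & ~prev)
        _, e_cols = np.nonzero(eq & ~nxt)
        lengths = (e_cols - s_cols + 1) * unit_bp
        out = {}
        for thr in min_lengths:
            ok = lengths >= thr
            per_ind = np.bincount(s_rows[ok], weights=lengths[ok], minlength=eq.shape[0])
            out[thr] = float(per_ind.mean() / genome_len)
        return out

    def froh(
        self,
        min_lengths: tuple[int, ...] = (500_000, 1_000_000),
        max_individuals: int | None = 100,
    ) -> dict[int, float]:
        """Mean label-based (IBD) F_ROH per minimum segment length (bp).

        ROH are maximal runs of genes at which the two haplotypes carry the
        same ancestry label; a run of k genes spans k gene blocks on the
        physical coordinate (gene plus intergenic spacer). With the default
        rolling label refresh this measures autozygosity due to recent
        shared ancestry.
        """
        if self.size == 0:
            return {thr: float("nan") for thr in min_lengths}
        anc = self.anc[self._sample_rows(max_individuals)]
        eq = anc[:, 0, :] == anc[:, 1, :]
        return self._run_froh(eq, self.layout.unit_bp, self.layout.genome_length_bp, min_lengths)

    def froh_genotype(
        self,
        min_lengths: tuple[int, ...] = (500_000, 1_000_000),
        max_individuals: int | None = 100,
    ) -> dict[int, float]:
        """Mean genotype-based F_ROH on the concatenated coding coordinate.

        ROH here are maximal runs of genes carrying no heterozygous site,
        the operational definition used on sequence data; run lengths and
        the genome length L count coding sequence only. Unlike the
        label-based measure this responds to standing diversity, collapsing
        when the heterozygous-site density rises above ~1 per threshold
        window (the mechanism by which a population expansion erases the
        bottleneck's ROH signal).
        """
        if self.size == 0:
            return {thr: float("nan") for thr in min_lengths}
        rows = self._sample_rows(max_individuals)
        het = self.mut[rows, 0, :] ^ self.mut[rows, 1, :]  # (n, M)
        het_gene = np.zeros((self.layout.n_genes, rows.size), dtype=bool)
        if self.n_segregating:
            np.logical_or.at(het_gene, self.mut_gene, het.T)
        eq = ~het_gene.T
        return self._run_froh(eq, self.layout.gene_length, self.layout.coding_length, min_lengths)

    def to_genotype_matrix(self):
        """Export segregating mutations as a biallelic genotype matrix.

        Each mutation becomes a site at a deterministic position inside its
        gene on the physical coordinate; genotypes are derived-allele counts.
        """
        from .core import GenotypeMatrix

        m = self.n_segregating
        offsets = np.arange(m) % self.layout.gene_length
        pos = self.mut_gene * self.layout.unit_bp + offsets
        order = np.argsort(pos, kind="stable")
        geno = (self.mut[:, 0, :] + self.mut[:, 1, :]).astype(np.int8)[:, order]
        return GenotypeMatrix(
            genotypes=geno,
            samples=[f"ind{int(i)}" for i in self.ids],
            chrom=self._chrom[self.mut_gene[order]].astype(str),
            pos=pos[order],
            ref=np.full(m, "A"),
            alt=np.full(m, "G"),
        )

    def load_by_class(self) -> pd.DataFrame:
        """Mean realized and masked load per deleterious class.

        Realized load is 2*hom / (2*hom + het) averaged over individuals
        (with fixed derived substitutions counting as homozygous in
        everyone); masked load is its complement on the same denominator.
        """
        hom = self.mut[:, 0, :] & self.mut[:, 1, :]
        het = self.mut[:, 0, :] ^ self.mut[:, 1, :]
        rows = []
        class_sets = [(name, self.mut_class == code) for name, code in _CLASS_CODE.items() if code > 0]
        class_sets.append(("all_deleterious", self.mut_class > 0))
        for name, mask in class_sets:
            if name == "all_deleterious":
                fixed = int(self.fixed_per_class[1:].sum())
            else:
                fixed = int(self.fixed_per_class[_CLASS_CODE[name]])
            nh = hom[:, mask].sum(axis=1) + fixed
            nt = het[:, mask].sum(axis=1)
            denom = 2.0 * nh + nt
            with np.errstate(invalid="ignore", divide="ignore"):
                realized = np.where(denom > 0, 2.0 * nh / np.maximum(denom, 1e-300), 0.0)
                masked = np.where(denom > 0, nt / np.maximum(denom, 1e-300), 0.0)
            rows.append(
                {
                    "class": name,
                    "n_hom_mean": float(nh.mean()) if nh.size else 0.0,
                    "n_het_mean": float(nt.mean()) if nt.size else 0.0,
                    "realized": float(realized.mean()) if realized.size else 0.0,
                    "masked": float(masked.mean()) if masked.size else 0.0,
                }
            )
        return pd.DataFrame(rows)


def merge_populations(a: Population, b: Population, n_shared_columns: int) -> Population:
    """Combine two populations evolved separately from a common origin.

    Both must share the layout and their first ``n_shared_columns``
    mutation columns (columns only appended since the separation, i.e.
    stepped with mutation cleanup disabled); columns appended independently
    in each population are kept distinct in the merged table. Individual
    ids are reassigned and pedigree back-references cleared.
    """
    if a.layout is not b.layout and a.layout != b.layout:
        raise ValueError("populations must share a genome layout")
    m0 = n_shared_columns
    if m0 > min(a.n_segregating, b.n_segregating):
        raise ValueError("n_shared_columns exceeds a population's column count")
    ka, kb = a.n_segregating - m0, b.n_segregating - m0
    new = a.copy()
    n_a, n_b = a.size, b.size
    for name in ("age", "sex", "subpop", "lineage_frac", "log_fitness",
                 "next_slot", "last_bred"):
        setattr(new, name, np.concatenate([getattr(a, name), getattr(b, name)]))
    new.mother = np.full(n_a + n_b, -1, dtype=np.int64)
    new.father = np.full(n_a + n_b, -1, dtype=np.int64)
    new.ids = np.arange(n_a + n_b, dtype=np.int64)
    new._next_id = n_a + n_b
    new.mate = np.concatenate([a.mate, np.where(b.mate >= 0, b.mate + n_a, -1)])
    new.paired = np.concatenate([a.paired, np.where(b.paired >= 0, b.paired + n_a, -1)])
    new.anc = np.concatenate([a.anc, b.anc])
    new._next_label = max(a._next_label, b._next_label)
    mut = np.zeros((n_a + n_b, 2, m0 + ka + kb), dtype=bool)
    mut[:n_a, :, : m0 + ka] = a.mut
    mut[n_a:, :, :m0] = b.mut[:, :, :m0]
    mut[n_a:, :, m0 + ka :] = b.mut[:, :, m0:]
    new.mut = mut
    for name in ("mut_s", "mut_h", "mut_gene", "mut_class", "_log_w_hom", "_log_w_het"):
        setattr(new, name, np.concatenate([
            getattr(a, name), getattr(b, name)[m0:]
        ]))
    # fixations were not converted during the separate phase (cleanup
    # disabled), so the shared pre-split counts are carried once
    new.fixed_per_class = a.fixed_per_class.copy()
    new._cleanup_mutations()
    return new


# ------------------------------------------------------------------ scenario runner

@dataclass
class ScenarioResult:
    trajectory: pd.DataFrame
    population: Population
    extinct: bool
    scale: float
    scenario: DemographicScenario
    layout: GenomeLayout


def _record(pop: Population, year: int, phase: str) -> dict:
    fr = pop.froh()
    fg = pop.froh_genotype()
    row = {
        "year": year,
        "phase": phase,
        "n": pop.size,
        "froh_500kb": fr[500_000],
        "froh_1mb": fr[1_000_000],
        "froh_gt_500kb": fg[500_000],
        "froh_gt_1mb": fg[1_000_000],
        "n_segregating": pop.n_segregating,
    }
    if pop.size:
        for rec in pop.load_by_class().to_dict("records"):
            row[f"realized_{rec['class']}"] = rec["realized"]
            row[f"masked_{rec['class']}"] = rec["masked"]
    return row


def run_scenario(
    scenario: DemographicScenario = GIBBON_SCENARIO,
    layout: GenomeLayout | None = None,
    dfe: DfeParams | None = None,
    seed: int | np.random.Generator = 0,
    scale: float = 1.0,
    record_every: int | None = None,
    stop_before_split: bool = False,
    **pop_kwargs,
) -> ScenarioResult:
    """Simulate a demographic scenario and record inbreeding/load trajectories.

    ``scale`` applies the standard desk rescaling: gene number, K values
    and epoch durations are multiplied by q while per-site rates and the
    fitness effect of s are divided by q (see :meth:`GenomeLayout.scaled`
    and :class:`DfeParams`); a DFE passed with an explicit ``s_scale`` is
    left untouched. Extinction before the scenario end truncates the
    trajectory and sets the extinct flag rather than raising.
    """
    layout = (layout or GenomeLayout()).scaled(scale)
    dfe = dfe or DfeParams()
    if scale != 1.0 and dfe.s_scale == 1.0:
        dfe = replace(dfe, s_scale=1.0 / scale)
    scn = scenario.scaled(scale)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = Population.founders(scn.epochs[0].k, layout, dfe, rng, **pop_kwargs)
    if record_every is None:
        record_every = max(1, scn.total_years // 150)
    records: list[dict] = []
    year = 0
    extinct = False

    def phase_years(phase: str, years: int, k_fn) -> bool:
        nonlocal year, extinct
        for t in range(years):
            pop.step(year, k_fn(t))
            if pop.size == 0:
                extinct = True
                records.append(_record(pop, year, phase))
                return False
            if year % record_every == 0 or t == years - 1:
                records.append(_record(pop, year, phase))
            year += 1
        return True

    scaled_s = dfe.s_scale
    alive = True
    for i, epoch in enumerate(scn.epochs):
        pop.set_selection_scale(scaled_s if epoch.k_is_scaled else 1.0)
        alive = phase_years(f"epoch_{i}", epoch.duration_years, lambda t, e=epoch: {0: e.k_at(t)})
        if not alive:
            break
    if alive and scn.split is not None and not stop_before_split:
        pop.split_lineages()
        pop.set_selection_scale(scaled_s if scn.split.k_is_scaled else 1.0)
        last = scn.epochs[-1]
        k_pre_split = last.k_end if last.k_end is not None else last.k
        alive = phase_years(
            "split", scn.split.duration_years, lambda t: scn.split.k_at(t, k_pre_split)
        )
    return ScenarioResult(
        trajectory=pd.DataFrame(records),
        population=pop,
        extinct=extinct,
        scale=scale,
        scenario=scn,
        layout=layout,
    )
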