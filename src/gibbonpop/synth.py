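"""Synthetic genotype, duplicate-library, two-lineage and pedigree generators.

Every generator is a pure function of its configuration and seed and returns,
next to the data, a *truth record* from which each injected artifact (allele
dropout, library error, crossover) can be recomputed exactly. This is what
makes the downstream QC and recombination estimators testable without any
real sequencing data.

The dropout model follows the phenomenon seen in low-input fecal DNA: at a
heterozygous genotype each of the two alleles is independently unobserved
with probability ``ado_rate``; if one allele survives the genotype is emitted
as the homozygote of the surviving allele, and if neither survives the call
is missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PhasedPedigree, TrioSet

__all__ = [
    "SynthConfig",
    "gen_trios",
    "gen_duplicate_libraries",
    "gen_two_lineage_panel",
    "gen_phased_pedigree",
]


class DegenerateDistributionError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters shared by the synthetic generators.

    ``maf_distribution`` supports ``"uniform"`` (params: low, high) and
    ``"beta"`` (params: a, b); the default uniform [0.05, 0.5] mirrors
    typical minor-allele-frequency filters applied to the real data.
    ``depth_distribution`` supports ``"poisson"`` (params: mean) and
    ``"constant"`` (params: value).
    """

    n_sites: int = 1000
    n_individuals: int = 10
    maf_distribution: str = "uniform"
    maf_params: tuple[float, ...] = (0.05, 0.5)
    ado_rate: float = 0.0
    genotype_error_rate: float = 0.0
    depth_distribution: str = "poisson"
    depth_params: tuple[float, ...] = (10.0,)
    split_generations: int = 0
    lineage_ne: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_individuals <= 0:
            raise ValueError("n_sites and n_individuals must be positive")
        for name in ("ado_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.split_generations < 0:
            raise ValueError("split_generations must be >= 0")
        if self.lineage_ne <= 0:
            raise ValueError("lineage_ne must be positive")


def _draw_mafs(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.maf_distribution == "uniform":
        low, high = cfg.maf_params
        freqs = rng.uniform(low, high, size=cfg.n_sites)
    elif cfg.maf_distribution == "beta":
        a, b = cfg.maf_params
        freqs = rng.beta(a, b, size=cfg.n_sites)
    else:
        raise ValueError(f"unknown maf_distribution {cfg.maf_distribution!r}")
    if np.all((freqs <= 0.0) | (freqs >= 1.0)):
        raise DegenerateDistributionError(
            f"maf_distribution {cfg.maf_distribution}{cfg.maf_params} yields only fixed sites"
        )
    return freqs


def _draw_depth(cfg: SynthConfig, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    if cfg.depth_distribution == "poisson":
        return rng.poisson(cfg.depth_params[0], size=shape).astype(np.int32)
    if cfg.depth_distribution == "constant":
        return np.full(shape, int(cfg.depth_params[0]), dtype=np.int32)
    raise ValueError(f"unknown depth_distribution {cfg.depth_distribution!r}")


def _hwe_genotypes(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, freqs[None, :], size=(n, freqs.size)).astype(np.int8)


def _site_table(cfg: SynthConfig) -> dict[str, np.ndarray]:
    return {
        "chrom": np.asarray(["1"] * cfg.n_sites),
        "pos": np.arange(cfg.n_sites, dtype=np.int64) * 100,
        "ref": np.asarray(["A"] * cfg.n_sites),
        "alt": np.asarray(["G"] * cfg.n_sites),
    }


def _inject_ado(
    genotypes: np.ndarray, ado_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply per-allele dropout at heterozygous genotypes.

    Returns (observed, drop_ref_mask, drop_alt_mask); the masks cover the
    full genotype array and are True only at het calls with a dropped allele.
    """
    het = genotypes == 1
    drop_ref = het & (rng.random(genotypes.shape) < ado_rate)
    drop_alt = het & (rng.random(genotypes.shape) < ado_rate)
    observed = genotypes.copy()
    observed[drop_ref & ~drop_alt] = 2  # surviving alt allele
    observed[drop_alt & ~drop_ref] = 0  # surviving ref allele
    observed[drop_ref & drop_alt] = MISSING
    return observed, drop_ref, drop_alt


_MEMBER_NAMES = np.asarray(["father", "mother", "offspring"])


def gen_trios(cfg: SynthConfig) -> tuple[TrioSet, pd.DataFrame]:
    """Generate ``cfg.n_individuals`` trios with injected allele dropout.

    Offspring genotypes are Mendelian-consistent before dropout injection.
    The truth record lists one row per genotype at which at least one allele
    was dropped, with columns trio/member/site/true_gt/observed_gt/n_dropped.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _draw_mafs(cfg, rng)
    n = cfg.n_individuals
    father = _hwe_genotypes(freqs, n, rng)
    mother = _hwe_genotypes(freqs, n, rng)
    # Each parent transmits one allele; P(alt transmitted) = genotype / 2.
    t_f = (rng.random(father.shape) < father / 2.0).astype(np.int8)
    t_m = (rng.random(mother.shape) < mother / 2.0).astype(np.int8)
    offspring = t_f + t_m
    true = np.stack([father, mother, offspring], axis=1)  # (n, 3, S)
    observed, drop_ref, drop_alt = _inject_ado(true, cfg.ado_rate, rng)

    any_drop = drop_ref | drop_alt
    trio_i, member_i, site_i = np.nonzero(any_drop)
    truth = pd.DataFrame(
        {
            "trio": trio_i,
            "member": _MEMBER_NAMES[member_i],
            "site": site_i,
            "true_gt": true[trio_i, member_i, site_i],
            "observed_gt": observed[trio_i, member_i, site_i],
            "n_dropped": (
                drop_ref[trio_i, member_i, site_i].astype(int)
                + drop_alt[trio_i, member_i, site_i].astype(int)
            ),
        }
    )
    truth.attrs["n_true_het_genotypes"] = int((true == 1).sum())
    trios = TrioSet(
        genotypes=observed,
        depth=_draw_depth(cfg, true.shape, rng),
        trio_ids=[(f"F{i}", f"M{i}", f"O{i}") for i in range(n)],
        **_site_table(cfg),
    )
    return trios, truth


def gen_duplicate_libraries(
    cfg: SynthConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Two genotype matrices from duplicate libraries of the same individuals.

    Each library call is independently wrong with probability
    ``genotype_error_rate``; an erroneous call is replaced by one of the two
    other genotype states uniformly at random. The truth record contains one
    row per (individual, site) where either library deviates from the true
    genotype, with a ``discordant`` column marking library-vs-library
    disagreement.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _draw_mafs(cfg, rng)
    true = _hwe_genotypes(freqs, cfg.n_individuals, rng)

    def corrupt(g: np.ndarray) -> np.ndarray:
        err = rng.random(g.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=g.shape)  # +1 or +2 mod 3 != identity
        out = g.copy()
        out[err] = ((g[err] + shift[err]) % 3).astype(np.int8)
        return out

    lib_a, lib_b = corrupt(true), corrupt(true)
    ind_i, site_i = np.nonzero((lib_a != true) | (lib_b != true))
    truth = pd.DataFrame(
        {
            "individual": ind_i,
            "site": site_i,
            "true_gt": true[ind_i, site_i],
            "lib_a": lib_a[ind_i, site_i],
            "lib_b": lib_b[ind_i, site_i],
            "discordant": lib_a[ind_i, site_i] != lib_b[ind_i, site_i],
        }
    )
    samples = [f"ind{i}" for i in range(cfg.n_individuals)]
    sites = _site_table(cfg)
    make = lambda g: GenotypeMatrix(  # noqa: E731
        genotypes=g,
        samples=samples,
        depth=_draw_depth(cfg, g.shape, rng),
        **sites,
    )
    return make(lib_a), make(lib_b), truth


def gen_two_lineage_panel(cfg: SynthConfig) -> GenotypeMatrix:
    """Panel of two lineages drifted apart for ``split_generations``.

    Allele frequencies drift independently in each lineage as a
    Wright-Fisher binomial walk of size ``2 * lineage_ne`` per generation,
    so between-lineage divergence grows with the split time.
    """
    if cfg.n_individuals < 4:
        raise ValueError("need at least 2 individuals per lineage (n_individuals >= 4)")
    rng = np.random.default_rng(cfg.seed)
    ancestral = _draw_mafs(cfg, rng)

    def drift(freqs: np.ndarray) -> np.ndarray:
        f = freqs.copy()
        two_n = 2 * cfg.lineage_ne
        for _ in range(cfg.split_generations):
            f = rng.binomial(two_n, f) / two_n
        return f

    n_a = cfg.n_individuals // 2
    n_b = cfg.n_individuals - n_a
    g_a = _hwe_genotypes(drift(ancestral), n_a, rng)
    g_b = _hwe_genotypes(drift(ancestral), n_b, rng)
    g = np.vstack([g_a, g_b])
    return GenotypeMatrix(
        genotypes=g,
        samples=[f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)],
        depth=_draw_depth(cfg, g.shape, rng),
        lineage=np.asarray(["A"] * n_a + ["B"] * n_b),
        **_site_table(cfg),
    )


def gen_phased_pedigree(
    n_meioses: int,
    crossover_rate: float,
    n_loci: int,
    seed: int = 0,
    locus_spacing_bp: int = 1000,
) -> tuple[PhasedPedigree, np.ndarray]:
    """Phased parent and offspring gametes with known crossover positions.

    Between each pair of adjacent loci the transmitted haplotype switches
    with probability ``crossover_rate``. Returns the pedigree and the truth
    crossover indicator of shape (n_meioses, n_loci - 1).
    """
    if n_loci < 2:
        raise ValueError("n_loci must be >= 2 (no adjacent locus pairs otherwise)")
    if not 0.0 <= crossover_rate <= 1.0:
        raise ValueError("crossover_rate outside [0, 1]")
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    rng = np.random.default_rng(seed)
    start = rng.integers(0, 2, size=(n_meioses, 1))
    switches = rng.random((n_meioses, n_loci - 1)) < crossover_rate
    source = np.hstack([start, (start + np.cumsum(switches, axis=1)) % 2]).astype(np.int8)
    parent = np.vstack([np.zeros(n_loci, dtype=np.int8), np.ones(n_loci, dtype=np.int8)])
    gametes = parent[source, np.arange(n_loci)[None, :]]
    ped = PhasedPedigree(
        positions=(np.arange(n_loci, dtype=np.int64) + 1) * locus_spacing_bp,
        parent_haplotypes=parent,
        gametes=gametes,
    )
    return ped, switches
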