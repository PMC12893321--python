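"""Shared containers for genotype and pedigree data.

Genotypes are coded as counts of the alternate allele: 0 (hom ref),
1 (het), 2 (hom alt), with :data:`MISSING` (-1) for uncalled genotypes.
Half-called genotypes are treated as missing. Internal coordinates are
0-based half-open; VCF ingestion converts from 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Code for a missing (uncalled) genotype.
MISSING = -1

HOM_REF, HET, HOM_ALT = 0, 1, 2


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites, with optional per-genotype depth."""

    genotypes: np.ndarray  # (n_individuals, n_sites) int8
    samples: list[str]
    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 0-based
    ref: np.ndarray  # (n_sites,) str
    alt: np.ndarray  # (n_sites,) str
    depth: np.ndarray | None = None  # (n_individuals, n_sites) int
    lineage: np.ndarray | None = None  # (n_individuals,) str labels

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D individuals x sites array")
        n_ind, n_sites = self.genotypes.shape
        if len(self.samples) != n_ind:
            raise ValueError(
                f"{len(self.samples)} sample names for {n_ind} genotype rows"
            )
        for name in ("chrom", "pos", "ref", "alt"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_sites,):
                raise ValueError(f"{name} must have one entry per site")
            setattr(self, name, arr)
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.genotypes.shape:
                raise ValueError("depth must match genotypes shape")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.genotypes != MISSING

    def alt_allele_counts(self) -> np.ndarray:
        """Per-site alternate allele count over called genotypes."""
        g = np.where(self.called(), self.genotypes, 0)
        return g.sum(axis=0)

    def called_chromosomes(self) -> np.ndarray:
        """Per-site number of called allele copies (2 x called genotypes)."""
        return 2 * self.called().sum(axis=0)


# Member order within a trio.
FATHER, MOTHER, OFFSPRING = 0, 1, 2


@dataclass
class TrioSet:
    """Parent-parent-offspring genotype triples over shared sites.

    ``genotypes`` has shape (n_trios, 3, n_sites); the member axis is
    ordered father, mother, offspring.
    """

    genotypes: np.ndarray  # (n_trios, 3, n_sites) int8
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    depth: np.ndarray | None = None  # (n_trios, 3, n_sites)
    trio_ids: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[1] != 3:
            raise ValueError("genotypes must have shape (n_trios, 3, n_sites)")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.genotypes.shape:
                raise ValueError("depth must match genotypes shape")

    @property
    def n_trios(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[2]


@dataclass
class PhasedPedigree:
    """Phased parental haplotypes and offspring gametes for crossover counting.

    Every locus is informative: the two parental haplotypes carry distinct
    allele codes, so each transmitted allele identifies its source haplotype.
    """

    positions: np.ndarray  # (n_loci,) bp, ascending
    parent_haplotypes: np.ndarray  # (2, n_loci) allele codes
    gametes: np.ndarray  # (n_meioses, n_loci) allele codes

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.parent_haplotypes = np.asarray(self.parent_haplotypes)
        self.gametes = np.atleast_2d(np.asarray(self.gametes))
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("locus positions must be strictly increasing")
        if np.any(self.parent_haplotypes[0] == self.parent_haplotypes[1]):
            raise ValueError("parental haplotypes must differ at every locus")

    @property
    def n_meioses(self) -> int:
        return self.gametes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.positions.shape[0]

    def source_haplotypes(self) -> np.ndarray:
        """(n_meioses, n_loci) indicator of the parental haplotype of origin."""
        src = np.full(self.gametes.shape, -1, dtype=np.int8)
        for h in (0, 1):
            src[self.gametes == self.parent_haplotypes[h][None, :]] = h
        if np.any(src < 0):
            raise ValueError("gamete allele matches neither parental haplotype")
        return src
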