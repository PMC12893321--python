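"""Population-genetic statistics: heterozygosity, genetic load, F_ROH,
GC4 recombination proxy, Grantham-based classification, and pedigree-based
crossover counting.

Genetic load is expressed per the ratio of derived homozygous allele copies,

    realized = 2 * n_hom_derived / (2 * n_hom_derived + n_het),

the fitness cost already exposed in homozygotes, and its complement on the
same denominator, the *masked* load still hidden in heterozygotes. Derived
alleles are polarized as the minor allele (the major-allele homozygote is
taken as the ancestral state); no outgroup polarization is attempted.

F_ROH is the summed length of runs of homozygosity at or above a minimum
length divided by the genome length, an individual inbreeding measure.
GC4 — the GC fraction at fourfold-degenerate third codon positions — serves
as a proxy for the local recombination rate via GC-biased gene conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .core import HET, HOM_ALT, HOM_REF, MISSING, PhasedPedigree

__all__ = [
    "LoadEstimate",
    "RohProfile",
    "Gc4Record",
    "genome_heterozygosity",
    "windowed_heterozygosity",
    "expected_heterozygosity",
    "polarize_minor",
    "genetic_load",
    "classify_missense",
    "froh",
    "gc4",
    "partition_gc4",
    "pedigree_recombination_rate",
]

GRANTHAM_MIN, GRANTHAM_MAX = 5, 215
GRANTHAM_DELETERIOUS_THRESHOLD = 150


# ---------------------------------------------------------------- heterozygosity

def genome_heterozygosity(n_het_sites: int, effective_length: int) -> float:
    """Heterozygous sites per base pair of effectively covered genome."""
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    if n_het_sites < 0:
        raise ValueError("n_het_sites must be non-negative")
    h = n_het_sites / effective_length
    if h > 1:
        raise ValueError("more heterozygous sites than effective length")
    return h


def windowed_heterozygosity(
    positions: np.ndarray,
    is_het: np.ndarray,
    window_size: int = 1_000_000,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Sliding (non-overlapping) window heterozygosity along one chromosome."""
    positions = np.asarray(positions)
    is_het = np.asarray(is_het, dtype=bool)
    length = int(genome_length if genome_length is not None else positions.max() + 1)
    n_windows = int(np.ceil(length / window_size))
    idx = np.minimum(positions // window_size, n_windows - 1)
    counts = np.bincount(idx[is_het], minlength=n_windows)
    starts = np.arange(n_windows) * window_size
    sizes = np.minimum(starts + window_size, length) - starts
    return pd.DataFrame(
        {"start": starts, "end": starts + sizes, "n_het": counts, "het": counts / sizes}
    )


def expected_heterozygosity(p):
    """Expected heterozygosity He = 2 p (1 - p), p the major-allele frequency."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    he = 2.0 * p * (1.0 - p)
    return float(he) if he.ndim == 0 else he


# ---------------------------------------------------------------- genetic load

@dataclass
class LoadEstimate:
    """Realized and masked genetic load from derived-allele genotype counts."""

    n_hom_derived: int
    n_het: int
    class_label: str | None = None

    @property
    def defined(self) -> bool:
        return (self.n_hom_derived + self.n_het) > 0

    @property
    def realized(self) -> float:
        if not self.defined:
            return 0.0
        d = 2 * self.n_hom_derived
        return d / (d + self.n_het)

    @property
    def masked(self) -> float:
        if not self.defined:
            return 0.0
        return self.n_het / (2 * self.n_hom_derived + self.n_het)


def polarize_minor(genotypes: np.ndarray) -> np.ndarray:
    """Per-site flag: True where the ALT allele is the minor (derived) allele.

    Ties at frequency 0.5 keep ALT as derived. Missing genotypes are
    excluded from the frequency computation.
    """
    g = np.atleast_2d(np.asarray(genotypes))
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    return freq <= 0.5


def genetic_load(
    genotypes: np.ndarray,
    derived_is_alt: np.ndarray | None = None,
    class_label: str | None = None,
) -> LoadEstimate:
    """Pooled load estimate over a (individuals x sites) genotype array.

    ``derived_is_alt`` gives the derived-allele polarity per site; when
    omitted the minor allele is taken as derived. A sample without any
    derived allele yields a defined-but-flagged zero estimate
    (``LoadEstimate.defined`` is False), not an error.
    """
    g = np.atleast_2d(np.asarray(genotypes))
    if derived_is_alt is None:
        derived_is_alt = polarize_minor(g)
    derived_is_alt = np.asarray(derived_is_alt, dtype=bool)
    hom_derived = np.where(derived_is_alt[None, :], g == HOM_ALT, g == HOM_REF)
    return LoadEstimate(
        n_hom_derived=int(hom_derived.sum()),
        n_het=int((g == HET).sum()),
        class_label=class_label,
    )


def classify_missense(grantham_score: int) -> str:
    """Classify a missense change by Grantham distance: >=150 is deleterious."""
    if not GRANTHAM_MIN <= grantham_score <= GRANTHAM_MAX:
        raise ValueError(
            f"Grantham score {grantham_score} outside [{GRANTHAM_MIN}, {GRANTHAM_MAX}]"
        )
    return "deleterious" if grantham_score >= GRANTHAM_DELETERIOUS_THRESHOLD else "benign"


# ---------------------------------------------------------------- F_ROH

@dataclass
class RohProfile:
    segments: list[tuple[str, int, int]]
    min_length: int
    froh: float


def froh(
    segments: list[tuple[str, int, int]],
    min_length: int,
    genome_length: int,
) -> RohProfile:
    """F_ROH = sum of ROH segment lengths >= min_length over genome length.

    Segments are (chromosome, start, end) in bp, 0-based half-open, sorted
    and non-overlapping within each chromosome.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_chrom: dict[str, int] = {}
    total = 0
    for chrom, start, end in segments:
        if end <= start:
            raise ValueError(f"empty or inverted segment ({chrom}, {start}, {end})")
        if chrom in by_chrom and start < by_chrom[chrom]:
            raise ValueError(f"overlapping or unsorted ROH segments on {chrom}")
        by_chrom[chrom] = end
        if end - start >= min_length:
            total += end - start
    value = total / genome_length
    if value > 1:
        raise ValueError("summed ROH length exceeds genome length")
    return RohProfile(segments=list(segments), min_length=min_length, froh=value)


# ---------------------------------------------------------------- GC4

def _fourfold_prefixes() -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    prefixes = set()
    for first in "ACGT":
        for second in "ACGT":
            p = first + second
            aas = {table.forward_table.get(p + b) for b in "ACGT"}
            if None not in aas and len(aas) == 1:
                prefixes.add(p)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()
_STOPS = frozenset(CodonTable.unambiguous_dna_by_id[1].stop_codons)


@dataclass
class Gc4Record:
    gene_id: str
    n_fourfold_sites: int
    gc4: float | None
    recombination_class: str | None = None


def gc4(coding_sequence: str, gene_id: str = "") -> Gc4Record:
    """GC fraction over third positions of fourfold-degenerate codons.

    The sequence must be an in-frame CDS (length divisible by 3, standard
    genetic code). An internal stop codon is an error; a terminal stop is
    allowed and ignored. Codons containing ambiguity codes are skipped.
    """
    seq = coding_sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    n4 = gc = 0
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        if codon[:2] in FOURFOLD_PREFIXES and codon[2] in "ACGT":
            n4 += 1
            gc += codon[2] in "GC"
    return Gc4Record(
        gene_id=gene_id,
        n_fourfold_sites=n4,
        gc4=(gc / n4) if n4 > 0 else None,
    )


def partition_gc4(records: list[Gc4Record], ties: str = "low") -> tuple[list[Gc4Record], list[Gc4Record]]:
    """Split genes into (high, low) recombination classes at the GC4 median.

    Genes with undefined GC4 are left unclassified. Values equal to the
    median join the low class by default (``ties="high"`` flips this).
    """
    if ties not in ("low", "high"):
        raise ValueError("ties must be 'low' or 'high'")
    defined = [r for r in records if r.gc4 is not None]
    if len(defined) < 2:
        raise ValueError("need >= 2 genes with defined GC4")
    values = np.array([r.gc4 for r in defined])
    if np.ptp(values) == 0:
        raise ValueError("all GC4 values identical: median split degenerate")
    median = float(np.median(values))
    high, low = [], []
    for r in defined:
        is_high = r.gc4 > median if ties == "low" else r.gc4 >= median
        r.recombination_class = "high" if is_high else "low"
        (high if is_high else low).append(r)
    return high, low


# ---------------------------------------------------------------- pedigree recombination

def pedigree_recombination_rate(
    phased: PhasedPedigree,
    region: tuple[int, int] | None = None,
) -> float:
    """Crossovers per adjacent phased-allele pair within a bp region.

    A crossover is counted between two neighbouring informative loci when
    the transmitted alleles derive from different parental haplotypes
    (parent AB/ab transmitting Ab or aB).
    """
    source = phased.source_haplotypes()
    if region is not None:
        lo, hi = region
        keep = (phased.positions >= lo) & (phased.positions < hi)
        source = source[:, keep]
    if source.shape[1] < 2:
        raise ValueError("fewer than 2 informative loci in region")
    switches = source[:, 1:] != source[:, :-1]
    return float(switches.sum() / switches.size)
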