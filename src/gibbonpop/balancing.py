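"""Folded site-frequency spectra and a frequency-clustering balancing-selection scan.

Balancing selection (e.g. heterozygote advantage) keeps variants at
intermediate frequency and, through linkage, gathers *clusters* of
surrounding variants at frequencies similar to the balanced core site. The
score implemented here rewards exactly that clustering: for a core site
with folded frequency f0 and flanking folded frequencies f_i inside a
window, the score is the summed similarity weight in excess of its
genome-wide expectation,

    score = sum_i [ w(f_i, f0) - wbar(f0) ],   w(f, f0) = 1 - |f - f0| / 0.5,

where wbar(f0) is the mean similarity of a random genome site to the core
frequency. The background term makes the score an *excess* clustering
measure: a rare variant surrounded by other rare variants (the neutral
norm) scores near zero, while a cluster of frequencies tighter than the
genome-wide spectrum scores positive. The score is maximal when every
flanking variant sits exactly at the core frequency, and it is invariant
to allele relabelling because only folded (minor-allele) frequencies
enter. The functional form is deliberately pluggable: externally computed
scores can be passed straight to :func:`select_top`, which applies the
top-5% rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix

__all__ = [
    "SiteScore",
    "folded_sfs",
    "folded_sfs_from_matrix",
    "beta_score",
    "beta_scores",
    "select_top",
    "flank_compare",
]


@dataclass
class SiteScore:
    position: int
    folded_frequency: float
    score: float
    selected: bool = False


def folded_sfs(allele_counts: np.ndarray, n_chromosomes: int) -> pd.Series:
    """Folded SFS: counts of segregating sites by minor-allele count.

    Bins run 1 .. floor(n/2) chromosomes; monomorphic sites are excluded
    (with a warning if nothing segregates).
    """
    ac = np.asarray(allele_counts)
    if np.any((ac < 0) | (ac > n_chromosomes)):
        raise ValueError("allele counts outside [0, n_chromosomes]")
    minor = np.minimum(ac, n_chromosomes - ac)
    seg = minor[(ac > 0) & (ac < n_chromosomes)]
    bins = np.arange(1, n_chromosomes // 2 + 1)
    if seg.size == 0:
        warnings.warn("only monomorphic sites: folded SFS is empty", stacklevel=2)
        return pd.Series(np.zeros(bins.size, dtype=int), index=bins, name="n_sites")
    counts = np.bincount(seg, minlength=n_chromosomes // 2 + 1)[1:]
    return pd.Series(counts, index=bins, name="n_sites")


def folded_sfs_from_matrix(gm: GenotypeMatrix) -> pd.Series:
    """Folded SFS of a diploid genotype matrix without missing data."""
    if not gm.called().all():
        raise ValueError("folded SFS over a matrix requires complete genotypes")
    return folded_sfs(gm.alt_allele_counts(), 2 * gm.n_individuals)


def beta_score(
    core_frequency: float,
    flank_frequencies: np.ndarray,
    background_similarity: float = 0.0,
) -> float:
    """Similarity-weighted clustering score of one core site.

    ``background_similarity`` is the expected similarity weight of a random
    genome site to the core frequency (0 gives the raw summed weight). An
    empty flanking set is a baseline score of 0.
    """
    if not 0.0 <= core_frequency <= 0.5:
        raise ValueError("core folded frequency must lie in [0, 0.5]")
    f = np.asarray(flank_frequencies, dtype=float)
    if np.any((f < 0) | (f > 0.5)):
        raise ValueError("folded frequencies must lie in [0, 0.5]")
    if f.size == 0:
        return 0.0
    w = 1.0 - np.abs(f - core_frequency) / 0.5
    return float(np.sum(w - background_similarity))


def _background_similarity(freqs: np.ndarray, cores: np.ndarray) -> np.ndarray:
    """Mean similarity weight of a random genome site to each core frequency.

    Computed in O(n log n) from prefix sums of the sorted frequency vector.
    """
    srt = np.sort(freqs)
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    k = np.searchsorted(srt, cores, side="left")
    total_below = cores * k - csum[k]
    total_above = (csum[-1] - csum[k]) - cores * (srt.size - k)
    mean_abs_dev = (total_below + total_above) / srt.size
    return 1.0 - mean_abs_dev / 0.5


def beta_scores(
    positions: np.ndarray,
    folded_frequencies: np.ndarray,
    window_bp: int = 1000,
) -> np.ndarray:
    """Score every site against its flanking window (``window_bp`` each side).

    The genome-wide folded frequency spectrum of the supplied sites serves
    as the neutral background for the excess-clustering correction.
    """
    pos = np.asarray(positions)
    freq = np.asarray(folded_frequencies, dtype=float)
    if pos.size == 0:
        raise ValueError("empty window: no sites to score")
    if pos.size != freq.size:
        raise ValueError("positions and frequencies must align")
    order = np.argsort(pos, kind="stable")
    pos_s, freq_s = pos[order], freq[order]
    background = _background_similarity(freq, freq_s)
    scores_s = np.empty(pos_s.size)
    lo = np.searchsorted(pos_s, pos_s - window_bp, side="left")
    hi = np.searchsorted(pos_s, pos_s + window_bp, side="right")
    for i in range(pos_s.size):
        flank = np.concatenate([freq_s[lo[i] : i], freq_s[i + 1 : hi[i]]])
        scores_s[i] = beta_score(freq_s[i], flank, background[i])
    scores = np.empty_like(scores_s)
    scores[order] = scores_s
    return scores


def select_top(
    scores: np.ndarray,
    positions: np.ndarray | None = None,
    folded_frequencies: np.ndarray | None = None,
    fraction: float = 0.05,
) -> list[SiteScore]:
    """Mark the top-``fraction`` scoring sites as balancing-selection candidates.

    Exactly ceil(fraction * n) sites are selected; ties at the threshold are
    broken by genomic position (leftmost first).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("no scores to select from")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if positions is None:
        positions = np.arange(n)
    positions = np.asarray(positions)
    if folded_frequencies is None:
        folded_frequencies = np.full(n, np.nan)
    k = int(np.ceil(fraction * n))
    order = np.lexsort((positions, -scores))  # score desc, then position asc
    selected_idx = set(order[:k].tolist())
    return [
        SiteScore(
            position=int(positions[i]),
            folded_frequency=float(folded_frequencies[i]),
            score=float(scores[i]),
            selected=i in selected_idx,
        )
        for i in range(n)
    ]


def flank_compare(gene_rates: pd.DataFrame, flank_size: int = 10_000) -> dict:
    """Compare per-gene recombination rates with their 10-kb flanking regions.

    ``gene_rates`` needs columns gene_id, gene_rate, left_rate, right_rate;
    genes with a missing flank rate are excluded (counted in the report).
    Reports a paired Wilcoxon signed-rank test of gene vs mean flank and a
    paired t test of left vs right flank (flank symmetry).
    """
    required = {"gene_id", "gene_rate", "left_rate", "right_rate"}
    if not required.issubset(gene_rates.columns):
        raise ValueError(f"gene_rates must have columns {sorted(required)}")
    complete = gene_rates.dropna(subset=["gene_rate", "left_rate", "right_rate"])
    n_excluded = len(gene_rates) - len(complete)
    gene = complete["gene_rate"].to_numpy(dtype=float)
    left = complete["left_rate"].to_numpy(dtype=float)
    right = complete["right_rate"].to_numpy(dtype=float)
    flank = (left + right) / 2.0
    diff = gene - flank

    if np.allclose(diff, 0.0):
        wilcoxon = {"statistic": 0.0, "p_value": 1.0}
    else:
        res = stats.wilcoxon(gene, flank)
        wilcoxon = {"statistic": float(res.statistic), "p_value": float(res.pvalue)}
    if np.allclose(left, right):
        lr = {"statistic": 0.0, "p_value": 1.0}
    else:
        t = stats.ttest_rel(left, right)
        lr = {"statistic": float(t.statistic), "p_value": float(t.pvalue)}

    return {
        "n_genes": int(len(complete)),
        "n_excluded": int(n_excluded),
        "flank_size": flank_size,
        "mean_gene_rate": float(gene.mean()) if gene.size else np.nan,
        "mean_flank_rate": float(flank.mean()) if flank.size else np.nan,
        "gene_vs_flank_wilcoxon": wilcoxon,
        "left_vs_right_paired_t": lr,
        "per_gene": complete.assign(flank_rate=flank, gene_minus_flank=diff),
    }
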