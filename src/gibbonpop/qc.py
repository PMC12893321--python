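"""Genotyping-error estimation for noninvasive (fecal) genomic data.

Allele dropout (ADO) is detected from parent-parent-offspring trios through
Mendelian inconsistency: when the parental genotypes are AA and Aa an
offspring aa reveals a dropped allele, and when the parents are AA and aa
any homozygous offspring does. A second, model-free error estimate comes
from genotype discordance between duplicate libraries of the same
individual. The coverage-saturation ("Solow growth") model
``y = a - exp(-b*x + c)`` relates genome coverage y to sequencing data
amount x and is used to plan how much data is worth generating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import FATHER, HET, HOM_ALT, HOM_REF, MISSING, MOTHER, OFFSPRING, GenotypeMatrix, TrioSet

__all__ = [
    "AdoEstimate",
    "SolowFit",
    "count_mendelian_ado",
    "genotype_discordance",
    "ado_depth_profile",
    "fit_solow",
    "NoInformativeSitesError",
    "SolowFitError",
]


class NoInformativeSitesError(ValueError):
    pass


class SolowFitError(RuntimeError):
    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class AdoEstimate:
    """ADO events over informative trio sites; rate = n_events / n_informative."""

    n_events: int
    n_informative: int
    depth_bin: tuple[float, float] | None = None

    @property
    def rate(self) -> float:
        if self.n_informative == 0:
            raise NoInformativeSitesError("no informative sites: rate undefined (not 0)")
        return self.n_events / self.n_informative


def _ado_masks(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(informative, event) masks over (n_trios, n_sites) trio genotypes.

    Informative sites are those where all three members are called and the
    parental pair could expose a dropout under one of the two detection
    rules: (hom x het) or (hom-ref x hom-alt).
    """
    f, m, o = (genotypes[:, i, :] for i in (FATHER, MOTHER, OFFSPRING))
    called = (f != MISSING) & (m != MISSING) & (o != MISSING)

    hom_het = ((f == HOM_REF) & (m == HET)) | ((f == HET) & (m == HOM_REF))
    hom_het_alt = ((f == HOM_ALT) & (m == HET)) | ((f == HET) & (m == HOM_ALT))
    opp_hom = ((f == HOM_REF) & (m == HOM_ALT)) | ((f == HOM_ALT) & (m == HOM_REF))
    informative = called & (hom_het | hom_het_alt | opp_hom)

    # AA x Aa -> aa (and the mirrored aa x Aa -> AA); AA x aa -> AA or aa.
    event = called & (
        (hom_het & (o == HOM_ALT))
        | (hom_het_alt & (o == HOM_REF))
        | (opp_hom & (o != HET))
    )
    return informative, event


def count_mendelian_ado(trios: TrioSet) -> AdoEstimate:
    """Count ADO events under the two Mendelian-inconsistency rules."""
    informative, event = _ado_masks(trios.genotypes)
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise NoInformativeSitesError(
            "no informative trio sites (all-called with a detecting parental pair)"
        )
    return AdoEstimate(n_events=int(event.sum()), n_informative=n_inf)


def genotype_discordance(dup_a: GenotypeMatrix, dup_b: GenotypeMatrix) -> float:
    """Fraction of jointly-called genotypes that differ between duplicates."""
    if dup_a.genotypes.shape != dup_b.genotypes.shape:
        raise ValueError("duplicate matrices must share individuals and sites")
    both = dup_a.called() & dup_b.called()
    n = int(both.sum())
    if n == 0:
        raise ValueError("no jointly-called genotypes: discordance undefined")
    return float((dup_a.genotypes[both] != dup_b.genotypes[both]).sum() / n)


def ado_depth_profile(
    trios: TrioSet,
    depth_bins: list[float],
    tolerance: float = 0.005,
    binning: str = "site",
) -> tuple[list[AdoEstimate], float | None]:
    """Per-depth-bin ADO estimates and the depth at which the rate plateaus.

    ``depth_bins`` are bin edges; site depth is the minimum depth across the
    three trio members (``binning="site"``) or the trio mean
    (``binning="mean"``). The plateau is the left edge of the first bin
    beyond which the absolute rate change between consecutive non-empty bins
    stays below ``tolerance``; ``None`` if the profile never settles.
    """
    if trios.depth is None:
        raise ValueError("trio set has no depth information")
    if binning == "site":
        depth = trios.depth.min(axis=1)
    elif binning == "mean":
        depth = trios.depth.mean(axis=1)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    informative, event = _ado_masks(trios.genotypes)

    edges = np.asarray(depth_bins, dtype=float)
    estimates: list[AdoEstimate] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (depth >= lo) & (depth < hi)
        estimates.append(
            AdoEstimate(
                n_events=int(event[in_bin].sum()),
                n_informative=int(informative[in_bin].sum()),
                depth_bin=(float(lo), float(hi)),
            )
        )
    filled = [e for e in estimates if e.n_informative > 0]
    plateau = None
    for i, est in enumerate(filled):
        later = filled[i:]
        deltas = [abs(b.rate - a.rate) for a, b in zip(later[:-1], later[1:])]
        if all(d < tolerance for d in deltas):
            plateau = est.depth_bin[0]
            break
    return estimates, plateau


@dataclass
class SolowFit:
    """Fitted coverage-saturation curve y = a - exp(-b*x + c).

    ``a`` is the maximal genome coverage, ``b`` the saturation rate constant
    and ``c`` an offset; ``tipping_point`` is the data amount beyond which
    the marginal coverage gain dy/dx drops below the requested tolerance.
    """

    a: float
    b: float
    c: float
    residual: float
    tipping_point: float
    residual_trace: list[float] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a - np.exp(-self.b * np.asarray(x, dtype=float) + self.c)


def fit_solow(
    amounts: np.ndarray,
    coverages: np.ndarray,
    marginal_gain: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> SolowFit:
    """Least-squares fit of the coverage-saturation model.

    Requires >=3 distinct data amounts and coverages in [0, 1]. The fit is
    seeded by linearising ``log(a - y) = -b*x + c`` at a grid of candidate
    ``a`` values and polished with a bounded quasi-Newton minimisation of
    the sum of squared errors; the best-so-far residual per iteration is
    recorded in ``residual_trace`` (non-increasing by construction).
    """
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(coverages, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct data amounts")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("coverages must lie in [0, 1]")
    if np.ptp(y) < 1e-12:
        raise SolowFitError(f"constant coverage {y[0]:.4g}: saturation model degenerate")

    def sse(params: np.ndarray) -> float:
        a, b, c = params
        r = y - (a - np.exp(-b * x + c))
        return float(r @ r)

    best = None
    ymax = y.max()
    for a0 in np.linspace(min(ymax + 1e-4, 1.0), 1.0, 8):
        gap = np.clip(a0 - y, 1e-10, None)
        slope, intercept = np.polyfit(x, np.log(gap), 1)
        p0 = np.array([a0, max(-slope, 1e-6), intercept])
        if best is None or sse(p0) < sse(best):
            best = p0

    trace: list[float] = []

    def record(params: np.ndarray) -> None:
        val = sse(params)
        trace.append(min(val, trace[-1]) if trace else val)

    record(best)
    res = minimize(
        sse,
        best,
        method="L-BFGS-B",
        bounds=[(1e-6, 1.0), (1e-9, None), (None, None)],
        callback=record,
        options={"maxiter": max_iter, "ftol": tol},
    )
    if not res.success and res.fun > 1e-6:
        raise SolowFitError(f"saturation fit did not converge: {res.message}", residual=float(res.fun))
    a, b, c = res.x
    # dy/dx = b * exp(-b*x + c) < marginal_gain  =>  x > (c + log(b / marginal_gain)) / b
    tipping = (c + np.log(b / marginal_gain)) / b if b > 0 else np.inf
    return SolowFit(
        a=float(a),
        b=float(b),
        c=float(c),
        residual=float(res.fun),
        tipping_point=float(tipping),
        residual_trace=trace,
    )
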