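import itertools

import numpy as np
import pytest

from gibbonpop.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_cfg():
    return SynthConfig(n_sites=10_000, n_individuals=10, ado_rate=0.05, seed=7)


def binomial_ci(p: float, n: int, z: float = 2.576) -> tuple[float, float]:
    """Normal-approximation binomial CI (z=2.576 for 99%)."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


def expected_ado_detection(ado: float, maf_low=0.05, maf_high=0.5, grid=400):
    """Enumeration oracle: expected Mendelian-detection rate under the
    generator's model (HWE parents, per-allele dropout at heterozygotes),
    integrated over the uniform minor-allele-frequency distribution."""
    MISS = -1

    def observed_dist(g):
        if g == 1:
            return {1: (1 - ado) ** 2, 0: ado * (1 - ado), 2: ado * (1 - ado), MISS: ado**2}
        return {g: 1.0}

    e_inf = e_evt = 0.0
    for f in np.linspace(maf_low, maf_high, grid):
        hwe = {0: (1 - f) ** 2, 1: 2 * f * (1 - f), 2: f**2}
        for tf, tm in itertools.product((0, 1, 2), repeat=2):
            p_parents = hwe[tf] * hwe[tm]
            # Mendelian offspring distribution
            off = {}
            for a, b in itertools.product((0, 1), repeat=2):
                pa = tf / 2 if a else 1 - tf / 2
                pb = tm / 2 if b else 1 - tm / 2
                off[a + b] = off.get(a + b, 0.0) + pa * pb
            for to, p_o in off.items():
                base = p_parents * p_o
                for of, pf in observed_dist(tf).items():
                    for om, pm in observed_dist(tm).items():
                        pair = {of, om}
                        informative = pair in ({0, 1}, {1, 2}, {0, 2})
                        if not informative or MISS in (of, om):
                            continue
                        for oo, po in observed_dist(to).items():
                            if oo == MISS:
                                continue
                            p = base * pf * pm * po
                            e_inf += p
                            if pair == {0, 2}:
                                event = oo != 1
                            else:
                                hom = of if of != 1 else om
                                event = oo == 2 - hom
                            e_evt += p * event
    return e_evt / e_inf



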