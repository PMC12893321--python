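# gibbonpop

Population-genetic tooling built around the recovery of the Hainan gibbon
(*Nomascus hainanus*), the world's rarest primate — a population that
declined to 13 observed individuals in 2003 and has since rebounded to
~42. The package is aimed at conservation-genomics practitioners who work
with noninvasive (fecal) sequencing data and want to reason about
genotyping error, inbreeding, genetic load and the viability consequences
of mating between long-separated lineages.

Four things live here:

1. **Fecal-genomics QC** — allele-dropout (ADO) estimation from trios via
   Mendelian inconsistency (parents AA × Aa cannot produce aa without a
   dropped allele; AA × aa cannot produce a homozygote), duplicate-library
   genotype discordance, ADO-versus-depth profiles, and the coverage
   saturation model `y = a − exp(−b·x + c)` used to plan sequencing
   effort.
2. **Population-genetic statistics** — per-bp heterozygosity and
   He = 2p(1−p); realized genetic load
   `2·n_hom_derived / (2·n_hom_derived + n_het)` and its masked
   complement; Grantham-score missense classification (≥150 deleterious);
   F_ROH = Σ length(ROH_i)/L; GC content at fourfold-degenerate sites
   (GC4, a recombination-rate proxy) with a median high/low split; and
   pedigree-based crossover counting from phased haplotypes.
3. **A balancing-selection scan** — folded site-frequency spectra, an
   excess-clustering score for intermediate-frequency variant clusters,
   the top-5% selection rule, and gene-versus-flank recombination
   comparisons.
4. **An individual-based non-Wright-Fisher simulator and PVA** — gene-block
   genomes (19,197 genes × 1458 bp on 25 chromosomes), a gamma
   distribution of fitness effects with s-dependent dominance, polygynous
   age-structured yearly life cycle, the five-phase gibbon demographic
   history (50 ky burn-in at K = 10,000 → LGM bottleneck at 500 →
   expansion to 20,000 → decline to 3000 → 450-year split into lineages
   of K = 6 and 5), and population viability projections under three
   lineage-cross mating policies.

Everything is exercisable on synthetic data with exact truth records; no
external datasets are required.

## Worked example

Generate trios with 5% per-allele dropout injected, then estimate ADO back
from Mendelian inconsistency:

```bash
gibbonpop synth trios --n-sites 10000 --n-individuals 10 --ado-rate 0.05 \
    --seed 7 --out-vcf trios.vcf --out-ped trios.ped --out-truth truth.tsv
gibbonpop qc ado-trio trios.vcf trios.ped
```

```
n_events	3490
n_informative	51155
ado_rate	0.068224
```

51,155 trio sites are informative (all three members called, parental pair
hom × het or hom × hom-opposite) and 3,490 show a Mendelian-impossible
offspring genotype. The detection rate 6.8% is larger than the injected
per-allele rate because opposite-homozygote parental sites expose either
dropped allele of the obligate-heterozygote offspring (the test suite
checks the estimate against an enumeration oracle of the full observation
model). The same trios at `--ado-rate 0.01` give `ado_rate 0.014`:
the estimator tracks the injected rate monotonically.

From the library, a scaled run of the whole demographic history:

```python
>>> from gibbonpop import run_scenario, GIBBON_SCENARIO
>>> res = run_scenario(GIBBON_SCENARIO, seed=11, scale=0.05, stop_before_split=True)
>>> tr = res.trajectory
>>> float(tr[tr.phase == "epoch_1"].froh_gt_500kb.iloc[-1])   # LGM bottleneck end
0.07021233974358974
>>> float(tr[tr.phase == "epoch_2"].froh_gt_500kb.iloc[-1])   # expansion peak (5 kya)
0.0
```

The bottleneck leaves ~7% of the coding genome in runs of homozygosity
≥500 kb; the post-glacial expansion erases them (in this single replicate
to below the per-individual resolution — the acceptance script averages
20 replicates).

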