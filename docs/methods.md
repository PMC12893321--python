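# Methods

This note documents the models and procedures implemented in `gibbonpop`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Genotype QC for noninvasive data

**Allele dropout (ADO) from trios.** At a heterozygous genotype in
low-input fecal DNA, each allele can fail to be observed; a genotype with
one surviving allele is called as the homozygote of that allele. Two
Mendelian rules expose such errors in parent–parent–offspring trios: with
parents AA × Aa an offspring aa is impossible without dropout, and with
parents AA × aa any homozygous offspring is. The estimator counts rule
violations over *informative* sites — sites where all three members are
called and the parental pair is hom × het or hom-ref × hom-alt (other
configurations can never expose a dropout). The denominator is a
documented choice: the source data do not define one, so raw event and
informative-site counts are reported alongside the rate for recomputation
under other conventions. Note the detection rate is not the per-allele
dropout probability itself — only a subset of dropouts is visible through
the rules — but it is a strictly monotone function of it; the test suite
checks the estimator against an enumeration oracle that integrates the
full observation model over the allele-frequency distribution.

**Duplicate-library discordance.** The fraction of jointly-called
genotypes that differ between two libraries of the same individual. This
captures dropout plus all other random genotyping error; on synthetic
duplicates it equals the truth-record discordant-site fraction exactly.

**ADO-versus-depth profile.** ADO estimates per depth bin (site depth =
minimum across the trio, or the trio mean via a flag; the source data do
not say which was used). The plateau is the left edge of the first bin
beyond which consecutive non-empty bins change by less than a tolerance
(default 0.005 absolute).

**Coverage saturation.** Genome coverage y versus data amount x is
modelled as y = a − exp(−b·x + c), a the maximal coverage. The exponent is
read as −b·x + c (three identifiable constants); the alternative reading
a − e^(−b·x) + c would make a and c jointly unidentifiable. Fitting is
least squares: log-linearisation over a grid of a-values for the seed,
L-BFGS-B for the polish, with the best-so-far residual recorded per
iteration. The tipping point solves dy/dx = marginal_gain (default 0.01
coverage per data unit).

## Population-genetic statistics

- Heterozygosity: het sites / effective length; expected heterozygosity
  He = 2p(1−p) with p the major-allele frequency.
- Genetic load: realized = 2·hom_derived / (2·hom_derived + het) and
  masked = its complement on the same denominator. The derived allele is
  the minor allele (major-allele homozygote = ancestral state); no
  outgroup polarization. The masked-load formula is not printed anywhere
  authoritative; the complement-on-shared-denominator definition is this
  package's documented choice. A sample with no derived alleles yields a
  flagged zero estimate, not an error.
- Grantham classification: missense changes scoring ≥150 (of the 5–215
  range) are deleterious, <150 benign.
- F_ROH: summed length of ROH segments at or above a threshold (defaults
  500 kb and 1 Mb) divided by genome length. The function consumes
  segments (from the simulator's trackers or external callers); empirical
  ROH *calling* from genotype data is intentionally out of scope.
- GC4: GC fraction at third positions of fourfold-degenerate codons
  (standard genetic code), defined only for genes with at least one such
  codon; genes are split into high/low recombination classes at the
  median GC4, ties joining the low class by default (flag-switchable).
- Pedigree recombination: crossovers per adjacent phased-allele pair,
  a crossover being a switch of parental haplotype of origin between
  neighbouring informative loci.

## Balancing-selection scan

The folded SFS bins segregating sites by minor-allele count. The site
score is an excess-clustering statistic: for core folded frequency f0 and
flanking folded frequencies f_i within a window (default 1 kb each side),
score = Σ_i [w(f_i, f0) − w̄(f0)] with w = 1 − |f_i − f0|/0.5 and w̄ the
mean similarity of a random genome site to f0. Subtracting the
genome-wide background makes a rare site surrounded by rare sites (the
neutral norm) score near zero while a frequency cluster tighter than the
background spectrum scores positive. The published ß estimators are more
elaborate (they calibrate against speciation time and mutation rate); the
interface therefore also accepts externally computed scores, and the
selection rule — top 5% of scores, ties broken by position, exactly
⌈0.05·n⌉ sites — is independent of the score's functional form.

## The individual-based forward simulator

**Genome.** Gene blocks: 19,197 genes of 1458 bp on 25 chromosomes,
100 kb of non-coding sequence between genes. Coding mutations arise at
1e-8 per site per meiosis; crossovers fall between adjacent genes with
probability 100 kb × 1e-8 = 1e-3, never within a gene; chromosomes
assort freely. 30% of mutations are neutral; the rest draw |s| from a
gamma DFE (shape 0.186, mean 0.01314833 — the human-derived DFE commonly
used for primate load simulation; configurable). Dominance steps with s:
h = 0 (s < −0.1), 0.01 (−0.1 < s < −0.01), 0.1 (−0.01 ≤ s < −0.001),
0.4 (s ≥ −0.001); boundary values join the more recessive neighbour.
Fitness is multiplicative, ×(1+s) per homozygous and ×(1+h·s) per
heterozygous mutation; mutations that fix become substitutions and stop
affecting survival.

**Life cycle (yearly).** Breeding males (age ≥ 7) hold up to two fixed
mates (females ≥ 7, initially only females that did not breed the
previous year) and alternate between them; females breed at most every
second year; one offspring per successful copulation. Viability selection
then applies survival probability fitness × (1 − m(age)) × min(1, K/N).
The age factors printed for this life history (0.1 newborns, 0.05 ages
1–2, 0.03 ages 3–6, 0.1 age 7, 0.05 ages 8–30, 0.25 ages 31–35, 0.5 ages
36–40, death past 40) are age-specific annual *mortalities*: read as
survival multipliers they would make survival to breeding age ~1e-7 and
every population instantly extinct, contradicting the viability results
they support. A flag restores the literal multiplier reading.

**Inbreeding tracking.** Two ROH measures are maintained. (a) Label ROH:
every founder haplotype carries a unique ancestry label per gene; ROH are
maximal runs where the two haplotypes agree, measured on the physical
coordinate. Each gamete is re-based with a fresh label with probability
0.01, giving a rolling recent-ancestry reference — without it, labels
drift to fixation in a bottleneck and the measure saturates irreversibly.
This measure tracks recent pedigree autozygosity and is used for the PVA
inbreeding trajectories. (b) Genotype ROH: maximal runs of genes carrying
no heterozygous site, measured on the concatenated coding coordinate —
the operational definition applied to sequence data. It responds to
standing diversity and collapses when heterozygous-site density exceeds
~1 per threshold window, which is precisely the mechanism by which a
post-bottleneck expansion erases the ROH signal; it is used for the
expansion-peak/LGM contrast.

**Demographic scenarios.** Gibbon history: K = 10,000 for 50 ky
(burn-in), 500 for 20 ky (pre-LGM bottleneck), linear expansion to a peak
of 20,000 over 15 ky, 3000 until 450 years ago, then a split into
lineages A and B whose K declines (exponentially, configurable) from half
the pre-split K to 6 and 5. The island control is identical minus the
expansion. Extinction truncates the trajectory with a flag.

**Desk rescaling.** A single factor q (acceptance runs use q = 0.05)
scales chromosome count (genes per chromosome preserved), K values and
epoch durations by q and the per-site mutation and recombination rates by
1/q; selection coefficients are rescaled by 1/q *in their fitness effect
only*, with class labels and dominance always assigned from the unscaled
s. This is the standard population-genetic rescaling: it preserves
population-scaled diversity (4Nqu/q), the genetic map, the
IBD-length-to-ancestry-depth correspondence and the drift–selection
balance N·s, so the scaled trajectories are comparable to full-scale ones
at ~1/400 the cost. Three deliberate exceptions keep absolute-size phases
faithful: K values that would fall below 6 stay unscaled (the terminal
lineage sizes are already tiny); the duration of a phase whose K stays
unscaled is also left unscaled — compressing the 45 generations the
lineages spend differentiating at K = 6/5 would erase the drift and
purging that phase produces; and selection acts with the raw coefficients
in those phases (and in the viability projection, whose
extinction-determining early generations run at absolute sizes), since
the 1/q fitness rescaling is only meaningful where N itself is scaled.

## Population viability analysis

Projections start from the scenario end state: the two lineages after
their decline, ~6–11 individuals, conditioned on each lineage retaining a
potential breeding pair (the real population's persistence embodies the
same survivorship; the conditioning retries the post-split tail, which is
statistically independent between lineages and therefore retried per
lineage). Replicates then run 100 generations of 10 yearly cycles at
K = 2000 (scaled) under three mating policies: every pairing
inter-lineage, inter-lineage with probability 0.5 per pairing, or
unconstrained. Hybrid offspring carry admixture fractions; an individual
is classed with a lineage when its ancestry fraction passes 0.5 and
counts as an inter-lineage partner for either pure class. The constraint
binds only while an eligible inter-lineage partner exists — once
admixture has blended the classes the policy falls back to unconstrained
pairing rather than deadlocking. Reported: extinction rate (with
Clopper–Pearson CIs), per-replicate size and F_ROH(≥500 kb) trajectories,
and per-generation paired Wilcoxon signed-rank contrasts between
scenarios at matched seeds.

## Synthetic data

The generators produce diploid biallelic genotypes with a controllable
MAF spectrum (default uniform 0.05–0.5, matching typical MAF filters),
per-allele dropout at heterozygotes, duplicate libraries with independent
uniform genotype errors, two-lineage panels drifted apart by a
Wright–Fisher frequency walk, and phased pedigrees with Bernoulli
crossovers between adjacent loci. Every injected artifact is returned in
a truth record sufficient to recompute it exactly. Not emulated:
read-level errors, contamination, linkage between sites in the genotype
panels, and depth–genotype-quality correlation; passing tests therefore
validate the estimators' logic and calibration, not robustness to those
real-data pathologies.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run at q = 0.05
(scaled genome 768 genes on one chromosome, ancestral K = 500) with 20
scenario replicates and 200 PVA replicates per mating scenario; the
paired expansion-versus-island contrast runs at q = 0.05 with the shared
burn-in and bottleneck phases computed once per group and 10 paired tails
branching from each of 5 independent bottleneck end states (common random
numbers per pair), compared at the pre-split endpoint — the terminal
split is common to both scenarios and its survivorship filtering would
otherwise dominate the comparison. Selection coefficients are floored at
−0.999999 so log-fitness stays finite (effectively lethal); mutation
columns are cleaned up (lost dropped, fixed converted to substitutions)
every 25 years; degenerate inputs (no informative sites, constant
coverage, all-identical GC4, monomorphic SFS input) raise typed errors
or warnings as documented on each function.

## Known limitations

- The ß score is a deliberately simple excess-clustering statistic, not a
  re-implementation of the published ß family; its absolute values are
  not comparable across datasets with very different SFS shapes.
- Scaled extinction rates condition on the survivorship of the terminal
  split; the conditioned ensemble is somewhat fitter than an
  unconditioned one would be.
- The genotype-ROH measure on a 768-gene scaled genome has coarse
  per-individual granularity (a 500-kb window is ~45% of one
  chromosome's coding length); population means over replicates are the
  meaningful quantity.
- Demographic parameters outside the printed scenario (rebound details,
  fecundity probability, split ramp shape) are configurable defaults, not
  inferred quantities.
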