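# Methods

`admixsel` studies post-admixture selection in three-way admixed human
cohorts. It contains four scientific components: a forward simulator of
admixture under selection, a two-layer haplotype-cluster model for local
ancestry inference fitted by weighted EM, a genome scan on ancestry dosages,
and deterministic selection-coefficient estimators. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish.

## Forward simulation of admixture under selection

Three source populations (Amerindian, European and African proxies)
contribute haplotypes to a single founding pulse, followed by `generations`
(default 20) rounds of random mating with viability selection.

**Source panels.** Per SNP, an ancestral frequency is drawn Uniform(0.1, 0.9)
and each population's frequency from the Balding–Nichols Beta distribution
`Beta(p(1-F)/F, (1-p)(1-F)/F)`, where the per-population drift parameter `F`
approximates that population's Fst to the ancestral pool; the Hudson Fst
between two panels is then approximately `(F_a + F_b)/2`. Defaults are
`F = (0.25, 0.15, 0.15)`, calibrated so pairwise panel Fst matches published
human continental values (European–African ≈ 0.15; Amerindian populations
more drifted, ≈ 0.20 to either). Haplotypes are mosaics of 64 founder
haplotypes per population, switching founders per marker interval with
probability `1 - exp(-1000 d)` (d in Morgans) plus a 0.2% per-site copy
error; this produces linkage disequilibrium decaying on the ~0.1 cM scale.
This generator is a parametric stand-in for a demographic model: it matches
frequency differentiation and within-population haplotype structure, but not
deep coalescent history (no migration, no bottlenecks, no realistic site
frequency spectrum).

**Admixture and selection.** Generation 0 draws `n_pool` (default 50,000)
haplotypes from the panels at proportions 0.50/0.45/0.05. The 3 Mb region is
split into three segments by two recombination hotspots (the 0.5 Mb
mid-section is centered; crossover probability per generation defaults to 0.2
at each hotspot). Each generation repeats `n_pool/2` times: two parent
haplotypes are drawn with replacement, a haplotype whose mid-section ancestry
is the selected one (African proxy) carrying sampling weight `1 + s`; the
pair crosses over independently at each hotspot; both recombinants are
emitted. This is haploid viability selection: the expected selected-ancestry
frequency follows `p' = p(1+s)/(1+ps)` exactly, which is the calibration
oracle used in the tests. Selection acts on mid-section *ancestry*, which is
atomic per haplotype because crossovers happen only at the two boundaries —
no focal SNP is needed. Since haplotypes never recombine inside segments,
the simulator tracks (population, panel row) per segment and materializes
alleles only for the final cohort; a 50,000-haplotype pool over 20
generations simulates in under a second, so the full-size pool is kept even
in reduced settings unless a test exercises drift deliberately.

After the final generation, `2 x n_cohort_diplotypes` haplotypes are sampled
without replacement and paired consecutively into diplotypes (the pairing
scheme is arbitrary and irrelevant under random mating). Training panels
(default 200 haplotypes per population) are set aside from the source panels
before admixture.

**Switch errors.** Scanning markers left to right, each heterozygous site of
a diplotype initiates a suffix swap of its two haplotypes with a fixed
probability (2% for the cohort and the Amerindian-proxy panel, 1% for the
European/African-proxy panels). Genotypes are invariant under this operation
by construction.

**What the simulation does not emulate:** genotyping error, array
ascertainment, missing data patterns, related individuals, multi-pulse or
continuous admixture, background selection, and realistic recombination-map
variation outside the two hotspots. Recovery results on these data therefore
demonstrate correctness of the machinery under the stated generative model,
not performance on real arrays.

## Two-layer cluster model and weighted EM

The latent state at a marker is (ancestry s, haplotype cluster j), with
`n_lower` clusters (default 15) divided as evenly as possible among
`n_upper` ancestries (default 3, giving 5/5/5). Emissions are
Bernoulli(theta_mj). Along the map, the ancestry switches per interval with
probability `1 - exp(-g d)` (g = admixture generations, d in Morgans),
landing on an ancestry drawn from the individual's admixture proportions and
a cluster drawn uniformly within it; without an ancestry switch, the cluster
switches within the ancestry with probability `1 - exp(-lambda d)`. The
within-ancestry switch rate lambda is fixed at 100/Morgan: the chain must
move between haplotype clusters much faster than between ancestries
(ancestry tracts are ~5 cM at g=20, haplotype-sharing tracts an order of
magnitude shorter), and the fit is insensitive to its exact value because
theta carries the signal. Exact forward-backward gives the cluster
marginals; diplotypes run the product chain over ordered cluster pairs with
phase integrated out of the emissions, so unphased genotypes need no prior
phasing.

**Weighted M-step.** The cluster allele-frequency update is a weighted ratio
of posterior-weighted allele counts, with one weight per row: training
haplotypes get `w_t` (default 1) and cohort rows `w_c`. Weights are
normalized by their maximum inside the update, so a common weight cancels
bit-for-bit — with no training panel the cohort weight is immaterial, which
is what lets an absent ancestry (e.g. no Amerindian panel) be learned from
the cohort alone. The default `w_c = 0.1 min(1, n_train/n_cohort)` keeps the
training panels dominant in the anchored clusters' frequencies (w_t >> w_c):
with comparable training and cohort sizes an unweighted fit lets the admixed
cohort drag the anchored European/African clusters toward cohort averages,
which inflates the African dosage track in the no-Amerindian setting; at
w_c = 0.1 the partial-mode African average-dosage track agrees with the
supervised one to ~0.002 mean absolute deviation on reduced-scale
simulations.

**Other EM details.** Per-individual admixture proportions are re-estimated
each step from the expected ancestry-draw counts (initial draw plus
redraw events accumulated from the transition posteriors), which is the
exact M-step for this parameterization in haplotype mode; diplotype mode
uses the standard occupancy approximation. Training rows are pinned to their
ancestry (one-hot proportions, never updated). theta is initialized per run
as `0.7 x training-panel frequency + 0.3 x Uniform(0.2, 0.8)` where a panel
exists, pure Uniform(0.2, 0.8) otherwise, and clamped to
[1e-4, 1 - 1e-4] throughout; a cluster with zero weighted exposure at a
marker keeps its previous frequency (logged). Missing sites contribute a
unit emission and are excluded from the update. With these updates the
weighted observed-data log-likelihood (w_t x training + w_c x cohort) is
non-decreasing over iterations, which the tests assert at 1e-8 relative
tolerance.

**Runs and label alignment.** Dosages are averaged over `em_runs`
independent restarts (default 10) of `em_steps` iterations (default 20).
Averaging is done on dosage fields, not parameters: dosages are the
quantity consumed downstream and are invariant to within-ancestry cluster
permutations. Ancestries with a training panel are anchored by
construction; remaining labels are matched to the first run by greedy
maximization of dosage-field correlation (ties broken by run order,
logged). In structure mode (no labels at all) this is haplotype-based
structure analysis: the per-individual admixture proportions are the mean
dosage across markers divided by ploidy.

## Dosage scan

Average dosages are means over individuals, or — when a family map is given
— means over family means, so each family counts once regardless of size.
Per ancestry, the genome-wide mean and sample standard deviation (ssd, n-1
denominator: "sample" standard deviation is taken literally) are computed
over all markers, including any selected region; an elevated region
therefore inflates the ssd, which is conservative. `z = (avg - mean)/ssd`
per marker; the attached one-sided upper-tail normal p-value is descriptive
only — the z-scores of neighbouring markers are strongly dependent and no
multiplicity adjustment is attempted. The called region is the set of
markers whose average dosage exceeds a threshold on the diploid [0, 2]
scale, with a contiguity flag; the derived phenotype is an individual's mean
dosage over the called region.

A caution for small scanned regions: when the selected region is a sizable
fraction of the scanned window (as in the 3 Mb simulations, where the
mid-section is 1/6 of the markers), the per-marker z is geometrically
bounded near 2 regardless of effect size, because the region itself inflates
the ssd. The z-threshold rule is an outlier rule for genome-scale scans, not
a calibrated test.

## Selection coefficients

Given the pre-selection proxy `p0` (genome-wide mean average dosage) and the
peak `p1`, three deterministic, infinite-population models are fitted over
`n = 20` generations. The simple model `p1 = p0 (1+s)^20` has the closed
form `s = exp(log(p1/p0)/20) - 1`, is scale invariant, and lower-bounds the
other two because both bounded recursions grow slower than `f(1+s)` per
generation. The dominance model (`f' = f(1+s)/(1+(2-f)fs)`) and additive
model (`f' = f(1+s+fs)/(1+2fs)`) act on frequencies, i.e. half the dosages,
and are solved by interval bisection on s — justified by strict monotonicity
of the final frequency in s — from the bracket [0, 1] (auto-doubled upward
if needed) until the final-frequency residual is below `epsilon` (default
1e-8; the tolerance is on the frequency scale, where a 1e-8 residual is far
below the 3-decimal reporting precision of s). Reported values are rounded
to 3 decimals; full precision is retained in the result object. No drift
correction or confidence interval is attempted: the estimates are
deterministic transforms of (p0, p1).

## Pipeline region call

The end-to-end driver must decide whether a positive-selection region exists
before fitting s. With an explicit dosage threshold (e.g. the 0.30 marker-set
rule used for defining association phenotypes at genome scale) the region is
simply the markers above it. The default is adaptive, designed for small
scanned windows where z is bounded (above): the background level is the
*median* average dosage (robust to contamination by a selected region
occupying a minority of markers, where the mean is not); the candidate
region is the markers above the midpoint of background and peak; and the
call is made only if the implied simple-model coefficient
`s = exp(log(peak/background)/n) - 1` clears a detection floor (`min_s`,
default 0.03, chosen between the drift scale of the neutral null and the
smallest design strength 0.02). The reported `p0` remains the genome-wide
mean, matching the genome-scale convention.

## Reduced problem sizes

Full-scale defaults follow the study design (50,000-haplotype pool, 3,000
markers at 1000 SNPs/cM over 3 Mb, 1,000 cohort diplotypes, 200 training
haplotypes per population, 10 EM runs x 20 steps). The documented reduced
scale used by the test suite is a 5,000-haplotype pool, 600 markers
(200 SNPs/cM), 200 cohort diplotypes and 5 EM runs — the package's choice of
desk-scale problem sizes; recovery tolerances are unchanged between scales.
The pool is simulated in the segment-triple representation, so tests that
check simulator calibration use the full 50,000-haplotype pool directly.

## Known limitations

- The transition parameterization (exponential switch maps, fixed lambda,
  uniform within-ancestry cluster weights) is a standard admixture-HMM form,
  not a re-derivation of any particular released tool; no bit-compatibility
  with existing software is intended.
- The upper-layer rate uses the admixture-generation count as given; no
  recombination-rate estimation is exposed.
- Diplotype mode's admixture-proportion update is an occupancy
  approximation, so exact likelihood monotonicity is guaranteed only in
  haplotype mode.
- Hitchhiking is real: at hotspot crossover 0.2 per generation, flanking
  segments retain a detectable lift from mid-section selection at s = 0.10
  in early generations. Flank neutrality holds only under fast crossover
  (0.5), and the tests state it there.
- The scan's normal p-values are descriptive; the z rule is not calibrated
  for small regions (see above).
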