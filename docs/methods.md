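# Methods

This note records the statistical models, algorithms, parameter choices and
known limitations behind `f2gbs`.  It states no empirical claim that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

An F2 intercross between two inbred parents segregates 1 A : 2 H : 1 B at
every locus (A/B = parent-1/parent-2 homozygote, H = heterozygote).  The
package's central object is the ABH matrix: individuals × physically
ordered markers over the alphabet {A, B, H, N}.  Physical coordinates are
1-based; heterozygous nucleotide calls are unordered; the missing genotype
is `N` in ABH-CSV and `./.` in VCF.  Sample roles (parental replicate vs
F2) live in a sidecar table rather than being parsed out of sample names,
because replicate naming conventions vary between labs.

## Filtering

Stages run in a fixed order, each recorded with in/out counts:

1. **Parental consistency.**  A site survives iff all non-missing calls
   within each parental replicate set agree, both consensus genotypes are
   homozygous, and the two consensus alleles differ.  Sites with no
   non-missing call for a parent are dropped, not guessed.  The consensus
   allele pair is recorded and later drives ABH encoding.
2. **Minor allele frequency.**  MAF is computed over F2 samples only
   (parental replicates would drag the frequency toward 0.5); homozygotes
   contribute two allele copies, heterozygotes one of each; removal is
   strict (`< 0.25`), so MAF exactly at threshold survives.
3. **Depth mask.**  F2 calls with total read depth below 7 become missing.
   Seven reads bound the heterozygote-undercall probability at
   `2·(1/2)^7 = 1.5625%`.  Parental calls are exempt: the triplicate rule
   already protects them.  Total (not per-allele) depth is used.
4. **Thinning.**  A greedy left-to-right scan per chromosome keeps a site
   iff it lies ≥ 64 bp beyond the last kept site (64 bp is the sequencing
   tag length, so closer SNPs are redundant calls from one tag).  The
   first site of each crowded cluster is kept.
5. **Missingness.**  Sites whose missing-F2 fraction exceeds the chosen
   tier (0.05 / 0.50 / 0.75) are removed.

Whether MAF should precede the depth mask is not determined by upstream
tools' conventions alone; this pipeline computes MAF first (the order used
by the SNP caller that produces such tables), and both stages are
parameters of `filter_pipeline`.

## Imputation and error correction

Three passes per individual and chromosome, always impute → het-correct →
stretch-correct.  Each pass computes maximal runs **from its input row**
and rewrites all qualifying runs in one sweep, so results are independent
of scan direction; chromosomes never interact.

* *Impute*: a maximal `N` run is filled iff its nearest non-missing
  neighbours on both sides are equal; no length limit.  Runs touching a
  chromosome end are left alone (a single flank is not evidence enough).
* *Het-correct*: a maximal run containing only A/B/N, of length ≤ 4, with
  `H` immediately on both sides, becomes all `H`.  The threshold 4 is a
  tunable (`CorrectionParams.het_run_max`).
* *Stretch-correct*: a maximal run of one code, of length ≤ 1, whose two
  neighbours equal each other and differ from the run, is replaced by the
  neighbour value.  Runs of `N` may be replaced (so `H N H → H H H`), but
  an `N` neighbour never overwrites a called genotype — the passes can
  only reduce missingness, never create it.

Two deliberate consequences: the stretch pass is *not* idempotent in rare
configurations (its own replacements can merge runs and expose a new
flanked singleton; the declarative single sweep was chosen over iteration
to keep the semantics order-free and simple to verify against a per-cell
oracle), and runs at chromosome ends are never corrected (one flank only).
Imputation never alters a called genotype; `count(N)` is non-increasing
through the whole chain.

These rules presume parental haplotype blocks are long relative to the
marker spacing, i.e. that a genuine `H hom… H` excursion spanning ≤ 4
markers is rare.  That holds at the sub-cM marker spacing of real GBS maps
but degrades on sparse maps (several cM between markers), where the passes
will also rewrite genuine short excursions — see the simulator section.

**Merging.**  Two populations genotyped with different enzymes share no
markers; their matrices are merged by physical position (union of markers,
union of individuals, `N` where a marker was not assayed in an
individual's population), after each population's own post-processing, and
flank-imputation is re-run so each population's haplotype blocks fill the
other's marker grid.  The double-crossover risk this imputation ignores is
bounded by the genome-average recombination density: at 3.84 cM/Mb
(1536 cM over 400 Mb), two crossovers inside a 1-Mb window have
probability (0.0384)² ≈ 0.0015.

## Error profiling

The six-motif census counts windows `x y x` (x ≠ y, both called) along
each individual and chromosome; the centre marker and the individual are
credited.  Windows containing `N` are skipped — absence of evidence is not
a genotype.  Overlapping windows all count.  Counting is meant for
imputed-but-uncorrected data; after correction the motifs are gone by
construction.  The per-marker chi-square against 1:2:1 (2 df) is a
convenience statistic for segregation distortion, beyond the plain
frequency profile.

## Genetic maps

Adjacent-pair recombination fractions are estimated by maximum likelihood
on the 3×3 joint genotype table.  Writing s = 1−r, class probabilities are
s²/4, rs/2, r²/4 … with the double-heterozygote class (s²+r²)/2 — a
mixture of coupling (0 recombinant gametes) and repulsion (2).  EM iterates
the expected recombinant-gamete count (`2r²/(r²+s²)` for the double het,
fixed integers elsewhere) to |Δr| < 1e-8, clips to [0, 0.5], and the
estimate is capped at 0.4999 before the map-function transform so
distances stay finite.  Pairs with a missing genotype are dropped from the
table (imputation precedes mapping, so little is lost).  Distances
accumulate from 0 along the physical marker order via Haldane (default)
or Kosambi; marker ordering itself is taken from physical position, never
re-estimated.  Chained two-point estimation was chosen over a multipoint
HMM: for near-complete post-imputation data the two are equivalent for
total length, and the two-point likelihood is directly verifiable against
a grid-search oracle (the suite checks agreement to |Δr| < 1e-3).

## QTL scanning

Genotype draws on the scan grid come from the exact conditional
distribution under a phase-known 4-state Markov chain over ordered gamete
pairs: per gamete, the allele switches between flanking positions with
Haldane probability `c = (1−e^(−2d/100))/2`; the posterior at a grid point
conditions on the nearest called marker on each side (Markov ⇒ exact), and
falls back to the 1:2:1 prior where a flank is absent.  The grid is the
union of a fixed-step lattice (default 1 cM) with the marker positions, so
an observed marker reproduces its genotype in every draw.

Each draw is scanned by least squares: intercept, additive contrast
(−1, 0, +1), dominance indicator.  `LOD = (n/2) log₁₀(RSS₀/RSS₁)`;
evidence across the `n_draws = 16` default draws combines as
`log₁₀ mean(10^LOD)` (computed via logsumexp), which reduces to the
single-draw LOD when draws agree.  Phenotypes are used untransformed.

Significance: the phenotype vector is permuted across individuals
(genotypes, and hence the LD structure, fixed), the genome-wide maximum
LOD recorded per permutation, and the threshold is the empirical (1−α)
quantile (α = 0.05, 1000 permutations by default; the power driver
reduces to 200 for desk-scale runtime).  Credible intervals: `10^LOD` is
normalized to unit area by the trapezoid rule and the interval grows
outward from the peak (middle of a tied plateau; ties expand both sides)
until it holds ≥ 95% of the area, endpoints on grid points — a flat
profile yields a centred interval covering 95% of the chromosome.  Peak
effects and variance explained are computed from the *observed* genotypes
at the marker nearest the peak (deterministic, and faithful to
"class-mean" effect definitions); additive effects are signed so that
positive means the parent-2 allele increases the trait.

## Simulator

`sim_map` allocates markers to chromosomes proportionally to length
(largest-remainder, ≥ 2 per chromosome) and spaces them equally including
both ends (or uniformly at random).  The default chromosome lengths are
the 12-chromosome rice consensus values (140, 115, 130, 110, 100, 105,
110, 100, 75, 80, 100, 105 cM; 1270 cM total).

`sim_f2` builds each individual from two independent gametes per
chromosome.  Crossovers follow the chi-square interference model: chiasma
intermediates arrive as a Poisson process at rate 2(m+1) per 100 cM,
every (m+1)-th (random phase) resolves, and each chiasma involves a given
chromatid with probability 1/2.  Expected crossovers per gamete are
length/100 for every m; `m = 0` is the no-interference Poisson/Haldane
model.  The default `m = 10` reflects the strong positive interference of
plant meiosis, and matters here for a structural reason: the correction
passes interpret short homozygous excursions between heterozygous flanks
as errors, which is only valid when close double crossovers are rare.
Under a Poisson model at ~3 cM marker spacing such excursions are common
enough that correction visibly shortens even noise-free maps; with
interference they are negligible, matching the regime the correction was
designed for.  (Excursions caused by *single* crossovers on each of the
two gametes within a short window are not suppressed by interference —
this is why correction still slightly shortens sparse-map data, and why
the method wants dense markers.)

Phenotypes: `y = Σ_q a_q·x_q + d_q·1(het_q) + ε`, x ∈ {−1, 0, +1},
ε ~ N(0, σ²) with σ = 1 by default.  A single QTL with a = 0.5 thus
contributes a²/2 = 0.125 genetic variance, 11.1% of the total 1.125 —
this parameterization is stated explicitly because per-QTL
variance-contribution figures depend on it and are not portable between
parameterizations.

GBS noise is layered independently per cell: systematic flips at a random
`error_marker_fraction` of markers first (defaults `H→B` at 0.15 and
`A→H` at 0.30, chosen so the two dominant co-occurring error motifs of
real data, HBH and AHA, arise in comparable numbers at the designated
markers); then heterozygote undercalling with probability `2·(1/2)^d`
under a fixed or Poisson depth model; then missingness.  The depth default
used by the nucleotide-level fixture generator (Poisson mean 30) reflects
the high per-site coverage of a strongly multiplexed rare-cutter library,
and puts ~92% of heterozygous calls within a two-fold allelic-depth ratio.

What the simulator does **not** emulate: read-level artefacts (PCR bias,
alignment error, paralog collapse — error-prone markers are a stand-in for
their aggregate effect), segregation distortion from incompatibility loci,
missingness that clusters by individual or library, and linkage between
error rate and local sequence context.  Passing tests therefore show the
algorithms are correct under the stated noise model, not that real data
meets that model.

`power_experiment` counts a QTL as detected when any scan position within
±10 cM of its true location reaches the genome-wide threshold, and reports
per-QTL power plus the probability of detecting all QTL, over an
(individuals × markers) grid with 100 replicates by default.

## Numerical and testing choices

* All randomness flows from explicit `numpy.random.Generator` seeds;
  derived seeds stay below 2³¹.
* RSS values are floored at 1e-12 before the LOD log; LOD is floored at 0.
* Degenerate inputs: constant phenotypes raise; chromosomes with < 2
  markers map to zero length with a warning; markers with all-missing
  genotypes give NaN frequency profiles.
* Oracle tests compare the correction passes against per-cell scanning
  oracles exhaustively for all strings up to length 8 (~87k strings) plus
  thousands of random longer strings; EM against a 1e-4-step grid search;
  site counting against naive substring search.
* Desk-scale problem sizes in the suite (e.g. 20 seeds × (n = 500,
  400 markers) for map recovery; 20 seeds × (n = 600, 200 permutations)
  for QTL recovery; 60 replicates for null calibration on a reduced
  4-chromosome genome) were chosen to keep the full suite under a few
  minutes while leaving 3σ statistical margins.

## Known limitations

* Two-point chained maps inherit noise additively along chromosomes; a
  multipoint HMM would pool information (and is the natural extension).
* No cross-chromosome linkage diagnostics: residual map distention caused
  by markers linked across chromosomes (e.g. misplaced scaffolds) is not
  detected or filtered.
* The correction passes are deterministic rules, not a probabilistic
  model; they trade a small, quantifiable loss of genuine short
  excursions for a large removal of errors, and that trade-off worsens as
  marker spacing grows.
* Fragment prediction ignores cut-position offsets within recognition
  sites and methylation sensitivity.
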