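# Methods

This note documents the models, estimators, numerical choices and
limitations behind `demearc`, in the spirit of a methods supplement.

## Data model

A `SiteTable` is a dense per-site × per-sample matrix of diploid genotype
calls over short RAD loci, carrying **both variant and invariant sites**.
Genotypes are stored as alternate-allele dosage (0/1/2, −1 missing) with a
parallel DP (depth) matrix; every variant site is biallelic. Keeping
invariant sites is essential: π and D_XY are per-site quantities, and the
denominator (number of pairwise comparisons actually made) can only be
counted if the monomorphic background and its missingness are retained.
Half-calls are treated as missing.

## Filtering

* **Depth masking.** A genotype is set missing if `DP < min_dp` (default
  5) or if its DP exceeds the `high_percentile` (default 0.975,
  linear-interpolation quantile) of that sample's DP distribution over its
  genotyped sites. The low rule removes unreliable calls; the high rule
  targets collapsed paralogs, whose apparent coverage doubles. After
  masking, `recompute_alleles` re-derives each site's variant/invariant
  status (a site whose ALT copies were all masked becomes invariant; a
  site fixed for ALT is relabelled), keeping downstream estimators
  consistent. Recomputation is the default and can be disabled.
* **Overmerge (θ) filter.** Per locus, `S` counts segregating sites and
  Watterson's estimator is `θ_W = S / a_n` with `a_n = Σ_{i<n} 1/i` and
  `n` the rounded mean number of genotyped haploid lineages across the
  locus's sites (missingness makes `n` site-specific; the rounded mean is
  our resolution of that ambiguity; loci with n < 2 are flagged
  uncomputable). Loci with `θ_W` strictly above the 99.5th percentile of
  the distribution are blacklisted. On exchangeable data this flags ~0.5%
  of loci by construction; the filter is aimed at the heavy right tail
  that overmerged clusters produce.
* **Presence / MAC / thinning.** Sites present in fewer than
  `ceil(min_presence × |scope|)` individuals of the relevant scope are
  dropped (inclusive "at least" boundary); variant sites with minor allele
  count below `min_mac` are removed (invariant sites untouched); thinning
  keeps the first (smallest-position) variant per locus — deterministic,
  idempotent, and the standard way to obtain quasi-unlinked variants from
  RAD loci.

Filters only remove sites or set genotypes missing; they never alter a
retained genotype, so any composition of filters yields a subtable of its
input.

## Diversity and divergence

π (within) and D_XY (between) are **ratios of sums**: per retained site
the numerator accumulates differing allele pairs among genotyped lineages
(within-deme pairs for π, cross-deme pairs for D_XY) and the denominator
the total pairs compared; the estimate is Σnum/Σden. The alternative —
averaging per-site ratios — systematically overweights poorly genotyped
sites and is excluded by a guard test. Invariant sites contribute zero to
numerators and positively to denominators. Each deme is filtered for
presence independently for π (≥50% of its individuals by default);
pairwise statistics require presence in each deme (default 70%). Demes
under five individuals are flagged excluded from comparisons.

F_ST is a ratio of summed per-site variance components: Weir–Cockerham
(1984) two-population components a, b, c by default (the common default of
diversity pipelines), or the Hudson/Bhatia ratio-of-averages form.
Monomorphic sites and sites with fewer than two genotyped individuals in
either deme contribute nothing. Group comparisons (e.g. habitat means)
use Welch's unequal-variance *t* with Satterthwaite degrees of freedom.

## Folded spectra and projection

Spectra are built from unlinked variants (one per locus) present in ≥70%
of the pooled individuals of the deme or pair. Because ancestral states
are unknown, spectra are folded on the *global* minor allele (ties resolve
to ALT). A site with `d` minor copies among `n` genotyped lineages is
projected to `m = 2 × projection individuals` lineages via the
hypergeometric expectation
`P(j) = C(d, j) C(n−d, m−j) / C(n, m)`; projected (fractional) counts are
kept as reals — composite likelihood does not require integer counts, and
rounding would bias low classes. Sites with `n < m` are dropped with a
logged count.

Folding conventions: in 1-D, class `j < m/2` collects unfolded `j` and
`m−j`; the central class keeps its own mass once; class 0 is the
monomorphic-after-projection mass, recorded but masked from likelihoods.
In 2-D, cells `(i, j)` and `(m1−i, m2−j)` merge into the member with the
smaller total count (ties toward smaller `i`; the self-symmetric centre
keeps its own mass once), and the corners `(0,0)`/`(m1,m2)` are masked.
The same folding code produces observed and expected spectra, so the
likelihood is internally consistent whatever the convention.

Projection size: 6 individuals per deme for joint spectra; for single
demes the projection in 5–7 individuals that retains the most segregating
mass is chosen automatically and recorded in provenance. Eligibility
follows the sampling rules of the archipelago design: ≥7 sampled
individuals per deme, and for pairs ≥2000 usable variants per deme.

## Demographic models

Eight models, all in generations and diploid effective sizes, migration as
a symmetric per-lineage backward probability per generation:

* Two-deme: ancestral size `N_ANC` splits at `T_DIV` into constant
  `N_DEME1`, `N_DEME2`. Gene-flow windows (backward time):
  ISO1 none; ISO2 `[T_INT, T_DIV]` with `0.5·T_DIV ≤ T_INT ≤ 0.9·T_DIV`
  (early contact, later isolation); MIG1 `[0, T_INT]` with
  `0.1·T_DIV ≤ T_INT ≤ 0.5·T_DIV` (recent contact); MIG2 `[0, T_DIV]`.
  Active migration respects `MIG ≥ 5 × 10⁻⁷`; the search's upper bound
  (10⁻²) sits in the strong-migration saturation regime where the jSFS no
  longer changes.
* Single-deme: one instantaneous resize to `N_ANC` at `T_0 ≤ 300,000`
  generations. CONST constrains `0.9 ≤ N_ANC/N_DEME ≤ 1.1`; EXPAND
  `N_ANC ≤ 10⁻²·N_DEME`; CONTRACT `N_ANC ≥ 10²·N_DEME`; BOTTLE pins
  `N_ANC = N_DEME` with an episodic crash to `N_BOT ≤ 10⁻²·N_DEME` over
  `[T_0, T_0 + T_BOT]`. The bottleneck duration is a free parameter
  bounded to `[1, 0.2·T_0]` generations, keeping the event episodic.

Parameter counts for AIC equal the number of free parameters: ISO1 3,
ISO2/MIG1 5, MIG2 4, CONST/EXPAND/CONTRACT 2, BOTTLE 3 (N_ANC pinned).
They are configurable.

## Expected spectra

Likelihood fitting conditions on polymorphism (no invariant sites), so one
contemporary size must be fixed externally: `N_e = π̂ / 4μ` with
`μ = 2.8 × 10⁻⁹` by default (for pairs, the deme with the larger π,
recorded in provenance).

The expected folded spectrum under a model is the normalized vector of
expected branch lengths subtending each frequency class — the same
quantity a SNP-simulation engine estimates, with the mutation-placement
noise integrated out. Two engines compute it:

* **Single-deme (time-rescaling).** Standard-coalescent interval draws
  `E_k ~ Exp(C(k,2))` are made once per seed and mapped through the
  piecewise-constant size history's cumulative coalescent intensity
  (piecewise-linear, inverted in closed form). The topology factor is
  analytic: the expected number of branches subtending `i` of `n` leaves
  while `k` lineages remain is `k·C(n−i−1, k−2)/C(n−1, k−1)`. Each
  likelihood evaluation therefore reuses identical random numbers (common
  random numbers, CRN) and costs a fraction of a millisecond at 10⁴
  replicates.
* **Two-deme (structured coalescent).** A numba-compiled Gillespie
  simulation tracks, per lineage, the number of sampled lineages subtended
  in each deme, accumulating interval lengths into the unfolded joint
  grid; coalescence rates are `C(k_d,2)/2N_d`, migration `m·k` inside the
  model's gene-flow window, with a clean merge at `T_DIV`. One fixed seed
  per fit gives CRN across parameter evaluations and across models.
  Migration is clipped at `4·min(N1,N2)·m = 50`: beyond that the spectrum
  sits at its strong-migration limit (differences far below simulation
  noise) while the Gillespie event count keeps growing linearly in `m`,
  so the clip changes nothing numerically and bounds evaluation cost.

Both engines are cross-validated against msprime branch-mode allele
frequency spectra in the test suite. Expected proportions over unmasked
entries are floored at `0.1 / n_sims` and renormalized so the composite
log-likelihood `lnL = Σ observed_j · ln p_j` stays finite.

## Optimization and model selection

The maximizer is a multi-start cyclic conditional-maximization (an ECM
analogue): each free parameter in turn is maximized by golden-section
search on its box (sizes, times and migration on log10 scale; constrained
parameters as ratios of their reference, e.g. `T_INT/T_DIV`). Line-search
brackets span the full box on the first loop and shrink geometrically
around the incumbent thereafter, so late loops refine rather than rescan
whole decades. Three additions make AIC comparisons robust to optimizer
luck:

* **Nested warm starts** — models are fitted simplest-first and each
  richer model starts additionally from its nested special case (e.g.
  MIG2 from ISO1's solution with migration at its floor; BOTTLE from
  CONST with a one-generation crash), so a special case can never beat
  its host model through search failure.
* **Moment-based starts** — for pairs, observed Hudson F_ST seeds both
  families: a pure-divergence start `T_DIV = 2N·F_ST/(1−F_ST)` and a
  migration-drift start `m = (1/F_ST − 1)/4N` with old divergence. The
  two-deme composite-likelihood surface is bimodal (an isolation-mimic
  basin and a migration basin); these starts guarantee both basins are
  visited for every model.
* **Cross-polish and consensus finalization** — after the first pass,
  every model is re-polished from every other model's mapped solution
  (equalizing search effort). All best parameter sets are then
  re-evaluated at high replicate count with one shared seed, and each
  model is additionally evaluated at the overall-best model's mapped
  solution, keeping the better point. Near-equivalent models (a migration
  model stuck at its migration floor is the canonical case) therefore
  score from the same optimum and are separated by their AIC penalty, not
  by which point of the noisy search surface each happened to stop on.

Selection follows the information-theoretic standard:
`ΔAIC_i = AIC_i − min AIC`, relative likelihood `exp(−Δ_i/2)`, AIC weight
normalized over the compared set. Natural logs throughout. Parametric
bootstrap confidence intervals and conversion of parameters to calendar
units are out of scope.

## Synthetic data generator

`synthdata` simulates independent 121-bp non-recombining loci (free
recombination between loci) with msprime under any of the eight models,
Jukes–Cantor mutations at `μ = 2.8 × 10⁻⁹` by default; sites with more
than two observed alleles are dropped and counted. Missingness is a
two-level process — whole-(sample, locus) dropout (the allelic-dropout
proxy) then independent genotype dropout, composite expectation
`d + (1−d)m`, defaulting to ~35% overall — and per-genotype DP is negative
binomial (variance `μ + 0.3μ²`) around per-sample means drawn uniformly
from 18–77×. Everything derives from one integer seed; identical seeds
give byte-identical VCF exports.

What the generator does **not** emulate: sequencing error in genotype
calls, divergence-dependent allelic dropout (a hook exists but is off by
default because no quantitative model is available), assembly artifacts
beyond the dropout/overmerge proxies, linkage within loci beyond the
single shared genealogy, or reference bias. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to every artifact of real ddRAD
data.

## Calibration and recovery studies (problem sizes)

The test suite runs these at desk scale, one CPU:

* **Generator calibration** — 20 datasets of 5,000 loci × 121 bp, 10
  diploids, `N = 10⁴`, `μ = 2.8 × 10⁻⁹`: pooled π within 3 SE of
  `4Nμ = 1.12 × 10⁻⁴`; per-seed folded SFS consistent with the folded
  neutral `1/i` shape (χ², α = 0.01) in ≥19/20 seeds.
* **Persistence recovery** — truths CONST and BOTTLE at `N_DEME = 10⁵`
  (the Ne implied by dune-habitat π ≈ 0.0013), 10,000 loci, 8 diploids,
  10% missingness; BOTTLE: `T_0 = 20,000`, `N_BOT = 10⁻²N`,
  `T_BOT = 1,000` (crash intensity 0.5, leaving a recoverable
  deep-ancestry signal). Search: 20 starts × ≤30 loops at 10⁴
  replicates/evaluation. Success: the generating class (high vs low
  persistence) tops the AIC weights in ≥16/20 seeds per truth.
* **Isolation recovery** — truths ISO1 (`MIG = 0`) and MIG2
  (`MIG = 10⁻³`) in population-scaled units (`N = 10³`, `μ = 2.8 × 10⁻⁷`,
  preserving `4Nμ` ≈ the empirical π and giving `4Nm = 4` under MIG2),
  `T_DIV = 2,000` (one coalescent unit), 6,000 loci, 8 + 8 diploids.
  Success: the generating class (isolation vs contact) tops in ≥16/20
  seeds per truth.

The paper-scale settings (100 starts × 100 loops × 5 × 10⁵ simulations)
remain available through `SearchConfig`.

## Known limitations

* Composite likelihood ignores linkage between the retained variants;
  AIC on composite likelihoods is a heuristic ranking, not a calibrated
  test — standard for SFS pipelines, but weights should be read as
  relative support only.
* The folded, projected spectrum (5–7 individuals) carries limited deep-
  history information; CONTRACT with an old event is intrinsically hard to
  separate from CONST at a few thousand variants, and near-ties between
  nested models are decided by the AIC penalty.
* The θ overmerge filter assumes exchangeable loci; under strong
  population structure its null flag rate can deviate from the nominal
  0.5%.
* `N_e = π/4μ` scaling inherits any bias in π (e.g. post-bottleneck
  diversity deficits); model comparison is robust to this because every
  model shares the same fixed size.
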