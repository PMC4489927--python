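# Methods

`lincsynteny` implements a comparative-genomics pipeline that asks whether
the *gene-neighborhood* (microsynteny) of lincRNAs expressed during human
neocortical neurogenesis is conserved differently in large-brained (high
gyrencephaly index, GI > 1.5) versus small-brained (low-GI) mammals, and
whether departures from a phylogenetic null expectation track brain size
rather than divergence time. This note records the models, the defaults and
why, the numerical choices, and what the synthetic generator does and does
not establish.

## Pipeline model

1. **Zone-specific expression.** LincRNA counts over four dissected fetal
   neocortex zones — ventricular zone (VZ), inner/outer subventricular zone
   (ISVZ/OSVZ) and cortical plate (CP) — are tested zone-vs-VZ with a
   minimal negative-binomial stage (below). The union of zone-significant,
   upregulated lincRNAs is the "expressed during neurogenesis" set.
2. **Gene-neighborhoods.** For each lincRNA the neighborhood is its
   immediately flanking protein-coding genes: the nearest coding gene
   wholly left and wholly right on the same chromosome, strand ignored,
   overlapping genes excluded, edge-to-edge distances. LincRNAs with no
   flank in the expressed set are discarded.
3. **Cross-species placement.** The lincRNA sequence is located in each
   target genome by seed-and-extend local alignment (exact 11-mers, then
   affine-gap Smith–Waterman inside a window; full dynamic programming when
   the problem is small). A hit is accepted when E < 1e-4 and query
   coverage > 0.20 (strict); a spaced-seed "discontiguous" pass rescues
   queries the contiguous pass misses and flags the result.
4. **Conservation scoring.** A lincRNA is conserved in a species (1) when
   at least one reference flank's 1-to-1 ortholog is among the coding genes
   immediately flanking the placed locus; 0 when the locus is placed but no
   flank ortholog is adjacent; missing (excluded from totals) when the
   locus cannot be placed or no coding gene is annotated within the
   adjacency window. Chromosome identity is *not* required.
5. **Phylogenetic expectation.** Per-species conserved totals `S_i` are
   modeled as exponential decay from the reference count `N` toward a
   single optimum `theta`:

       E[S_i] = theta + (N - theta) * exp(-alpha * d_i)

   with `d_i` the patristic distance from the reference (human) and
   residual covariance from a single-optimum Ornstein–Uhlenbeck process on
   the ultrametric tree,

       V_ij = sigma^2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)),

   `t_ij` being the shared root-to-MRCA time (Brownian motion is the
   `alpha -> 0` limit). Deviations are reported as
   `100 (S_i - E[S_i]) / E[S_i]` and contrasted by GI class.
6. **Comparative statistics.** OLS R² of conservation on GI and on log10
   body weight / longevity; Steiger's (1980) Z for comparing the dependent
   correlations; per-GI-class adjusted-R² regressions on molecular-rate
   deviations (the rate-confound check); per-lincRNA mean/median PhastCons
   and PhyloP aggregation with pooled-variance t-tests contrasting
   TF-adjacent neighborhoods; and a pooled two-proportion Z for
   enhancer-overlap enrichment.

## Design choices where the design was open

- **Expectation-curve formulation.** "Expected conservation from
  phylogenetic relatedness under a single-optimum OU/PGLS model" admits
  several constructions. We fit decay-from-the-reference with OU residuals
  — the minimal model that anchors at `S = N` for `d = 0`, saturates at a
  single optimum, and uses OU-structured generalized least squares. It is
  isolated behind `phylo.fit_ou_expectation` so an alternative (e.g.
  ancestral-state prediction) can be swapped in.
- **Fitting.** Profile maximum likelihood: for fixed `alpha`, `theta` has a
  closed-form GLS solution and `sigma^2` a closed-form ML solution;
  `alpha` is searched on a 41-point log grid over [1e-4, 50] per unit tree
  depth and refined by bounded 1-D optimization, never returning less
  likelihood than the best grid point. Trees are rescaled to unit depth and
  parameters back-transformed. `theta` is clipped to `[0, N]` — the optimum
  is itself a conservation count, and unclipped extrapolation can produce
  negative expected counts (undefined percentage deviations). `sigma^2` is
  floored at 1e-12 so that exact-fit (zero-residual) data remain finite.
  The reference species is excluded from the residual likelihood; it enters
  only as the curve anchor. Multiple trees are fitted independently and
  their expectation curves averaged.
- **t-test flavor.** Student's pooled-variance by default (a single T with
  no variance caveat suggests the classical test); Welch available via
  `welch=True` for sensitivity. "Median score" contrasts are t-tests on
  per-lincRNA medians (the lincRNA is the unit of analysis). The group
  order is (without TF) − (with TF), so higher conservation of TF-adjacent
  lincRNAs yields negative T.
- **R² conventions.** Plain R² for trait comparisons; adjusted R² (which
  may be negative under the null) for the rate-confound regressions. Body
  weight and longevity are log10-transformed by default (standard for
  allometric traits; `log_predictors=False` disables).
- **DE stage.** Median-of-ratios size factors (rescaled so the median
  factor is 1 — the overall scale is arbitrary and cancels in all tests);
  per-gene method-of-moments NB dispersion floored at 1e-8, no shrinkage
  trend; Wald test on the difference of log group means (group mean = mean
  of normalized counts, making fold changes exactly invariant to rescaling
  a sample together with its factor); BH correction; q < 0.05 and positive
  fold change define zone membership. Both-groups-zero genes get p = 1.
- **E-values.** `E = K m n exp(-lambda S)` with `(K, lambda)` calibrated
  once per scoring scheme by aligning random sequence pairs and fitting the
  *tail* of the score distribution (log survival regressed on score over
  survival 0.25 down to 5/n_pairs). Tail fitting, rather than whole-sample
  Gumbel ML, keeps predictions accurate in the ~1% regime where acceptance
  decisions are made; integer-lattice scores make the bulk fit unreliable.
- **Adjacency in target species.** "Flanking" in a non-reference species
  means the single nearest coding gene on each side of the placed locus
  (plus genes overlapping the locus), within a configurable window
  (default 5 Mb) beyond which adjacency is denied. The window exists
  because a purely visual adjacency judgment has no numeric analogue.
- **Tie-breaks.** Two genes with the same nearest edge: the
  lexicographically smaller gene id wins, deterministically.

## The synthetic generator: what it emulates

The generator emits a world with the statistical structure the analysis
assumes, not a biologically realistic genome:

- **Tree.** Pure-birth (Yule) tree rescaled to depth 1.0, ultrametric by
  construction, with a designated reference leaf "human". GI classes are
  clade-structured: the smallest clade containing the reference holding at
  least half the species is "high", the rest "low".
- **Loss process.** Each lincRNA neighborhood survives on the lineage to
  species *i* with probability `exp(-rate_i * d(human, i))`, with
  clade-specific rates (defaults: high-GI 0.5, low-GI 1.5 losses per unit
  branch length — the 3x contrast of the stated world). Loss is
  irreversible and independent across lineages (survival is drawn per
  species from the lineage's own exponential, not propagated as shared
  events on internal edges). On loss both flank orthologs are relocated to
  a junk chromosome; the distal genes become the locus's neighbors, so a
  relocated flank is never adjacent. Control ("non-neurodevelopmental")
  lincRNAs lose at the clade-averaged rate in all species, so their
  conservation is explained by divergence alone. The reference retains
  everything.
- **Geometry.** Each lincRNA occupies its own chromosome; spacer distances
  are log-normal with configurable median. The default median is 46 kb
  (the empirical calibration for the neighborhood-distance summary); the
  distribution *shape* is a declared choice, not an empirical claim.
  Sequence-bearing runs (homology exercised end-to-end) scale the median
  down (examples use 0.8–2 kb) purely so desk-scale alignment fits the
  runtime budget; the scoring logic is scale-free.
- **Sequences.** LincRNA loci carry the reference sequence, optionally
  mutated at per-site probability `1 - exp(-subst_rate * d)`; everything
  else is species-private random DNA. No indel or codon model (sequence
  realism is a non-goal); with `subst_rate = 0` placement is exact, which
  is what the truth-table equality tests require.
- **Counts.** NB with mean/dispersion parameterization (`Var = mu + phi
  mu^2`), log-normal per-gene baselines around mean 100, dispersion 0.05,
  four zones × 5 replicates, truly differential lincRNAs shifted by 2
  log2-units in one (occasionally two) germinal zones.
- **Tracks.** Per-lincRNA latent baselines (PhastCons 0.4 ± 0.15, PhyloP
  0.5 ± 0.3 between lincRNAs) shifted additively by `tf_effect` (default
  0.2) for TF-adjacent lincRNAs, plus per-base noise; PhastCons-like
  values clipped to [0, 1].
- **Traits.** GI uniform on (1.6, 3.2) for high-GI and (1.05, 1.45) for
  low-GI species (never exactly 1.5); log10 body weight and longevity
  increase linearly in GI plus noise; molecular-rate deviation is
  independent noise.
- **Reproducibility.** One master seed; each stage draws from
  `default_rng([seed, stage_offset])` with fixed offsets, so regeneration
  is byte-identical.

A green test on this world establishes that the *inference machinery* is
correct (placement exactness, truth-table recovery, calibrated error rates,
sign recovery of clade-contrasted loss). It does not establish anything
about real genomes: assembly gaps, annotation error, lineage-specific
duplications, non-independent loss events and sequence turnover are all
absent by design.

## Tolerances and degenerate inputs

- Ultrametricity is required (relative tolerance 1e-4 on tip depths) for
  the OU covariance; non-ultrametric trees raise a model-assumption error.
- Singular OU covariances raise with a condition-number report; an `alpha`
  estimate within 1% of a search bound sets `at_bound` and warns.
- Constant totals fit exactly (`theta = N`, all deviations 0) via the
  `sigma^2` floor. Percentage deviations require strictly positive
  expected counts and otherwise raise.
- Alignment problems up to 1e6 DP cells skip seeding and run the full
  dynamic program, so every instance up to ~200 bp × ~5 kb is exact;
  beyond that, sensitivity depends on an exact seed word surviving
  (contiguous 11-mer, or the spaced pattern `111010010100110111` in the
  fallback pass).
- Dispersion -> 0 in the generator switches NB draws to Poisson.

## Stated-world parameters for the headline checks

- OU parameter recovery runs at the stated design (102 tips, `theta = 60`,
  `N = 142`, `alpha = 2`, 200 replicates); the residual scale is not part
  of the stated design and is fixed once at `sigma^2 = 100` (stationary SD
  ~5 on counts of order 60–142 — modest comparative-data noise).
- The deviation-sign check uses 24 species, 142 lincRNAs, rates 0.5/1.5,
  100 replicates, and measures the pooled fraction of low-GI species
  deviations that are negative.
- The DE size check uses 30 samples per group (a "large n" null); the
  power check uses the stated 5 vs 5 at 4-fold, mean 200, dispersion 0.02.

## Known limitations

- The replication t-tests on the real per-lincRNA PhastCons/PhyloP table
  require that third-party supplement to be supplied by the user (see
  README); the code path is otherwise validated on a synthetic stand-in.
- Legacy `.xls` cannot be read in this environment (no `xlrd`); convert to
  `.xlsx` or CSV first.
- The scorer resolves only 1-to-1 orthologs; multi-copy families and
  synteny-block chaining are out of scope.
- The aligner searches supplied target sequences only; there is no
  genome-scale index, and targets beyond a few Mb per chromosome are
  outside the intended desk scale.
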