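# Methods

## The statistical problem

A diffuse-flow library is a mixture: organisms genuinely associated with
the vent habitat plus background deep-sea water entrained during
sampling. Comparing each vent library against its region's off-axis
(background) library identifies the OTUs whose relative frequency cannot
be explained by the background alone. Everything downstream — richness,
evenness, ordination, chemistry correlation — is then run both on total
communities and on the background-subtracted ("vent-specific") subsets.

## Differential-abundance tests

For an OTU with count `x` in a vent library of `N1` reads and `y` in the
off-axis library of `N2` reads, under equal underlying rates the
conditional distribution of `y` given `x` is

    P(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is negative binomial with `r = x + 1` and success probability
`N1/(N1+N2)`. The Audic–Claverie p-value sums this law over the
requested tail; both tails include the observed `y`, and the two-sided
value is the doubled smaller tail capped at 1. Tail sums are evaluated
in log space through `gammaln` (`logsumexp` over `k = 0..y` for the
lower tail; the upper tail is summed to 40 conditional standard
deviations past the mean, where the remaining geometric mass is below
double precision). The implementation agrees with an exact
rational-arithmetic (fractions.Fraction) brute-force oracle to < 1e-10
over randomized grids, and with the negative-binomial cdf/sf route as an
independent library cross-check.

Note that this conditional test is *not* exchangeable in `(x, y)` even
at equal depths: e.g. with `N1 = N2`, `x=5, y=0` gives `2·(1/2)^6` while
`x=0, y=5` gives `2·Σ_{k≥5}(1/2)^{k+1}` — a factor of two apart. The
direction that conditions on the vent count is used throughout.

The second test is the pooled two-proportion z test with
`p̂ = (x+y)/(N1+N2)`; degenerate pooled estimates (0 or 1) return
`z = 0, p = 1`.

**Enrichment rule.** An OTU is called vent-specific when (i) both tests
reject at `alpha = 0.01` (the conservative conjunction; `rule` exposes
either/ac_only/z_only), (ii) the frequency ratio is strictly greater
than `min_fold = 2` (with `+inf` when `y = 0`), and (iii) the direction
is vent-enriched (`x/N1 > y/N2`). No multiple-testing correction is
applied by default; a per-sample Benjamini–Hochberg layer sits behind
`fdr=True`. OTUs absent from both libraries are untestable and never
enriched. Per-sample bookkeeping (enriched set, vent-specific read
count, percent of library) and the region union (with its count of
union OTUs also detected off axis) are both emitted, since per-sample
and union scopes answer different questions.

## Alpha diversity

All estimators consume raw integer counts; relative frequencies are
never stored rounded.

* **Chao1 (bias-corrected, default):** `S = Sobs + n1(n1-1)/(2(n2+1))`
  with the classical variance formulas (separate `n2 > 0` / `n2 = 0`
  branches) and the log-normal 95% CI on `T = S - Sobs`. With no
  singletons the CI degenerates to `(Sobs, S)`. The classic
  `n1²/(2 n2)` form is available behind a flag.
* **Good's coverage:** `C = 1 - n1/N`.
* **Inverse Simpson:** unbiased `D = Σ n_i(n_i-1) / (N(N-1))`,
  estimate `1/D`, delta-method normal 95% CI from
  `var(D) ≈ (4/N)(Σp³ - (Σp²)²)`. The CI construction is approximate
  and documented as such (it is not a validation surface). All-singleton
  samples report `Sobs` with a degeneracy warning.
* **Simpson evenness:** `E = (1/D)/Sobs`, computed from the unrounded
  inverse Simpson. Worked-example comparisons against published table
  cells allow ±1 unit in the last printed digit because the published
  tables mix rounding and truncation.
* **np-Shannon (Chao–Shen):** coverage-deflated frequencies
  `p̃ = C n/N` with the Horvitz–Thompson denominator
  `1 - (1-p̃)^N`; natural log (the published magnitudes are in nats).
* **Rarefaction:** exact hypergeometric expectation
  `E[S_m] = Σ_i [1 - C(N-n_i, m)/C(N, m)]` via log-gamma; strictly
  increasing and concave with endpoint `Sobs`.
* **Phylogenetic diversity:** rarefied Faith-type PD — the mean, over
  `reps` (default 1000) subsamples of `m` (default 200) reads drawn
  without replacement (multivariate hypergeometric), of the total branch
  length of the union of root-to-leaf paths of the OTUs present in the
  subsample. The path to the tree's deepest shared ancestor is included;
  Monte-Carlo standard error is reported; `m = N` is deterministic.
  Whether the original "phylo diversity" column is exactly this Faith
  rarefaction is not fully specified; rarefied Faith PD is implemented
  and labelled as such.

## Beta diversity and environment correlation

* **θ_YC / Bray–Curtis** on relative abundances (vectors must sum to 1
  within 1e-9); distances are `1 - similarity`. NMDS operates on the
  θ_YC distance because stress minimisation needs dissimilarities.
* **NMDS:** SMACOF iterative majorization. Each iteration fits a
  monotone (isotonic) regression of configuration distances on the
  dissimilarities (exact ties pooled — the primary approach to ties)
  and applies the Guttman transform. Kruskal stress-1
  `sqrt(Σ(d - d̂)²/Σd²)` is tracked per iteration (non-increasing
  within a restart) and the best of `restarts = 20` initialisations is
  kept — one principal-coordinates start plus random starts. Defaults:
  `max_iter = 500`, `tol = 1e-7` on stress change. Coordinates are
  centred and principal-axis rotated; non-convergence returns the best
  configuration flagged `converged=False`.
* **Vector fitting:** per-axis Pearson `r_j` and magnitude
  `r = sqrt(Σ r_j²)` (biplot-vector semantics; per-axis values are also
  emitted). Retention: OTUs need `r ≥ 0.6` and ≥ 200 total reads;
  chemistry needs `r ≥ 0.2` after log transform. Constant variables are
  excluded with a warning. Under a permutation null with `n = 12`
  samples and 2 axes, `r²` is approximately `chi2(2)/(n-1)`, so the
  expected null retention rate at the 0.6 threshold is
  `exp(-(n-1)·0.36/2) ≈ 0.14` — the sequence floor, not the r filter,
  does most of the OTU screening.
* **Chemistry log transform:** `ln(value + pseudocount)` with the
  pseudocount equal to the variable's smallest positive observed value
  (concentration tables contain zeros); pH is exempt (already a log
  quantity); variables that remain non-positive are left untransformed
  with a warning.
* **BIOENV:** variables are log-transformed, z-scored, and searched
  exhaustively up to `max_subset_size`; each subset is scored by the
  Spearman ρ between its inter-sample Euclidean distances and the
  community dissimilarities. Requires ≥ 4 complete samples; variables
  with missing values are dropped with a warning. The result is
  invariant to variable ordering.
* **Clustering:** scipy agglomerative linkage (average by default — a
  standard choice for Bray–Curtis community clustering) on
  lexicographically sorted sample ids, making tie-breaking deterministic
  and input-order independent.

## Synthetic study generator

The generator emulates the two-region design with known truth at every
stage. Per region: one off-axis library and 4 (EPR) / 6 (Guaymas) vent
libraries; depths log-uniform over 15,000–77,000 reads.

* **Background:** dominant MGI OTU at exactly 0.60, secondary SUP05 OTU
  at 0.07 (EPR) / 0.13 (Guaymas), remaining mass lognormal
  (`sigma = 1.0`) over the tail of 500 / 300 background OTUs. At default
  depths the off-axis Good's coverage is ≥ 0.99. Taxonomy comes from a
  fixed 12-lineage vocabulary so domain partitions are deterministic.
* **Planted enrichment:** 396 (EPR) / 90 (Guaymas) vent-enriched OTUs
  with fold changes log-uniform on [2, 100]; 96% / 72% are entirely
  absent from the background (de-novo vent abundance lognormal, median
  1e-4, sigma 1.5), the remainder drawn from the rare background tail.
  Present OTUs receive *exactly* `fold x background` relative abundance
  (after per-sample jitter, floored so the realized fold stays > 2);
  the non-planted background is uniformly diluted to absorb the planted
  mass, so realized folds round-trip from the stored compositions to
  machine precision, and the generator errors out if the planted mass
  reaches 1.
* **Venting intensity:** each vent sample draws a latent
  `g ~ N(0,1)` (clipped to ±1.5) that (i) scales total planted mass
  (coupling 0.3), (ii) tilts composition *within* the planted set via
  fixed per-OTU sensitivities (coupling 0.6) — a uniform scale would
  cancel under renormalisation of the vent-specific subset — and (iii)
  scales the driver chemistry. This makes within-region community
  structure a one-dimensional gradient that the chemistry drivers
  track, which is precisely what BIOENV is supposed to find.
* **Chemistry:** lognormal noise (CV 0.3) around region means with the
  planted contrasts Co ×10 and Fe ×30 higher at EPR and Ni ×2.5 higher
  at Guaymas; NH4, sulfide and Mg are contrast-free distractors; pH is
  normal. Drivers (Co, Fe, Ni) additionally track the intensity
  gradient (coupling 0.75). Off-axis samples carry no chemistry.
  "BIOENV recovers the drivers" is scored as: the overall best subset is
  non-empty and contains only driver variables — the three drivers are
  redundant proxies of one gradient, so demanding all three would test
  redundancy rather than recovery.
* **Tree:** random coalescent-style topology by pairwise joining with
  exponential branch lengths, so PD is non-trivial and testable.

What the generator deliberately does **not** model: sequencing noise and
chimeras, PCR/primer bias, read-length variation, overdispersion beyond
multinomial sampling, shared OTUs between regions, and any spatial or
temporal structure. Passing the recovery suite therefore shows the
statistics behave correctly under the stated mixture model, not that the
upstream wet-lab pipeline is reproduced.

## Problem sizes and seeds

The validation suite (tests/test_acceptance.py, scripts/acceptance.py)
uses: 200 randomized cases for each oracle-agreement sweep; 100 null
replicates of 500-OTU libraries at depth 30,000 for the type-I
calibration; one default scenario for recall and NMDS silhouette; and 50
scenario seeds for BIOENV driver recovery. These sizes give stable
estimates (binomial SE below ~0.06 on the recovery rate) while keeping
the whole suite inside a few minutes. All randomness flows from explicit
seeds; the pipeline derives per-stage seeds by hashing stage names into
the root seed, so a run is reproducible end to end from `(inputs, seed)`.

## Known limitations

* The Audic–Claverie two-sided convention (doubled smaller tail) makes
  p-values conservative near the conditional mode and asymmetric under
  swapping the libraries (see above).
* The inverse-Simpson and Chao1 intervals are classical approximations;
  bootstrap intervals are out of scope.
* BIOENV inherits the usual selection-bias caveat: the best ρ over many
  subsets is optimistically biased; on pure-noise chemistry with 10
  samples its mean |ρ| is ≈ 0.2–0.3.
* OTUs are assumed pre-clustered (0.03 distance); no re-clustering,
  denoising, or taxonomy assignment is performed.
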