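# Methods

This note documents the models and procedures bloomnet implements, the
defaults it ships with and why, what the synthetic generator does and does
not emulate, and the known limitations.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Preprocessing

Rarefaction draws, per sample, a fixed number of reads without replacement
from the sample's count multiset (one multivariate hypergeometric draw per
sample), matching the random resampling of physical sequence reads; drawing
a sample's full depth is the identity.  Alpha diversity follows the classic
amplicon conventions: Shannon entropy in nats, the bias-corrected Chao1
estimator S_obs + n1(n1−1)/(2(n2+1)) (defined even when no doubletons
exist), and Good's coverage 1 − n1/N.  The prevalence filter keeps OTUs
with nonzero counts in at least `min_prevalence` samples (default 8, for a
12-sample design) and is idempotent.

## Eutrophication index

EI = DIN × DIP × COD × 10⁶ / 4500, DIN = NO3-N + NO2-N + NH4-N, DIP =
PO4-P, all in mg/L.  Concentrations below the instrument detection limit
are carried through parsing as explicit markers and substituted only when
the index is computed.  The default policy substitutes the limit itself
("<0.01" → 0.01): on the bundled field table this policy reproduces the
published index for the five samples whose inputs round-trip exactly
(AD1-2, AD2-2, AD2-3, AD3-1, AD3-2), whereas substituting zero or half the
limit does not.  The remaining samples do not reproduce exactly under any
constant substitution — their published values were evidently computed from
unrounded instrument readings — so they serve as plausibility context, not
as references.  Zero and half-limit substitution remain available
(`below_detection=`) for sensitivity analyses.

## Correlation input: why CLR

Correlations are computed between OTU rows of the rarefied table after a
configurable transform (`transform` = `clr` | `log` | `none`).  The default
is the centered log-ratio, log(x+0.5) minus the per-sample mean log,
computed on the full table before the prevalence filter selects rows (the
centering reference is the whole community).

The default is not cosmetic.  A bloom community carries one taxon with a
large, volatile share of the reads (the generator's default gives the focal
taxon 60% on average).  Proportions are closed: every other taxon's
relative abundance is modulated by the dominant taxon's swings through the
shared denominator, which manufactures strong pairwise correlations between
taxa that are statistically independent.  On raw proportions this closure
effect pushes roughly 1% of independent-pair correlations above |r| = 0.85
in the default synthetic community — enough that no threshold separates
planted from spurious edges.  The CLR cancels the per-sample denominator
exactly, and module recovery becomes near-perfect.  `none` and `log` are
retained for comparison with pipelines that correlate raw proportions.

## RMT threshold selection

The correlation matrix is hard-thresholded on an ascending grid (default
0.30–0.99, step 0.01).  At each candidate, rows with no remaining
off-diagonal entry are dropped, the retained submatrix is eigendecomposed,
and the spectrum is unfolded: a monotone PCHIP interpolant through quantile
knots approximates the cumulative spectral function, mapping the spectrum
to unit mean spacing.  The nearest-neighbor spacings are then tested
against the Poisson form P(d) = e^(−d) by a chi-square on 20 equal bins
over [0, 3] plus a pooled tail, with cells pooled right-to-left to expected
counts ≥ 5.  Spectra of matrices still dominated by correlated noise show
level repulsion (Wigner/GOE statistics) and are rejected; once only
decoupled modular blocks remain, spacings become exponential and the test
accepts.  The selected cutoff is the lowest candidate whose decision is
Poisson and stays Poisson for the next `persistence` candidates.

Numerical defaults and their provenance:

- **Unfolding knots.** The standalone `unfold_eigenvalues` defaults to 30
  knots, chosen by a calibration study on 200 independent true-Poisson
  spectra of 500 levels (false-rejection 5.0%, the nominal level; denser or
  coarser knots mis-calibrate to 6–9%).  The scan passes its own
  `unfold_knots = 20`, denser relative to its 100–300-level thresholded
  spectra; a single scale-free rule fails one regime or the other.
- **Persistence = 4.** Each candidate's chi-square decision carries the
  nominal ~5% error, so the accept/reject sequence wobbles inside the
  transition band; requiring four consecutive further acceptances prevents
  selecting a transient window.  On planted ground truth this stopping rule
  selects thresholds of 0.81–0.92 across seeds, bracketing the cutoffs
  (0.89–0.90) that the same procedure class reports on real bloom tables.
- **Significance 0.05, grid bounds, bin count** are exposed in
  `RmtScanConfig`; none is published by the upstream pipeline this stage
  reimplements, so all are engineering choices.

**Regime requirement (limitation).** NNSD-based selection assumes the
correlated blocks are a substantial share of the retained spectrum.  Sparse
*independent* noise fragments (dyads, small trees) have genuinely Poisson
spacing statistics — a superposition of independent spectra is
near-Poisson — so if noise OTUs dominate the retained node set the test
turns Poisson before noise edges are gone and the selected threshold is too
low.  Real tables are protected by their rank-abundance structure: most
rare OTUs fall to the prevalence filter.  The generator's defaults mirror
that (below), and the 10-seed recovery study in the decisions record shows
the failure mode surviving in roughly 2 seeds of 10; with 12 samples per
community this is inherent small-sample behavior, not a tuning artifact.

## Network, modularity, roles, nulls

Edges keep their correlation value and sign (|r| ≥ cutoff, sign of r);
isolated nodes are excluded.  All topology metrics ignore edge signs.
Mean geodesic distance averages over reachable pairs only, so
multi-component networks stay finite; clustering of degree-<2 nodes counts
as 0 in the mean.

Modularity is Q = Σ_s [l_s/L − (d_s/2L)²].  Community detection is
agglomerative greedy Q maximization (merge the connected pair with the
largest ΔQ = l_ab/L − d_a d_b/(2L²) while any gain is positive, ties broken
by the lexicographically smallest community-id pair), followed by a
deterministic Kernighan–Lin refinement: rounds of tentative single-node
moves — always the best remaining move, even when negative — keeping the
best prefix of each chain.  The refinement exists because pure greedy
merging lands measurably below the exhaustive optimum on a few percent of
small graphs (verified against brute-force enumeration over all partitions
of ≤ 8 nodes); with refinement the suite-wide gap stays within 0.05.  Both
stages are deterministic, so identical inputs give byte-identical module
assignments.

Null models preserve the degree sequence by attempted double-edge swaps
(10 × L attempts; swaps creating self-loops or multi-edges are rejected;
a star graph is correctly left unchanged).  `null_distribution` reruns the
full detection pipeline per replicate and reports mean ± sd of modularity,
geodesic distance and clustering (default 100 replicates; sample sd,
0 for a single replicate).

Zi is the z-score of a node's within-module degree against its module's
mean and population sd (Zi = 0 where the sd is 0, e.g. clique-like
modules); Pi = 1 − Σ_s (k_is/k_i)².  Roles use the conventional cutoffs:
module hub Zi > 2.5, connector Pi > 0.62, network hub both, peripheral
neither.  Note that in planted near-clique modules every member has the
same within-module degree, so Zi ≈ 0 everywhere and hubs only appear in
sparser, degree-heterogeneous networks — field networks, in practice.

## Community comparison

Bray-Curtis Σ|x−y|/Σ(x+y) on column-normalized profiles and Euclidean
distance, via scipy.  PERMANOVA partitions squared distances
(SS_total = Σ d²/N; within-group analog per group) into among/within sums;
pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)), R² = SS_A/SS_total.  MRPP's δ is the
group-size-weighted mean within-group distance; A = 1 − δ/mean(permuted δ).
Both tests enumerate all distinct relabelings when there are no more of
them than the requested permutation count (exact p, identity included) and
otherwise sample with the (1+b)/(1+m) estimator, which cannot return zero.
The single-factor screen is the one-term distance-based linear model on the
Gower-centered inner-product matrix (continuous predictor, permutation p),
run per variable and per metric to mirror the factor-by-factor screening
table of field studies; it is cross-checked against vegan's `adonis2` in
the tests.  Per-taxon comparisons use Welch's t on relative abundances with
both raw and Benjamini-Hochberg counts reported (raw 0.05 as the
field-convention default); a taxon constant on both sides with equal means
is reported as p = 1.

## Synthetic generator

Per OTU j (module m) and sample s:
log w_js = μ_j + σ(√ρ f_ms + √(1−ρ) ε_js), with f and ε standard normal,
so module members correlate at exactly ρ on the latent log scale
(default ρ = 0.95); background OTUs carry noise only.  The focal OTU (first
member of module 1) is rescaled to an expected community share of
`dominance` (default 0.6, the scale of cyanobacterial dominance in bloom
fractions).  Counts are one multinomial draw of `depth` reads per sample
(default 31,736, a realistic rarefied depth), so column sums are exact and
all sampling noise is composition-consistent.

Planted OTUs draw μ_j ~ N(0, 1); background OTUs draw
μ_j ~ N(background_log_mean, background_log_sd) = N(−6, 2), a rank-
abundance rare tail.  Consequently a realistic fraction of OTUs (roughly
half, at the defaults) falls below the 8-of-12 prevalence filter, as real
rarefied tables do.  This matters beyond realism: it is what keeps
independent background pairs scarce enough in the retained correlation
matrix for the RMT stage to work (see the regime requirement above).  The
default module structure is 5 modules × 30 OTUs in 300 OTUs / 12 samples —
module sizes at the scale of the largest modules in real bloom networks,
and large enough that the correlated blocks dominate the retained spectrum.

Environmental covariates are log-linear monotone functions of a module's
standardized total relative abundance plus lognormal noise (or pure noise
for unlinked variables), around baselines matching a late-bloom field
sheet.  Random-matrix fixtures provide the two reference spacing ensembles:
a symmetrized Gaussian matrix (GOE, Wigner statistics) and a diagonal of
independent uniforms (Poisson statistics).

What the generator does *not* emulate: phylogenetic correlation structure,
taxon-specific PCR/extraction bias, overdispersion beyond the lognormal
factor model, zero-inflation beyond multinomial sampling of rare taxa, and
any spatial or temporal autocorrelation between samples.  Passing the
planted-recovery tests therefore shows the chain is correct and calibrated
under a clean factor model at n = 12 — not that field tables at n = 12
will yield equally clean recovery.

All randomness flows from explicit seeds (numpy Generator); there is no
global random state, and the pipeline derives per-stage sub-seeds from one
master seed, making full runs byte-reproducible.

## Problem sizes

Defaults throughout are desk-scale by design: 300-OTU communities,
~70-candidate threshold scans on ≤ 300-level spectra, 100-replicate nulls,
999 permutations.  The test suite's heavier checks (brute-force modularity
enumeration, 20-seed calibrations, full planted recovery) complete in a few
minutes on one core.
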