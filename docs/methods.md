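# Methods

`nbacknet` analyzes band-specific cortical functional connectivity in a
two-condition working-memory experiment (0-back control vs. 2-back
load), from trial-wise regional band power to group statistics.  This
note records the model, its assumptions, the numerical choices, and
what the synthetic cohorts do and do not establish.

## Pipeline

For every subject, condition c ∈ {0-back, 2-back} and band
b ∈ {theta (4–7 Hz), alpha (8–12 Hz)}:

1. **Power series.** One band-power value per epoch and cortical region
   of interest (ROI), concatenated over the subject's correct trials:
   an 80 × n_trials matrix.  The 80 ROIs are the cortical subset of the
   116-parcel AAL atlas (26 cerebellar and 10 subcortical parcels
   excluded; EEG source estimates are unreliable at depth).
2. **Connectivity.** Pearson correlation between every pair of ROI
   power series → a symmetric 80 × 80 weighted matrix, unit diagonal.
3. **Proportional thresholding.** For each sparsity s on a grid
   (10–50%, full profile step 1%), keep the `round(s·N(N−1)/2)`
   top-ranked ROI pairs and binarize.  Ranking is by |r| by default
   (`signed` optional); ties break by ascending (row, col) index, and
   `round` is half-away-from-zero, so edge counts are exact and
   platform-stable.  The ranking is computed once per matrix, making
   the networks nested across the grid.
4. **Graph metrics.** Clustering coefficient C (mean over nodes of
   2Eᵢ/(kᵢ(kᵢ−1)), 0 where kᵢ<2), characteristic path length L (mean
   shortest hop count over ordered pairs; an error on disconnected
   networks), global efficiency E_global (mean of 1/d, unreachable
   pairs contribute 0), local efficiency E_local (mean global
   efficiency of each node's neighbor subgraph; subgraphs with <2 nodes
   contribute 0), and raw (unnormalized) betweenness centrality bᵢ with
   fractional counting over multiple shortest paths (Brandes
   accumulation).
5. **Null normalization.** γ = C/C_rand, λ = L/L_rand, σ = γ/λ, where
   C_rand and L_rand are means over (default) 100 Maslov–Sneppen
   degree-preserving surrogates.  A network is flagged small-world when
   γ ≥ 1.5 and |λ − 1| ≤ 0.15 (both configurable — the criterion
   "γ ≫ 1, λ ≈ 1" is qualitative).
6. **Integration over sparsity.** Every metric curve is reduced to its
   trapezoidal area over the sparsity range, removing the dependence on
   any single threshold.
7. **Group statistics.** Two-tailed paired t-tests 2-back vs. 0-back on
   the 7 integrated global metrics (α = 0.05) and on the 80 integrated
   nodal betweenness values (α = 0.01 uncorrected, with
   Benjamini–Hochberg FDR at q = 0.05 reported alongside — the dual
   reporting mirrors exploratory practice).  Reaction time and accuracy
   get the same paired test as a manipulation check.  Metrics with a
   significant group difference are then correlated (Pearson, p from
   the exact t-transform, df = n − 2) with reaction time and accuracy
   over pooled subject × condition observations (n = 2 × 28 = 56).
   Pooling is the default because reference r/p value pairs at that
   sample size are mutually consistent with df = 54 and not with
   df = 26; per-condition correlation is available via `rt_mode` and
   subsetting.

The code is organized statsmodels-style: `NBackNetworkModel` holds data
and configuration, `fit()` returns an `NBackNetworkResults` with the
test tables, `summary()`, plotting and `save()`.

## Null model details

Each surrogate performs `swap_budget × |E|` attempted double-edge swaps
((a,b),(c,d) → (a,d),(c,b)), rejecting self-loops and multi-edges.  Two
connectivity policies are implemented: `per-swap` re-checks
connectedness after each accepted swap and reverts on failure;
`final` (ensemble default) rewires freely, verifies connectedness once,
and retries with a perturbed seed on failure (falling back to per-swap
mode after 20 retries).  At the densities analyzed here (≥10%),
disconnected draws are rare, so both policies sample essentially the
same null; the final-check policy is faster by roughly the swap budget.
Every surrogate that leaves the sampler is verified to have the exact
degree multiset, edge count and connectedness of its source.  The full
profile uses a swap budget of 10; the fast profile (used for simulation
studies) uses 5, which mixes amply at these sizes while halving the
dominant cost.

## Synthetic cohorts

No recordings are distributed with the package, so a generator
(`generate_cohort`) emulates the study conditions: 28 subjects, 80
ROIs, correct-trial counts drawn per subject and condition from
N(42.30, 2.3²) and N(36.95, 4.6²) (the emulated design's mean ± SD, shared across
bands because both bands derive from the same trials, floored at 10).

**Marginals and copula.** Power is positive and right-skewed; trials
are drawn as exp(μ + σz) with z latent Gaussian (μ = 2.0, σ = 0.3).
Pearson correlations of lognormals attenuate the latent ρ slightly;
all tests are direction- and recovery-based, so this is accepted.

**Latent correlation structure.** Each condition × band cell uses the
elementwise maximum of

* a block structure: `rho_within = 0.60` inside 8 equal ROI modules,
  `rho_between = 0.35` outside, and
* a spatial kernel `0.92 · 0.94^(d−1)` over circular ROI distance d,
  emulating the strong short-range autocorrelation that source leakage
  imprints on neighboring parcels.

The kernel matters beyond realism: with ~40 trials, sample-correlation
noise (sd ≈ 0.1) otherwise isolates occasional nodes or detaches whole
modules at 10% sparsity, whereas real cortical recordings yield fully connected networks
over this entire density range.  Slow decay is forced by correlation
transitivity (a matrix with r = 0.92 to both neighbors cannot drop to
0.5 at distance 2), and the resulting near-diagonal edges are strong
enough (sampling sd ≈ 0.03) that the thresholded graphs retain a
connected lattice backbone.  Matrices are checked positive
semi-definite at construction (defaults need no repair; one
eigenvalue-clipping repair pass is applied if a configuration requires
it, then a hard error).  As a final guarantee the generator
rejection-samples each cell's power draw until the 10%-sparsity network
is connected (nestedness makes 10% the binding case; at the defaults
fewer than ~1% of draws are redrawn).  The synthetic distribution is
thus conditioned on the reachability property real data exhibit.

**Planted effects.**

* (theta, 2-back): off-block correlations rise by
  `delta_integration = 0.12` plus a subject effect ~N(0, 0.03²)
  (clipped at 3 SD).  Under rank-based thresholding the long-range
  edges displace short-range ones → λ decreases, E_global increases.
* (alpha, 2-back): within-block correlations fall by
  `delta_segregation = 0.12` (plus the subject effect) **and** the
  spatial kernel amplitude falls by half that amount.  The second
  component is essential: a pure within-block magnitude drop that
  preserves edge ranks leaves the *binary* graph almost unchanged
  (verified empirically — paired t ≈ 0 for any delta), because
  proportional thresholding only sees ranks.  Weakened local synchrony
  is also the natural physiological reading of reduced alpha-band
  segregation.

Effect sizes were calibrated so that recovery power at n = 28 is ≥ 0.9
for all three planted contrasts under the fast analysis profile.

**Behavior.** Reaction time is linear in the subject's own integrated
theta-band λ and integrated alpha-band C (computed from the subject's
simulated data via the same construction the analysis uses, 9-point
grid, 20 surrogates), plus a 2-back offset and Gaussian noise, floored
at 150 ms; coefficients are negative, planting the reported negative
RT–network correlations.  Accuracy is baseline minus a load drop plus
noise, clipped to [0, 1].  Non-target variants get small offsets so the
behavioral table has the study's four columns.

**RNG discipline.** All draws derive from
`SeedSequence([seed, crc32(subject), crc32(condition), …])`
substreams, so adding subjects or reordering analyses never perturbs
existing draws, and identical (config, seed) regenerate byte-identical
cohorts.

## What the synthetic tests do and do not show

Passing recovery tests show the pipeline detects integration and
segregation shifts of the planted form at realistic sample sizes, and
that its type-I rate is nominal when the two conditions are genuinely
exchangeable.  They do not validate the generator against real EEG:
volume conduction, 1/f spectra, artifacts, non-stationarity and
heterogeneous module sizes are not modeled, and the spatial kernel is a
stand-in for leakage, not a leadfield simulation.

One empirical caveat the simulations surfaced: with the study's
*unequal* correct-trial counts (≈42 vs. ≈37), the noisier 2-back
correlations systematically shift clustering-sensitive binary metrics
even with no condition effect (rejection rates up to ~0.11 at nominal
0.05 over 100 null cohorts).  Proportional thresholding equalizes edge
*count*, not estimator noise.  Type-I simulations therefore equalize
the trial-count distributions (exchangeable null); analyses of real
designs with unequal trial counts should consider trial subsampling.

## Profiles and problem sizes

The full profile (41 sparsity points, 100 surrogates, swap budget 10)
matches the reference protocol and is the default for single-cohort
analysis (~2 min for 28 subjects).  Simulation studies in the test
suite use the fast profile (9 points, 20 surrogates, swap budget 5) and
scale structure, not conditions: type-I control runs 200 null cohorts
at 40 ROIs; effect recovery runs 20 cohorts at the full 28 × 80 size.
Graph kernels are numba-compiled (dense adjacency, uint64 bitset BFS),
making a fast-profile cohort analysis a few seconds.

## Known limitations

* Betweenness is reported raw; any fixed-N normalization is a constant
  factor and cannot change the paired tests.
* The small-world flag thresholds (γ ≥ 1.5, |λ − 1| ≤ 0.15) are
  conventions; strongly lattice-like networks (e.g. Watts–Strogatz at
  low rewiring) can have σ ≫ 1 yet λ ≈ 1.2.
* L raises on disconnected networks rather than imputing; the
  generator's reachability conditioning makes this unreachable for
  default cohorts, but user-supplied data may trip it at low sparsity.
* Modules are equal-sized contiguous blocks; the spatial kernel and
  module structure are confounded by construction (both are
  short-range), which is why the alpha effect acts on both.
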