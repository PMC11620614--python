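# Methods

## Model

Sequence space is modelled as the Hamming graph over all A^L sequences of
length L: vertices are sequences, edges join sequences differing at exactly
one position by an allowed substitution. Each sequence is independently
functional with probability P_fs (site percolation). A cluster is a connected
component of the functional subgraph; a continuous functional path (CFP) is a
path within one. For a vertex-transitive graph of degree z the percolation
threshold is approximately 1/z, and 1/z is a lower bound that the true
threshold approaches from above as degree and size grow. With z = A_t·L
single-mutation neighbours, and (A_t·L)^{n_m}/n_m! neighbours within n_m
mutations, the working approximation is

    P_th(n_m) = n_m! / (A_t·L)^{n_m}.

This is treated throughout as a conservative lower bound on the true
threshold, which the simulator quantifies empirically.

Around a wildtype, local functionality decays as the hyper-exponential
P_loc(n) = exp(-alpha·n - beta·n^2), the standard form under pervasive
negative epistasis (beta > 0). The maximum Hamming distance n_max with
P_loc(n) > P_th is the positive root of beta·n^2 + alpha·n = -ln(P_th),
rounded to the nearest integer. An alternative stepwise estimate multiplies
per-round tolerated-mutation fractions cumulatively and returns the last step
whose running product still exceeds P_th (strict inequality).

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| A_t | 7.5 | average amino-acid transitions reachable per nucleotide mutation (genetic-code average); the idealised simulator uses A - 1 |
| nonsynonymous fraction | 0.69 | fraction of random nucleotide mutations that change the protein; rescales all-mutation decay coefficients by 1/f (alpha) and 1/f² (beta) |
| cluster cap | 20,000 | BFS stops and flags the cluster "large" past this size; at the scales studied every cluster beyond it spans the space |
| detect fraction | 0.05 | large-cluster fraction defining the empirical transition point in a sweep |
| sweep grid | 0.016–0.024, step 0.001 | occupancy range bracketing 1/60 for the L=10, A=7 space |
| max_nm | 200 | search bound for the minimum mutation count; P_th(n_m) is not monotone forever (the factorial eventually dominates), so absence below the bound is an explicit not-found condition |

## Numerical choices

- All threshold arithmetic is in log space (log-factorial via `lgamma`), so
  n_m up to a few hundred and L up to 10^4 never overflow, and the minimum-
  mutation-count comparison `P_th(n_m) <= P_fs` is performed on logarithms.
- Biasing-ratio exponents use floor(log10 x), corrected by direct power
  comparison so exact powers of ten are never off by one ulp. The bundled
  literature table is internally inconsistent between floor and
  nearest-integer exponents; floor reproduces more rows and mismatches are
  annotated, not silently corrected.
- Display rounding follows the source tables: thresholds at two significant
  figures (trailing zeros kept), identities rounded half-up (the source
  tables round 72.5 to 73), one decimal for the local-functionality table.
- The strict minimum-mutation-count rule (first n_m with P_th <= P_fs)
  reproduces 9 of the 16 printed rows; the seven deviating rows (all by one
  mutation except one outlier row that is consistent only with a much larger
  A_t) are flagged in fixture metadata and excluded from the matching tests.
  An order-of-magnitude relaxation reproduces a different subset while
  breaking rows the strict rule gets right, so a single criterion cannot
  reproduce the full printed column.
- The local-functionality fit is nonlinear least squares in linear p-space
  (`scipy.optimize.curve_fit`), seeded by the exact log-space polynomial
  solution, which is also available behind `log_space=True`. Observations at
  excluded Hamming distances (e.g. a known outlier at n = 1) are dropped
  before fitting.
- The hyper-exponential n_max uses nearest-integer rounding of the
  continuous root; the alternative "largest n with P_loc(n) > P_th" gives
  one-lower values for two of the three bundled proteins and was rejected.
  Note the printed sequence identity for the GFP row (95.0%) corresponds to
  the unrounded root; the identity formula applied to the integer n_max = 12
  gives 94.9%, which is what the package reports.

## Simulator

- **Lazy occupancy.** Each sequence's uniform deviate is a SplitMix64-style
  integer hash of (seed, flat base-A index), mapped to [0, 1) at 53-bit
  precision. No matrix is materialised: the 2.8 × 10⁸-sequence L=10, A=7
  space needs only the BFS frontier in memory. The hash is deterministic and
  platform-independent, so identical configurations replay identically, and
  thresholding the *same* deviates at two occupancies yields an exact
  monotone coupling: the functional set at lower P_fs is a subset of the set
  at higher P_fs, hence per-seed cluster size is non-decreasing in P_fs.
  Equivalence in distribution with materialised numpy-RNG occupancy was
  verified directly on the full L=10, A=7 space.
- **Traversal.** Iterative breadth-first search with an explicit frontier
  (no recursion), vectorised neighbour generation, and a visited set holding
  cluster members only; nonfunctional candidates are re-hashed on
  re-encounter rather than stored. Verified exactly against networkx
  connected components on exhaustively enumerated small spaces.
- **Start and target.** The start sequence (all first letter) is functional
  by construction — a nonfunctional start would make every trial degenerate —
  and a target hit must itself be functional, since it terminates a CFP.
  Both behaviours are config switches. The target is the all-second-letter
  sequence plus its Hamming ball of radius Tol.
- **Restricted transitions.** When A_t < A - 1, allowed substitutions are
  symmetric cyclic offsets (±1 … ±A_t/2 mod A). Symmetry requires a
  negation-closed offset set, so an odd A_t is only accepted for even A
  (where the self-inverse half-turn offset exists); odd A_t with odd A is
  rejected — an odd-degree symmetric circulant on an odd cycle cannot exist.
- **Power-law fit.** The cluster-size exponent tau is estimated by
  regressing log10 density on log10 size over logarithmic bins (6 per
  decade), with three standard refinements: bins holding fewer than 5 sizes
  are dropped, each bin's abscissa is the empirical mean of its sizes, and
  the regression is weighted by sqrt(count). On synthetic discrete power-law
  samples (inverse-CDF, n = 10⁴, s_min = 5) this recovers tau = 2 within
  ±0.08 and tau = 3 within ±0.14 across 30 seeds; a maximum-likelihood
  estimator is deliberately out of scope.

## Synthetic data and what the tests show

Test inputs are generated programmatically: exhaustive small spaces
(A^L ≤ 10⁴) for oracle comparisons, hash-seeded replicate spaces at the
study's stated sizes (L=10, A=7; grid 0.016–0.024; 50–100 replicates per
point; cap 20,000; 100-run size distributions), noiseless and
lognormal-noised hyper-exponential decay curves, and inverse-CDF power-law
samples. These emulate the idealised uniform-occupancy model exactly — which
is the object of study — but not real fitness landscapes: real functional
sequences are correlated, anisotropic and biased toward wildtypes, so
passing tests validate the percolation machinery, not any claim about a
particular protein's landscape beyond the literature P_fs and decay inputs.

## Problem sizes

The bundled analytic tables are instantaneous. Simulation-backed checks use
L=10, A=7 with 50 replicates per grid point in the test suite and 100 in the
acceptance script, 100-run size distributions, and 10-trial connectivity
means; the full test suite runs in well under two minutes and the acceptance
script in about ten seconds on one CPU.

## Known limitations and open discrepancies

- The simulated phase transition at L=10, A=7, measured as the smallest grid
  occupancy with ≥5% space-spanning start clusters, is 0.020 — 0.33
  percentage points above 1/60, somewhat larger than the ~0.2-point offset
  the source analysis reports. The measurement is robust to the replicate
  count (the large-cluster fraction at 0.019 is 0 in over 300 replicates),
  reproduces identically under materialised numpy occupancy, and the
  traversal is oracle-verified, so the package reports the computed value.
- Near the transition (occupancy 0.019), a few percent of start clusters
  fall between 300 and 20,000 sequences: the strict small/large bimodality
  holds away from the critical point but not arbitrarily close to it, where
  cluster sizes are power-law distributed.
- Four-to-seven rows of the bundled protein table cannot be reproduced by
  any single minimum-mutation-count criterion (see above); the reproduction
  report annotates every such cell rather than matching it.
- The simulator is n_m = 1 only; multi-mutation neighbourhoods enter solely
  through the closed-form threshold. No indel moves are modelled.
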