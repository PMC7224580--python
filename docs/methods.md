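# Methods

## Model

The two-site, sequential, distributive PTM cycle — forward enzyme `E`
modifying `S0 -> S1 -> S2`, reverse enzyme `F` demodifying `S2 -> S1 -> S0`
— is treated at steady state only.  Each of the four enzymatic reactions
may follow an arbitrary mechanism of intermediate complexes; all mechanism
detail is aggregated into generalised binding parameters (reciprocal total
generalised Michaelis–Menten constants) and generalised catalytic
efficiencies.  Flux balance around each modification loop, substrate
conservation and enzyme conservation reduce the network to two bivariate
polynomials `Phi1, Phi2` of total degree 4 in the normalised free-enzyme
concentrations `(u, v)`, whose common zeros are the steady states.

Non-dimensional parameters, in the fixed theta-order used everywhere:

| theta | symbol | meaning | default box |
|---|---|---|---|
| 1 | alpha | catalytic-efficiency ratio of the S0<->S1 loop | [0.1, 10] |
| 2 | beta  | catalytic-efficiency ratio of the S1<->S2 loop | [0.1, 10] |
| 3 | eps0  | binding of S0 to E, x E_tot | [0.1, 10] |
| 4 | eps1  | binding of S1 to E, x E_tot | [0.1, 10] |
| 5 | eps2  | rebinding of the product S2 to E, x E_tot | [0.1, 10] or 0 |
| 6 | phi0  | rebinding of the product S0 to F, x F_tot | [0.1, 10] or 0 |
| 7 | phi1  | binding of S1 to F, x F_tot | [0.1, 10] |
| 8 | phi2  | binding of S2 to F, x F_tot | [0.1, 10] |

Weak irreversibility keeps `eps2, phi0 > 0` (products can rebind, as
thermodynamics requires); strong irreversibility forces them to zero
exactly, leaving a six-parameter system.  Conserved totals enter as
`sigma = S_tot/E_tot`, `lam = S_tot/F_tot`, `zeta = E_tot/F_tot`; the whole
study fixes `zeta = 1`, `lam = sigma` and scans `sigma`.  `lam` is stored
independently so that unequal enzyme totals remain expressible.

Two independent construction routes guard against coefficient
transcription errors: the fully expanded 24-term coefficient grids, and a
factorised form `zeta*u*v*((1-u)(psi1 + u psi2 + v psi3) - sigma*u*psi2)`
built by polynomial arithmetic from the rational functions `psi_k` spanned
by `{v/u, 1, u/v}`.  The psi coefficients used are
`psi1 = (alpha/zeta, 1, beta*zeta)` (and the eps-/phi-weighted analogues),
which make the two routes agree identically for every `zeta`; with
`zeta = 1` — the only configuration analysed — this coincides with the more
common presentation that attaches `zeta` to the first slot.  Tests verify
route agreement on 1000 random draws and against an exact rational
symbolic expansion.

Only stationarity is assessed: one positive real solution is called
monostable, three bistable.  Stability proper would require fixing a
concrete mechanism and examining Jacobian eigenvalues of the full kinetic
system, and is out of scope.

## Solver

Bezout's bound gives 16 projective solutions.  Generic structure (verified
as an invariant, never assumed silently): origin of multiplicity 6, seven
finite nonzero solutions (five under strong irreversibility), the rest at
infinity.  The solver:

1. **Elimination.**  Sylvester resultant in `v` (7x7 for weak, 5x5 for
   strong mode), with the determinant evaluated at the 17th (batch) or
   33rd (careful path) roots of unity and interpolated by FFT — exact up
   to rounding since the resultant degree is 13 (weak) / 11 (strong).
2. **Structural deflation.**  The origin's `u^6` factor is removed by
   index, not by thresholding the valuation: at large `sigma` the
   coefficient `c6` legitimately sits many orders below the largest
   coefficients, and a magnitude test would misread it as zero.  The
   surrounding structure (nothing below index 6, nothing above the generic
   degree) is still checked.
3. **Roots.**  Companion-matrix eigenvalues of the deflated factor after
   geometric coefficient balancing (`u -> s x` with
   `s = (|c_low|/|c_high|)^(1/deg)`).
4. **Back-substitution.**  `v`-candidates from both polynomials at each
   `u`-root; the candidate minimising the scaled residual wins.
5. **Newton refinement** on the full 2x2 system, followed by
   *realification*: a near-real iterate is re-polished in real arithmetic,
   and accepted (imaginary part exactly zero) only if the real iteration
   converges back onto it.  This is what lets the magnitude classifier
   below operate with double precision.
6. **Classification** of each coordinate as small / ambiguous / infinite /
   nonzero-real / nonzero-nonreal by magnitude thresholds
   (`t_zmin = 1e-25`, `t_zmax = 1e-10`, `t_inf = 1e8`), evaluated in that
   order.  A point is positive real iff both coordinates are nonzero-real
   with positive real parts.

### Multi-scale rescue and escalation

At large `sigma` the seven finite solutions split into a cluster of size
`~1/sigma` (the physical, enzyme-saturated branch) and clusters up to
`~10 sigma`.  A determinant evaluated on the unit circle cannot represent
resultant coefficients more than ~14 orders below its largest one, so no
single evaluation scale resolves all clusters in double precision.  Points
failing any genericity check are re-solved with the variables rescaled by
`1/sigma` and by `sigma`, each rescaled elimination truncated at its noise
floor, and the candidate roots of all passes pooled, polished and
deduplicated.  Remaining stragglers escalate per point: plain 33-node
elimination, pooled dual-scale, sheared projection (`u -> u + g v`), and
finally an exact-rational resultant with 50-digit multiprecision roots.
Only a point that survives none of these is labelled NONGENERIC — it is
excluded from estimator numerators and denominators and tallied, never
silently dropped.  At `sigma = 500` about 0.4% of points take the rescue
pass and well under 0.1% reach the exact rung; NONGENERIC labels are
rare enough that none appeared in runs of 2x10^5 points.

Two artifacts of the multiplicity-6 origin needed explicit handling: both
curves share the same quadratic tangent cone, so (a) Newton can stall at
tiny nonzero coordinates with tiny residuals (rejected when an iterate has
moved into `|u|+|v| < 3e-5` by more than 25% of its own starting
magnitude — genuine solutions stay above `~1/(20 sigma)` for every `sigma`
used), and (b) the origin's resultant valuation exceeds naive expectations
under some projections, which is why deflation is structural.

A Newton-contraction certificate (non-singular Jacobian, quadratic step
contraction over three iterations) stands in for exact alpha-theory
certification; the origin, being singular, is never certified.  The local
intersection multiplicity of the origin is read off as the `u = 0`
valuation of the resultant, with a sheared projection when another
solution sits near `u = 0`.

An independent cross-check solves with the opposite elimination order
(`u` instead of `v`); tests require the two solution sets to agree on 100
random draws.

## Sampling and estimators

* **ILR sampling**: each log10 coordinate independent and uniform on
  `[-p, p]`.  All randomness flows through a counter-based Philox
  generator keyed by explicit seeds.
* **Volume**: the bistable fraction of the (generic) sample, CI half-width
  `z * delta_hat / sqrt(n)` with `delta_hat` the sample standard deviation
  of the indicator.  Zero bistable points report the rule-of-three upper
  bound `3/n`.
* **VEGAS**: per axis, the 50 bins over `[-1, 1]` are re-sized so that
  each contains an equal share of the smoothed projected bistable mass
  (smoothing `f <- ceil(K f / #set) + 1`, `K = 1000`, so empty bins keep
  nonzero weight); each iteration draws `N` points with a near-equal
  stratified allocation over bins (one shared uniform offset per axis, the
  allocation assigned to points in an independent random order per axis so
  bin ranks on different axes are uncorrelated), each coordinate uniform
  within its bin.  Defined for the `p = 1` box only.  At `sigma = 10` a
  two-iteration run enriches the bistable fraction of draws by a factor of
  ~50 over ILR sampling.
* **Connectivity**: spanning forest of the fixed-radius graph by BFS with
  exact KD-tree ball queries; the component partition equals the full
  graph's (brute-force-verified on small sets), the edge set is traversal
  dependent and not contractual.  The closed-form radius
  `Delta = [V_H (1 - (1-c)^(1/(N-1))) / c_d]^(1/d)` (unit d-ball volume
  `c_d`, coverage `c = 0.99`) is evaluated at the run's own effective
  sample size `N' = (#bistable_augmented / #bistable_initial) * N_initial`.
  The conventional fixed value 0.15 presumes `N' ~ 5e8`; desk-scale runs
  get `Delta ~ 0.3-0.5` from the same rule.
* **Refinement**: non-largest components are joined toward the largest by
  testing bistability along segments to the K approximate nearest
  neighbours (KD-tree with relative slack 0.001), sub-divided at
  `0.98 Delta`; K grows per iteration by the rule (j+1, 3(j+1), 10(j+1))
  according to the size of the second component; iteration stops when the
  largest-component share stabilises.
* **Visibility**: M pairs of distinct bistable points drawn without
  replacement; the K-fold ratio tests the K equally spaced interior points
  `t = j/(K+1)` of each log-space segment and therefore upper-bounds the
  true visibility ratio.  The CI carries the finite-population correction
  `sqrt(1 - M/N)` with `N = (#bistable)^2`.
* **Blinking**: on a common sample labelled across the grid, a point is
  blinking at `sigma` if bistable there and monostable at some larger grid
  value; "asymptotically monostable" means monostable at the largest grid
  value (500 in the main grid).  Points with any NONGENERIC entry in their
  profile are disqualified and counted.
* **Tradeoff**: `K_hat(sigma)` is the sample maximum of
  `eps2 * phi0` over bistable points — an empirical bound, not a fitted
  hyperbola.  At desk scale this statistic fluctuates by ~±30% between
  samples of ~2000 bistable points, more than the bound grows across the
  upper sigma grid, so its increase with sigma is not reliably resolvable
  here; measurements on enriched samples even show the maximum falling
  from sigma = 10 to 500, consistent with extreme-rebinding bistable
  points being blinking boundary points that leave the region as sigma
  grows.

## Problem sizes

The study conditions are those of the source analysis; simulation sizes
are chosen so a desk machine reproduces the *qualitative* results with
defensible statistics.  Tests and the acceptance script use: 2x10^5 ILR
points for the weak-mode volume at `sigma = 500` (Monte Carlo standard
error ~0.023 pp at a 1.05% fraction) and for the blinking scan over the 13
grid values `sigma >= 2`; 2x10^4 points for the strong-mode volume
(standard error ~0.29 pp at 20%); 10^5 points for the `sigma = 1`
zero-volume check; VEGAS with T = 2 iterations of 5x10^4 points; 500 pairs
for visibility.  Cluster-scale absolute counts (millions of bistable
points per sigma) are explicitly not reproduced; the qualitative patterns
— one giant component, >10x enrichment, blinking points on the region's
boundary, `K_hat` increasing in `sigma` — are asserted instead.

## What the synthetic sampling shows and does not show

All inputs are internally generated parameter points; there is no external
data.  Passing tests therefore demonstrate properties of the mathematical
model under log-uniform sampling of the stated boxes — not properties of
any measured enzyme system.  In particular the box `[0.1, 10]` encodes the
choice of 1 as the nominal value of every non-dimensional parameter;
conclusions such as the ~1% saturating bistable volume are relative to
that measure and box.

## Numerical choices and degenerate inputs

* Dedup tolerance 1e-8 (relative); merged clusters flag the point
  NONGENERIC rather than guessing multiplicities.
* Residual acceptance 1e-10 relative to the coefficient scale times the
  local term magnitude `max(1, |u|+|v|)^4` — an absolute bound is
  unattainable for the legitimately huge far-cluster solutions.
* An ambiguous coordinate (imaginary magnitude between `t_zmin` and
  `t_zmax`) triggers escalation; after the 50-digit pass the ambiguity
  threshold tightens to 1e-11 before a point is declared NONGENERIC.
* The stratified VEGAS assignment rule is clipped at the last bin (the
  raw offset rule would otherwise address bin M+1 for the final
  points of an iteration).
* `estimate_volume` requires at least two generic points;
  `estimate_visibility` refuses more pairs than exist; VEGAS refuses an
  empty seed set (bootstrap with ILR first) and coordinates outside the
  unit box.

## Known limitations

* No homotopy continuation and no exact alpha-theory certificates; the
  Newton-contraction certificate is heuristic (though backed by the exact
  elimination rung).
* Projective solutions at infinity are not enumerated; only the finite
  count is checked against the Bezout bookkeeping.
* Stability of steady states is not assessed anywhere.
* The desk-scale connectivity graphs say nothing about fine topological
  features (holes, higher Betti numbers); persistent homology is out of
  scope.
* VEGAS is defined only on the `p = 1` box, as used in the analysis.
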