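# Methods

## Model and procedure

The method treats a normal-tissue co-expression network as a population
reference and estimates, for one case sample at a time, which reference
interactions that sample has lost. It assumes (i) control expression is
normalized and comparable across samples, (ii) an interaction is
well-described by a linear co-expression relationship over controls, and
(iii) a case sample whose expression pair sits far from that control
relationship has perturbed the interaction. No claim is made about
direction (strengthened vs. weakened co-expression is not distinguished)
or mechanism.

Stages, with the quantities they produce:

1. **Reference network** (controls only). Unsigned soft-threshold
   adjacency `|r|^β`; TOM similarity; average-linkage clustering of
   `1 − TOM`; a permutation preservation filter against a held-out
   control split; per-community retention of the top-weight fraction of
   gene pairs. Edges are TOM weights in (0, 1] and exist only inside
   communities — every downstream quantity is per-community, so
   cross-community pairs never enter any score.
2. **Edge models** (controls only). Per edge, OLS of the
   lexicographically larger gene on the smaller, plus the median and MAD
   of control perpendicular distances to the fitted line.
3. **Individualization** (one case sample). Modified z-score of the case
   distance, one-tailed normal p, flag at `p < α`; flagged edges are
   removed.
4. **Scoring.** Weighted global efficiency per community
   (path length `Σ 1/w`, disconnected pairs contribute 0); cohesion score
   = individualized/reference efficiency ratio; per-gene connectivity
   loss = flagged incident weight fraction; druggable-target ranking.
5. **Stratification.** Threshold sweep of cohort cohesion scores against
   survival with the log-rank test.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| soft power β | `"auto"` (smallest of 1..20 with scale-free fit R² ≥ 0.8, argmax fallback) | adjacency sharpening; `6` is the conventional unsigned choice and what the synthetic workflows pass explicitly |
| top fraction | 0.1 | per-community edge retention by TOM weight (ties: lexicographic pair order) |
| min community size | 30 genes | clusters below this become `unassigned` and are never scored |
| preservation | 200 permutations, Zsummary > 10, split 80/20, seed 17 | two-statistic Zsummary: z of test-split TOM density + z of train/test intra-community connectivity correlation, averaged |
| α | 0.001 | per-edge one-tailed flag threshold (z > 3.09); no multiple-testing correction across edges, deliberately |
| MAD constant | 1.486 | scale factor in the modified z-score as the method defines it; 1.4826 available via `mad_constant` |
| sweep | step 0.001, min group 10, horizon 5 | grid `0, step, …, 1`; `score < t` is the low-cohesion group; events after the horizon are censored at it |

## Numerical and convention choices

- **Disconnected pairs.** The efficiency sum assigns disconnected pairs a
  contribution of zero (the standard global-efficiency convention). The
  alternative reading "distance = 0 ⇒ contribution 1/0" would make every
  score with an isolated gene infinite and contradicts the score's [0, 1]
  range, so it is rejected.
- **Shortest paths** run on each community's dense submatrix via
  `scipy.sparse.csgraph` Dijkstra (all `1/w > 0`); the test suite checks
  agreement with an independent hand-written Floyd–Warshall to 1e-10
  relative error.
- **Regression orientation.** Perpendicular distance to an OLS line is
  not symmetric in which gene is the regressor; the lexicographically
  smaller gene id is always X. This is a documented convention, not a
  claim about the biology.
- **Degenerate scales.** A zero-MAD edge makes the modified z undefined;
  any excess over the median is treated as +inf (flagged at any α), a
  case at or below the median as 0. Zero-variance regressors make an
  edge unfittable; such edges are dropped from the reference before any
  scoring so reference and individualized efficiencies always share an
  edge universe, and more than 10% of them aborts the run as malformed
  input.
- **Exact boundary losses.** A gene whose every incident edge is flagged
  gets connectivity loss exactly 1.0 (not a float sum that may land at
  1 − 1e-16), so ties at total disconnection are decided by the
  documented strength tie-break rather than by summation order.
- **Community detection cut.** Dynamic tree cutting is replaced by a
  static cut at the merge height (among candidate heights) maximizing
  weighted modularity of the induced partition. The downstream math is
  agnostic to the cutter; the static cut is deterministic and directly
  testable. Ties favor the first maximizing height.
- **Sweep ties** resolve to the smaller threshold; the optimized p is
  reported as-is and is optimistic by construction (the output says so).
  Thresholds inducing identical splits share one log-rank evaluation —
  a pure caching step with no numerical effect; the grid log-rank is a
  vectorized Mantel–Haenszel implementation verified against lifelines
  to machine precision, and `logrank()` itself delegates to lifelines.

## Calibration of the modified z-score

Perpendicular distances are *folded* residuals: under a Gaussian edge
model they are `|N(0, σ_perp)|`. The median of that distribution is
0.6745·σ_perp and its MAD is 0.3991·σ_perp, so 1.486·MAD ≈ 0.593·σ_perp —
the 1.486 constant restores σ for *signed* Gaussian residuals, not for
folded ones. Referencing the modified z against the standard-normal upper
tail therefore flags more than the nominal α of null edges: analytically
≈1.2% at α = 0.001 and ≈4% at α = 0.01, which is exactly what
`scripts/acceptance.py` measures as `null_edge_flag_rate_at_alpha_0.01`
on null cases. The flag threshold is thus best read as a fixed robust
cutoff (`d > d̃ + 3.09·1.486·MAD` at α = 0.001) rather than a calibrated
error rate. The detection and ranking results are unaffected — they
depend on contrast between perturbed and null edges, not on the nominal
level — but users comparing flag counts across α values should be aware
of the inflation. An empirical-null option is a possible extension; it is
not implemented.

## What the synthetic generator emulates — and what it does not

`simulate` produces the statistical structure the method assumes:

- **Controls**: multivariate-normal draws; each planted community is a
  single-factor block whose loadings decline ~10% from the first gene
  (the designated hub) to the last, calibrated so the mean pairwise
  within-block correlation equals `within_correlation` (default 0.9);
  blocks are mutually independent and background genes are pure noise.
  The hub gradient matters twice: real co-expression modules have
  hub-to-periphery structure, and the preservation filter's
  connectivity-correlation statistic is uninformative on an exchangeable
  (equicorrelated) block — with the gradient, planted communities pass
  Zsummary > 10 robustly.
- **Cases**: drawn from the control distribution, then decorrelated
  inside one target community by independently re-drawing a gene subset
  sized to cover the requested fraction of pairs (re-draw, not
  mean-shift: the method detects co-expression deviation, and a
  mean-shifted-but-correlated sample should *not* be flagged). In hub
  mode only the designated hub is re-drawn, with its spread inflated
  (the hub-mode studies use 20× the control SD): this emulates a gene so
  grossly dysregulated that it loses effectively all its reference
  connectivity — at marginal severity a re-drawn value lands near the
  regression line too often for "loses all connectivity" to be
  reachable, so the severe regime is the one the scenario describes.
- **Survival**: exponential event times, hazard ×`hazard_ratio` for
  low-cohesion samples, uniform censoring.

Default scale: 300 genes in five blocks of 40–80, 500 controls, 200
cases — sizes chosen so per-edge distance summaries are stable and the
full pipeline runs in seconds on one CPU.

Not emulated: RNA-seq count noise (negative binomial marginals), batch
effects, between-community correlation, and real-data gene symbol/
annotation issues. Passing tests on these fixtures show the machinery is
correct and the planted signal is recovered under the model's own
assumptions; they do not certify performance on real cohorts with batch
structure or non-Gaussian noise.

## Known limitations

- Single-sample flags are marginal per edge; no FDR control across the
  ~10³ edges of a reference network (by design, matching the method).
- The optimal-cutpoint log-rank p is threshold-optimized and should be
  validated on an independent cohort before clinical interpretation.
- Communities dropped by the preservation filter are silently absent
  from all score matrices; inspect the preservation report when a label
  you expect is missing.
- The scale-free fit criterion in `pick_soft_power` has no meaningful
  regime on block-structured data (including these fixtures); it exists
  for real transcriptome-scale inputs, and the fallback behaviour is a
  logged argmax, never an error.
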