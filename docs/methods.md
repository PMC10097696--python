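# Methods

## Model

### Reputation dynamics

The population state is the image matrix `M(t)`: integer scores
`r_ij ∈ [V, A]` that player `i` privately assigns to player `j`, including
`i`'s own self-score `r_ii`.  Judgments are thresholded scores: `j` is good
in `i`'s eyes iff `r_ij ≥ S` (a `tie_rule` option makes the comparison
strict; simulations show no qualitative difference, and the lenient rule is
the default).  All players share one assessment frame `(V, A, S)`; the
symmetric frame `(-R, R, 0)` is standard, and `(0, 1, 1)` recovers the
binary-reputation baseline exactly (see *Binary reduction* below).

Each round one ordered (donor, recipient) pair is drawn uniformly from the
`N(N-1)` possibilities.  The donor acts according to their norm's action
table applied to their own judgments `(J_dd, J_dr)`.  The donor's score is
then updated *in the eyes of each updater independently*: each updater
applies their own assessment table to their own pre-round judgments of
donor and recipient and the action they perceived, moving `r_i,donor` by ±1
with clamping at the frame bounds.  Only the donor's column of `M` can
change in a round.

Who updates, and with what error, is the one place the verbal model is
ambiguous; the package's conventions are:

* the **donor** always updates their self-score and perceives their own
  action without error (people know what they did);
* the **recipient** always observes, but misperceives the action with
  probability ε like any observer;
* each **third party** observes with probability q and, if observing,
  misperceives with probability ε — all independently.

Flags on `GameParams` (`donor_self_update`, `recipient_error`) expose the
alternative conventions.

### Norm tables

All leading-eight norms share the bits that make cooperation stable under
public information: cooperation with a good recipient is assessed
positively, defection against a good recipient negatively, justified
defection (good donor, bad recipient) positively; good players cooperate
with good recipients, defect on bad ones, and bad players cooperate with
good recipients to regain standing.  The free bits — `α(G,B,C)`,
`α(B,B,C)`, `α(B,B,D)` — enumerate L1–L8, with the action between two bad
players being the payoff-rational response to the norm's own `(B,B)`
assessments (cooperate only if cooperation is credited and defection
condemned).  ALLC and ALLD are constant tables in the same formalism, so
the engine has a single code path.  A norm is **gullible** if it assesses a
bad player's defection against another bad player positively
(`α(B,B,D) = +1`); L3–L6 are gullible, L1, L2, L7, L8 are not.

Two structural cross-checks root the index assignment: the recovery-time
slopes versus `N` split into the groups `{L1, L3, L4, L7}` (slope ≈ 1) and
`{L2, L5, L6, L8}` (slope ≈ 1.3), which is exactly the `α(G,B,C)` split;
and the four norms with high equilibrium abundance are exactly the
non-gullible ones.

### Evolutionary layer

Norms spread by pairwise-comparison imitation with Fermi probability
`1/(1+exp(−s(π_j − π_i)))`; `s ≥ 0` is the selection strength (the symbols
`s` and `β` both denote this one parameter).  In the rare-mutation limit
the population is homogeneous except during single invasion attempts, so
only the three two-norm simplex edges matter; mixed three-norm states are
never visited.  For each edge and each mutant count `k = 1..N-1` the
reputation dynamics are simulated and the class-averaged payoffs
`π_M(k), π_R(k)` recorded; the fixation probability is computed with the
cumulative products accumulated in log space (at `N = 50` and large payoff
differences the raw products underflow).  Neutrality is exact: identical
payoff vectors or `s = 0` give exactly `1/N` in floating point.

The three-state chain has off-diagonal transitions `ρ/2` — from a resident
state, the next mutant is one of the *other two* norms with probability 1/2
each — where `ρ` is the fixation probability of the *incoming* norm's
mutant into the *current* resident.  Its stationary distribution (solved as
a bordered linear system, residual ≤ 1e-10) is the selection–mutation
equilibrium; the equilibrium cooperation rate weights each homogeneous
population's self-cooperation rate (ALLC → 1, ALLD → 0, the leading-eight
norm → simulated) by its abundance.

## Estimators

`avg_judgment[i, j]` is the exact time average of the post-round judgment
indicator over the accumulation window, maintained lazily (an entry's
contribution is flushed only when its label flips, so accumulation is O(1)
amortized per update rather than O(N²) per round).

`coop_rate[i, j]` is the time average of the donor's *intended* action
`β(J_ii(t), J_ij(t))`.  Because the realized action is a deterministic
function of the current labels and the pair draw is independent of the
state, this estimator has the same expectation as the per-pair empirical
frequency (cooperations over rounds with `i` donor and `j` recipient) but
uses every round instead of the ~`T/N(N-1)` rounds in which the pair was
actually drawn.  The empirical ratio is kept as
`ReputationStats.empirical_coop_rate`; pairs never drawn after burn-in are
imputed there from the intended action against the time-averaged judgments
(and counted in `n_unobserved_pairs`).  Payoffs use `coop_rate`.

## Simulation engine

The round loop is a numba kernel.  Randomness is numba's in-njit MT19937,
seeded per run, so identical seeds reproduce a run bit for bit.
Third-party observation/misperception is sampled by counts: per round the
number of non-observers is `Binomial(N-2, 1-q)` (inverse-CDF from a
precomputed table, one uniform), the misperceiver count is
`Binomial(n_obs, ε)`, and the index sets are drawn uniformly (Floyd's
subset sampling; rejection sampling for the misperceivers).  This is
distributionally identical to one independent draw per observer — each
third party skips with probability `1-q`, updates with the flipped action
with probability `qε`, and with the true action otherwise — at roughly a
quarter of the RNG cost (~0.7 µs per round at `N = 50`).  The exact-chain
oracle test (below) checks precisely this distribution against an
independent implementation.

**Binary reduction.**  A separate kernel implements the binary baseline
directly — reputations are G/B labels *set* (not incremented) by each
assessment.  It consumes the random stream in exactly the same order as
the quantitative kernel, so with the binary frame and a shared seed the two
engines produce identical trajectories; the suite asserts snapshot-level
equality.  This coupling is what licenses comparing quantitative and binary
results as "same noise, different assessment granularity".

**Exact oracle.**  `exact_stationary_small` enumerates every image matrix
(`(A-V+1)^(N²)` states), builds the exact one-round transition matrix by
marginalizing the pair draw, observation and misperception per updater, and
finds its stationary distribution by power iteration (tolerance 1e-13).
It is feasible only for tiny instances (`N ≤ 3`, `R ≤ 1`, ~2×10⁴ states)
and is used as an independent oracle: stationary judgment expectations must
match simulated time averages within three Monte-Carlo standard errors.

## Recovery experiments

Homogeneous leading-eight population, perfect information (`ε = 0, q = 1`),
default frame `R = 3`.  The population starts at the consensus score
(the lowest good score, `S`) with a single off-diagonal entry set to `S-1`:
one observer privately considers one player (mildly) bad.  *Recovery* means
every player again judges every player good — labels, not scores, since
judgments are what drive behavior.  Replicates record recovery (within a
round cap), rounds to recovery, and defections en route; summary defection
counts condition on recovery, because a capped replicate defects
indefinitely.  The binary-vs-quantitative comparison pairs replicate seeds
across frames, so the donor/recipient sequences coincide while both runs
are in progress and the time difference is a paired estimate.  The
strictest norms (L6, L8) very rarely (≲0.5% at small `N`) lock into a
polarized configuration that never recovers; recovery fractions are
reported rather than assumed to be 1.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `b`, `c` | donation benefit, cost (payoff units) | 5, 1 | standard benefit-to-cost ratio of 5 |
| `q` | third-party observation probability | 0.9 | scarce-but-common information |
| `ε` | misperception probability | 0.05 | baseline noise; 0.1 for the high-noise analyses |
| `R` | symmetric score range `[-R, R]` | 5 | fine-grained reputations; `R = 3` for recovery |
| `S` | judgment threshold | 0 | symmetric frame |
| `N` | population size | 50 (evolution), 90 (mixed-thirds reputation runs) | matches the study conditions |
| `s` | selection strength | 1 | strong but not deterministic selection |
| `T` | rounds per composition | 2×10⁵ | desk scale; see below |
| burn-in | rounds excluded from averages | `T/10` | transient from the all-good start |
| replicates | seeds per composition | 3 | error bars at reduced `T` |

## Desk scale and known limitations

The reference analyses run 5×10⁶ rounds per population composition; this
package's defaults use 2×10⁵ rounds × 3 seeds per composition so that the
full pipeline for one norm (three edges × 49 compositions × 3 seeds plus
homogeneous runs) completes in under two minutes on one core.  At this
scale the equilibrium quantities are reproducible to within about one
percentage point across seeds, but carry a small systematic bias: payoff
estimates still fluctuate, and the fixation formula is convex in the
payoffs, which slightly suppresses the leading norm's invasion of ALLD and
inflates ALLD's equilibrium share.  Concretely, L2's equilibrium
cooperation at ε = 0.1 measures ≈79.5% at desk scale, ≈81.8% at 6×10⁵
rounds per composition, converging upward toward the full-scale value;
abundance anchors that are insensitive to this bias (L2 under the binary
frame, ≈91%, and at R = 1, ≈47%) agree closely with full-scale results.
`scripts/acceptance.py` uses 3×10⁵ rounds per composition — the largest
uniform scale that keeps the full eight-quantity recomputation near ten
minutes on one core — while the test suite uses 2×10⁵.

Other limitations, by construction: well-mixed populations only (no
structure or groups); at most three competing norms (the rare-mutation
chain over {L_i, ALLC, ALLD}); deterministic (pure) action rules; no
gossip or public broadcasting of judgments; the finite-mutation-rate
imitation process is not simulated — the rare-mutation chain is the model.
The synthetic dynamics also idealize real reputation systems: errors are
i.i.d., the norm is common knowledge within a homogeneous population, and
all players share one assessment frame.  Passing tests therefore show the
mechanism — error correction through score buffering — not a calibrated
prediction for any empirical community.
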