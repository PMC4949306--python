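# Methods

## The model

A group of N individuals, initially indistinguishable, repeatedly meets in
pairwise contests. Each individual x carries a resource holding potential
(RHP) score, RHP_{x,t}, measuring its current ability to win an escalated
fight; everyone starts at the same RHP_initial. Both members of a chosen
pair decide simultaneously, with full knowledge of both scores, whether to
escalate: x fights when

    RHP_{x,t} / RHP_{y,t} >= theta_x,

where theta_x >= 0 is x's aggression threshold — its heritable strategy.
The inequality is inclusive, so two equal individuals with theta <= 1 both
fight. If both fight, x wins with probability RHP_x / (RHP_x + RHP_y);
the winner's RHP is multiplied by (1 + V1), the loser's by (1 - C1). If
only one fights, the fighter gains (1 + V2) and the retreater pays
(1 - C2); a double kowtow costs both (1 - C2). Winner and loser effects
are therefore mediated entirely through the RHP feedback: winning makes
future wins more likely, losing makes them less likely.

Throughout the analytics we use the default preset V1 = V2 = V, C1 = C,
C2 = 0: having your opponent concede is as good as beating it, and
conceding itself is free (losing a fight is the injury). Fitness at the
horizon T is either

* **log-RHP** — E[ln RHP_{x,T}], the plentiful-resources payoff: each win
  (loss) moves the payoff by the same increment regardless of the current
  score, exactly as in matrix games such as Hawk-Dove; or
* **share** — E[ln RHP_{x,T} / (ln RHP_{x,T} + ln RHP_{y,T})], the
  limited-resources payoff (reproductive skew): what matters is the
  proportion of a fixed resource claimed from the specific opponent.

## Exact two-player analysis

Under the default preset the RHP ratio of two mutually fighting
individuals is ((1+V)/(1-C))^d, where d = wins - losses of the focal
player. A threshold theta therefore acts through the integer

    k = floor(d_theta) + 1,   d_theta = -ln(theta) / (ln(1+V) - ln(1-C)),

the concession class: the individual retreats exactly when its losses
exceed its wins by k. All thetas in [((1-C)/(1+V))^k, ((1-C)/(1+V))^(k-1))
behave identically; the interval midpoint theta_rep labels the class. The
boundary convention floor(d) + 1 follows from applying the inclusive fight
rule literally; it differs from the ceiling convention only at exact
interval endpoints, a measure-zero set on which no reported quantity sits.
theta > 1 maps to the immediate-retreat class (k = 0 sentinel); theta = 0
(never retreat) has d = +inf.

The contest is then an absorbing random walk on d with state-dependent
step probability W(d) = r^d / (r^d + 1), r = (1+V)/(1-C), interior while
-k_x < d < k_y. On absorption at time t* the conceder's RHP freezes
(C2 = 0) while the winner collects a further (1+V) factor in each of the
remaining T - t* rounds (it fights, the other retreats). Paths still
interior at T are censored, both individuals keeping their accumulated
score. Expected payoffs and the stopping-time law are computed by a
forward dynamic programme over (t, d) — O(T·(k_x + k_y)) work — instead of
the 2^T outcome sum; both players' terminal log scores are recoverable
from (t, d) alone because wins = (t + d)/2 on the mutual-fight segment.
All log-RHP arithmetic is additive in log space, so large horizons cannot
overflow.

Two deliberate error conditions: C1 = 1 or C2 = 1 (RHP annihilated) is
rejected because ln RHP diverges, and the share payoff raises a
numeric-domain error if any reachable path has a non-positive terminal
log RHP (impossible at the default RHP_initial = 10 with the grids used
here, but reachable for tiny initial scores).

An independent brute-force oracle (`expected_payoff_bruteforce`)
recursively enumerates every fight outcome using only the per-round
micro-rules — threshold decisions on actual RHP values, the logistic win
probability, the multiplicative updates — never the (t, d) reduction. It
is restricted to T <= 14 and agrees with the dynamic programme to 1e-10
across random parameter sets; a seeded Monte-Carlo cross-check (the group
simulation engine run on a pair) agrees within sampling error.

The stopping time T_s — the round of the last mutual fight — has support
{1} when k_x = k_y = 1 (the single interior state is left immediately),
and otherwise the union of the parity sequences k_x + 2n and k_y + 2n.
The closed-form support predicate is cross-checked against the nonzero
masses of the exact first-passage distribution.

## ESS detection

A pure strategy is an ESS when its payoff-matrix column is maximised
strictly at the diagonal (condition 1); exact ties fall through to the
standard second condition (the incumbent must beat the invader in the
invader's own world). Strictness uses a 1e-9 tolerance so floating-point
noise cannot manufacture ties. Mixed equilibria are out of scope: the
solver reports NONE_FOUND rather than computing mixtures. The default
strategy grid is k = 1..8 — an arbitrary large cut-off corresponding to
small thresholds — with immediate retreat prepended when V = 0, where
conceding at once is a live candidate.

At V = C = 0.1, T = 20, RHP_initial = 10 the unique pure ESS is k = 3
(theta_rep 0.61, interval [0.55, 0.67]) under the log-RHP payoff and
k = 5 (theta_rep 0.41) under the share payoff: when resources are scarce
it pays to be more aggressive, because hurting the opponent directly
increases one's share.

**Scaling law.** For small V and C, d_theta ≈ -ln(theta)/(V + C), so
replacing (V, C) by (alpha·V, alpha·C) preserves behaviour if theta is
replaced by theta^alpha. `scaling_consistency` reports the exact d values
and classes on both sides of the rescaling; the validity guard V + C <=
0.3 only logs a warning, since the approximation degrades smoothly.

## A note on the published payoff table

The package's exact log-payoff matrix at V = C = 0.1, T = 20 agrees with
the published 8x8 table on the diagonal and for most entries, but 16 of
64 printed entries deviate by more than their printed precision (up to
0.047), with the largest deviations concentrated in the first column —
exactly the entries with the largest path-wise payoff variance. Because
the dynamic programme, the brute-force enumeration and an independent
Monte-Carlo estimate coincide (and reproduce the closed-form diagonal
entry 3.2030), we conclude the printed table was itself estimated by
simulation. The ESS identification, the published share-payoff table (all
entries within 0.005) and every other reported quantity reproduce. The
corresponding reproduction test compares all 64 entries at the printed
precision and currently fails on those entries; it is kept as-is rather
than loosened.

## Evolutionary simulation

For N > 2 the payoff analysis is intractable, so the ESS is found by
simulation. Each generation: `n_groups` groups of N individuals are
formed, every individual drawing its threshold i.i.d. from the current
frequency vector p over the grid Theta = {0.1, 0.2, ..., 1.0}; within a
group, `contests_per_group` rounds each pick a uniformly random unordered
pair and resolve it by the micro-rules; each individual's terminal
ln(RHP) is added to its strategy's accumulator H; finally p <- H / sum(H).
This is frequency-proportional-to-fitness dynamics without mutation:
strategies that hit zero frequency never return, and in practice the mass
concentrates on a single grid point, declared the ESS (the p-weighted
mean is reported when the final vector is not concentrated, mode and mean
are both always available). The engine is vectorised across groups and
works in log-RHP space; any preset (V1 != V2, C2 > 0) is supported here.

Because ln(RHP) can dip slightly below zero for the most stubborn
strategies in very long contests (theta = 0.1 individuals can accumulate
enough losses), credited payoffs are clamped at a configurable floor
(default 0) with a logged warning; this touches a handful of individuals
per early generation and none once low thresholds die out.

**Matched horizons.** The contest horizon is a real parameter of the
game: longer horizons reward aggression, because the eventual winner
collects uncontested gains in every round after its opponent concedes.
At V = C = 0.1 the exact pairwise ESS is k = 3 (theta in [0.55, 0.67]) at
T = 20 but k = 6 (theta = 0.3 on the grid) at T = 200 — and the
simulation converges to exactly these values when run at the matching
number of contests. Validation of the simulation against the exact
analysis therefore always matches `contests_per_group` to the analytic
horizon T; the N = 2 validation run uses 20 contests, mirroring the
pairwise worked example. The N = 4 sweep values quoted here use 200
contests per group.

**Scales.** Desk scale is 500 groups per generation with a generation
budget of 300 (200-contest runs) or 2000 (20-contest runs, where
selection per generation is weaker), with early stopping once max p >=
1 - 1e-3 holds for 20 consecutive generations; every tested seed then
concentrates fully (p = 1 on one strategy). Study scale — 10,000 groups,
10,000 generations, no early stop — is available via
`EvolutionConfig.paper_scale` or `domhier evolve --scale paper` and takes
hours, not minutes. At desk scale weakly selected settings (e.g.
V = C = 0.05) may not concentrate within budget; the trajectory output
and the concentration diagnostic make that visible.

## Synthetic fixtures

`make_fixtures` draws random default-preset parameter sets (V, C in
[0.01, 0.3], T in [4, 24]) and always includes the named presets of the
worked examples. These fixtures exercise the mathematics of the model;
they do not emulate any empirical data — no individual variation in
initial RHP, no assessment error, no measurement noise — so passing tests
demonstrate internal correctness of the game analysis, not fit to animal
data.

## Known limitations

* The exact machinery requires the default preset; general presets are
  Monte-Carlo only (the (t, d) reduction breaks when retreating changes
  RHP).
* No mixed-strategy ESS computation; no mutation, spatial structure or
  assortative grouping in the simulation; one threshold per individual
  per lifetime.
* The continued post-concession growth of the winner's RHP is a model
  assumption that becomes unrealistic when the horizon greatly exceeds
  the stopping time — one reason horizon choice matters (see above).
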