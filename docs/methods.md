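# Methods

## Model

Two players repeat a prisoner's dilemma for infinitely many rounds without
discounting and maximize their average per-round payoff. Stage payoffs are
(R, S, T, P) with T > R > P > S and 2R > T + S; the donation game is the
additive special case R = b − c, S = −c, T = b, P = 0 with benefit b > cost
c > 0. All closed-form partner characterizations in this package are for the
donation game; the cycle oracle works for any prisoner's dilemma.

A player's *n-history* is the tuple of its last n actions, oldest first.
Histories are indexed lexicographically with C before D (C = bit 0, oldest
action in the most significant position), so the all-C history has index 0
and the all-D history index 2ⁿ − 1. This orientation matters: a reactive-2
vector (p_CC, p_CD, p_DC, p_DD) has p_CD responding to "cooperated two rounds
ago, defected last round" and p_DC to the reverse. Strategy families:
reactive-n (conditions on the coplayer's n-history), self-reactive-n (own
n-history), counting-n (number of coplayer cooperations in the last n rounds,
entries ordered r_n down to r_0), memory-n (joint history, own-major
indexing). Shorter-memory strategies are lifted to longer memory by
replicating the response over the ignored older positions (the last n_from
actions occupy the least significant index bits).

Strategies do not carry initial moves. In the no-discounting limit initial
moves only matter through which recurrent class of the repeated-game chain is
reached; they are supplied per analysis (an explicit initial joint history
for Cesàro averages, maximization over initial histories for best-response
computations).

## Exact payoffs

The repeated game between memory-n players is a Markov chain over the 4ⁿ
joint histories (pairs of n-histories aligned by round), encoded as
s = h₁·2ⁿ + h₂. The transition kernel is the outer product of the two
players' conditional action probabilities; rows sum to one by construction.
Per-round payoffs and cooperation rates are expectations of the last joint
action under the long-run distribution.

- *Ergodic case* (every effective entry strictly inside (0,1)): the unique
  stationary distribution solves (Kᵀ − I)π = 0, Σπ = 1. We solve
  (Kᵀ − I + 𝟙𝟙ᵀ)π = 𝟙, a standard nonsingular reformulation; no
  eigen-iteration. Tolerances: row sums are exact to construction; results
  are reproducible to machine precision.
- *Reducible case* (deterministic entries): the Cesàro average from an
  explicit initial state is used. Strongly connected components of the
  kernel's support graph are classified into recurrent classes and transient
  states; absorption probabilities into each recurrent class are solved
  linearly and the occupation distribution is the absorption-weighted mixture
  of class stationary distributions. `stationary_payoffs` falls back to this
  route with a warning (defaulting to the all-cooperation initial history)
  when entries are on the boundary.

Implementation errors flip the executed action with probability ε ∈ [0, 0.5),
equivalent to the entry-wise map q ↦ (1 − 2ε)q + ε applied to both players;
reactive strategies condition on executed (post-error) actions.

Deterministic periodic deviations do not need a chain at all: a cycle of
length L with preceding-history windows h_t earns
(1/L) Σ_t [p_{h_t}·(R or T) + (1 − p_{h_t})·(S or P)] per round against a
reactive p, which in the donation game reduces to (b/L)Σ p_{h_t} − c·n_C/L.

A replicate-averaged Monte-Carlo rollout (`monte_carlo_payoffs`, default 50
replicates totalling 10⁶ rounds, 1000 burn-in rounds each) serves as an
independent cross-check of the chain computations in the test suite; the
comparison is at three across-replicate standard errors.

## Partner verification

Against a reactive-n player, a best response always exists among the 2^(2ⁿ)
deterministic self-reactive-n strategies, whose long-run behaviors are
precisely the simple cycles of the order-n de Bruijn graph on {C, D}
(3 cycles at n = 1; 6 at n = 2; 19 at n = 3). The oracle
(`is_partner_oracle`) therefore checks niceness (all-C entry equal to 1) and
compares the maximum cycle payoff against R. The deviator picks its initial
history, so the maximum runs over all cycles. Ties count as partners: the
characterizing inequalities are weak, and the Nash tolerance is 1e−9.
Defector strategies are verified symmetrically: all-D entry 0 and no cycle
earning more than P.

The minimal-constraint extraction substitutes the niceness equality into
every cycle inequality, merges exactly proportional inequalities with
rational arithmetic (keeping the shortest representative cycle), and then
drops each inequality that is implied by the remaining ones over the
probability box, tested by linear programming (HiGHS, 1e−9 slack). At
c/b = 1/2 this leaves {D, CD} at n = 2 and {D, CD, CCD, CDD, CCDD} at n = 3.

The reduction itself is cross-checked by brute force: every deterministic
memory-n deviator (16 at n = 1, 65,536 at n = 2) is evaluated against random
reactive opponents. For n = 2 the enumeration solves all 65,536 discounted
16-state value systems in one batched linear solve (discount 1 − 10⁻⁶ as a
screening pass), then re-evaluates the near-optimal candidates exactly via
the stationary distributions of their recurrent classes; the reported
maximum is an exact stationary average. The screening margin (10⁻⁵ relative)
exceeds the discounted-value bias by orders of magnitude for interior
opponents, and the final equality check is at 1e−8.

Partner volumes are Monte-Carlo estimates over the nice slice (all-C entry
pinned to 1, remaining entries uniform); closed-form references are the
product ∏_k max(0, 1 − (k/n)(c/b)) for counting-n and
(1 − c/b)(1 − (c/b)²/2) for reactive-2. A "full-cube" mode drawing every
entry uniformly is provided for completeness; under the exact niceness
requirement its estimate is zero almost surely.

## Evolutionary dynamics

A population of size N (default 100) is monomorphic at a resident strategy,
initially unconditional defection. Each elementary step draws one mutant with
i.i.d. uniform entries from the chosen family; it fixes with the pairwise
comparison probability

φ_M = (1 + Σ_{i=1}^{N−1} Π_{j=1}^{i} exp(−β(π_{M,j} − π_{R,j})))⁻¹,

computed in log-space, at selection strength β (default 1). Mixed-population
payoffs use complete mixing without self-interaction,
π_{M,k} = ((k−1)π(M,M) + (N−k)π(M,R))/(N−1) and symmetrically for the
resident; the pairwise payoffs come from the exact chain. When either
strategy has an entry exactly 0 or 1 (in practice only the initial
all-defector resident — uniform mutants are interior almost surely) both
strategies are regularized with an implementation error of 10⁻⁶ to keep the
chain ergodic; this perturbs donation payoffs by O(10⁻⁶), far below any
threshold used.

Per step the trace records the resident's strategy, self-payoff,
self-cooperation rate, partner flag and whether the mutant fixed; per
resident it records both sojourn time and the number of resisted mutants, so
"most abundant" can be read either way. Residents are classified as partners
with the niceness equality relaxed: the all-C entry must be at least 0.95
(uniform mutation never produces exact niceness) and the remaining partner
inequalities of the family's characterization must hold.

The generator's default study conditions are the donation game b = 1,
c = 0.5, N = 100, β = 1. Test-scale runs use 10⁵ elementary steps (and the
cost sweep c ∈ {0.2, 0.5, 0.8} with 5 seeds per cell); at this scale the
cooperation-vs-cost trend and the partner-abundance/cooperation rank
correlation are stable, while long-run abundance values retain visible
seed-to-seed noise. What these runs demonstrate is the qualitative mechanism
— cooperation evolves exactly when partner-like residents dominate — not
precise abundance levels, which require one to two orders of magnitude more
steps to pin down.

## Limitations

- Closed-form partner conditions cover donation-game reactive n ≤ 3 and
  counting-n; other cases go through the cycle oracle (any PD, n ≤ 6 —
  simple-cycle counts grow super-exponentially beyond that).
- No discounting and no finite-horizon payoffs; equilibrium results are for
  error rate ε = 0 (the ε machinery transforms payoffs but the partner
  characterizations are not re-derived under persistent errors).
- The evolutionary module implements the rare-mutation (monomorphic
  resident) limit only; polymorphic or structured populations are out of
  scope.
- The exhaustive memory-deviator cross-check is limited to n ≤ 2 by the
  2^(4ⁿ) enumeration size.
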