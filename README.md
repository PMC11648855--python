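# reactiven

Partner strategies in the repeated prisoner's dilemma with finite memory:
exact payoffs, Nash verification, and rare-mutation evolutionary dynamics for
**reactive-n** strategies.

## The problem

Direct reciprocity is modeled as an infinitely repeated prisoner's dilemma:
each round two players cooperate (C) or defect (D), with stage payoffs
T > R > P > S and 2R > T + S. In the donation game, cooperation pays a cost
c so the coplayer gains a benefit b > c (R = b − c, S = −c, T = b, P = 0).
A **reactive-n** strategy p = (p_h) conditions its cooperation probability on
the coplayer's last n actions h ∈ {C,D}ⁿ. A strategy is **nice** if it
cooperates for sure after n rounds of coplayer cooperation, and a **partner**
if it is nice and sustains full cooperation as a Nash equilibrium — no
deviation earns more than R per round against it.

Checking the Nash property naively requires uncountably many payoff
comparisons. The package implements the reduction that makes it finite:
against a reactive-n player, a best response always exists among the
*deterministic self-reactive-n* strategies — strategies that condition only
on their own last n moves. Their long-run behavior is a periodic action
sequence, a simple cycle of the order-n de Bruijn graph (C-loop, D-loop,
CD-alternation, CCD, ... ). A nice p is a partner iff no such cycle
beats R per round against it, where a cycle of length L with n_C
cooperations earns, in the donation game,

    (b/L) * sum_t p_{h_t}  -  c * n_C / L        per round,

with h_t the n actions preceding position t, read cyclically.

For the donation game this yields closed forms. Reactive-2: p is a partner
iff p_CC = 1, (p_CD + p_DC)/2 ≤ 1 − c/(2b), and p_DD ≤ 1 − c/b. Reactive-3
has six analogous averaged conditions. For counting-n strategies
r = (r_n, ..., r_0) (which react only to how often the coplayer cooperated):
r_n = 1 and r_{n−k} ≤ 1 − (k/n)(c/b) — the cooperation probability drops by
c/(nb) per remembered defection. Redundancy reduction over all deviation
cycles shows it suffices to check 2 deviations at n = 2 (alternation, ALLD)
and 5 at n = 3 (plus CCD, CDD, CCDD).

Whether partners actually *evolve* is tested with rare-mutation
pairwise-comparison dynamics: a monomorphic population of size N is
challenged by uniform random mutants, which fix with the explicit pairwise
comparison fixation probability at selection strength β.

## Worked example

```python
import reactiven as rv

game = rv.GameParameters.donation(b=1.0, c=0.5)

# Is (1, 0.7, 0.7, 0.4) a reactive-2 partner?
p = rv.ReactiveStrategy(2, [1, 0.7, 0.7, 0.4])
report = rv.is_partner_oracle(p, game)
print(report.verdict, report.worst_deviation, report.worst_payoff)
# partner C 0.5

ok, slacks = rv.is_partner_reactive2(p, game)
print(ok, slacks)
# True {'nice': 0.0, 'CD': 0.050000000000000044, 'D': 0.09999999999999998}
```

The best deviation is full cooperation itself, tied at the mutual-cooperation
payoff b − c = 0.5 (a partner makes its coplayer's best response cooperative).
The alternation deviation earns only (0.7 + 0.7)/2 − 0.5/2 = 0.45 per round,
leaving 0.05 slack on the averaged condition; the strategy is a partner. Raising the mixed-history
entries to 0.9 flips the verdict:

```python
print(rv.is_partner_oracle(rv.ReactiveStrategy(2, [1, .9, .9, .4]), game).verdict)
# exploitable
print(rv.minimal_constraints(2, game))
# ['D', 'CD']
```

The same checks are available from the shell:

```
reactiven check --strategy 1,0.7,0.7,0.4 --b 1 --c 0.5
reactiven minimal --n 3 --b 1 --c 0.5
reactiven volume --family counting --n 3 --b 1 --c 0.5 --samples 100000 --seed 1
reactiven evolve --family reactive --n 1 --b 1 --c 0.5 --beta 1 --N 100 \
    --steps 100000 --seed 7 --out trace.csv
```

`evolve` writes one CSV row per elementary step (`step, p0..p_k, payoff,
coop_rate, partner, accepted`) and prints a JSON summary with the partner
abundance (fraction of time the resident satisfies the partner inequalities
and cooperates after full cooperation with probability ≥ 0.95) and the
average self-cooperation rate.

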