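# Methods

## Model

The simulator implements a minimal iterated-learning model of the cultural
emergence of combinatorial signal structure. Its components, in the order the
code composes them:

**Hypothesis space** (`iterlearn.language_space`). Languages are total maps
from 4 atomic meanings to 8 fixed signals; the space of 8⁴ = 4096 languages is
enumerated in mixed-radix order (the last meaning's signal index varies
fastest), so language indices are stable across platforms. The inventory's
character structure is deliberately constrained — onsets {a, b} pair only with
rhymes {c, d}, and {p, q} only with {r, s} — which is what makes a full 2 × 2
recombination ("combinatorial") class possible while keeping the space tiny.
Classification predicates:

* degenerate — exactly one distinct signal (8 languages);
* combinatorial — all meanings carry distinct signals *and* the signal set is
  exactly the Cartesian product of its per-position character sets: maximal
  reuse of meaningless elements with no meaning distinction collapsed
  (2 signal sets × 4! orderings = 48 languages);
* holistic — all meanings carry distinct signals, not combinatorial (1632);
* other — the remainder (2408).

The "full Cartesian product" formulation is equivalent, on the default
inventory, to requiring exactly two distinct characters in each position, and
it generalizes to other inventories and signal lengths.

**Coding length and prior.** L(l) = −Σᵢ log₂ p(lᵢ) over the language's eight
character occurrences, with p(lᵢ) the character's relative frequency within
the language's own concatenated signal string; P(l) ∝ 2^−L(l), normalized.
This per-language-frequency reading is the one that reproduces the canonical
values of 8, 16 and 24 bits for `ac ac ac ac`, `ac ad bc bd` and
`ac bd pr qs`. Note a consequence that is easy to miss: coding length is
constant *within* the degenerate (8 bits) and combinatorial (16 bits) classes
but **not** within the holistic class — holistic languages that happen to
reuse characters cost less (the distribution over the 1632 holistic languages
is 20 bits × 1152, 22 × 384, 24 × 96; only the 96 with all eight characters
distinct attain 24 bits). The simulator uses these faithful per-language
values; the canonical prior ratios (degenerate/holistic = 2¹⁶,
degenerate/combinatorial = 2⁸) hold for the worked-example pairs.

**Learning** (`iterlearn.agents`). Full-posterior Bayesian updating over all
4096 hypotheses; no sampling or approximation is needed at this scale. The
observation likelihood is 1 − ε for the paired signal and ε/3 otherwise. The
ε/3 divisor encodes a production-error model with three incorrect
alternatives; it is kept at 3 (exposed as `n_alternatives`) even though the
inventory offers seven alternatives, because the model is defined that way —
the likelihood is an agent's *assumption* about its interlocutor, not a
normalized distribution over the eight signals, and it is used only as an
unnormalized update weight. Updates run in linear double precision with
renormalization after every observation: 4096 well-scaled weights cannot
underflow within an update, and the sequential-vs-batch oracle test pins the
accumulated error below 10⁻¹².

**Production** (`iterlearn.production`). score(s) = Σₗ P(l|d) · C(s|l,m) with
C(s|l,m) = (1/a)^γ when l pairs s with m (a = ambiguity of s in l), else 0.
Production is strict argmax. Argmax ties are broken uniformly at random — not
by index — because symmetric posteriors (e.g. a newborn's prior, which is
invariant under the signal relabelling symmetry of the inventory) produce
exact score ties, and index-order tie-breaking would bias the emerging
conventions toward low-index signals. After the argmax, with probability ε
the producer emits a uniformly chosen *different* signal ("a random other
signal" is read as uniform over the seven others). (1/4)¹⁰⁰ ≈ 6 × 10⁻⁶¹ is
representable in double precision, so scores need no log-space handling even
at γ = 100.

**Population loop** (`iterlearn.population`). Defaults: 10 agents, 20
episodes/iteration, ε = 0.05, initial language `ac bd pr qs` as a point-mass
posterior for every initial agent (the limiting case of an agent trained to
ceiling on that language). Initial ages 0–9 are assigned arbitrarily — the
initial agents are interchangeable point masses, so the assignment is
unobservable. Each iteration: turnover (oldest removed, survivors age by one,
untrained newborn added, restoring the age multiset {0,…,9}), then the
episodes, then the end-of-iteration snapshot of the oldest agent's
class-aggregated posterior. The learner is drawn independently per episode
from the agents other than the producer, so the same learner may be hit
repeatedly within an iteration. The `midlife` producer is the agent of age
exactly 5: of the ambiguous readings of "half way through the lifespan"
(ages 4 vs 5), age 5 is the one under which a focal agent's nine lifetime
producers split five older / four younger, which is the defining property of
the condition.

## Crossover statistic

A run's crossover generation is the generation (= block of 10 iterations)
containing the **first recorded iteration** at which the oldest agent's
combinatorial mass exceeds its holistic mass; a crossover first observed at
iteration 35 is generation 4. An alternative operationalization — testing
only at each generation's final iteration — was considered and rejected: the
oldest-agent trace fluctuates at the iteration scale early in a run (the
identity of the oldest agent changes every iteration), and sampling only
every tenth iteration systematically misses the first overtake, inflating the
measured crossover by one to two generations. Batch summaries report the
median over per-run crossovers, with non-crossing runs entered as +∞ so they
can delay the median but never drag it downward, plus the fraction of runs
crossed by each generation.

## Randomness and reproducibility

One RNG stream per run (numpy PCG64), seeded by
`SeedSequence(entropy=base_seed, spawn_key=(run_index,))`: runs are
individually reproducible, and distinct run indices are guaranteed distinct
streams. A fixed (config, n_runs, base_seed) triple reproduces a batch
bit-for-bit; the suite asserts this.

## Problem sizes

The package's canonical batch sizes are the model's native ones: 100 runs for
the 200-iteration learning-from-learners batch (the statistic of interest, the
median crossover generation, sits near the majority boundary at generation 4,
so the full 100 runs are used to keep its sampling error small), and 30 runs
for each of the two 2000-iteration learn-from-oldest batches, whose endpoint
comparisons (which class dominates the final mean posterior; the acceleration
ratio of median crossovers between conditions) are coarser. A single
2000-iteration run takes roughly two seconds on one core; the full replicate
suite in `tests/test_acceptance.py` runs in a few minutes.

## What the simulations show — and what they do not

The model is deliberately minimal: atomic meanings, a fixed eight-signal
space, uniform meaning frequencies, a single global ε, strict argmax
production, and a rigid death-by-seniority demography with exactly one
producer-selection rule per condition. Passing its tests shows that the
trade-off between a compressibility prior and ambiguity-avoiding production
reproduces the qualitative phenomena — drift to degenerate languages without
a communicative pressure, emergence of combinatorial languages with it, and a
large (≈ 8–10× at these settings) acceleration when learners learn from
other learners — *within this model*. It says nothing quantitative about real
emerging sign languages: there is no richer social network, no variable
lifespan or population size, no probability-matching production, no
compositional (upper) level of structure, and the signal space admits no
gradient phonetics. Those are modelling non-goals, not approximations.

## Known limitations

* The ε/3 likelihood divisor and the seven-alternative production noise are
  intentionally inconsistent with each other (see above); agents therefore
  hold a slightly misspecified model of their interlocutors.
* Crossover is measured on the oldest agent only, mirroring the recorded
  trace; population-median measures would be smoother but are not what the
  model's headline claim is about.
* `class_counts` equality (8/1632/48/2408) and the constant-bit properties are
  specific to the default inventory; generalized inventories get the same
  machinery but no guarantees about class sizes.
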