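# iterlearn

Agent-based Bayesian iterated-learning simulations of how *combinatorial
structure* (the lower level of duality of patterning) emerges in a
communication system, and how population transmission structure modulates the
rate of its emergence.

The package is aimed at researchers in language evolution and cultural
evolution who want a small, fully enumerable model in which the trade-off
between **learnability** (a simplicity prior) and **expressivity**
(ambiguity-avoiding rational production) can be studied exactly, run by run,
without approximate inference.

## The model

**Languages.** Four atomic meanings each map to one of eight two-character
signals `ac bd ad bc pr ps qr qs` (meanings may share a signal), giving
8⁴ = 4096 possible languages. Each language is *degenerate* (one signal for
everything; 8 of these), *holistic* (four distinct signals with no systematic
recombination; 1632), *combinatorial* (four distinct signals forming a full
2 × 2 recombination of per-position elements — the languages with minimal
pairs; 48), or *other* (2408).

**Learning.** Agents are Bayesian: P(l | d) ∝ P(l) · P(d | l) over all 4096
hypotheses. The prior is a simplicity (MDL) prior, P(l) ∝ 2^−L(l) with coding
length L(l) = −Σᵢ log₂ p(lᵢ) over the eight characters of the language
(p(lᵢ) is the character's relative frequency within the language itself), so
e.g. `ac ac ac ac` costs 8 bits, `ac ad bc bd` 16 bits and `ac bd pr qs` 24
bits. The likelihood of an observed meaning–signal pair is 1 − ε when the
language pairs them and ε/3 otherwise (ε = 0.05 by default).

**Production.** A producer scores each signal by
Σₗ P(l | d) · C(s | l, m), where C(s | l, m) = (1/a)^γ if l pairs s with m
(a = the signal's ambiguity in l) and 0 otherwise, emits the argmax (ties
uniform at random), and errs to a uniformly chosen other signal with
probability ε. γ = 0 ignores ambiguity; γ = 100 avoids it almost surely.

**Population.** Ten agents, all initialized to the same holistic language
`ac bd pr qs`. Each iteration the oldest agent is replaced by an untrained
newborn (posterior = prior), then 20 episodes take place: a random meaning, a
producer, and a random *other* agent that updates its posterior on the emitted
pair. Under the `oldest` condition the most experienced agent always produces
(vertical transmission); under `midlife` the producer is the agent half way
through its lifespan, i.e. an agent that is itself still learning (horizontal,
learning-from-learners transmission). One *generation* = 10 iterations (a
complete population replacement). Each iteration the oldest agent's posterior
mass on the four classes is recorded.

The headline statistic is the **crossover generation**: the generation
containing the first iteration at which the oldest agent's combinatorial mass
exceeds its holistic mass.

## Worked example

```python
import iterlearn as il

space = il.enumerate_languages()
print("languages:", space.n_languages)
print("class counts:", il.class_counts(space))

config = il.SimulationConfig(gamma=100.0, condition="midlife", n_iterations=200)
batch = il.run_batch(config, n_runs=100, base_seed=0, space=space)
summary = il.summarize_crossovers(batch)
print("median crossover generation:", summary.median)
print("fraction of runs crossed by generation 4:", summary.fraction_crossed_by[3])
print("final mean class masses:", batch.mean_masses[-1].round(3))
```

prints

```
languages: 4096
class counts: {'degenerate': 8, 'holistic': 1632, 'combinatorial': 48, 'other': 2408}
median crossover generation: 4.0
fraction of runs crossed by generation 4: 0.51
final mean class masses: [0.    0.076 0.846 0.078]
```

Read: with strong ambiguity avoidance (γ = 100) and agents learning from an
agent that is itself mid-learning, the median run's oldest agent comes to
favour combinatorial over holistic languages within four generations, and by
generation 20 the population's veteran posterior is dominated by combinatorial
languages (mass 0.846). With γ = 0 the same machinery converges to degenerate
languages instead (convergence to the prior), and under the `oldest` condition
the combinatorial takeover still happens but roughly an order of magnitude
more slowly (median ≈ 30 generations at these settings).

## Command line

```bash
iterlearn run --gamma 100 --condition midlife --iterations 200 --runs 100 \
              --seed 0 --out-dir out/
iterlearn figure1 --runs 100 --out-dir out/    # the three canonical panels
iterlearn space --out language_space.csv       # the enumerated hypothesis space
```

`iterlearn run` writes per-run trace CSVs, a mean trace, a per-run crossover
table and a JSON manifest with the full configuration and seed; flags can also
be given via `--config file.yaml` (flags override the file).

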