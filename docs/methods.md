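# Methods

## Model

`normknock` simulates indirect reciprocity in a well-mixed population of
`N` agents playing the giving game. Each agent privately holds a binary
image (Good/Bad) of every other agent and always sees itself as Good. A
generation consists of `R` rounds; a round has two phases.

**Phase A (games).** Every agent acts once as donor: it draws a
recipient uniformly from the other `N − 1` agents, intends to cooperate
iff its image of the recipient is Good, and the intended action is
inverted with the implementation-error probability `q`. A realized
cooperation costs the donor `c` and gives the recipient `b` (`b > c >
0`); defection transfers nothing. Accumulated payoff is `U_i = b·W_i −
c·V_i`, with `W_i` donations received and `V_i` donations given this
generation.

**Phase B (image updating).** Every observer `i` re-evaluates every
donor `j ≠ i` by applying `i`'s norm to (`j`'s realized action in the
*previous* round, `i`'s current image of `j`'s then-recipient), then the
fresh image is inverted with the perception-error probability `p`.
Updates are synchronous: all evaluations read the pre-phase-B matrix.
In the first round of a generation each donor is attributed a uniformly
random action (with every image still initialized to Good, the
attributed recipient does not matter). This one-round lag is the
default `evaluation_timing="lagged"`; see "Design choices" for the
alternative.

**Norms.** A norm is one of the 2⁴ = 16 assessment rules, a four-locus
G/B genotype: locus 1 judges cooperation toward a Good recipient, locus
2 cooperation toward Bad, locus 3 defection against Good, locus 4
defection against Bad. Norms are encoded as integers 0–15 (locus 1 =
most significant bit, G = 1). Named norms: ALLG = GGGG, ALLB = BBBB,
Shunning SH = GBBB, Stern Judging SJ = GBBG, Image Scoring IS = GGBB,
Simple Standing ST = GGBG.

**Evolution.** After `R` rounds each offspring slot independently picks
two parents (with replacement, possibly itself) by roulette selection
with probabilities `Π_i = (U_i − U_min)² / Σ_j (U_j − U_min)²`,
applies per-locus uniform crossover, and flips each locus with mutation
probability `m`. Replacement is synchronous. When all payoffs are equal
the formula is 0/0; the uniform distribution is used, the unique
symmetric completion.

**Norm knockout.** A knockout set bans norms from ever existing: the
initial population is drawn uniformly from the complement, and any
offspring whose genotype lands in the set is redrawn uniformly from the
complement. Multiple simultaneous knockouts are supported; the standard
experiment knocks out exactly one norm.

## Parameters

| name | meaning | default | note |
|------|---------|---------|------|
| `N` (`n_agents`) | population size | 500 (`paper`), 200 (`desk`) | |
| `G` (`generations`) | generations | 1000 / 500 | |
| `R` (`rounds`) | rounds per generation | 500 / 200 | every agent donates once per round |
| `b` | benefit | 5.0 | swept over [3, 6] in knockout experiments |
| `c` | cost | 1.0 | payoff unit |
| `p` | perception error | 0 | error regime uses 0.001 |
| `q` | implementation error | 0 | error regime uses 0.001 |
| `m` | per-locus mutation | 0.01 | maintains norm diversity |

The `desk` scale preset (N=200, R=200, G=500, 10 replications) exists so
the qualitative phenomena — emergence of cooperation through strict
norms, and its collapse under knockout of an indispensable norm — can be
demonstrated in minutes on one core; the `paper` preset (N=500, R=500,
G=1000, 50 replications) is the full experimental scale and takes
several hours. All shipped analyses and tests run the desk scale; the preset
switch is the escalation path for full-fidelity runs.

## Observables

* **Cooperation ratio** of a generation: realized cooperative donations
  divided by `N·R` (per round: divided by `N`). Realized (post-`q`)
  actions are counted, since they are what recipients experience.
* **Majority transitions**: the per-generation argmax of the norm
  census, sampled over a window of 20 generations before and 100 after
  the first generation whose cooperation ratio exceeds 0.8, truncated at
  the first ALLG majority, consecutive runs collapsed. Ties break to
  the lowest integer norm code so replications are exactly reproducible
  (ties are measure-zero at N=500 but common in small tests).
* **Terminal cooperation**: mean cooperation ratio over a terminal
  window (default: the final 10% of generations), averaged over
  replications. A knocked-out norm is classified **indispensable** when
  this average is below 0.1.

## Design choices

**Evaluation timing.** The update rule is ambiguous between two
readings: observers judging the current round's actions
(`same_round`) or the previous round's (`lagged`, with round 1
attributed at random). Both are implemented; `lagged` is the default
because the two readings produce different societies and only the
lagged one makes the strict norms indispensable. Judging yesterday's
action against today's image of the recipient is retroactively harsh —
a donor who helped a then-Good recipient is condemned by observers who
have since turned against that recipient — and exactly this harshness
lets SH suppress ALLB. Under `same_round` evaluation, cooperation
survives the knockout of SH's helpers (IS, ST) and even thrives with ST
knocked out in the error regime, erasing the knockout phenomenology;
this persists at full scale, so it is a model difference, not a scale
artifact.

**Degenerate roulette.** All-equal payoffs (e.g. a generation of total
defection) give the uniform distribution, covered by a dedicated test.

**Parents with replacement.** The selection text allows an agent to
pick itself; nothing requires the two parents to be distinct, so they
are drawn i.i.d.

**Random numbers.** All simulation draws come from the legacy MT19937
stream (`numpy.random.RandomState`) because the numba fast path
implements exactly that stream, letting three independently written
engines — the production numba kernel, a vectorized NumPy engine, and a
naive scalar reference — be bit-identical from one seed. The draw
protocol per round is fixed: N recipient uniforms (`r = floor(u·(N−1))`
shifted past self), N implementation-flip uniforms if `q > 0`, the
lagged round-1 attribution (N recipient + N action uniforms), then
perception flips. Perception flips are located by geometric skipping
over the off-diagonal pairs in row-major order — an exact sampler of
i.i.d. Bernoulli(`p`) flip positions that costs one uniform per flip
instead of one per pair, which is what makes `p = 0.001` runs tractable
(`p = 1` flips everything without draws). Evolution draws per
generation: an (N, 2) parent block, an (N, 4) crossover block (u < 1/2
copies parent a, locus 1 first), an (N, 4) mutation block if `m > 0`,
then one redraw per knocked-out offspring. Each replication owns one
seeded stream; per-generation engine seeds are derived from it, and
experiment cells derive per-run seeds from the master seed via
`SeedSequence(master, (cell, replication))`.

## What the scaled-down runs show — and what they do not

At desk scale with the default model, knocking out SH, IS, or (in the
error regime) ST collapses terminal cooperation to ≈ 0.02–0.04, and
knocking out SJ at b = 6 leaves ≈ 4% — the indispensability
phenomenology in full. Baseline emergence, however, is bimodal: a run
either ignites (maximum cooperation ratio > 0.9, majority path through
strict norms with SH strictly before any tolerant majority) or stays
trapped in an SH ↔ ALLB standoff whose cooperation ratio peaks near
0.5. In the standoff almost all payoffs tie near zero, so the escape
that lets SH eliminate ALLB outright is partly drift-assisted: its
per-run probability falls as the population grows and rises with the
number of generations. At N = 200 and G = 500 roughly half the seeds
ignite, so per-seed emergence statistics (unlike the knockout collapse,
which is robust seed by seed) are high-variance at this scale and
should not be read as precise reproduction targets. Ignited runs can
also relapse: once the tolerant GG** coexistence drifts toward
unconditional ALLG, defectors may re-invade — the maintaining role of
the action-sensitive GG** norms (IS, ST) is visible in which runs stay
cooperative.

The simulator emulates exactly the stated stochastic process; it does
not model spatial structure, partner choice, gossip, or action rules
other than "cooperate iff Good" — passing tests say nothing about
societies with those features.

## Numerical notes

* Payoffs are exact: conservation `Σ U = (b − c) · #cooperations` holds
  to the last bit and is asserted across random configurations.
* Trajectory CSV files round-trip losslessly (`repr` of Python floats).
* The numba kernel compiles on first use (~1–2 s, cached); a pure-NumPy
  path (`use_kernel=False`) produces bit-identical trajectories.

## Known limitations

* Single action rule; assessment is private (no reputation consensus).
* The desk preset understates the baseline ignition probability (see
  above); knockout conclusions are unaffected.
* `lagged` timing leaves the final round's actions unevaluated within a
  generation; this is inherent to the one-round lag.
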