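# coalsim

A desk-scale engine for three-player weighted majority coalition games.
`coalsim` plays simple weighted majority games — e.g. the classic
5(4-3-2) game, where bargainers A, B and C hold 4, 3 and 2 resources and
any coalition with at least 5 resources can divide a fixed payoff — under
two bargaining protocols, using configurable software agents in place of
human participants, and computes the outcome statistics usually reported
for such studies.

## What's inside

- **`coalsim.game`** — game configuration (resources, decision point,
  payoff, granularity, grand-coalition / no-selection toggles, round
  limit, bonus conversion rate), coalition feasibility, offer validation
  with distinct error types per failure mode, and a flat key-value config
  format with bit-exact round-trip.
- **`coalsim.onestep`** — the one-step display protocol: simultaneous
  mandatory offers, a deduplicated display board, selections, and
  immediate formation on unanimity, round by round.
- **`coalsim.altoffers`** — the alternative-offers protocol: unanimity
  yields a *tentative* coalition, the excluded bargainer may counteroffer
  to one member, and a ratification loop lets the target defect (making
  the counteroffer the new tentative coalition) until one is ratified.
- **`coalsim.agents`** — the `AgentStrategy` contract (propose / select /
  counter / ratify / respond-to-deadline, each driven by a view plus a
  private seeded stream) with reference strategies: `equity`
  (resource-proportional demands), `equal_split`, `random`, and `timeout`
  (misses deadlines with a given probability).
- **`coalsim.simulator`** — batch sessions: seats agents into positions
  randomly or by effort rank (earned-resources mode), derives per-triad
  seeds from one master seed, models per-decision dropout, and
  round-trips outcomes through a versioned CSV schema plus a CSV event
  log.
- **`coalsim.stats`** — frequency tables, Cohen's w, the chi-square
  goodness-of-fit test, its power and minimum detectable effect size via
  the noncentral chi-square distribution, odds ratios, and Cohen's d.

All-equity triads in the 5(4-3-2) game deterministically produce the
BC coalition with a 60/40 split — the two weaker bargainers freeze out
the strongest (the Strength-is-Weakness pattern) because their mutual
coalition is the cheapest and most profitable for both.

## CLI

Run a batch session from a YAML config:

```sh
coalsim simulate --config session.yaml --protocol one_step \
    --n-triads 52 --seed 1 --out results/
```

writes `outcomes.csv`, `events.csv` and `summary.json`. A minimal
`session.yaml`:

```yaml
game:
  resources: [4, 3, 2]
  decision_point: 5
  payoff: 100
  grand_coalition: false
  allow_no_selection: false
  max_rounds: 10
  conversion_rate: 0.05
protocol: one_step
n_triads: 52
resource_mode: random   # or earned
dropout_prob: 0.0
seed: 1
roster:
  - strategy: equity
  - strategy: equity
  - strategy: equity
```

Analyze outcomes (or a hand-entered table):

```sh
coalsim analyze --outcomes results/outcomes.csv --report report.json
coalsim analyze --counts BC=52,AC=22,AB=6
```

The report includes observed/expected proportions, w, the GOF statistic
and p-value, power at the observed w, and the minimum detectable w at
80% power.

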