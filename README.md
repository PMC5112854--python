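# meliosim

Agent-based simulation of two *completely uncoupled* learning rules in
repeated two-person normal-form games with noisy rewards:

* **Melioration learning** — epsilon-greedy Q-learning whose Q-values are
  incremental means of the rewards obtained from each action (the local
  reinforcement rate), with uniform random tie-breaking among maximisers.
* **Roth–Erev learning** — probability-matching over accumulated
  propensities; the chosen action gains `(1 − ε)·reward`, every other
  action the spillover `ε/(n−1)·reward`, with a small positive floor.

Pairs of identical learners play a fixed partner for many rounds.  Each
agent observes only its own choices and rewards; realised rewards are the
game's mean payoffs plus independent Gaussian noise (SD 1 by default).
The package ships a catalogue of eleven classic games (prisoner's
dilemma, guess-2/3-of-the-average, a three-equilibria dominance game,
parameterised coordination games, battle of the sexes, chicken, a 4×4
dispersion game, matching pennies, rock–paper–scissors, Shapley's game,
and a parameterised inspection game), plus game-theoretic reference
predictions (weak dominance, maximin, pure and mixed Nash equilibria via
support enumeration, payoff dominance) to compare simulations against.

Headline behaviours reproduced by the test suite: learners acquire weakly
dominant actions; without dominance they settle on pure Nash equilibria
with structure-dependent shares; in games with only a mixed equilibrium
the long-run choice frequencies approach the equilibrium mix (invariant
to the inspection game's punishment level); in Shapley's game cumulative
frequencies keep oscillating without convergence.

## Layout

| Module | Contents |
| --- | --- |
| `meliosim.games` | `NormalFormGame`, reward sampling, fixture catalogue, JSON game specs |
| `meliosim.learners` | `MeliorationState` / `RothErevState`, choice and update rules |
| `meliosim.engine` | `play_pair` reference loop, vectorised `run_batch`, per-pair seeding |
| `meliosim.equilibria` | dominance, maximin, pure/mixed Nash, payoff dominance |
| `meliosim.summaries` | outcome distributions, cumulative-frequency trajectories, convergence diagnostic |
| `meliosim.config`, `meliosim.io`, `meliosim.replicate`, `meliosim.cli` | run configuration, CSV serialisation, preset experiments, CLI |

Payoff-matrix orientation: rows index player x's actions and columns
player y's actions in **both** matrices; `mean_payoff_y[i, j]` is y's mean
reward when x plays action `i` and y plays `j`.

## CLI

```bash
# run a seeded batch and write per-pair results
meliosim simulate --game pd --rule melioration --pairs 1000 --rounds 1000 \
    --epsilon 0.1 --seed 1 --out results.csv

# fixture parameters and trajectory logging
meliosim simulate --game inspection --param punishment=1.4 --rule melioration \
    --pairs 200 --rounds 20000 --epsilon 0.2 --seed 1 \
    --out results.csv --trajectories traj.csv

# equilibrium report for any fixture or JSON game spec
meliosim equilibria --game coordination --json

# summarise results (outcomes | trajectories | convergence)
meliosim summarize --in results.csv --what outcomes --out report.csv
meliosim summarize --in traj.csv --what convergence --tolerance 0.05

# preset experiments (fig2 ... fig14), scaled down for quick runs
meliosim replicate --experiment fig10 --scale 0.1 --seed 1 --outdir replication
```

Results CSVs carry a `#` comment header echoing the configuration and
seed; read them with `comment="#"`.  Game specs are JSON objects with
keys `name`, `actions_x`, `actions_y`, `mean_payoff_x`, `mean_payoff_y`,
`noise_sd`.

## Reproducibility

Every source of randomness flows from the master seed.  Pair `i` draws
its random block from `SeedSequence([master_seed, i])`, so per-pair
results are independent of batch size, chunking, and execution order,
and whole batches replay bit-identically.
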