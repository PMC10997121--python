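# Methods

## The selection model

`rrvote` ranks items by sequential re-weighted range voting. The input is
a participants × items matrix of priority scores on a fixed scale
`[0, K]`; a missing entry is an abstention. Items are ranked one at a
time. Let `S_i` be participant *i*'s cumulative sum of scores given to the
already-ranked winners (0 before the first round). The participant's
individual weight is

    w_i = C / (C + S_i^A / K)

and each round the unranked item with the largest weighted total
`Σ_i w_i · score_ij` takes the next rank. With all `S_i = 0` every weight
is exactly 1, so **round 1's winner is always the argmax of the raw column
sums**, whatever the parameters — a useful invariant that the tests and
the acceptance script both exercise.

Assumptions built into the model: scores are comparable across
participants on a common scale; a participant's influence should shrink as
their favoured items win (the proportional-representation property of
RRV); and the scale's zero means "no priority", which is information,
whereas an abstention is the absence of information.

### The decay-aggression exponent

The decay-adjusted variant introduces the exponent `A` on the raw
cumulative sum: `w = C / (C + S^A / K)`. The exponent deliberately applies
to `S` alone, not to `S/K`: only that grouping makes `A > 1` decay *more*
aggressively than `A = 1` for the typical regime `S < K` seen after the
first winners, which is the variant's entire purpose. At `A = 1` the
variant reduces to the regular formula exactly (asserted to machine
precision on a dense grid of `S`).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `constant` (C) | decay offset, dimensionless | 0.5 | the reference illustration value; fully configurable |
| `max_scale` (K) | top of the scoring scale | required (estimator can infer from data) | an a-priori property of the survey, not of the data |
| `decay_aggression` (A) | exponent on the winner-score sum | 1.0 | regular RRV; 4 is the canonical "aggressive" setting, values < 1 ease the decay |
| `top_n` | ranks to assign | `"all"` | |
| `tie_policy` | `input_order` / `lowest_dispersion` / `error` | `input_order` | a batch tool must decide; the tie set is always reported regardless |
| `zero_total_policy` | behaviour when all remaining totals are 0 | `stop` | ranks among universally zero-priority items are meaningless; `rank_by_tie_policy` ranks them anyway for callers that need a total order |
| `tie_tolerance` | relative tie-detection tolerance | 1e-9 | subgroup-mean inputs are real-valued; integer panels still produce exact ties |

A "mild" decay aggression has no default anywhere in the package (the CLI
`conditions` subcommand requires `--mild-a` explicitly): no principled
default exists, and inventing one would suggest otherwise.

## Abstention semantics

An abstention contributes 0 to item totals **and** 0 to the abstainer's
winner-score sum: abstaining on a winner does not spend influence. This
choice preserves the null-participant law (an all-abstain row never
changes any round's winner) and keeps "no opinion" distinct from "no
priority". The two differ observably in the descriptive statistics: a
zero scorer counts toward an item's `n_scorers`, an abstainer does not.
Abstentions are likewise excluded from subgroup means rather than imputed
as 0; a subgroup whose members all abstained aggregates to an abstention.

## Numerical choices

* Weights are recomputed from scratch each round as a pure function of the
  cumulative sum, never incrementally multiplied — no drift, and the code
  matches the formula literally.
* Tie detection is relative: items within `tie_tolerance × max(1, |best|)`
  of the best total tie. `lowest_dispersion` breaks ties by smallest
  per-item sample standard deviation, falling back to input order when
  dispersions are equal or undefined.
* Scores may be any reals in `[0, K]` (subgroup means are first-class
  inputs); no integrality is assumed anywhere in the loop.
* There is no hard size cap; the loop is vectorized (one matrix-vector
  product per round) and handles hundreds × hundreds interactively.
* Degenerate inputs: a single participant (or identical clones) yields the
  descending score order, since one shared weight rescales all totals
  alike; an empty tie set plus `max total = 0` halts under the default
  policy with the remainder reported as unranked.

## Heterogeneity statistics

Per item: number of scorers, mean, sample (n−1) standard deviation
(reported as missing when fewer than two scorers), min, max, range, and —
when subgroup labels exist — the standard deviation across subgroup means.
These are descriptive aids (e.g. for resolving ties by consensus
strength); the sample SD is a conventional choice, not a canonical one.

## The synthetic panel generator

`generate_panel` draws bloc-structured panels: each bloc gives its
favoured items one score and everything else another, then per-cell
Gaussian noise is added, values are clamped to `[0, K]` and optionally
rounded to integers, and abstentions are sampled independently per cell.
Generated matrices therefore always pass validation by construction, and
noise-free panels are exact bloc profiles — which is what makes the
proportionality fixtures (`disjoint_bloc_panel(60, 40)` etc.)
deterministic hand-traceable oracles.

`kleefstra_like_panel` is a fixture preset emulating the *shape* of a
rare-disease guideline prioritization panel: 31 participants in 7
subgroups (a core group, five expertise working groups, ten patient
representatives) scoring 45 key questions on 0–5 integers with moderate
bloc structure and 5% abstentions. It is synthetic: it reproduces
dimensions and structure, not any real score distribution. Tests passing
on it demonstrate the machinery (validation, aggregation, the four-way
condition comparison, intersection reporting), not agreement with any
particular real panel's output.

What the generator does **not** model: correlated abstention
(missing-not-at-random), within-bloc heterogeneity of conviction,
per-indicator sub-scores, or strategic scoring. Conclusions about
behaviour on real panels should be limited accordingly.

## Verification strategy and problem sizes

The loop is cross-checked against an independently written naive
pure-python implementation (explicit nested loops, formula inlined) on
200+ random panels up to 8 × 8 with ~15% abstentions, across
`A ∈ {0.5, 1, 2, 4}` — winner sequences must match exactly and selection
totals to a 1e-9 relative tolerance. Structural laws (first-winner,
single-voter, clone-panel, permutation and null-participant invariance,
weight bounds and monotone decay) are property-tested with seeded /
derandomized hypothesis strategies. The bloc fixtures used for the
proportionality checks are 100 voters × 10 items; the condition-comparison
demonstration uses the 31 × 45 synthetic panel.

## Known limitations

* Tie-breaking by input order makes column order meaningful; callers who
  need order-independence should use `tie_policy="error"` or
  `lowest_dispersion` and handle residual ties upstream.
* `lowest_dispersion` uses individual-level SD even when the ranked input
  is subgroup means.
* XLSX input is read-only; only the first worksheet is consulted.
* The mean is the only subgroup aggregation shipped; the API leaves room
  for alternatives (e.g. median) without change.
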