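# Methods

## Task discretization

The protocol is simulated at the resolution of the preprocessed data: one
binary frame per 12-s timestep. The published timings divide exactly:
habituation 60 s → 5 steps, danger maximum 72 s → 6 steps, ITI 180 s → 15
steps. The shock schedule (one 0.5-s shock per 3.5 s, at most 20) is laid
out in continuous time from shock-period onset — shock k at k·3.5 s — and a
step's shock bit is 1 iff at least one shock falls inside it; the 20th shock
lands at 66.5 s, so a full shock period spans 6 steps delivering
4+3+4+3+4+2 = 20 shocks. `TaskConfig` validates
`shock_max_steps = ceil(max_shocks · shock_interval_s / timestep_s)`; the
other second-valued identities hold for the default config and are asserted
in tests rather than enforced on custom configs, so desk-scale variants
(fewer sessions/trials, shorter homecage blocks) remain expressible.

Because the data are binary per step, a press anywhere within a step counts
for that step. An escape press's own step retains shock = 1 (the animal was
shocked before escaping). Presses during habituation and the ITI are
recorded (ARs / ITRs) but do not move the phase; the homecage has no lever,
so homecage frames always carry press = 0 — the simulator forces the action
to OTHER there. A trial ends its shock period at a press, at the step cap,
or once the maximum shock count is delivered, whichever comes first.

## Learning rule and replay order

Per timestep t: observe the stimulus vector xₜ, compute choice probabilities
(softmax over propensities with the perseveration bonus on the previous
action, scaled by the exploitation gain Β — Β = 0 therefore gives exactly
uniform choice, the analytic anchor used in tests), take or observe the
action, compute r from the frame's shock bit and the action, form
δ = r + γ·V(xₜ₊₁) − V(xₜ) with the *pre-update* weights, then update the
critic (active stimuli, rate α) and the chosen action's actor weights (rate
ε) and set previous-action ← action. The final step of the experiment uses
V(next) = 0. Weights start at zero; the previous action starts at OTHER and
is not reset at session boundaries (500 homecage steps intervene anyway, so
the choice is inert in practice).

The likelihood replay and the generative simulator implement this same
order; a test replays a simulated rat's own frames and checks the two
agents' final weights coincide. Homecage frames update the agent (forced
OTHER, r = 0) but contribute nothing to the negLLE, since behavior was not
recorded in the home cage; `include_homecage=True` on
`neg_log_likelihood`/`fit_grid` scores them too, for anyone wanting the
alternative convention.

## Parameters

| name | meaning | default | range |
|---|---|---|---|
| `alpha` | critic learning rate | 0.15 | [0, 1] |
| `eps_actor` | actor learning rate | 0.15 | [0, 1] |
| `beta_exploit` | exploitation/exploration gain | 5.0 | ≥ 0 |
| `r_shock` | reinforcement of a shocked step | −2.0 | ≤ 0 |
| `r_press` | press cost (fixed in Model C) | −0.05 | ≤ 0 |
| `persev` | perseveration bonus | 0.5 | real |
| `gamma` | temporal discount | 0.8 | [0, 1] |

Defaults are the center points of the default search grid (`GridSpec`):
α, ε ∈ [0.05, 0.25] step 0.05; Β ∈ [1, 9] step 2; R_shock ∈ [−3, −0.5] step
0.5; P ∈ [0, 1] step 0.25; γ ∈ [0.5, 0.95] step 0.15. The source protocol
does not print its grid ranges, so these are package choices sized for a
tractable (15 000-point) desk-scale search; R_shock's default is −2.0, the
lower-middle grid value, because the exact range midpoint (−1.75) is not a
grid point. `r_press = −0.05` is a configurable setting, not a constant:
the value used by the original estimation is not printed, only that Model C
holds it fixed.

## Grid search

Grid points are generated by index (`min + k·step`, inclusive endpoints) to
avoid floating-point accumulation; enumeration is lexicographic in the
fixed order (α, ε, Β, R_shock, P, γ) and ties in negLLE go to the first
point in that order, making fits reproducible. `fit_grid` replays the data
once with all G parameter vectors as (G,)-arrays; `neg_log_likelihood` is
the identical engine at G = 1, so an exhaustive scalar re-scan reproduces
the vectorized argmin bit for bit (tested on a 729-point grid).
Per-observation likelihood terms are computed as log(1 + e^∓Βδq) via
`logaddexp`, so extreme propensities saturate to 0/1 probabilities without
overflow; a zero probability for an observed action (possible only at
infinite propensities) raises rather than returning an infinite negLLE.

## Simulation and scoring

`simulate_rat` runs n independent agents (default 100), seeding run i from
child i of `numpy.random.SeedSequence(master_seed)`; one uniform draw is
consumed per chamber timestep. One scorer serves simulated and
empirical-format data: per trial "A" if any danger frame carries a press,
else "E" if any shock frame does, else "."; ARs are habituation presses per
session; ITRs are ITI presses binned into minutes 1–3 (steps 1–5, 6–10,
11–15 of the 15-step ITI). A trial with both a danger press and shock
frames is impossible under the task rules and raises a scorer error rather
than being silently scored "A".

## Synthetic data

A synthetic rat is one generative run kept as a dataset, so it satisfies
every frame and task-structure invariant by construction and is
format-identical to the empirical per-rat CSVs. The default two-strain
cohort (S-/W-prefixed IDs) uses invented parameter centers — the source data
report estimates only as figure distributions, so these stand-ins emulate
"two groups differing in exploitation, shock sensitivity, perseveration and
discounting", not the empirical strains. Synthetic data share the model's
assumptions exactly: no sensor noise, no missed sessions, no within-rat
drift. A green recovery test therefore establishes identifiability of the
parameters *under the model*, not robustness to model misspecification.

The recovery harness draws rats at random points of a 27-point grid — three
widely spaced values spanning the default ranges of α, Β and R_shock, the
other parameters pinned at the defaults — and refits on the same grid.
Wide spacing was chosen once, for identifiability at desk scale, before any
recovery result was inspected.

## Numerical and design notes

- All replay arithmetic is float64; determinism is exact (same data and
  parameters give bitwise-identical negLLE).
- negLLE is a sum of nonnegative terms, hence ≥ 0 and nondecreasing in
  dataset length (property-tested).
- Perseveration enters inside the softmax (scaled by Β); an alternative
  convention adds it outside the gain. The inside form makes Β = 0 exactly
  uniform, which the analytic anchor test exploits.
- The homecage block length (500 steps/session) follows the estimation
  design and is applied after every session, including the last.
- Readers accept case-insensitive headers and documented synonyms (DS/SS/
  Sh/Chamb/Home/Lever), since deposited files vary cosmetically; writers
  emit the canonical spellings.

## Limitations

- Only the Model C free/fixed split is implemented; no model comparison
  across variants, no gradient/simplex optimizers, no hierarchical fitting.
- Linear function approximation over five binary stimuli; no eligibility
  traces; exactly two actions.
- Shock intensity, tone/light physics and continuous-time dynamics are out
  of scope; the simulator is exact only at the 12-s resolution of the data.
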