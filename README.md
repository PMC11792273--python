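# screentrial

Simulation engine and analysis toolkit for **Bayesian adaptive platform
trials embedded in population screening programmes**, built around a
health-equity outcome: attendance at referral among the population groups
with the worst baseline access.

## The problem

Large screening programmes (the motivating case is community eye screening)
refer on the order of 100 people every 72 hours for further care, and many —
disproportionately members of *left-behind* sociodemographic groups — never
attend. A platform trial runs a series of pragmatic randomised comparisons of
cheap service modifications (SMS wording, vouchers, opening hours) against
current care, using routinely collected attendance as the outcome, and
adopts each winner before testing the next idea. Because effect sizes worth
acting on are small (1–5 percentage points) and the interventions are
low-risk, the design favours high power and tolerates an elevated
false-positive rate.

## The design

For each arm *k*, attendance is binomial with rate θ<sub>k</sub>, given a
regularising conjugate prior θ<sub>k</sub> ~ Beta(100, 100); after *n*
referrals with *s* attendances the posterior is Beta(100 + s, 100 + n − s).
Every 100 observed outcomes (≈ every 72 h) the engine computes

- **P(best)** — the posterior probability that each arm has the strictly
  highest attendance rate, and
- **P(equivalent)** — the posterior probability that all arms lie within the
  equivalence margin δ (default 1 percentage point) of the best,

and applies three stopping rules in priority order:

1. **Superiority** — some arm's P(best) exceeds *x* (default 95%); that arm
   is the winner.
2. **Practical equivalence** — P(equivalent) exceeds *y* (default 95%); no
   winner.
3. **Ceiling** — enrolment reaches a maximum (default 10 000); indeterminate.

Comparison probabilities are computed either by joint Monte-Carlo sampling
of the posteriors (any number of arms) or, for two arms, by deterministic
beta quadrature accurate to ~10⁻⁶. Allocation is permuted-block
randomisation (blocks of 4–12, optionally stratified), and the whole
platform closes once every sociodemographic group reaches 80% attendance.

The package provides the trial engine (`run_trial`, `replay_recorded`), a
synthetic referral-stream generator with subgroup structure and additive arm
effects (`PopulationSpec`), operating-characteristics simulation
(`run_scenario`, `run_grid`, `threshold_sweep`), and disaggregated equity
analysis (`attendance_by_group`, `identify_left_behind`, `equity_report`).

## Worked example

```python
from screentrial import (Arm, PopulationSpec, Subgroup, TrialConfig,
                         attendance_by_group, equity_report,
                         identify_left_behind, run_trial)

config = TrialConfig(
    arms=[Arm("control", is_control=True), Arm("voucher")],
    master_seed=42,
)
population = PopulationSpec(
    subgroups=(
        Subgroup("rural_women", 0.15, 0.35),     # 15% of referrals, 35% baseline attendance
        Subgroup("everyone_else", 0.85, 0.55),
    ),
    arm_effects={"control": 0.0,
                 "voucher": {"rural_women": 0.15, "everyone_else": 0.05}},
    seed=42,
)
result = run_trial(config, population)
```

The trial stops at the 15th interim analysis by superiority:

```
stopped: rule1_superiority  winner: voucher
interims: 15  enrolled: 1500
P(best) at stop: {'control': 0.0294, 'voucher': 0.9706}
  control: 394/750 attended, posterior mean 0.520
  voucher: 435/750 attended, posterior mean 0.563
winner posterior mean 0.563 vs true rate 0.585
```

After 1500 referrals the voucher arm's probability of being best (0.9706)
exceeds the 95% threshold, so the voucher becomes the new standard care. The
winner's posterior mean (0.563) is reported next to its true generative rate
(0.585): early stopping makes this estimate systematically optimistic when
effects are small, and the engine tracks that bias. The equity report on the
same participants,

```python
table = attendance_by_group(result.participants)
left_behind = identify_left_behind(table)       # lowest-attendance groups ≥ 10% of population
report = equity_report(result.participants, left_behind)
```

identifies `rural_women` as the left-behind group and prints the primary
(left-behind, 0.394) and overall (0.553) attendance with their gap (15.9
percentage points).

A command-line interface wraps the same operations:

```bash
screentrial fixture extreme_effect --out demo/
screentrial simulate --config demo/extreme_effect.yaml --out demo/run/
screentrial equity-report --participants demo/run/participants.csv --out demo/eq/
screentrial threshold-sweep --x 0.90,0.95,0.99 --d 0 --n-sims 100 --out demo/sweep/
```

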