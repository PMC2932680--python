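# Model and methods

## The decision rule

`leadsim` simulates a cohesive animal group whose members must each keep a
set of physiological and social reserves above zero. Time advances in
one-minute steps. Agent *i*'s reserve for need *A* is `r[i,A]`, bounded by
its capacity `R[i,A]` — the agent's daily requirement for that need. The
motivation (probability to lead) is the reserve deficit scaled by the
group-typical requirement:

    alpha[i,A] = (R[i,A] − r[i,A]) / mean_j R[j,A]
    P[i] = max_A alpha[i,A]

The agent with the highest `P` leads: the whole group adopts the activity
that refills the leader's most-depleted need, travelling to the serving
area when one exists. `alpha` is 0 at a full reserve and about 1 at an
empty one for a group-typical member.

The normalizer is the crux of the model and is pluggable
(`SimConfig(normalizer=...)`):

* `"group_mean"` (default) — comparisons between individuals are
  comparisons of *absolute* deficits on a per-need scale. An agent whose
  requirements outstrip its groupmates' accumulates larger deficits in the
  same time and therefore spends more time holding the highest motivation.
  This is the mechanism by which leaders emerge from requirement
  heterogeneity.
* `"own"` — the classic `1 − r/R` form. Because every drain in the model
  scales with the requirement it depletes, all agents' motivations then
  grow at identical rates and leadership degenerates to noise; the form is
  kept for comparison experiments.

## Bout structure

Leadership is re-evaluated at every activity boundary, and — for feeding
and drinking — every minute during the bout: a nutrient bout continues
only while its leader still holds the highest motivation, with a 2-minute
commitment once the patch is reached. Resting and socializing bouts are
not preemptible: they run until the leader's reserve is full, with a fixed
5-minute minimum. Travel is never interrupted. A handover that changes the
group's activity counts as a new leadership decision and is credited to
the new leader; a silent handover within the same activity is not a
decision.

The mixed semantics are deliberate. If every bout runs strictly until the
leader is full, large-bodied agents with large accumulated deficits block
the group for hundreds of minutes and followers starve; if every bout is
preemptible each minute, the group hops between areas incessantly and the
activity budget is dominated by travel. The mixed rule reproduces a viable
system (no deaths over 90 days in any tested configuration) with a
realistic activity budget, and makes the 5-minute minimum on rest/social
bouts meaningful.

## The two model variants

**Dyad** — two agents, two abstract needs. Requirements come from a 3 x 10
design table (condition 1: all equal; condition 2: individually unequal
but equal sums; condition 3: agent A's requirements exceed B's by a ratio
rising from 1.0 to 1.45). Both reserves of both agents drain continuously
at `0.07/min` per 1000 units of requirement (sd = mean/2), i.e. the drain
is proportional to the requirement; intake is 10 units/min at the need's
serving area. There is no night. With requirement-proportional drains the
high-requirement agent accumulates larger absolute deficits and dominates
leadership in condition 3, while conditions 1–2 stay symmetric.

**Five-need groups** — 5–20 agents from five age/sex categories (adult
male, cycling female, lactating female, subadult, juvenile) with protein
(g), energy (KJ), water (ml), social time (min) and resting time (min)
reserves. Nutrient requirements scale with body mass (protein
2.54 g/day/kg, energy 351.7 KJ/day/kg, water 0.24 ml per KJ of energy);
lactating females carry 1.25x protein and 2x energy (water follows
energy). Social and resting requirements are category-level constants.

Expenditure per minute:

| need    | rule |
|---------|------|
| protein | continuous daytime drain 0.0027±0.0013 g/kg/min, all activities including protein foraging; frozen at night |
| energy  | per activity, per kg: foraging/socializing 0.29±0.15, walking 0.24±0.10, resting (day and night) 0.10±0.05 KJ/min/kg |
| water   | per activity, per kg: foraging/socializing 0.07±0.035, walking 0.0575±0.023, resting 0.025±0.012 ml/min/kg |
| social  | requirement/720 per daytime minute (sd = mean/2) outside social bouts; frozen at night |
| rest    | requirement/720 per daytime minute (sd = mean/2) outside rest bouts; refilled at night |

All Gaussian components are truncated at zero, drawn independently per
agent per minute. Protein is a continuous drain rather than a
foraging-only cost: protein turnover does not stop when the animal stops
eating, and a foraging-only protein cost would make protein a need that
never drives leadership. The `/720` divisor equals the 720-minute active
day, so a social or resting tank drains over exactly one undisturbed day.

Intake per minute (for every agent present, leader and followers alike,
clamped at capacity): protein 0.217/0.217/0.217/0.202/0.126 g/min and
energy 41.9/38.9/38.2/28.4/23.7 KJ/min by category; water 50±25 ml/min;
social and rest 1.0±0.5 min/min. Intake rates are category-level
constants, not per-agent draws: an agent whose feeding rate fell
materially below its class mean could not cover its own daily drain
within any feasible activity budget, and a single such agent deadlocks
the whole group's schedule. Heterogeneity between individuals therefore
enters through body mass (hence all nutrient requirements) and category.

**Night.** At step 720 of each 1440-step day the group walks to the
resting site and rests until dawn. The resting reserve refills overnight;
the social reserve is frozen (it neither drains nor refills while the
group sleeps); energy and water burn at resting rates. The forced move is
not a leadership decision. The dawn wake-up is a normal boundary.

**Death.** An agent dies when a reserve is driven strictly below zero and
the same minute's intake does not lift it back. Exactly-empty is the
brink, still alive: the deterministic social/rest drain reaches exactly
zero at dusk by construction whenever an agent went a whole day without
that activity, and the night (or the next morning's near-maximal
motivation) rescues it. A death stops the replicate.

## World

A 96 x 96 m torus (1 m cells). Four fixed areas (protein patch, energy
patch, waterhole, resting site) sit at the corners of a centred square:
pairwise 48 m along sides and 67.9 m across toroidal diagonals, each
exactly 33.9 m from the torus middle where the group starts. The dyad
variant uses two areas 48 m apart, also equidistant from the start. Note
that the maximal toroidal separation on this world is sqrt(48² + 48²) ≈
67.9 m. The group moves as a single point at 0.4 m/s (24 m per step),
along the shortest toroidal line, arriving when within the 2 m area
radius. Areas have unlimited capacity.

## Activity budget accounting

Each daytime minute (steps 0–719) is classified as moving, foraging
(protein + energy + drinking), resting or socializing; the budget is the
partition of daytime, since the forced night rest would otherwise fix the
resting fraction at ≥50% by design. The raw five-way daytime budget and
the night minutes are also reported.

## Group sampling (synthetic rosters)

Heterogeneous groups draw a category composition from the empirical
statistics for 10-individual groups (means 1.6/3.1/1.7/1.9/1.8,
clipped to the observed min/max, always ≥1 adult male, repaired to the
target size by adjusting the largest category; scaled proportionally for
n = 5 and 20). Masses are Normal(category mean, sd) truncated at 0.5 kg;
requirements follow the mass formulas. Homogeneous ("equal needs") groups
are n identical cycling females at the category mean mass. What the
sampler does *not* emulate: kinship and social-bond structure, seasonal
requirement changes, demographic turnover, and within-category intake
variation — so passing tests say nothing about those aspects of real
groups.

## Statistics

Leadership shares are pooled over replicates per group (per-replicate
shares are kept for the nonparametric tests and for within-replicate
ranked curves). Dyad comparisons use a two-sample Kolmogorov-Smirnov test
on the two agents' per-replicate shares; larger groups use Kruskal-Wallis
across agents (alpha = 0.05). Rank curves are fitted with linear,
exponential, power and logarithmic families; exponential rank fits use
x = rank/n and y = share·n, the scale on which decay constants are
comparable across group sizes. The threshold analysis pools one point per
individual (x = its maximum over needs of requirement relative to the
mean of its groupmates, or its relative body mass; y = its pooled
leadership share) and fits the Hill sigmoid y = xⁿ/(xⁿ + Sⁿ) with S ∈
(0, 10], n ∈ [1, 100], multi-start least squares. F statistics and
p-values of curve fits are reported but are descriptive only.

## Numerical choices

* One compiled per-minute kernel (numba) drives both variants; Gaussian
  noise comes from a block-refilled standard-normal buffer
  (`mean + sd·z`, truncated at 0). A pure-Python reference driver
  reproduces the kernel minute-for-minute in deterministic dyad runs
  (exercised in the test suite).
* Replicate seeds derive from a root seed through `SeedSequence([root,
  replicate])`, so replicates are order-independent and any single
  replicate can be reproduced in isolation.
* Exact motivation ties (common at the start, when everyone is full, and
  among agents with identical requirements) are broken uniformly at
  random from the replicate's generator, with tolerance 1e-12.
* A bout's "full" test uses a 1e-9 absolute tolerance; initial reserves
  are full capacities (configurable).
* Deterministic mode zeroes every noise sd (tie-breaks remain seeded) and
  backs golden-file regression tests.

## Problem sizes

The packaged experiments use 10 sampled groups per condition and 100
replicates x 90 days per group (50 replicates for the dyad conditions and
the 20-agent groups inside the test suite); the original design of 1000
replicates is available by raising `--replicates`. At these sizes every
experiment reruns from scratch in minutes on one core.

## Known limitations

* The motivation normalizer and the preemption rule are reconstructions;
  both are isolated behind `SimConfig` switches so alternative functional
  forms can be explored.
* Leadership in heterogeneous groups is winner-take-most: the top
  individual's pooled share exceeds one half in most sampled groups, and
  second-tier high-requirement individuals (e.g. additional lactating
  females or a second adult male) hold near-zero shares. Hill-threshold
  estimates on pooled share-vs-ratio points are therefore sensitive to
  those second-tier points and land above the ratio of the top leaders.
* In homogeneous groups agents are exchangeable, so pooled ranked shares
  concentrate tightly at 1/n; ranked spreads wider than a point or two
  require real between-individual heterogeneity.
* Social time arithmetic: a subadult's 170.5 min/day social requirement
  with 1 min/min intake forces at least ~19% of daytime to be social time
  in any viable steady state; budget targets below that are unreachable
  under these parameter tables.
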