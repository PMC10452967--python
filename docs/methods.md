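# Methods

This note records the models implemented in `antctx`, the parameter
choices behind their defaults, and the places where the design was
genuinely open.

## Cyclic systems and the criterion statistics

A rank-n cyclic system has n contents, each measured in two of n
contexts, with contexts chaining in a single cycle. Here the contents
are the four distant good nests and the contexts the nearby poor
alternatives; the two experiments sharing a good nest form a linked
pair. Outcomes are coded +1 for migration to the good nest, −1 for the
poor one, so the acceptance probability p maps to the expectation
m = 2p − 1 and a pair's product expectation is
E = 1 − 2p_a − 2p_b + 4p_ab.

`s_odd` is computed in closed form: the maximum signed sum over
odd-minus sign patterns equals Σ|E_k| when the count of negative E_k is
odd, and Σ|E_k| − 2·min|E_k| otherwise (the smallest-magnitude term is
sacrificed to fix the parity). The test suite checks this against full
enumeration for ranks 3–6.

Two conventions of the inconsistent-connectedness correction Δ are
supported:

- **linked** (default): Δ = Σ_k |m_A(k) − m_B(k)| over the same
  linked pairs that supply the correlations. This is the convention
  under which the worked example reproduces its published statistics
  (Δ = 1.20, ΔC_cbd ≈ −2.88 from two-decimal inputs).
- **chained**: Δ summed over the shared-context connections between
  consecutive pairs (the orthodox cyclic-system convention; 0.08 on the
  worked example).

The two coincide whenever the system is consistently connected. The
statistics are ΔC_chsh = s_odd − (n−2) and ΔC_cbd = ΔC_chsh − Δ, with
strict positivity (tolerance 1e−9) flagging violation, so a system
landing exactly on the bound counts as non-violating.

**LP oracle.** As an independent check, `noncontextual_lp_oracle` poses
the orthodox coupling problem: over the 2^(2n) deterministic
assignments to all 2n variables, maximize the total probability of
agreement across the n connections subject to each pair's observed 2×2
distribution. The system is noncontextual iff the maximum reaches the
sum of the per-connection Fréchet ceilings (1 − |p_i − p_j| each). On
consistently connected systems this is equivalent to s_odd ≤ n − 2,
which the suite verifies on 1,000 random marginal-zero rank-4 systems.
On deterministic but inconsistently connected systems (the
intransitive-preference fixture) the oracle correctly reports
noncontextual even though ΔC_chsh = 2: the entire apparent violation is
absorbed by Δ. Rank is capped at 6 to keep the atom count small.

## The emigration simulator

Each ant is an independent five-state Markov chain: evaluating
home/inferior/superior site, committed to inferior/superior (absorbing).
Defaults are the study conditions: 10,000 ants, thresholds
T ~ Normal(5, 1) fixed per ant, fresh assessment error Normal(0, 1) per
evaluation, home quality −1000 (never acceptable), and the published
travel-time matrix (36 s home–poor, 143 s home–good, 116 s poor–good,
derived from an 8.4 mm/s walking speed). The threshold distribution is
read as Normal(5, 1) — its published "mean 0, SD 1" entry is the
standardized offset — because nest qualities of 3.1–6.5 only
discriminate against a mean-5 threshold.

**Discovery kernel.** The published discovery table's rows do not sum
to 1, but its *columns* sum to exactly 1.00. We therefore read it as a
column-stochastic Markov kernel (columns = current location) and store
its transpose row-major: from home an ant stays put w.p. 0.91, finds
the poor site w.p. 0.06 and the good site w.p. 0.03; from the poor site
it stays w.p. 0.80, returns home w.p. 0.15, finds the good site
w.p. 0.05; from the good site it stays w.p. 0.91. Each epoch is one
categorical draw; the ant then assesses whichever non-home site it
occupies (staying in an "evaluating" state means assessing the same
site again with fresh noise). Moving charges the travel time; staying
costs one second. Under this reading a 10,000-ant run reproduces the
reference acceptance probabilities of all eight design experiments to
within ±0.011, the four constructed joints to within ±0.013, and the
experiment-8 preference reversal (p < 0.5). The alternative reading
(row-wise independent discovery probabilities with random tie-breaking)
was evaluated by exact absorption-probability calculation and
undershoots the reference acceptance row by ≈0.19 uniformly; it was
rejected on that basis.

**Outputs.** `switch_rate` is the fraction of the whole colony whose
first-discovered site was the poor one but that committed to the good
one (the colony-level rate; the rate conditional on first finding the
poor site is much larger and matches no published figure).
`n_reject_poor` counts ants that assessed the poor site at least once
and never committed to it — the only operationalization of "invariably
rejects" available from the event log. Duration is the last commitment
time in minutes. The simulator reproduces the order of magnitude of the
reference durations (tens to thousands of minutes, longest for the
hard discriminations) but not their exact values, which depend on
scheduler clock details that are not recoverable; no downstream
statistic uses durations. A run is cut off (and flagged, with the
uncommitted count reported) if an ant's clock exceeds `max_time`,
default 315,600 s = 10× the longest reference duration.

**Determinism.** One `numpy` Generator per experiment drives the
vectorized epoch loop; identical config + seed gives bit-identical
results (tested end to end).

## Joint probabilities and errors

Ants with high thresholds reject the poor nest wherever they meet it,
so across the two linked runs at least
h = min(rejectors_A, rejectors_B)/n of the colony had no alternative to
the good site; the rest are treated as independent across runs:
p_ab = h + (p_a − h)(p_b − h). The construction is heuristic: in corner
cases it can undershoot the Fréchet lower bound, in which case it is
clipped with a warning (downstream arithmetic requires a valid joint).

Marginal acceptance probabilities get the textbook proportion SE
√(p(1−p)/n). (The reference table's SE column is ≈1.7× larger than
this at n = 10,000; the effective n behind it is unstated, and no
statistic here depends on it.) The joint's SE comes from bootstrap
resampling: each experiment's per-ant outcomes collapse to five
categories (good × rejected-poor, good × never-assessed, poor,
uncommitted × 2), so resampling ants with replacement is a single
multinomial draw per experiment; 100,000 resamples is the default.
SEs for the ΔC statistics are propagated the same way, resampling all
eight experiments jointly; this yields ≈0.011 for ΔC_chsh and ≈0.031
for ΔC_cbd at full scale (the reference values ±0.0482/±0.0538 were
presumably computed on the larger-SE scale noted above).

## The zero-noise colony model

The infinite-population limit is a linear compartment model: a fraction
z starts scouting, scouts commit to the superior/inferior site at rates
αs·H and αs·(1−H), leak home at rate α, and home ants rejoin the scouts
at rate αs. All mass eventually commits, split H : 1−H, so the winner
is the majority-preferred site — independent of αs, α and z, which only
shape the time course (verified on a parameter grid). Ties (H = 0.5)
resolve to the superior site; this is the only tie rule consistent with
the zero-noise criterion pair (ΔC_chsh, ΔC_cbd) = (2, 0) obtained from
the reference H row, whose first entry is 0.50. Duration is the time
for the winner's committed fraction to reach 90% of its asymptote (the
asymptote itself is H < 0.9 in general, so an absolute 90% level would
never be crossed); it decreases in αs and increases in α. With
deterministic outcomes the pairwise joints are plain products (anything
with 0 is 0; two 1s give 1) and error bars are meaningless, so none are
produced. The specific published equation system behind this model is
not public; the implementation is defined by — and tested against —
these behavioral contracts, not a particular trajectory.

Note that when the zero-noise arm is driven by *simulated* rather than
tabulated acceptance probabilities (as `run_study` does), experiment 1
sits at the 0.50 tie and its binary outcome flips with the simulation
seed; the (2, 0) result is a statement about the reference H row.

## What the simulations do and do not show

The simulator generates the study conditions, not real colonies: no
tandem running or carrying, no quorum sensing, no spatial geometry
beyond the travel/discovery abstraction, fixed thresholds with
homogeneous noise. Passing tests show that the pipeline's statistics
are computed correctly and that the study's conditions yield its
published conclusions (strong Type I contextuality, broken sign
transitivity, no Type II contextuality); they do not show that real
*Temnothorax* colonies are or are not contextual.

## Problem sizes used in the tests

The full-scale checks run four experiments at 10,000 ants; the property
suite uses 2,000 ants × 5 seeds for the monotonicity ordering, 1,000
random systems for the LP equivalence, and a 150–300-ant smoke study
for end-to-end determinism — sizes at which every assertion is stable
across seeds while the whole suite stays fast.
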