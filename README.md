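# antctx

Can a colony of ants be *truly* contextual? Social insect colonies make
collective decisions — which nest to emigrate to — through threshold rules
distributed over thousands of workers, and those decisions are known to show
intransitive preferences and context effects. `antctx` asks whether such a
system can violate the bounds that separate classically explainable
correlations from true (Type II) contextuality, using the
Contextuality-by-Default (CbD) framework for cyclic systems.

The package is aimed at researchers in collective behaviour and
quantum-cognition-adjacent decision theory who want a reproducible, tested
pipeline for (a) simulating forced nest emigration by *Temnothorax*-style
colonies, and (b) running CHSH/CbD contextuality analyses on any rank-n
cyclic system of binary variables.

## The model and the statistics

**Emigration simulator** (`antctx.emigration`). Each of 10,000 ants is an
independent realization of a five-state Markov chain (evaluating home /
inferior / superior site; committed to inferior / superior — absorbing).
An ant carries a fixed acceptance threshold `T ~ N(5, 1)`; every epoch it
assesses the site it occupies with fresh noise `ε ~ N(0, 1)` and commits iff
`q + ε ≥ T`, where `q` is the site quality. Movement follows a Markov
transition kernel between home (quality −1000, never acceptable), a nearby
poor nest and a distant good nest; travel charges time to the ant's clock.

**Design** (`antctx.design`). Eight experiments cross four good nests
(qualities q1–q4 = 5, 5.5, 6, 6.5) with four poor alternatives (c1–c4 = 3.1,
3.6, 4.1, 4.6). Experiments sharing a good nest form four linked pairs whose
contexts chain in a single 4-cycle — the CHSH scenario.

**Joint construction** (`antctx.estimation`). The joint probability of
accepting the good nest in both contexts combines the "invariant rejectors"
floor with an independence term:
`p_ab = h + (p_a − h)(p_b − h)`, where `h` is the min fraction of ants that
assessed and rejected the poor nest in the two runs. Its SE comes from
100,000 multinomial bootstrap resamples of per-ant outcomes.

**Contextuality statistics** (`antctx.cyclic`). With ±1 coding (+1 = good
nest), each linked pair yields `E = 1 − 2p_a − 2p_b + 4p_ab`. For a rank-n
cyclic system,

```
s_odd(E)  = max over odd-minus sign patterns of Σ ±E_k
ΔC_chsh   = s_odd − (n − 2)                      # CHSH form
ΔC_cbd    = s_odd − (n − 2) − Δ                  # CbD form
Δ         = Σ_k |m_A(k) − m_B(k)|,  m = 2p − 1   # inconsistent connectedness
```

`ΔC_cbd > 0` is true (Type II) contextuality; `Δ > 0` alone is Type I.
An independent linear program over the 2^(2n) deterministic outcome atoms
(`noncontextual_lp_oracle`) cross-checks the verdict. A zero-noise
infinite-population model (`antctx.colony_ode`) supplies the
winner-take-all limit: the colony selects the majority-preferred site with
certainty, so outcomes are exactly ±1.

## Worked example

```python
from antctx import run_study

rep = run_study(seed=1)             # 8 experiments x 10,000 ants, ~5 s
print(rep.report_mc.dC_chsh, rep.report_mc.dC_cbd)
```

The equivalent staged run (`python analysis/02_simulate_emigrations.py
--seed 1`, then `03_joint_estimates.py` and `04_contextuality.py`) printed:

```
correlations E = [-0.087, 0.1014, 0.0704, 0.0624]
s_odd = 0.3212   Delta = 1.1912
dC_chsh = -1.6788 ± 0.0109  (reference -1.68)
dC_cbd  = -2.8700 ± 0.0311  (reference -2.88)
sign-transitive: False   Type I (Delta>0): True   Type II (dC_cbd>0): False
LP oracle: noncontextual=True (margin 0.00e+00)
```

Reading: the colony shows a preference reversal (experiment 8 accepts the
good nest in only ~49% of cases) and hence broken sign transitivity and
strong inconsistent connectedness (Δ ≈ 1.19), but both criterion statistics
stay well below zero — the correlations are fully explainable by a
context-independent model. The zero-noise colony-level limit of the same
design lands exactly on the classical boundary (ΔC_chsh = 2, ΔC_cbd = 0):
contextuality is approachable in principle but not exceeded.

The staged version of the same analysis lives in `analysis/01…04` (zero-noise
feasibility, simulations, joint estimation, contextuality report), writing
tables to `results/`. A thin CLI covers the same ground:
`antctx run`, `antctx simulate`, `antctx analyze`, `antctx fixtures --name pr-box`.

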