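# tcellnet

Hybrid Boolean-network analysis of early CD4 T-cell activation.

Naive CD4 T cells integrate three kinds of cues: antigen recognition through
the T-cell receptor (TCR), costimulation through CD28 binding the CD80/86
ligands on the antigen-presenting cell, and polarizing cytokines from the
microenvironment. `tcellnet` bundles a concise 46-node logical model of this
decision: a 30-node activation core (TCR/CD28 proximal signaling converging
on AP-1, NFAT and NF-κB and the IL-2 gene, the Ndrg1 anergy factor, the
CTLA-4 checkpoint, and the AMPK/mTOR metabolic switch) plus four
cytokine-driven differentiation modules (Th1, Th2, Th17, Treg). The package
is equally usable as a general engine for user-supplied Boolean networks.

## The model in brief

Each node is a Boolean variable updated by a logical rule,
x_i(t+1) = F_i(x(t)), synchronously (all nodes at once) or asynchronously
(one seeded random sweep per step). Attractors are the solutions of the
fixed-point system x = F(x), found exactly either by bit-parallel exhaustive
sweep or by an all-solutions SAT search, so both update schemes share one
attractor set. The probability that a phenotype emerges is estimated by its
relative basin size p = ω/Ω, the fraction of initial states converging to
attractors of that functional class.

One variable is continuous: the stimulatory capacity of CD80/86, which
CTLA-4 dimers progressively capture from CD28. It decays as the logistic
sigmoid

    CD8086(t) = 1 / (exp(β (t − t_d)) + 1),      dc/dt = −β c (1 − c),

with rate β = 50 and half-decay time t_d = 10 steps by default, and enters
the Boolean layer through a threshold θ = 0.5 (Glass-style hybrid coupling).
This turns sustained activation into the checkpoint arrest: activation
completes by step t_ac ≈ 8, the switch fires at t_d, and the network shuts
down node by node.

## Worked example

```python
from tcellnet import build_model, run_scenario, enumerate_model_attractors

model = build_model()                      # 30-node core, 46-node full model

res = run_scenario("ndrg1_overexpression") # Ndrg1 forced on at stimulation
print(res.label)
print({m: res.final[m] for m in ("AP1", "NFAT", "NFKB", "IL2G", "CD25", "STAT5")})

census = enumerate_model_attractors(model)
print(len(census))
```

prints

```
anergy_no_cd28
{'AP1': 1, 'NFAT': 1, 'NFKB': 1, 'IL2G': 0, 'CD25': 0, 'STAT5': 0}
18
```

Forcing the anergy factor Ndrg1 on at the onset of full TCR/CD28 stimulation
leaves the three activation transcription factors active but silences the
IL-2 gene and its CD25/STAT5 feedback arm — a partial-activation (anergic)
phenotype. The attractor census finds 18 attractors: the activation pair,
the anergy pair, the checkpoint pair (differing only in the AMPK state),
eight no-activation attractors across input contexts, and one attractor per
effector phenotype.

The same operations are available from the shell:

```
tcellnet scenario --name checkpoint        # activation then CTLA-4 shutdown
tcellnet attractors --census               # classified attractor census
tcellnet basins --model bundled-core --samples 1000000 --seed 7
tcellnet reduce                            # 12-node attractor-equivalent core
```

`tcellnet basins` reports, for the 30-node core under synchronous updating,
the basin mass of each functional class with binomial standard errors; with
the bundled rules the checkpoint-context and activation classes take 12.5 %
each, the two anergy routes ≈ 1.5 % and ≈ 1.7 %, and the remainder is
unactivated (see `docs/methods.md` for what these classes mean and how the
trajectory-level classifier assigns them).

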