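# repsim — indirect reciprocity with quantitative reputation assessment

`repsim` is an agent-based simulator for studying how **nuanced reputations
stabilize cooperation** when social information is private and noisy.  It is
aimed at researchers in evolutionary game theory and social evolution who
want a fast, reproducible implementation of reputation dynamics under the
"leading eight" social norms, with reputations kept as integer scores rather
than binary good/bad labels.

## The model

A well-mixed population of `N` players repeatedly plays the **donation
game**: each round a random donor either pays cost `c` to give a benefit
`b > c` to a random recipient, or defects.  Every player `i` privately
tracks an integer reputation score `r_ij ∈ [V, A]` for every player `j`
(the **image matrix** `M(t)`), and judges `j` *good* when `r_ij ≥ S`, *bad*
otherwise.  In the symmetric frame `V = -R`, `A = R`, `S = 0`; with `V = 0,
A = 1, S = 1` the engine reduces exactly to the classical binary-reputation
baseline.

Behavior and judgment follow a **social norm** — an assessment rule
`α(J_donor, J_recipient, action) → ±1` that increments or decrements the
donor's score in the eyes of an observer, and an action rule
`β(J_self, J_recipient) → C/D`.  The package ships the leading-eight norms
L1–L8 plus ALLC and ALLD in one table formalism.  Information is imperfect:
third parties observe an interaction only with probability `q` and
misperceive the action with probability `ε`, independently and privately.

Long-run statistics give pairwise cooperation rates `x̂_ij` and payoffs

    π_i = 1/(N-1) · Σ_{j≠i} (b·x̂_ji − c·x̂_ij).

Norm competition is analyzed in the **rare-mutation limit** of a
pairwise-comparison (Fermi) imitation process with selection strength `s`:
a mutant norm `M` fixes in a resident population `R` with probability

    ρ_MR = 1 / (1 + Σ_{i=1}^{N-1} Π_{k=1}^{i} exp(−s·(π_M(k) − π_R(k)))),

and evolution reduces to a three-state Markov chain over the homogeneous
populations {L_i, ALLC, ALLD} whose stationary distribution is the
**selection–mutation equilibrium**.  A recovery module quantifies how a
homogeneous population heals a single private disagreement under perfect
information, and an exact brute-force Markov-chain oracle over the full
image-matrix state space validates the simulator on tiny instances.

## Worked example

Compete L1 against ALLC and ALLD at the standard parameter set
(`N=50, R=5, S=0, ε=0.05, q=0.9, b=5, c=1, s=1`):

```bash
repsim evolve --norm L1 --seed 1
```

```
abundance L1: 0.8095
abundance ALLC: 0.0235
abundance ALLD: 0.1670
equilibrium cooperation: 0.8330
```

L1 is adopted more than 80% of the time: quantitative assessment lets L1
players keep a correct self-image and single out defectors despite noise,
so L1 mutants invade ALLD populations well above the neutral rate `1/N`
while remaining immune to ALLD.  The equilibrium cooperation rate (83%)
weights each homogeneous population's self-cooperation by its abundance.

The same machinery from Python:

```python
from repsim import (AssessmentFrame, GameParams, Population,
                    run_reputation_dynamics)

pop = Population.from_counts([("L1", 30), ("ALLC", 30), ("ALLD", 30)])
stats = run_reputation_dynamics(pop, GameParams(eps=0.05, q=0.9),
                                AssessmentFrame.symmetric(5),
                                T=220_000, burn_in=20_000, seed=1)
print(stats.avg_judgment[0:30, 60:90].mean())   # L1's view of ALLD: 0.000
print(stats.avg_judgment[0:30, 0:30].mean())    # L1's view of L1:   1.000
```

Other entry points: `repsim norms list|show`, `repsim reputation`,
`repsim recover`, `repsim sweep`; see `docs/methods.md` for the model
details and numerical choices.

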