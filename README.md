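# tcommit

Dynamical modelling of T-cell lineage commitment: a four-gene
regulatory network (TCF-1, GATA-3, BCL11B, PU.1) driven by Notch
signalling, with every combinatorial logic for BCL11B regulation
compiled into Shea–Ackers rate equations, a constrained two-leg fitting
workflow, selection filters, and bifurcation analysis that classifies
commitment as reversible or irreversible.

## The problem

T-cell precursors entering the thymus (ETP/DN1 stage) retain
alternative fates until, under sustained Notch signalling, they cross
the DN2a→DN2b commitment threshold: BCL11B switches on with a marked
delay relative to TCF-1 and GATA-3, PU.1 is silenced, and the committed
state then persists even if Notch is withdrawn. `tcommit` asks which
regulatory logic at the BCL11B promoter can explain both the delay and
the irreversibility, for users who work on gene-regulatory-network
inference and cell-fate dynamics.

## The model

Each gene's expression obeys production-minus-decay dynamics with a
thermodynamic (Shea–Ackers) occupancy ratio, e.g. for BCL11B under the
OR logic:

    dB/dt = f_B · (κ₁N·ν + κ₂[TCF-1]^{n_T} + κ₃[GATA-3]^{n_G}) /
                  (1 + κ₁N·ν + κ₂[TCF-1]^{n_T} + κ₃[GATA-3]^{n_G}) − γ_B·B

where ν(t) is the sigmoidal Notch signal normalised to its maximum N,
and the Hill exponents are 1 (monomer) or 2 (dimer). All 32
combinations of {8 AND/OR gate forms over Notch, TCF-1, GATA-3} × {4
valency pairs} are enumerated and compiled automatically to disjunctive
normal form, one kinetic weight κ per minterm. TCF-1 and GATA-3 carry
Notch drive, mutual activation and PU.1 repression (monomers
throughout); PU.1 has only self-activation and is repressed by the
other three, so PU.1 = 0 is an invariant of the dynamics — silenced
PU.1 can never reactivate without an external drive.

Fitting proceeds in two constrained legs (PU.1 clamped while fitting
TCF-1/GATA-3/BCL11B, then the converse), with parameter bounds derived
from positivity of the implied Notch signal and a ≤ 3.5-fold cap on its
rise, followed by 95%-confidence-band and half-life plausibility
filters. See `docs/methods.md` for the full account.

## Worked example

```python
from tcommit import generate_reference_dataset, CommitmentModel

data = generate_reference_dataset(seed=1)          # five-stage synthetic dataset, CV 25%
model = CommitmentModel(data.series, logic="6d")
res = model.fit(seed=1)
print(res.summary())
```

```
          T-cell commitment model fit
==========================================================
configuration: 6d   dimer TCF-1 AND (Notch OR dimer GATA-3)
genes fitted: TCF-1, GATA-3, BCL11B (PU.1 clamped); n obs = 15
objective (normalised SSR): T=0.009559, G=0.008866, B=0.004963   total=0.02339
Notch fold increase day0->day4: 3.500 (cap 3.5)
----------------------------------------------------------
parameter         estimate
eta1N             0.024288
...
fold                   3.5
----------------------------------------------------------
effective half-lives (h): T=46.80, G=17.87, B=20.11
95% CI filter: T=pass, G=pass, B=pass
accepted: True
==========================================================
```

The fit is *accepted*: its trajectory threads the 95% confidence band
of every observed point for all three genes, its effective half-lives
fall in the plausible hours range, and the fitted Notch signal rises by
at most 3.5-fold (here exactly at the cap).

The headline bifurcation analysis runs from the packaged mean
parameters of the four configurations that survive selection:

```bash
$ tcommit bifurcate --config all --params winning --clamp-pu1
6d: T=irreversible, G=irreversible, B=irreversible, P=clamped-off
7b: T=irreversible, G=irreversible, B=irreversible, P=clamped-off
7d: T=irreversible, G=irreversible, B=irreversible, P=clamped-off
8b: T=irreversible, G=irreversible, B=reversible, P=clamped-off
```

Sweeping the Notch scale from full strength down to zero, BCL11B stays
on its committed high branch in the three configurations where Notch
enters through an OR (the accumulated TCF-1/GATA-3 dimer term sustains
it), and shuts off only in the pure-AND form 8b, whose production is
analytically zero without Notch — 3 of the 4 winning configurations
lock the fate in.

Other entry points: `tcommit enumerate` lists the 32 configurations,
`tcommit synth` writes synthetic stage data, `tcommit fit` /
`tcommit filter` run the estimation and selection on a CSV, and
`tcommit export-sbml` writes a model as SBML Level 3 Version 1.

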