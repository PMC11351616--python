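# sigbnet

Data-driven kinetic analysis of the *Bacillus subtilis* σ^B
partner-switching network.

In *B. subtilis*, availability of the general-stress sigma factor SigB
is controlled by its anti-sigma factor RsbW (active as a dimer W₂, which
sequesters SigB and phosphorylates the anti-anti-sigma factor RsbV) and
by the phosphatases RsbU/RsbP, which reactivate RsbV so it can displace
SigB from the W₂·SigB complex. `sigbnet` turns measured protein time
series for SigB, RsbW, RsbV, RsbU and RsbP into the forcing of a
mass-action ODE system for the seven free/bound species

    SigB_f, W₂_f, V_f, W₂SigB, W₂V, W₂V₂, VP

closed by the mass balances

    S(t)   = SigB_f + W₂SigB
    AS(t)  = 2(W₂_f + W₂V + W₂V₂ + W₂SigB)
    AAS(t) = V_f + W₂V + 2·W₂V₂ + VP

where S, AS, AAS are the measured totals of SigB, RsbW and RsbV.
Differentiating the balances replaces explicit synthesis/degradation
with the measured dS/dt, dAS/dt, dAAS/dt, obtained from cubic
least-squares B-spline fits evaluated analytically on a 1-minute grid.
On top of the core model the package provides perturbation scenarios
(scaling component amounts and rate constants), an initialization
diagnostic for the phosphorylated-RsbV starting pool, and a synthetic
replicate-data generator with known ground truth. It is intended for
systems biologists studying sigma-factor regulation and as a template
for driving kinetic models directly with expression time courses.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Generate a synthetic dataset, run the baseline simulation and the
perturbation grid:

```sh
$ sigbnet synth --seed 1 --out data.csv --truth truth.csv
wrote 210 rows to data.csv
wrote ground-truth curves to truth.csv

$ sigbnet simulate --data data.csv --out traj.csv
wrote traj.csv; final free SigB = 2.8340 y, max conservation residual = 1.08e-05 y, 0 feasibility flags

$ sigbnet scenarios --data data.csv --out runs
ran 15 scenarios (15 succeeded); wrote runs/summary.csv
```

`data.csv` holds 5 proteins × 14 time points × 3 replicates. The
simulate line says: at 130 min the free SigB pool is 2.834 on the
dimensionless y scale (raw intensity ÷ 3.7·10⁴); the model totals
deviated from the measured S/AS/AAS curves by at most ~10⁻⁵ y (pure
solver error — the equations conserve the totals identically); and no
species ever went negative. `runs/summary.csv` lists final and
window-mean free SigB per scenario: lowering RsbU, RsbV (AAS) or k₇₊
lowers final free SigB monotonically, raising the RsbW dose (AS ×5)
lowers it further, and shifting the SigB–W₂ binding equilibrium
(k₅₊ ×100, k₅₋ ÷100) sequesters the most, leaving 2.213 y free.

The initialization rule can be probed directly:

```sh
$ sigbnet check-init --data data.csv --vp-fraction 1.0
no artifact at vp_fraction=1
$ sigbnet check-init --data data.csv --vp-fraction 0.2
ARTIFACT at vp_fraction=0.2: 0 negative excursions (components: none), max relative conservation residual 0.0983, solver failed: False
```

Starting with only 20% of RsbV phosphorylated (and free V at zero)
leaves 80% of the measured RsbV unaccounted; the integration then
violates the RsbV mass balance by ~10% of its range — the solution is an
artifact. Only the fully phosphorylated start is consistent.

Library use mirrors the CLI:

```python
from sigbnet import (GeneratorSpec, generate_dataset, profiles_from_table,
                     KineticConstants, initial_state, simulate)

table, truth = generate_dataset(GeneratorSpec(seed=1))
table.to_csv("data.csv", index=False)
driving = profiles_from_table("data.csv")
result = simulate(driving, KineticConstants(), initial_state(driving))
print(result.final_state.sigb_free)   # 2.834046...
```

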