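# atnsim

Allometric trophic network simulator: randomly assembled, body-mass-structured
plant–animal communities, bioenergetic population dynamics integrated to a
stationary state, and power-law fits of community-level ecosystem functions
against animal species richness.

## Model in one paragraph

Each replicate community draws plant body masses log-uniformly from
[10⁰, 10⁶] and animal masses from [10², 10¹²]. Feeding links between an
animal and any resource (plant or animal) are weighted by an asymmetric
hump-shaped (Ricker) efficiency kernel of the consumer:resource mass ratio,
maximal at a ratio of 100; links weaker than 0.01 are pruned. Feeding follows
a multi-prey saturating functional response with a sampled Hill exponent,
conspecific interference, and mass-scaled capture coefficients and handling
times. Animals convert plant and animal prey with efficiencies 0.45 / 0.85
and pay quarter-power metabolic costs; plants grow by Liebig-minimum Monod
uptake of two chemostat nutrients. The stiff system is integrated with BDF
(tolerances 1e-10) to t = 150,000 with an absorbing extinction threshold of
1e-6. Six functions — animal/plant biomass stocks, gross herbivory and
intraguild-predation flows, and metabolic losses — are averaged over the
final 10,000 time units and fitted as `x = a · S_A^α` by log–log OLS.
Replicates whose final state contains a surviving plant with no surviving
consumer are flagged and excluded from the fits.

## CLI

```sh
atnsim simulate --seed 1 --sa 15 --out run/     # one replicate
atnsim sweep --preset desk --seed 1 --out sweep/ # reduced gradient sweep
atnsim sweep --levels 10,40,70,100 --reps 20 --out sweep/
atnsim fit --records sweep/records.csv --out fits.csv
atnsim fixtures --out fixtures/                  # tiny deterministic webs
```

`sweep --preset full` reproduces the published design (91 levels × 300
replicates — cluster-scale, expect days on one core). A YAML config file
(`--config`) can override sampling distributions, solver settings and
sensitivity variants (plant richness, strict-herbivore fraction, nutrient
turnover); a config hash is recorded in the output manifest.

## Package layout

| module | contents |
|---|---|
| `atnsim.community` | mass sampling, Ricker feeding-efficiency kernel, link pruning, per-replicate parameter draws |
| `atnsim.rates` | capture/handling/metabolic/growth kernels, functional response, nutrient parameters |
| `atnsim.dynamics` | right-hand side of the coupled biomass–nutrient ODE system |
| `atnsim.simulator` | initialisation, stiff integration with extinction events, discard rule |
| `atnsim.functions` | window-averaged stocks, flows, metabolic losses, mean body masses |
| `atnsim.experiment` | sweep orchestration, seed policy, OLS power-law fits |
| `atnsim.io`, `atnsim.cli` | plain-text community files, trajectory export, command line |
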