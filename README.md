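# llextract

Liquid–liquid equilibrium (LLE) toolkit for designing solvent extraction
of fermentation acids from dilute aqueous broth — the separation problem
behind recovering butyric acid (~2.7 wt% in water) with a high-boiling
ester solvent such as octyl acetate, where distillation alone would boil
off hundreds of kilograms of water per kilogram of product.

The package is aimed at process engineers and thermodynamics practitioners
who need to go from measured (or simulated) tie-line data to an extractor
design and a recovery cost:

- **`nrtl`** — multicomponent NRTL activity coefficients
  (G_ij = exp(−α_ij τ_ij)), the reduced Gibbs energy of mixing
  ΔG_mix/RT = Σ_k Σ_i L^k x_i^k (ln x_i^k + ln γ_i^k), and a
  tangent-plane-distance stability test.
- **`flash`** — isothermal two-liquid-phase flash solving
  x_i^I = z_i/(1 + (K_i − 1)L^II), x_i^II = K_i x_i^I,
  K_i = γ_i^I/γ_i^II by successive substitution with an inner
  Rachford–Rice solve, plus binodal-curve/tie-line tracing for ternary
  diagrams.
- **`estimation`** — the non-iterative K-value parameter estimator: the
  feed is placed on each measured tie-line by collinearity, the phase
  split comes from the lever rule on Euclidean distances, K is evaluated
  once at the measured compositions, and NRTL parameters are chosen to
  minimize the RMS deviation between computed and measured tie-line
  compositions subject to the fitted model's Gibbs energy of mixing being
  minimal at every measured feed — no flash inside the objective.
- **`cascade`** — steady-state countercurrent multistage equilibrium
  extractor (feed at the top stage, solvent at the bottom), recovery,
  distribution coefficient/selectivity, lever-rule material balances.
- **`economics`** — annualized recovery cost:
  (investment/payout + utilities)/(product rate × operating hours).
- **`synth`** — seeded generators for demixing NRTL systems and noisy
  tie-line datasets (0.003 mole-fraction standard uncertainty) with the
  ground truth retained, so everything is testable without external data.

See `docs/methods.md` for model details and numerical choices.

## Worked example

```python
import numpy as np
from llextract import *

# a water/solute/ester system with a known miscibility gap, and six
# noisy tie-lines emulating a measured LLE table
system = make_demixing_system("ternary_broth_like")
comps, truth = system
synth = generate_tielines(system, n=6, noise_sd=0.003, seed=1)

# recover NRTL parameters from the noisy tie-lines
fit = estimate_nrtl(synth.data, FitConfig(n_starts=16, seed=42))
print("RMS composition deviation:", round(fit.objective, 5))
print("Gibbs-feasible tie-lines: %d/%d" % (sum(fit.gibbs_feasible), len(synth.data)))

# flash a feed with the fitted model
fr = lle_flash([0.90, 0.04, 0.06], 298.15, fit.params)
print("x_aq =", np.round(fr.x_I, 4), " x_org =", np.round(fr.x_II, 4))
D, S = distribution_and_selectivity(fr.tieline(), "solute", "water", comps)
print("D =", round(D, 2), " S =", round(S, 1))

# an 8-stage countercurrent extractor on a dilute broth
feed = Stream.from_composition(comps, 100.0, [0.97, 0.03, 0.0], "feed")
solv = Stream.from_composition(comps, 20.0, [0.0, 0.0, 1.0], "solvent")
res = simulate_extractor(feed, solv, 8, 298.15, fit.params)
print("8-stage recovery:", round(recovery(feed, res.extract, "solute"), 4))

# annualized recovery cost from the packaged cost table
from llextract.io import read_cost_table, packaged_path
table, rate = read_cost_table(packaged_path("recovery_costs.yaml"))
print("unit cost: $%.2f/kg at %g kg/h" % (unit_recovery_cost(table, rate), rate))
```

Output:

```
RMS composition deviation: 0.00112
Gibbs-feasible tie-lines: 6/6
x_aq = [0.9632 0.0317 0.0051]  x_org = [0.0179 0.1556 0.8265]
D = 4.9  S = 263.5
8-stage recovery: 0.9588
unit cost: $0.23/kg at 265 kg/h
```

The fit deviation (0.0011) sits below the 0.003 measurement noise; all
six tie-lines pass the Gibbs-minimum feasibility check. The flash shows
the solute partitioning into the ester phase (distribution coefficient
D ≈ 5, water/solute selectivity S ≈ 260), which is why a modest 0.2
solvent-to-feed ratio recovers 96% of the solute in eight stages. The
$0.23/kg combines 1.032 M$ of investment over a 5-year payout with
0.273 M$/yr of utilities at 265 kg/h and 8000 h/yr.

The same steps are available from the shell:

```bash
llextract synth --preset ternary_broth_like --n 6 --seed 1 --out tielines.csv
llextract fit --tielines tielines.csv --components water,solute,ester --out fitted.json
llextract flash --params fitted.json --z 0.90,0.04,0.06
llextract extract --streams streams.json --params fitted.json --stages 8 --solute solute --out cascade
llextract cost --costs src/llextract/data/recovery_costs.yaml
```

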